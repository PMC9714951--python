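"""Tumor-specific hypermethylated (TS-Hyper) probe calling and downstream
gene-level integration.

A probe is TS-Hyper for a cohort when it is unmethylated (β ≤ 0.2) in
*every* cohort normal and its mean tumor β is at least 0.4 above the mean
normal β. Both thresholds are inclusive. Genes carrying at least two
TS-Hyper CpG-island probes are "potentially methylated"; those whose
tumor:normal expression ratio is < 0.6667 with p < 0.05 are concordantly
downregulated. Cross-cohort overlaps of island TS-Hyper sets are exact set
algebra after intersecting the probe universes.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    ValidationError,
)


@dataclasses.dataclass(frozen=True)
class TsHyperResult:
    """TS-Hyper probe set for one cohort with per-probe evidence."""

    cohort: str
    #: index probe_id; columns normal_max_beta, tumor_mean, normal_mean
    #: (+ region when annotation was supplied); TS-Hyper probes only.
    table: pd.DataFrame
    universe: pd.Index          # every probe that was assessed
    normal_max: float
    delta: float
    tumor_samples: tuple[str, ...]
    normal_samples: tuple[str, ...]

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    def region_counts(self) -> pd.Series:
        if "region" not in self.table.columns:
            raise ValidationError(
                "no region strata available; call call_ts_hyper with annotation"
            )
        return self.table["region"].value_counts()

    def island_probes(self) -> pd.Index:
        if "region" not in self.table.columns:
            raise ValidationError(
                "no region strata available; call call_ts_hyper with annotation"
            )
        return self.table.index[(self.table["region"] == "island").to_numpy()]


def call_ts_hyper(
    beta: BetaMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    normal_max: float = 0.2,
    delta: float = 0.4,
    annotation: ProbeAnnotation | None = None,
    cohort: str = "",
) -> TsHyperResult:
    """Call TS-Hyper probes by the two-clause rule.

    clause 1: β ≤ ``normal_max`` in every normal (inclusive);
    clause 2: mean(tumor β) − mean(normal β) ≥ ``delta`` (inclusive).
    """
    tumor_samples = list(tumor_samples)
    normal_samples = list(normal_samples)
    if not tumor_samples or not normal_samples:
        raise ValidationError("need at least one tumor and one normal sample")
    sub_t = beta.select(samples=tumor_samples)
    sub_n = beta.select(samples=normal_samples)
    for sub, label in ((sub_t, "tumor"), (sub_n, "normal")):
        if bool(sub.df.isna().to_numpy().any()):
            raise ValidationError(
                f"missing β values among {label} samples; apply the "
                "completeness filter before TS-Hyper calling"
            )
    n_max = sub_n.values.max(axis=1)
    n_mean = sub_n.values.mean(axis=1)
    t_mean = sub_t.values.mean(axis=1)
    called = (n_max <= normal_max) & (t_mean - n_mean >= delta)

    table = pd.DataFrame(
        {
            "normal_max_beta": n_max[called],
            "tumor_mean": t_mean[called],
            "normal_mean": n_mean[called],
        },
        index=beta.probe_ids[called],
    )
    if annotation is not None:
        table["region"] = annotation.region_of(table.index).to_numpy()
    return TsHyperResult(
        cohort=cohort,
        table=table,
        universe=beta.probe_ids,
        normal_max=normal_max,
        delta=delta,
        tumor_samples=tuple(tumor_samples),
        normal_samples=tuple(normal_samples),
    )


def genes_from_probes(
    ts: TsHyperResult,
    annotation: ProbeAnnotation,
    min_island_probes: int = 2,
) -> dict[str, int]:
    """Genes with at least ``min_island_probes`` island TS-Hyper probes.

    Returns ``{gene: island-probe count}``. A probe annotated to several
    genes credits each of them once; probes without gene annotation are
    ignored.
    """
    if min_island_probes < 1:
        raise ValueError("min_island_probes must be >= 1")
    island = annotation.region_of(ts.probes) == "island"
    island_probes = ts.probes[island.to_numpy()]
    counts: dict[str, int] = {}
    for genes in annotation.genes_of(island_probes):
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    return {g: c for g, c in counts.items() if c >= min_island_probes}


@dataclasses.dataclass(frozen=True)
class MethylatedGeneCall:
    """Expression evidence for one potentially methylated gene."""

    gene: str
    n_island_probes: int | None
    expression_ratio: float | None   # mean(tumor) / mean(normal)
    p_value: float | None
    downregulated: bool
    evaluable: bool


def integrate_expression(
    genes: Iterable[str] | Mapping[str, int],
    expression: ExpressionMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    ratio_max: float = 0.6667,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag concordantly downregulated genes among the methylated candidates.

    ratio = mean(tumor) / mean(normal) on the raw scale; the p-value is a
    Welch t-test on log2(x + 1). ``downregulated`` requires ratio <
    ``ratio_max`` (strict) and p < ``alpha`` (strict). Genes missing from
    the expression matrix, or with a zero normal mean, are reported as
    unevaluable rather than raising.
    """
    island_counts = dict(genes) if isinstance(genes, Mapping) else {g: None for g in genes}
    tumor_samples = list(tumor_samples)
    normal_samples = list(normal_samples)
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValidationError("need at least 2 samples per expression group")

    rows: list[MethylatedGeneCall] = []
    have = expression.gene_symbols
    for gene in sorted(island_counts):
        n_probes = island_counts[gene]
        if gene not in have:
            rows.append(MethylatedGeneCall(gene, n_probes, None, None, False, False))
            continue
        t = expression.df.loc[gene, tumor_samples].to_numpy(dtype=float)
        n = expression.df.loc[gene, normal_samples].to_numpy(dtype=float)
        n_mean = float(n.mean())
        if n_mean == 0:
            rows.append(MethylatedGeneCall(gene, n_probes, None, None, False, False))
            continue
        ratio = float(t.mean()) / n_mean
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-constant groups trigger scipy precision warnings; the
            # resulting p is replaced below when undefined
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(
                stats.ttest_ind(np.log2(t + 1), np.log2(n + 1), equal_var=False).pvalue
            )
        if np.isnan(p):
            p = 1.0
        flagged = (ratio < ratio_max) and (p < alpha)
        rows.append(MethylatedGeneCall(gene, n_probes, ratio, p, flagged, True))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("gene")


def cross_cohort_overlap(
    results: Sequence[TsHyperResult],
    restrict_to: str | None = "island",
) -> dict:
    """Exact overlap counts of TS-Hyper sets across cohorts.

    Probe universes are intersected first, so a probe only counts when it
    was assessable in every cohort. ``restrict_to`` keeps one region class
    (requires results carrying region strata); ``None`` keeps all probes.
    Returns per-set, pairwise, all-way intersection, union and exclusive
    (Venn-region) counts.
    """
    if len(results) < 2:
        raise ValidationError("need at least two cohorts to overlap")
    universe = results[0].universe
    for res in results[1:]:
        universe = universe.intersection(res.universe)
    if len(universe) == 0:
        raise ValidationError("cohort probe universes are disjoint")

    sets: dict[str, frozenset[str]] = {}
    for i, res in enumerate(results):
        name = res.cohort or f"cohort_{i + 1}"
        probes = res.island_probes() if restrict_to == "island" else (
            res.probes if restrict_to is None
            else res.table.index[(res.table["region"] == restrict_to).to_numpy()]
        )
        sets[name] = frozenset(pd.Index(probes).intersection(universe))

    names = list(sets)
    inter_all = frozenset.intersection(*sets.values())
    union_all = frozenset.union(*sets.values())
    pairwise = {
        f"{a}&{b}": len(sets[a] & sets[b]) for a, b in itertools.combinations(names, 2)
    }
    exclusive = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(*(sets[c] for c in combo))
            outside = frozenset.union(
                *(sets[c] for c in names if c not in combo), frozenset()
            )
            exclusive["&".join(combo)] = len(inside - outside)
    # inclusion–exclusion consistency is structural; expose it for callers
    assert sum(exclusive.values()) == len(union_all)
    return {
        "universe_size": len(universe),
        "per_set": {name: len(sets[name]) for name in names},
        "pairwise": pairwise,
        "intersection_all": len(inter_all),
        "union": len(union_all),
        "exclusive": exclusive,
    }
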