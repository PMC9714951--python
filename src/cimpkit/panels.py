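"""Marker-probe panel construction, restriction and sample classification.

A panel is an ordered CpG-island probe list selected by a two-clause rule:
β > ``high_beta`` in at least ``min_high_count`` positive samples AND
β < ``low_beta`` in *all* negative samples (no occupancy relaxation on the
negative side). Candidates are ranked — by two-group p-value or by mean
difference — and the top ``top_k`` kept. Panels can be reselected within a
restricted probe universe (e.g. the intersection of two array platforms)
with a relaxed positive occupancy.

Scoring a sample means averaging its β over the panel probes that are
present; classification uses a CIMP panel and a subtype panel:

* CIMP-panel mean < ``non_cimp_cutoff`` → ``non_CIMP``;
* CIMP-panel mean ≥ ``cimp_cutoff`` → CIMP, then subtype-panel mean ≥
  ``subtype_cutoff`` → ``CIMP_subtypeA_like`` else ``CIMP_subtypeB_like``;
* anything between the cutoffs → ``indeterminate``;
* < 50% of CIMP-panel probes measurable → ``unscorable``.

The 0.2 / 0.35 cutoffs are working defaults placed between the observed
non-CIMP cloud (< 0.2) and CIMP cloud (> 0.5) of panel averages; they are
parameters, not constants of nature.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ProbeAnnotation, ValidationError

RANKINGS = ("group_p_value", "mean_difference")

CLASS_LABELS = (
    "CIMP_subtypeA_like",
    "CIMP_subtypeB_like",
    "non_CIMP",
    "indeterminate",
    "unscorable",
)


@dataclasses.dataclass(frozen=True)
class PanelDefinition:
    """An ordered marker-probe list plus the parameters that produced it."""

    name: str
    probes: tuple[str, ...]
    #: per-candidate stats in rank order: p_value, mean_difference, n_high_pos
    stats: pd.DataFrame
    high_beta: float
    low_beta: float
    min_high_count: int
    top_k: int | None
    rank_by: str
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def is_empty(self) -> bool:
        return len(self.probes) == 0


def select_panel(
    beta: BetaMatrix,
    positive_samples: Sequence[str],
    negative_samples: Sequence[str],
    annotation: ProbeAnnotation,
    high_beta: float = 0.5,
    low_beta: float = 0.2,
    min_high_count: int | None = None,
    top_k: int | None = None,
    rank_by: str = "group_p_value",
    name: str = "panel",
) -> PanelDefinition:
    """Select an island marker panel by the high/low two-clause rule.

    ``min_high_count`` defaults to *all* positives; ``high_beta`` is a
    strict ``>`` and ``low_beta`` a strict ``<``. Zero candidates yield an
    empty panel with a warning, not an exception.
    """
    positive_samples = list(positive_samples)
    negative_samples = list(negative_samples)
    if not positive_samples or not negative_samples:
        raise ValidationError("need non-empty positive and negative sample sets")
    if min_high_count is None:
        min_high_count = len(positive_samples)
    if not 1 <= min_high_count <= len(positive_samples):
        raise ValueError(
            f"min_high_count must be in [1, {len(positive_samples)}], got {min_high_count}"
        )
    if rank_by not in RANKINGS:
        raise ValueError(f"rank_by must be one of {RANKINGS}")

    island = annotation.probes_in_region("island").intersection(beta.probe_ids)
    sub = beta.select(probes=list(island))
    pos = sub.select(samples=positive_samples)
    neg = sub.select(samples=negative_samples)
    for grp, label in ((pos, "positive"), (neg, "negative")):
        if bool(grp.df.isna().to_numpy().any()):
            raise ValidationError(f"missing β values among {label} samples")

    n_high = (pos.values > high_beta).sum(axis=1)
    neg_ok = (neg.values < low_beta).all(axis=1)
    candidate = (n_high >= min_high_count) & neg_ok
    cand_ids = sub.probe_ids[candidate]
    if len(cand_ids) == 0:
        warnings.warn(
            f"panel {name!r}: no probes satisfy the selection clauses", stacklevel=2
        )
        empty = pd.DataFrame(
            columns=["p_value", "mean_difference", "n_high_pos"]
        ).rename_axis("probe_id")
        return PanelDefinition(
            name, (), empty, high_beta, low_beta, min_high_count, top_k, rank_by
        )

    t = pos.values[candidate]
    n = neg.values[candidate]
    mean_diff = t.mean(axis=1) - n.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant candidates trigger scipy precision warnings; their
        # undefined p-values are replaced below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(t, n, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, np.asarray(p, dtype=float))

    table = pd.DataFrame(
        {
            "p_value": p,
            "mean_difference": mean_diff,
            "n_high_pos": n_high[candidate],
        },
        index=cand_ids,
    )
    key = "p_value" if rank_by == "group_p_value" else "mean_difference"
    ascending = rank_by == "group_p_value"
    table = table.sort_index().sort_values(key, ascending=ascending, kind="mergesort")
    if top_k is not None:
        table = table.iloc[:top_k]
    return PanelDefinition(
        name=name,
        probes=tuple(table.index),
        stats=table,
        high_beta=high_beta,
        low_beta=low_beta,
        min_high_count=min_high_count,
        top_k=top_k,
        rank_by=rank_by,
    )


def restrict_panel(
    beta: BetaMatrix,
    universe: Sequence[str] | pd.Index,
    positive_samples: Sequence[str],
    negative_samples: Sequence[str],
    annotation: ProbeAnnotation,
    high_beta: float = 0.5,
    low_beta: float = 0.2,
    min_high_count: int | None = None,
    top_k: int | None = None,
    rank_by: str = "group_p_value",
    name: str = "restricted_panel",
) -> PanelDefinition:
    """Re-run panel selection within a restricted probe universe.

    Used when the target dataset only measures a probe subset (e.g. the
    intersection of two array generations); ``min_high_count`` is typically
    relaxed below the full positive count here.
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValidationError("restriction universe is empty")
    available = beta.probe_ids.intersection(universe)
    if len(available) == 0:
        raise ValidationError("no overlap between matrix probes and universe")
    restricted = beta.select(probes=list(available))
    panel = select_panel(
        restricted,
        positive_samples,
        negative_samples,
        annotation,
        high_beta=high_beta,
        low_beta=low_beta,
        min_high_count=min_high_count,
        top_k=top_k,
        rank_by=rank_by,
        name=name,
    )
    return dataclasses.replace(panel, provenance=f"restricted to {len(universe)} probes")


def panel_means(
    beta: BetaMatrix, panel: PanelDefinition
) -> tuple[pd.Series, pd.Series]:
    """Per-sample mean β over the measurable panel probes, plus coverage.

    Panel probes absent from the matrix, or missing in a given sample,
    shrink the average's denominator; coverage is the measurable fraction.
    """
    if panel.is_empty:
        n = len(beta.sample_ids)
        return (
            pd.Series(np.nan, index=beta.sample_ids),
            pd.Series(0.0, index=beta.sample_ids),
        )
    present = pd.Index(panel.probes).intersection(beta.probe_ids)
    sub = beta.df.loc[present] if len(present) else beta.df.iloc[:0]
    measured = sub.notna().sum(axis=0)
    means = sub.mean(axis=0, skipna=True)
    coverage = measured / len(panel.probes)
    return means, coverage


def score_and_classify(
    beta: BetaMatrix,
    cimp_panel: PanelDefinition,
    subtype_panel: PanelDefinition,
    cimp_cutoff: float = 0.35,
    subtype_cutoff: float = 0.35,
    non_cimp_cutoff: float = 0.2,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Score every sample on both panels and classify.

    Returns a DataFrame indexed by sample with ``cimp_mean``,
    ``subtype_mean``, the two coverages, and ``sample_class``.
    """
    if cimp_panel.is_empty:
        raise ValidationError("CIMP panel is empty; cannot classify")
    if non_cimp_cutoff > cimp_cutoff:
        raise ValueError("non_cimp_cutoff must not exceed cimp_cutoff")
    cimp_mean, cimp_cov = panel_means(beta, cimp_panel)
    sub_mean, sub_cov = panel_means(beta, subtype_panel)

    classes = []
    for sample in beta.sample_ids:
        if cimp_cov[sample] < min_coverage:
            classes.append("unscorable")
        elif cimp_mean[sample] < non_cimp_cutoff:
            classes.append("non_CIMP")
        elif cimp_mean[sample] >= cimp_cutoff:
            if subtype_panel.is_empty or sub_cov[sample] < min_coverage or np.isnan(
                sub_mean[sample]
            ):
                classes.append("indeterminate")
            elif sub_mean[sample] >= subtype_cutoff:
                classes.append("CIMP_subtypeA_like")
            else:
                classes.append("CIMP_subtypeB_like")
        else:
            classes.append("indeterminate")
    return pd.DataFrame(
        {
            "cimp_mean": cimp_mean,
            "subtype_mean": sub_mean,
            "cimp_coverage": cimp_cov,
            "subtype_coverage": sub_cov,
            "sample_class": classes,
        },
        index=beta.sample_ids,
    )


def write_panel(panel: PanelDefinition, tsv_path, json_path=None) -> None:
    """Write the panel as a rank/probe/stats TSV plus a JSON parameter sidecar."""
    import json
    from pathlib import Path

    tsv_path = Path(tsv_path)
    out = panel.stats.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.rename_axis("probe_id").to_csv(tsv_path, sep="\t")
    if json_path is not None:
        params = {
            "name": panel.name,
            "n_probes": len(panel),
            "high_beta": panel.high_beta,
            "low_beta": panel.low_beta,
            "min_high_count": panel.min_high_count,
            "top_k": panel.top_k,
            "rank_by": panel.rank_by,
            "provenance": panel.provenance,
        }
        Path(json_path).write_text(json.dumps(params, indent=2, sort_keys=True))
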