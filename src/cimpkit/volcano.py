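"""Tumor-vs-normal volcano analysis of β-values.

Per probe: Δβ = mean(tumor) − mean(normal), a two-sample p-value, and a
call of ``hyper`` (Δβ ≥ +δ, p < α), ``hypo`` (Δβ ≤ −δ, p < α) or ``none``.
Defaults follow the standard printed criteria for this kind of analysis:
δ = 0.4, α = 0.01, no multiple-testing correction (the raw-p cutoff *is*
the rule). The two groups are cohort-level tumor and normal sets; the test
is chosen by name because methylation studies rarely state theirs:
``welch_t`` (default), ``student_t``, or ``mann_whitney``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ProbeAnnotation, ValidationError

TESTS = ("welch_t", "student_t", "mann_whitney")
CALLS = ("hyper", "hypo", "none")


@dataclasses.dataclass(frozen=True)
class VolcanoResult:
    """Per-probe Δβ, p-value and call, plus the parameters that made them."""

    table: pd.DataFrame  # index probe_id; columns delta_beta, p_value, call
    tumor_samples: tuple[str, ...]
    normal_samples: tuple[str, ...]
    delta: float
    alpha: float
    test: str

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def called(self, kind: str) -> pd.Index:
        if kind not in CALLS:
            raise ValueError(f"unknown call kind {kind!r}")
        return self.table.index[(self.table["call"] == kind).to_numpy()]


def _group_pvalues(t: np.ndarray, n: np.ndarray, test: str) -> np.ndarray:
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (near-constant) probes are handled explicitly afterwards
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "welch_t":
            res = stats.ttest_ind(t, n, axis=1, equal_var=False)
        elif test == "student_t":
            res = stats.ttest_ind(t, n, axis=1, equal_var=True)
        elif test == "mann_whitney":
            res = stats.mannwhitneyu(t, n, axis=1, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    return np.asarray(res.pvalue, dtype=float)


def volcano(
    beta: BetaMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    delta: float = 0.4,
    alpha: float = 0.01,
    test: str = "welch_t",
) -> VolcanoResult:
    """Two-group differential methylation with effect and significance gates.

    Probes with zero variance in *both* groups get p = 1 by convention
    (degenerate inputs are never called).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tumor_samples = list(tumor_samples)
    normal_samples = list(normal_samples)
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValidationError("need at least 2 samples per group")
    sub_t = beta.select(samples=tumor_samples)
    sub_n = beta.select(samples=normal_samples)
    for sub, label in ((sub_t, "tumor"), (sub_n, "normal")):
        if bool(sub.df.isna().to_numpy().any()):
            raise ValidationError(
                f"missing β values in the {label} group; apply the "
                "completeness filter before the volcano analysis"
            )
    t = sub_t.values
    n = sub_n.values
    delta_beta = t.mean(axis=1) - n.mean(axis=1)
    p = _group_pvalues(t, n, test)
    degenerate = (t.std(axis=1) == 0) & (n.std(axis=1) == 0)
    p = np.where(degenerate | np.isnan(p), 1.0, p)

    call = np.full(len(delta_beta), "none", dtype=object)
    call[(delta_beta >= delta) & (p < alpha)] = "hyper"
    call[(delta_beta <= -delta) & (p < alpha)] = "hypo"
    table = pd.DataFrame(
        {"delta_beta": delta_beta, "p_value": p, "call": call},
        index=beta.probe_ids,
    )
    return VolcanoResult(
        table=table,
        tumor_samples=tuple(tumor_samples),
        normal_samples=tuple(normal_samples),
        delta=delta,
        alpha=alpha,
        test=test,
    )


def count_calls_by_region(
    result: VolcanoResult, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Hyper/hypo call counts and fractions per CpG-region stratum.

    Every probe in the volcano table must be annotated (the denominators
    are the per-region probe totals of the analyzed set).
    """
    regions = annotation.region_of(result.table.index)  # raises on gaps
    df = result.table.assign(region=regions.to_numpy())
    out = []
    for region, group in df.groupby("region", sort=True):
        n_total = len(group)
        n_hyper = int((group["call"] == "hyper").sum())
        n_hypo = int((group["call"] == "hypo").sum())
        out.append(
            {
                "region": region,
                "n_probes": n_total,
                "hyper": n_hyper,
                "hypo": n_hypo,
                "frac_hyper": n_hyper / n_total,
                "frac_hypo": n_hypo / n_total,
            }
        )
    return pd.DataFrame(out).set_index("region")
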