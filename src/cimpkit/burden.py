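"""Per-tumor hypermethylation burden and its covariate correlations.

The burden statistic summarizes how much of the normally-unmethylated
CpG-island landscape a tumor has hypermethylated: fix the reference set of
island probes with β < 0.2 in every normal sample (strict ``<``), then
count, per tumor, the reference probes with β > 0.5 (strict ``>``). The
count (or its fraction of the reference size) is the tumor's burden, and
can be regressed on clinical covariates — linearly on tumor size, or as a
log-linear ("exponential") fit on age.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ProbeAnnotation, ValidationError


def normal_unmethylated_probes(
    beta: BetaMatrix,
    normal_samples: Sequence[str],
    annotation: ProbeAnnotation,
    max_beta: float = 0.2,
) -> pd.Index:
    """Island probes with β < ``max_beta`` (strict) in every listed normal."""
    normal_samples = list(normal_samples)
    if not normal_samples:
        raise ValidationError("normal sample set is empty")
    island = annotation.probes_in_region("island").intersection(beta.probe_ids)
    sub = beta.select(probes=list(island), samples=normal_samples)
    if bool(sub.df.isna().to_numpy().any()):
        raise ValidationError("missing β values among the normals; filter first")
    keep = (sub.values < max_beta).all(axis=1)
    return sub.probe_ids[keep]


def tumor_burden(
    beta: BetaMatrix,
    tumor_sample: str,
    reference: Sequence[str] | pd.Index,
    high_beta: float = 0.5,
) -> tuple[int, float]:
    """(count, fraction) of reference probes with β > ``high_beta`` (strict)."""
    reference = pd.Index(reference)
    if len(reference) == 0:
        raise ValidationError("reference probe set is empty")
    if tumor_sample not in beta.sample_ids:
        raise KeyError(f"unknown sample {tumor_sample!r}")
    values = beta.select(probes=list(reference)).df[tumor_sample]
    if bool(values.isna().any()):
        raise ValidationError(
            f"sample {tumor_sample!r} has missing values on the reference set"
        )
    count = int((values.to_numpy() > high_beta).sum())
    return count, count / len(reference)


def burden_table(
    beta: BetaMatrix,
    tumor_samples: Sequence[str],
    reference: Sequence[str] | pd.Index,
    high_beta: float = 0.5,
) -> pd.DataFrame:
    """Burden count and fraction for each tumor, as a tidy table."""
    rows = []
    for sample in tumor_samples:
        count, fraction = tumor_burden(beta, sample, reference, high_beta)
        rows.append({"sample_id": sample, "burden": count, "fraction": fraction})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclasses.dataclass(frozen=True)
class FitSummary:
    """Summary of a burden ~ covariate fit."""

    model: str                   # "linear" | "exponential"
    params: dict[str, float]     # slope/intercept, or amplitude/rate
    r: float
    r_squared: float
    n: int
    p_value: float


def correlate_burden(
    burdens: pd.Series | Sequence[float],
    covariate: pd.Series | Sequence[float],
    model: str = "linear",
) -> FitSummary:
    """Fit burden ~ covariate.

    ``linear``: ordinary least squares with Pearson r and r²;
    ``exponential``: least squares of log(burden) ~ covariate, parameters
    back-transformed to ``burden ≈ amplitude · exp(rate · covariate)``.
    Pairs with a missing value in either variable are dropped (and must
    leave ≥ 3 points); the exponential model requires positive burdens.
    """
    b = pd.Series(burdens, dtype=float)
    c = pd.Series(covariate, dtype=float)
    if isinstance(burdens, pd.Series) and isinstance(covariate, pd.Series):
        c = c.reindex(b.index)
    elif len(b) != len(c):
        raise ValidationError("burdens and covariate must have equal length")
    keep = b.notna().to_numpy() & c.notna().to_numpy()
    b, c = b.to_numpy()[keep], c.to_numpy()[keep]
    if len(b) < 3:
        raise ValidationError(f"need >= 3 complete (burden, covariate) pairs, got {len(b)}")
    if np.ptp(c) == 0:
        raise ValidationError("covariate has zero variance")

    if model == "linear":
        fit = stats.linregress(c, b)
        return FitSummary(
            model="linear",
            params={"slope": float(fit.slope), "intercept": float(fit.intercept)},
            r=float(fit.rvalue),
            r_squared=float(fit.rvalue**2),
            n=len(b),
            p_value=float(fit.pvalue),
        )
    if model == "exponential":
        if np.any(b <= 0):
            raise ValidationError("exponential model requires positive burdens")
        fit = stats.linregress(c, np.log(b))
        return FitSummary(
            model="exponential",
            params={
                "amplitude": float(np.exp(fit.intercept)),
                "rate": float(fit.slope),
            },
            r=float(fit.rvalue),
            r_squared=float(fit.rvalue**2),
            n=len(b),
            p_value=float(fit.pvalue),
        )
    raise ValueError(f"unknown model {model!r}; choose linear or exponential")


def plot_burden_scatter(
    table: pd.DataFrame,
    covariate_col: str,
    path,
    burden_col: str = "burden",
    fit: FitSummary | None = None,
) -> None:
    """Scatter of burden against a covariate with an optional trendline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[[burden_col, covariate_col]].dropna()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(sub[covariate_col], sub[burden_col], s=30, color="#39618f")
    if fit is not None and fit.model == "linear":
        xs = np.linspace(sub[covariate_col].min(), sub[covariate_col].max(), 50)
        ax.plot(xs, fit.params["intercept"] + fit.params["slope"] * xs,
                color="#a33", lw=1.2,
                label=f"r² = {fit.r_squared:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel(covariate_col)
    ax.set_ylabel("hypermethylation burden")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
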