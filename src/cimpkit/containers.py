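"""Core in-memory containers for 450K-style methylation analysis.

Every container is a thin, validated wrapper around a pandas object:

* :class:`BetaMatrix` — probes × samples β-values in ``[0, 1]``, with ``NaN``
  marking missing (undetected or masked) calls;
* :class:`ProbeAnnotation` — per-probe CpG-region class and gene symbols;
* :class:`SampleSheet` — per-sample cohort label, tumor/normal flag and
  clinical covariates;
* :class:`ExpressionMatrix` — genes × samples non-negative expression.

Wrapping rather than subclassing keeps validation at construction time and
leaves the familiar DataFrame API available through ``.df``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: The three CpG-region strata used throughout: CpG islands, the flanking
#: shores+shelves (reported jointly), and everything else ("open sea").
REGION_CLASSES = ("island", "shore_shelf", "other")


class ValidationError(ValueError):
    """A container invariant is violated (duplicate IDs, bad labels, ...)."""


class ParseError(ValueError):
    """A file could not be interpreted in the requested dialect."""


class BetaRangeError(ValueError):
    """A β-value lies outside the closed unit interval."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclasses.dataclass(frozen=True)
class BetaMatrix:
    """Probes × samples methylation β-values.

    ``df`` is indexed by probe ID with sample IDs as columns; ``NaN`` encodes
    a missing call. All non-missing values must lie in ``[0, 1]``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "probe IDs")
        _check_unique(self.df.columns, "sample IDs")
        values = self.df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bool(np.any(bad & ~np.isnan(values))):
            i, j = np.argwhere(bad & ~np.isnan(values))[0]
            raise BetaRangeError(
                f"β-value {values[i, j]!r} outside [0, 1] at probe "
                f"{self.df.index[i]!r}, sample {self.df.columns[j]!r}"
            )
        if self.df.to_numpy().dtype != np.float64:
            object.__setattr__(self, "df", self.df.astype(float))

    # -- basic views ------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the β call is missing."""
        return self.df.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    # -- subsetting -------------------------------------------------------
    def select(
        self,
        probes: Sequence[str] | pd.Index | None = None,
        samples: Sequence[str] | pd.Index | None = None,
    ) -> "BetaMatrix":
        """Order-preserving subset; unknown IDs raise ``KeyError``."""
        df = self.df
        if probes is not None:
            missing = pd.Index(probes).difference(df.index)
            if len(missing):
                raise KeyError(f"unknown probe IDs: {missing[:5].tolist()}")
            df = df.loc[list(probes)]
        if samples is not None:
            missing = pd.Index(samples).difference(df.columns)
            if len(missing):
                raise KeyError(f"unknown sample IDs: {missing[:5].tolist()}")
            df = df[list(samples)]
        return BetaMatrix(df)

    def complete_probes(self, samples: Iterable[str] | None = None) -> pd.Index:
        """Probes with zero missing values across ``samples`` (default: all)."""
        df = self.df if samples is None else self.select(samples=list(samples)).df
        return self.df.index[df.notna().all(axis=1).to_numpy()]

    def require_complete(self, context: str = "this operation") -> None:
        if bool(self.df.isna().to_numpy().any()):
            n = int(self.df.isna().to_numpy().sum())
            raise ValidationError(
                f"{context} requires a complete matrix but {n} cells are "
                "missing; filter with drop_incomplete_probes first"
            )


@dataclasses.dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe CpG-region class, gene symbols and chromosome.

    ``df`` is indexed by probe ID with columns:

    ``region_class``
        one of :data:`REGION_CLASSES`;
    ``gene_symbols``
        tuple of unique gene symbols (possibly empty);
    ``chromosome``
        optional label, ``None``/NaN allowed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "probe IDs")
        required = {"region_class", "gene_symbols"}
        missing = required.difference(self.df.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        bad = ~self.df["region_class"].isin(REGION_CLASSES)
        if bool(bad.any()):
            raise ValidationError(
                f"unknown region class values: "
                f"{self.df.loc[bad, 'region_class'].unique()[:5].tolist()}"
            )
        for probe, genes in self.df["gene_symbols"].items():
            if len(set(genes)) != len(tuple(genes)):
                raise ValidationError(f"duplicate gene symbols on probe {probe!r}")
        if "chromosome" not in self.df.columns:
            self.df["chromosome"] = None

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def region_of(self, probes: Iterable[str] | None = None) -> pd.Series:
        if probes is None:
            return self.df["region_class"]
        probes = pd.Index(probes)
        missing = probes.difference(self.df.index)
        if len(missing):
            raise ValidationError(f"unannotated probes: {missing[:5].tolist()}")
        return self.df.loc[probes, "region_class"]

    def probes_in_region(self, region: str) -> pd.Index:
        if region not in REGION_CLASSES:
            raise ValidationError(f"unknown region class {region!r}")
        return self.df.index[(self.df["region_class"] == region).to_numpy()]

    def region_counts(self, probes: Iterable[str] | None = None) -> pd.Series:
        """Probe counts per region class, always covering all three classes."""
        regions = self.region_of(probes)
        return regions.value_counts().reindex(REGION_CLASSES, fill_value=0)

    def genes_of(self, probes: Iterable[str]) -> pd.Series:
        """Gene-symbol tuples for ``probes`` (unannotated probes raise)."""
        probes = pd.Index(probes)
        missing = probes.difference(self.df.index)
        if len(missing):
            raise ValidationError(f"unannotated probes: {missing[:5].tolist()}")
        return self.df.loc[probes, "gene_symbols"]


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata.

    ``df`` is indexed by sample ID with columns ``cohort`` (str),
    ``is_tumor`` (bool), ``patient_id`` (str), ``size_cm`` (float, tumors
    only), ``age_years`` (float), ``pair_id`` (optional label linking a
    tumor group to its matched normal) and ``is_primary`` (bool; primary
    tumor vs metastasis/thrombus, used to gate covariate fits).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample IDs")
        required = {"cohort", "is_tumor", "patient_id"}
        missing = required.difference(self.df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        df = self.df.copy()
        for col, default in (
            ("size_cm", np.nan),
            ("age_years", np.nan),
            ("pair_id", None),
            ("is_primary", True),
        ):
            if col not in df.columns:
                df[col] = default
        df["is_tumor"] = df["is_tumor"].astype(bool)
        df["is_primary"] = df["is_primary"].fillna(True).astype(bool)
        sized_normals = df.index[(~df["is_tumor"]) & df["size_cm"].notna()]
        if len(sized_normals):
            raise ValidationError(
                f"tumor_size set on normal samples: {sized_normals[:5].tolist()}"
            )
        for col in ("size_cm", "age_years"):
            bad = df.index[df[col].notna() & (df[col] <= 0)]
            if len(bad):
                raise ValidationError(f"non-positive {col} on {bad[:5].tolist()}")
        for pair, group in df[df["pair_id"].notna()].groupby("pair_id"):
            n_normal = int((~group["is_tumor"]).sum())
            n_tumor = int(group["is_tumor"].sum())
            if n_normal != 1 or n_tumor < 1:
                raise ValidationError(
                    f"pair {pair!r} must link >=1 tumor with exactly 1 normal "
                    f"(got {n_tumor} tumors, {n_normal} normals)"
                )
            if group["patient_id"].nunique() != 1:
                raise ValidationError(f"pair {pair!r} spans multiple patients")
        object.__setattr__(self, "df", df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def tumors(self, cohort: str | None = None, primary_only: bool = False) -> pd.Index:
        mask = self.df["is_tumor"]
        if cohort is not None:
            mask = mask & (self.df["cohort"] == cohort)
        if primary_only:
            mask = mask & self.df["is_primary"]
        return self.df.index[mask.to_numpy()]

    def normals(self, cohort: str | None = None) -> pd.Index:
        mask = ~self.df["is_tumor"]
        if cohort is not None:
            mask = mask & (self.df["cohort"] == cohort)
        return self.df.index[mask.to_numpy()]

    def paired(self, cohort: str) -> tuple[pd.Index, pd.Index]:
        """(tumor, normal) sample IDs of a cohort that carry a pair label."""
        sub = self.df[(self.df["cohort"] == cohort) & self.df["pair_id"].notna()]
        return (
            sub.index[sub["is_tumor"].to_numpy()],
            sub.index[(~sub["is_tumor"]).to_numpy()],
        )

    @property
    def cohorts(self) -> list[str]:
        return list(dict.fromkeys(self.df["cohort"]))


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples non-negative expression values."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "gene symbols")
        _check_unique(self.df.columns, "sample IDs")
        values = self.df.to_numpy(dtype=float, copy=False)
        if bool(np.any(values < 0)):
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_symbols(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    def select(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.df
        if genes is not None:
            df = df.loc[list(genes)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df)
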