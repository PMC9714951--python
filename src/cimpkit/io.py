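"""Reading, writing and filtering of methylation matrices and metadata.

Supported β-matrix dialects:

``plain_tsv`` / ``csv``
    delimited text, header row of sample IDs, first column probe IDs,
    ``NA``/empty cells mark missing values;
``series_matrix``
    GEO series-matrix style: metadata lines prefixed ``!``, the data table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
    with an ``ID_REF`` header.

Probe annotation accepts both the canonical column names
(``probe_id``, ``cpg_relation``, ``gene_symbols``, ``chromosome``) and the
Illumina 450K manifest aliases (``IlmnID``/``Name``,
``Relation_to_UCSC_CpG_Island``, ``UCSC_RefGene_Name``, ``CHR``).

The two detection filters used upstream of every analysis live here too:
:func:`apply_detection_mask` (unreliable calls at detection p ≥ α become
missing) and :func:`drop_incomplete_probes` (only probes complete across an
explicit core-sample set survive). Both are strict pass-throughs for the
surviving values.
"""

from __future__ import annotations

import io as _io
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    ExpressionMatrix,
    ParseError,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

NA_VALUES = ["NA", "N/A", "null", "NULL", ""]

_DIALECT_SEPS = {"plain_tsv": "\t", "csv": ","}

_ANNOTATION_ALIASES = {
    "probe_id": ("probe_id", "IlmnID", "Name", "ID_REF"),
    "cpg_relation": ("cpg_relation", "Relation_to_UCSC_CpG_Island", "Relation_to_Island"),
    "gene_symbols": ("gene_symbols", "UCSC_RefGene_Name", "genes"),
    "chromosome": ("chromosome", "CHR", "chr"),
}

#: Manifest relation values collapsed onto the three region classes. Shores
#: and shelves are reported jointly throughout, so they share one class.
RELATION_MAP = {
    "Island": "island",
    "N_Shore": "shore_shelf",
    "S_Shore": "shore_shelf",
    "N_Shelf": "shore_shelf",
    "S_Shelf": "shore_shelf",
    "Shore": "shore_shelf",
    "Shelf": "shore_shelf",
}


# ---------------------------------------------------------------------------
# β matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, dialect: str = "plain_tsv") -> BetaMatrix:
    """Read a probes × samples β matrix.

    Parameters
    ----------
    path:
        delimited text file; first column probe IDs, header row sample IDs.
    dialect:
        one of ``plain_tsv``, ``csv``, ``series_matrix``.
    """
    path = Path(path)
    if dialect == "series_matrix":
        text = _extract_series_matrix_table(path)
        buffer: object = _io.StringIO(text)
        sep = "\t"
    elif dialect in _DIALECT_SEPS:
        buffer = path
        sep = _DIALECT_SEPS[dialect]
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    try:
        df = pd.read_csv(
            buffer,
            sep=sep,
            index_col=0,
            na_values=NA_VALUES,
            keep_default_na=False,
            comment=None,
        )
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found in header")
    if df.columns.str.startswith("Unnamed").any():
        raise ParseError(f"{path}: malformed header row")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric β values: {exc}") from exc
    return BetaMatrix(df)


def _extract_series_matrix_table(path: Path) -> str:
    lines = path.read_text().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        key = line.strip().strip('"').lower()
        if key.startswith("!series_matrix_table_begin"):
            begin = i + 1
        elif key.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin:
        raise ParseError(f"{path}: series_matrix table markers not found")
    table = [line.replace('"', "") for line in lines[begin:end]]
    if not table or not table[0].split("\t")[0].upper().startswith("ID_REF"):
        raise ParseError(f"{path}: series_matrix header must start with ID_REF")
    return "\n".join(table)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, dialect: str = "plain_tsv", decimals: int = 6
) -> Path:
    """Write a β matrix as delimited text (``NA`` marks missing cells)."""
    path = Path(path)
    sep = _DIALECT_SEPS.get(dialect)
    if sep is None:
        raise ParseError(f"unsupported output dialect {dialect!r}")
    beta.df.to_csv(path, sep=sep, na_rep="NA", float_format=f"%.{decimals}f")
    return path


# ---------------------------------------------------------------------------
# detection / completeness filters
# ---------------------------------------------------------------------------

def apply_detection_mask(
    beta: BetaMatrix, detection_p: pd.DataFrame, alpha: float = 0.01
) -> BetaMatrix:
    """Mask β calls whose detection p-value is ``>= alpha`` (inclusive).

    A detection p-value measures per-call signal-vs-background confidence on
    the array; calls at or above the threshold are unreliable and become
    missing. Every surviving value is passed through bit-identically.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if detection_p.shape != beta.shape:
        raise ValidationError(
            f"detection-p shape {detection_p.shape} != β shape {beta.shape}"
        )
    p = detection_p
    if not p.index.equals(beta.probe_ids) or not p.columns.equals(beta.sample_ids):
        try:
            p = p.loc[beta.probe_ids, beta.sample_ids]
        except KeyError as exc:
            raise ValidationError(f"detection-p IDs do not match β matrix: {exc}")
    masked = beta.df.mask(p.to_numpy(dtype=float) >= alpha)
    return BetaMatrix(masked)


def drop_incomplete_probes(beta: BetaMatrix, core_samples: Iterable[str]) -> BetaMatrix:
    """Keep exactly the probes with zero missing values across ``core_samples``.

    The core-sample set is an explicit parameter: the completeness rule is
    defined over a designated core cohort, not over whatever columns happen
    to be present. All samples are retained in the output.
    """
    core = list(core_samples)
    if not core:
        raise ValidationError("core_samples must be non-empty")
    unknown = pd.Index(core).difference(beta.sample_ids)
    if len(unknown):
        raise ValidationError(f"unknown core sample IDs: {unknown[:5].tolist()}")
    keep = beta.complete_probes(core)
    return BetaMatrix(beta.df.loc[keep])


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def _resolve_column(df: pd.DataFrame, canonical: str, required: bool = True) -> str | None:
    for alias in _ANNOTATION_ALIASES[canonical]:
        if alias in df.columns:
            return alias
    if required:
        raise ValidationError(
            f"annotation is missing a {canonical!r} column "
            f"(accepted names: {_ANNOTATION_ALIASES[canonical]})"
        )
    return None


def classify_relation(relation: object) -> str:
    """Map a manifest CpG-relation value onto island/shore_shelf/other."""
    if relation is None or (isinstance(relation, float) and np.isnan(relation)):
        return "other"
    return RELATION_MAP.get(str(relation).strip(), "other")


def parse_gene_field(field: object) -> tuple[str, ...]:
    """Split a semicolon-delimited gene list, de-duplicating in order."""
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return ()
    parts = [p.strip() for p in str(field).split(";")]
    return tuple(dict.fromkeys(p for p in parts if p))


def load_probe_annotation(path: str | Path, sep: str | None = None) -> ProbeAnnotation:
    """Load a manifest-style probe annotation table.

    Manifest relation values collapse as ``Island`` → island,
    ``N/S_Shore``/``N/S_Shelf`` → shore_shelf, anything else (including
    empty) → other; semicolon-delimited gene lists are split and
    de-duplicated. Every probe maps to exactly one region class.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False)
    probe_col = _resolve_column(raw, "probe_id")
    relation_col = _resolve_column(raw, "cpg_relation")
    gene_col = _resolve_column(raw, "gene_symbols")
    chrom_col = _resolve_column(raw, "chromosome", required=False)

    df = pd.DataFrame(
        {
            "region_class": raw[relation_col].map(classify_relation).to_numpy(),
            "gene_symbols": raw[gene_col].map(parse_gene_field).to_numpy(),
            "chromosome": raw[chrom_col].to_numpy() if chrom_col else None,
        },
        index=pd.Index(raw[probe_col].astype(str).to_numpy(), name="probe_id"),
    )
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> Path:
    path = Path(path)
    out = annotation.df.copy()
    out["gene_symbols"] = out["gene_symbols"].map(";".join)
    out = out.rename(columns={"region_class": "cpg_relation"})
    # region classes are themselves valid relation values for read-back:
    out["cpg_relation"] = out["cpg_relation"].map(
        {"island": "Island", "shore_shelf": "N_Shore", "other": ""}
    )
    out.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# sample sheets and expression
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV (sample_id, cohort, is_tumor, patient_id, ...)."""
    raw = pd.read_csv(Path(path), na_values=NA_VALUES, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValidationError("sample sheet must have a sample_id column")
    raw = raw.set_index("sample_id")
    raw.index = raw.index.astype(str)
    if "is_tumor" in raw.columns:
        raw["is_tumor"] = raw["is_tumor"].map(_parse_bool)
    if "is_primary" in raw.columns:
        raw["is_primary"] = raw["is_primary"].map(_parse_bool)
    for col in ("size_cm", "age_years"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if "pair_id" in raw.columns:
        raw["pair_id"] = raw["pair_id"].where(raw["pair_id"].astype(str) != "", None)
    return SampleSheet(raw)


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes", "y", "tumor"}:
        return True
    if text in {"false", "f", "0", "no", "n", "normal", ""}:
        return False
    raise ValidationError(f"cannot interpret boolean value {value!r}")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.df.to_csv(path, index_label="sample_id")
    return path


def read_expression_matrix(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    df = pd.read_csv(Path(path), sep=sep, index_col=0, na_values=NA_VALUES,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene_symbol"
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> Path:
    path = Path(path)
    expr.df.to_csv(path, sep=sep, float_format="%.6f")
    return path
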