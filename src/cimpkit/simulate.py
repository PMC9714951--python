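"""Synthetic 450K-style cohorts with planted CIMP structure.

The generator emulates the statistical structure a CIMP (CpG island
methylator phenotype) analysis relies on, at desk scale and with a fully
recorded planted truth:

* bimodal β-values: each probe has a stable baseline level drawn from an
  unmethylated Beta state (default ``Beta(2, 20)``) or, for a constitutively
  methylated stratum shared by all samples, a methylated state
  (``Beta(20, 4)``); individual measurements scatter around the baseline
  with small technical noise (``noise_sd``), the way array replicates do;
* CIMP tumors hypermethylate a per-tumor, region-weighted subset of
  "susceptible" probes — normally-unmethylated probes (baseline ≤
  ``susceptible_baseline_max``) — redrawing their β from the methylated
  state. Island probes are hit at the tumor's burden rate, shores/shelves
  and open-sea probes at weight-scaled lower rates (default 10:4:1);
* per-cohort burden levels: every tumor draws its island-scale burden
  fraction from the cohort's range (HLRCC-like high, SDHB-like lower and
  more variable, non-CIMP zero), so cohorts differ the way the kidney-tumor
  syndromes do;
* consistent targets: each CIMP cohort has a "core" probe set
  hypermethylated in every tumor of the cohort, partly shared between CIMP
  cohorts — hypermethylation is coordinated, not a fresh random draw per
  tumor, which is what makes marker panels transferable between cohorts;
* burden–size coupling: tumor size is linear in the burden fraction plus
  noise; ages are drawn independently;
* expression coupling: genes carrying ≥2 core hypermethylated island probes
  are transcriptionally downregulated in the cohort's tumors by a factor
  drawn around ``expr_downreg_factor``.

Probe-universe attributes (regions, gene map, baselines, core target sets)
come from a dedicated ``universe_seed`` substream so that two cohorts
simulated with different ``seed`` values share the same probe semantics:
panels learned on one cohort can be applied to an independently drawn one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .containers import (
    REGION_CLASSES,
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleSheet,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class SizeLink:
    """Linear coupling of tumor size (cm) to the burden fraction."""

    intercept_cm: float = 0.5
    slope_cm: float = 18.0
    noise_sd_cm: float = 0.3

    def implied_inverse_slope(self, burden_var: float) -> float:
        """Model-implied OLS coefficient of burden ~ size.

        With ``size = a + k·b + ε`` the population regression coefficient of
        burden on size is ``k·var(b) / (k²·var(b) + σ²)`` — the attenuated
        inverse slope. Used as the honest target in recovery checks.
        """
        k, s2 = self.slope_cm, self.noise_sd_cm**2
        return k * burden_var / (k**2 * burden_var + s2)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Tumor/normal counts and burden range for one cohort."""

    name: str
    n_tumors: int
    n_normals: int
    burden_range: tuple[float, float] = (0.0, 0.0)

    @property
    def is_cimp(self) -> bool:
        return self.burden_range[1] > 0


#: Default cohort composition: 15+6 CIMP-like tumors (HLRCC-like with high,
#: SDHB-like with lower and more variable burden), 13 non-CIMP tumors and
#: 11 normals across five syndromic cohorts.
DEFAULT_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("HLRCC", 15, 4, (0.10, 0.50)),
    CohortSpec("SDHB-RCC", 6, 4, (0.02, 0.30)),
    CohortSpec("VHL", 5, 3),
    CohortSpec("HPRC", 4, 0),
    CohortSpec("BHD", 4, 0),
)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults give the study-like cohort."""

    n_probes: int = 20_000
    #: island / shore_shelf / other proportions, 450K-like.
    region_props: tuple[float, float, float] = (0.315, 0.327, 0.358)
    cohorts: tuple[CohortSpec, ...] = DEFAULT_COHORTS
    unmeth_state: tuple[float, float] = (2.0, 20.0)
    meth_state: tuple[float, float] = (20.0, 4.0)
    region_hyper_weights: tuple[float, float, float] = (10.0, 4.0, 1.0)
    constitutive_fraction: float = 0.30
    susceptible_baseline_max: float = 0.15
    shared_core_fraction: float = 0.02
    size_link: SizeLink = dataclasses.field(default_factory=SizeLink)
    age_range: tuple[float, float] = (19.0, 63.0)
    #: ln-scale mean and sd of per-gene baseline expression.
    expr_baseline: tuple[float, float] = (5.0, 1.0)
    expr_downreg_factor: float = 0.4
    expr_downreg_ln_sd: float = 0.15
    expr_noise_ln_sd: float = 0.25
    #: fraction of island probes assigned to a gene, and probes per gene.
    gene_coverage: float = 0.75
    probes_per_gene: int = 3
    noise_sd: float = 0.03
    seed: int = 0
    universe_seed: int = 11

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if abs(sum(self.region_props) - 1.0) > 1e-6:
            raise ConfigError(f"region_props must sum to 1, got {self.region_props}")
        if min(self.region_props) < 0:
            raise ConfigError("region_props must be non-negative")
        for pair in (self.unmeth_state, self.meth_state):
            if min(pair) <= 0:
                raise ConfigError(f"Beta shape parameters must be positive: {pair}")
        if min(self.region_hyper_weights) <= 0:
            raise ConfigError("region_hyper_weights must be positive")
        for spec in self.cohorts:
            lo, hi = spec.burden_range
            if not (0 <= lo <= hi <= 1):
                raise ConfigError(
                    f"cohort {spec.name!r}: burden range must satisfy "
                    f"0 <= lo <= hi <= 1, got {spec.burden_range}"
                )
            if spec.n_tumors < 0 or spec.n_normals < 0:
                raise ConfigError(f"cohort {spec.name!r}: negative sample counts")
        if not 0 <= self.constitutive_fraction < 1:
            raise ConfigError("constitutive_fraction must be in [0, 1)")
        if not 0 <= self.shared_core_fraction <= 1:
            raise ConfigError("shared_core_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclasses.dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded while simulating.

    ``hyper_probes`` maps each tumor to its planted hypermethylated probes;
    ``cohort_core`` to the probes planted in *every* tumor of a CIMP cohort
    (the recoverable tumor-specific hypermethylation signal);
    ``burden_fraction`` to the realized fraction of susceptible island
    probes hypermethylated per tumor; ``methylated_genes`` to the genes with
    ≥2 core island probes per cohort (their expression is downregulated).
    """

    hyper_probes: dict[str, frozenset[str]]
    cohort_core: dict[str, frozenset[str]]
    burden_fraction: dict[str, float]
    methylated_genes: dict[str, frozenset[str]]
    susceptible_probes: frozenset[str]

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "hyper_probes": {k: sorted(v) for k, v in self.hyper_probes.items()},
            "cohort_core": {k: sorted(v) for k, v in self.cohort_core.items()},
            "burden_fraction": dict(self.burden_fraction),
            "methylated_genes": {k: sorted(v) for k, v in self.methylated_genes.items()},
            "susceptible_probes": sorted(self.susceptible_probes),
        }

    @classmethod
    def from_jsonable(cls, data: dict[str, Any]) -> "PlantedTruth":
        return cls(
            hyper_probes={k: frozenset(v) for k, v in data["hyper_probes"].items()},
            cohort_core={k: frozenset(v) for k, v in data["cohort_core"].items()},
            burden_fraction={k: float(v) for k, v in data["burden_fraction"].items()},
            methylated_genes={
                k: frozenset(v) for k, v in data["methylated_genes"].items()
            },
            susceptible_probes=frozenset(data["susceptible_probes"]),
        )


@dataclasses.dataclass(frozen=True)
class SimulatedCohort:
    beta: BetaMatrix
    annotation: ProbeAnnotation
    samples: SampleSheet
    expression: ExpressionMatrix
    truth: PlantedTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# probe universe
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class _Universe:
    probe_ids: np.ndarray
    regions: np.ndarray            # int codes into REGION_CLASSES
    baseline: np.ndarray           # per-probe baseline β level
    constitutive: np.ndarray       # bool
    susceptible: np.ndarray        # bool
    cohort_core: dict[str, np.ndarray]   # bool masks per CIMP cohort
    gene_of_probe: np.ndarray      # object array of gene symbol or ""
    gene_ids: np.ndarray
    chromosome: np.ndarray


def _build_universe(config: SimulationConfig) -> _Universe:
    rng = np.random.default_rng(config.universe_seed)
    n = config.n_probes
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])
    regions = rng.choice(len(REGION_CLASSES), size=n, p=config.region_props)
    constitutive = rng.random(n) < config.constitutive_fraction
    baseline = np.where(
        constitutive,
        rng.beta(*config.meth_state, size=n),
        rng.beta(*config.unmeth_state, size=n),
    )
    susceptible = (~constitutive) & (baseline <= config.susceptible_baseline_max)

    # region rate multipliers relative to islands
    w = np.asarray(config.region_hyper_weights, dtype=float)
    omega = w / w[0]
    omega_of = omega[regions]

    shared_rate = config.shared_core_fraction
    shared = susceptible & (rng.random(n) < shared_rate * omega_of)

    cohort_core: dict[str, np.ndarray] = {}
    for spec in config.cohorts:
        if not spec.is_cimp:
            continue
        b_lo = spec.burden_range[0]
        if b_lo <= 0:
            core = np.zeros(n, dtype=bool)
        elif b_lo <= shared_rate and shared_rate > 0:
            # thin the shared pool down to the cohort's floor rate
            core = shared & (rng.random(n) < b_lo / shared_rate)
        else:
            extra_rate = np.clip(
                (b_lo - shared_rate) * omega_of / np.maximum(1e-12, 1 - shared_rate * omega_of),
                0.0,
                1.0,
            )
            core = shared | (susceptible & ~shared & (rng.random(n) < extra_rate))
        cohort_core[spec.name] = core

    # gene map over island probes (promoter-style blocks of consecutive
    # probes in a random order); a fixed fraction stays intergenic
    island_idx = np.flatnonzero(regions == 0)
    shuffled = rng.permutation(island_idx)
    n_assigned = int(round(config.gene_coverage * len(island_idx)))
    gene_of_probe = np.full(n, "", dtype=object)
    gene_ids = []
    for g, start in enumerate(range(0, n_assigned, max(1, config.probes_per_gene))):
        block = shuffled[start : start + config.probes_per_gene]
        symbol = f"GENE{g + 1:05d}"
        gene_ids.append(symbol)
        for idx in block:
            gene_of_probe[idx] = symbol
    chromosome = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)])
    return _Universe(
        probe_ids=probe_ids,
        regions=regions,
        baseline=baseline,
        constitutive=constitutive,
        susceptible=susceptible,
        cohort_core=cohort_core,
        gene_of_probe=gene_of_probe,
        gene_ids=np.array(gene_ids),
        chromosome=chromosome,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort with planted truth.

    Deterministic for a given config: the probe universe derives from
    ``universe_seed`` and all sample-level draws from ``seed`` via
    deterministic substreams.
    """
    config = config or SimulationConfig()
    uni = _build_universe(config)
    n = config.n_probes

    seq = np.random.SeedSequence(config.seed)
    beta_rng, cov_rng, expr_rng = (np.random.default_rng(s) for s in seq.spawn(3))

    w = np.asarray(config.region_hyper_weights, dtype=float)
    omega_of = (w / w[0])[uni.regions]
    susc_island = uni.susceptible & (uni.regions == 0)
    n_susc_island = max(1, int(susc_island.sum()))

    columns: dict[str, np.ndarray] = {}
    rows: list[dict[str, Any]] = []
    hyper_probes: dict[str, frozenset[str]] = {}
    burden_fraction: dict[str, float] = {}

    def _noisy(levels: np.ndarray) -> np.ndarray:
        if config.noise_sd == 0:
            return np.clip(levels, 0.0, 1.0)
        return np.clip(levels + beta_rng.normal(0.0, config.noise_sd, size=levels.shape), 0.0, 1.0)

    for spec in config.cohorts:
        core = uni.cohort_core.get(spec.name, np.zeros(n, dtype=bool))
        b_lo = spec.burden_range[0]
        for t in range(spec.n_tumors):
            sample_id = f"{spec.name}_T{t + 1:02d}"
            values = _noisy(uni.baseline.copy())
            planted = np.zeros(n, dtype=bool)
            if spec.is_cimp:
                b = float(beta_rng.uniform(*spec.burden_range))
                private_rate = np.clip(
                    omega_of * (b - b_lo) / np.maximum(1e-12, 1.0 - b_lo * omega_of),
                    0.0,
                    1.0,
                )
                planted = core | (
                    uni.susceptible & ~core & (beta_rng.random(n) < private_rate)
                )
                k = int(planted.sum())
                values[planted] = _noisy(beta_rng.beta(*config.meth_state, size=k))
                size = max(
                    0.3,
                    config.size_link.intercept_cm
                    + config.size_link.slope_cm * b
                    + cov_rng.normal(0.0, config.size_link.noise_sd_cm),
                )
            else:
                size = float(cov_rng.uniform(1.0, 8.0))
            columns[sample_id] = values
            hyper_probes[sample_id] = frozenset(uni.probe_ids[planted])
            burden_fraction[sample_id] = float((planted & susc_island).sum() / n_susc_island)
            rows.append(
                {
                    "sample_id": sample_id,
                    "cohort": spec.name,
                    "is_tumor": True,
                    "patient_id": f"{spec.name}-pt{t + 1:02d}",
                    "size_cm": round(size, 2),
                    "age_years": round(float(cov_rng.uniform(*config.age_range)), 1),
                    "pair_id": f"{spec.name}-P{t + 1}" if t < spec.n_normals else None,
                    "is_primary": True,
                }
            )
        for m in range(spec.n_normals):
            sample_id = f"{spec.name}_N{m + 1:02d}"
            columns[sample_id] = _noisy(uni.baseline.copy())
            paired = m < spec.n_tumors
            rows.append(
                {
                    "sample_id": sample_id,
                    "cohort": spec.name,
                    "is_tumor": False,
                    "patient_id": f"{spec.name}-pt{m + 1:02d}" if paired
                    else f"{spec.name}-ptN{m + 1:02d}",
                    "size_cm": np.nan,
                    "age_years": round(float(cov_rng.uniform(*config.age_range)), 1),
                    "pair_id": f"{spec.name}-P{m + 1}" if paired else None,
                    "is_primary": True,
                }
            )

    beta = BetaMatrix(pd.DataFrame(columns, index=pd.Index(uni.probe_ids, name="probe_id")))
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "region_class": np.array(REGION_CLASSES, dtype=object)[uni.regions],
                "gene_symbols": [
                    (g,) if g else () for g in uni.gene_of_probe
                ],
                "chromosome": uni.chromosome,
            },
            index=pd.Index(uni.probe_ids, name="probe_id"),
        )
    )
    samples = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))

    # genes with >= 2 core island probes per CIMP cohort are downregulated
    methylated_genes: dict[str, frozenset[str]] = {}
    island = uni.regions == 0
    for name, core in uni.cohort_core.items():
        genes = pd.Series(uni.gene_of_probe[core & island])
        counts = genes[genes != ""].value_counts()
        methylated_genes[name] = frozenset(counts.index[counts >= 2])
    cohort_core_named = {
        name: frozenset(uni.probe_ids[mask]) for name, mask in uni.cohort_core.items()
    }

    expression = _simulate_expression(config, uni, samples, methylated_genes, expr_rng)

    truth = PlantedTruth(
        hyper_probes=hyper_probes,
        cohort_core=cohort_core_named,
        burden_fraction=burden_fraction,
        methylated_genes=methylated_genes,
        susceptible_probes=frozenset(uni.probe_ids[uni.susceptible]),
    )
    return SimulatedCohort(beta, annotation, samples, expression, truth, config)


def _simulate_expression(
    config: SimulationConfig,
    uni: _Universe,
    samples: SampleSheet,
    methylated_genes: dict[str, frozenset[str]],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    genes = uni.gene_ids
    mu, sd = config.expr_baseline
    baseline = np.exp(rng.normal(mu, sd, size=len(genes)))
    data: dict[str, np.ndarray] = {}
    gene_index = pd.Index(genes, name="gene_symbol")
    for sample_id, row in samples.df.iterrows():
        values = baseline * np.exp(rng.normal(0.0, config.expr_noise_ln_sd, size=len(genes)))
        planted = methylated_genes.get(row["cohort"], frozenset()) if row["is_tumor"] else frozenset()
        if planted:
            mask = gene_index.isin(planted)
            factors = np.exp(
                rng.normal(np.log(config.expr_downreg_factor), config.expr_downreg_ln_sd,
                           size=int(mask.sum()))
            )
            values[mask] = values[mask] * factors
        data[sample_id] = values
    return ExpressionMatrix(pd.DataFrame(data, index=gene_index))


# ---------------------------------------------------------------------------
# fixture export / import
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "beta": "beta.tsv",
    "annotation": "annotation.tsv",
    "samples": "samples.csv",
    "expression": "expression.tsv",
    "truth": "truth.json",
    "config": "config.yaml",
}


def export_fixture(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write all cohort components as plain-text interchange files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    mio.write_beta_matrix(cohort.beta, paths["beta"])
    mio.write_probe_annotation(cohort.annotation, paths["annotation"])
    mio.write_sample_sheet(cohort.samples, paths["samples"])
    mio.write_expression_matrix(cohort.expression, paths["expression"])
    paths["truth"].write_text(json.dumps(cohort.truth.to_jsonable(), indent=0, sort_keys=True))
    paths["config"].write_text(yaml.safe_dump(config_to_dict(cohort.config), sort_keys=True))
    return paths


def load_fixture(directory: str | Path) -> SimulatedCohort:
    """Read back a fixture directory written by :func:`export_fixture`."""
    directory = Path(directory)
    beta = mio.read_beta_matrix(directory / FIXTURE_FILES["beta"])
    annotation = mio.load_probe_annotation(directory / FIXTURE_FILES["annotation"])
    samples = mio.read_sample_sheet(directory / FIXTURE_FILES["samples"])
    expression = mio.read_expression_matrix(directory / FIXTURE_FILES["expression"])
    truth = PlantedTruth.from_jsonable(
        json.loads((directory / FIXTURE_FILES["truth"]).read_text())
    )
    config = config_from_dict(
        yaml.safe_load((directory / FIXTURE_FILES["config"]).read_text())
    )
    return SimulatedCohort(beta, annotation, samples, expression, truth, config)


def fixture_checksums(directory: str | Path) -> dict[str, str]:
    """SHA-256 of every fixture file (stability check across reruns)."""
    directory = Path(directory)
    return {
        name: hashlib.sha256((directory / fname).read_bytes()).hexdigest()
        for name, fname in FIXTURE_FILES.items()
        if (directory / fname).exists()
    }


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["cohorts"] = [dataclasses.asdict(c) for c in config.cohorts]
    for key in ("region_props", "unmeth_state", "meth_state",
                "region_hyper_weights", "age_range", "expr_baseline"):
        d[key] = list(d[key])
    for c in d["cohorts"]:
        c["burden_range"] = list(c["burden_range"])
    return d


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    data = dict(data)
    if "cohorts" in data:
        data["cohorts"] = tuple(
            CohortSpec(
                name=c["name"],
                n_tumors=int(c["n_tumors"]),
                n_normals=int(c["n_normals"]),
                burden_range=tuple(c.get("burden_range", (0.0, 0.0))),
            )
            for c in data["cohorts"]
        )
    if "size_link" in data and isinstance(data["size_link"], dict):
        data["size_link"] = SizeLink(**data["size_link"])
    for key in ("region_props", "unmeth_state", "meth_state",
                "region_hyper_weights", "age_range", "expr_baseline"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
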