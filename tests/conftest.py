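import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cimpkit as ck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_beta(values, probes=None, samples=None) -> ck.BetaMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ck.BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))


def make_annotation(region_by_probe, genes_by_probe=None) -> ck.ProbeAnnotation:
    genes_by_probe = genes_by_probe or {}
    df = pd.DataFrame(
        {
            "region_class": pd.Series(region_by_probe),
            "gene_symbols": pd.Series(
                {p: tuple(genes_by_probe.get(p, ())) for p in region_by_probe}
            ),
        }
    )
    df.index.name = "probe_id"
    return ck.ProbeAnnotation(df)


@pytest.fixture(scope="session")
def default_cohort() -> ck.SimulatedCohort:
    """The study-scale default synthetic cohort (20k probes, 34T/11N)."""
    return ck.simulate_cohort(ck.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config() -> ck.SimulationConfig:
    """Desk-scale two-cohort config for fast planted-truth tests."""
    return ck.SimulationConfig(
        n_probes=3000,
        cohorts=(
            ck.CohortSpec("CIMP-like", 6, 4, (0.20, 0.45)),
            ck.CohortSpec("quiet", 5, 4),
        ),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ck.SimulatedCohort:
    return ck.simulate_cohort(small_config)


def resimulate(config: ck.SimulationConfig, seed: int) -> ck.SimulatedCohort:
    return ck.simulate_cohort(dataclasses.replace(config, seed=seed))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
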