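import dataclasses

import numpy as np
import pandas as pd
import pytest

import cimpkit as ck

from _oracles import ts_hyper_probes
from conftest import make_annotation, make_beta, resimulate


def test_all_zero_matrix_gives_empty_set():
    beta = make_beta(np.zeros((10, 6)))
    res = ck.call_ts_hyper(beta, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
    assert len(res.probes) == 0


def test_boundary_probe_is_called():
    # normals {0.1, 0.15, 0.2, 0.05}: max exactly 0.2 (inclusive ≤),
    # tumor mean 0.525 gives Δ exactly 0.4 (inclusive ≥)
    values = np.array([[0.525, 0.525, 0.1, 0.15, 0.2, 0.05]])
    beta = make_beta(values, samples=["T0", "T1", "N0", "N1", "N2", "N3"])
    res = ck.call_ts_hyper(beta, ["T0", "T1"], ["N0", "N1", "N2", "N3"])
    assert list(res.probes) == ["cg000"]
    # nudging either clause past its boundary removes the call
    assert len(
        ck.call_ts_hyper(beta, ["T0", "T1"], ["N0", "N1", "N2", "N3"], delta=0.4001).probes
    ) == 0
    assert len(
        ck.call_ts_hyper(beta, ["T0", "T1"], ["N0", "N1", "N2", "N3"], normal_max=0.1999).probes
    ) == 0


def test_monotone_in_thresholds(rng):
    beta = make_beta(rng.random((300, 8)))
    tumors, normals = ["S0", "S1", "S2", "S3"], ["S4", "S5", "S6", "S7"]
    base = set(ck.call_ts_hyper(beta, tumors, normals, 0.2, 0.4).probes)
    looser_delta = set(ck.call_ts_hyper(beta, tumors, normals, 0.2, 0.3).probes)
    looser_nmax = set(ck.call_ts_hyper(beta, tumors, normals, 0.3, 0.4).probes)
    assert base <= looser_delta
    assert base <= looser_nmax


def test_matches_brute_force_on_random_matrix(rng):
    beta = make_beta(rng.random((400, 7)))
    tumors, normals = ["S0", "S1", "S2"], ["S3", "S4", "S5", "S6"]
    res = ck.call_ts_hyper(beta, tumors, normals)
    assert set(res.probes) == ts_hyper_probes(beta.df, tumors, normals)


def test_planted_recovery_on_synthetic_cohort(small_config):
    sens, fpr = [], []
    for rep in range(5):
        cohort = resimulate(small_config, 40 + rep)
        ss = cohort.samples
        res = ck.call_ts_hyper(
            cohort.beta,
            list(ss.tumors("CIMP-like")),
            list(ss.normals("CIMP-like")),
        )
        core = cohort.truth.cohort_core["CIMP-like"]
        called = set(res.probes)
        sens.append(len(called & core) / len(core))
        fpr.append(len(called - core) / (cohort.beta.shape[0] - len(core)))
    assert np.mean(sens) >= 0.95
    assert np.mean(fpr) <= 0.01


def test_empty_groups_rejected(rng):
    beta = make_beta(rng.random((5, 4)))
    with pytest.raises(ck.ValidationError):
        ck.call_ts_hyper(beta, [], ["S0"])


def test_agreement_improves_with_group_size():
    """Planted-vs-called F1 improves as tumor/normal group size grows."""

    def mean_f1(n_per_group):
        scores = []
        for rep in range(4):
            config = ck.SimulationConfig(
                n_probes=3000,
                cohorts=(ck.CohortSpec("c", n_per_group, n_per_group, (0.15, 0.45)),),
                seed=70 + rep,
            )
            cohort = ck.simulate_cohort(config)
            ss = cohort.samples
            called = set(
                ck.call_ts_hyper(
                    cohort.beta, list(ss.tumors()), list(ss.normals())
                ).probes
            )
            core = cohort.truth.cohort_core["c"]
            tp = len(called & core)
            precision = tp / len(called) if called else 0.0
            recall = tp / len(core)
            scores.append(
                0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
            )
        return np.mean(scores)

    f1 = {n: mean_f1(n) for n in (2, 4, 8)}
    assert f1[2] <= f1[4] + 0.02
    assert f1[4] <= f1[8] + 0.02
    assert f1[2] < f1[8]


# ---------------------------------------------------------------------------
# gene aggregation
# ---------------------------------------------------------------------------

def _toy_gene_setup():
    """6 probes / 3 genes; hand-planted TS-Hyper calls."""
    # tumors at 0.9 on called probes; normals at 0.05 everywhere
    values = np.full((6, 4), 0.05)
    for i in (0, 1, 2, 4):  # called probes
        values[i, :2] = 0.9
    beta = make_beta(values, samples=["T0", "T1", "N0", "N1"])
    regions = {
        "cg000": "island", "cg001": "island", "cg002": "island",
        "cg003": "island", "cg004": "shore_shelf", "cg005": "island",
    }
    genes = {
        "cg000": ("GA",), "cg001": ("GA", "GB"), "cg002": ("GB",),
        "cg003": ("GC",), "cg004": ("GC",), "cg005": ("GC",),
    }
    ann = make_annotation(regions, genes)
    res = ck.call_ts_hyper(beta, ["T0", "T1"], ["N0", "N1"], annotation=ann)
    assert set(res.probes) == {"cg000", "cg001", "cg002", "cg004"}
    return res, ann


def test_gene_counts_match_hand_enumeration():
    res, ann = _toy_gene_setup()
    # island TS-Hyper probes: cg000 (GA), cg001 (GA,GB), cg002 (GB);
    # cg004 is called but shore_shelf, so GC never reaches the threshold
    genes = ck.genes_from_probes(res, ann, min_island_probes=2)
    assert genes == {"GA": 2, "GB": 2}


def test_single_probe_gene_excluded_at_default_threshold():
    res, ann = _toy_gene_setup()
    at_one = ck.genes_from_probes(res, ann, min_island_probes=1)
    at_two = ck.genes_from_probes(res, ann, min_island_probes=2)
    assert set(at_two) <= set(at_one)
    assert set(at_one) == {"GA", "GB"}


def test_empty_ts_hyper_gives_empty_genes():
    beta = make_beta(np.zeros((4, 4)))
    ann = make_annotation({p: "island" for p in beta.probe_ids})
    res = ck.call_ts_hyper(beta, ["S0", "S1"], ["S2", "S3"], annotation=ann)
    assert ck.genes_from_probes(res, ann) == {}


# ---------------------------------------------------------------------------
# expression integration
# ---------------------------------------------------------------------------

def _expr(values, genes, samples):
    return ck.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def test_identical_expression_not_flagged(rng):
    base = rng.uniform(50, 150, size=(3, 4))
    expr = _expr(np.column_stack([base, base]), ["G1", "G2", "G3"],
                 [f"T{j}" for j in range(4)] + [f"N{j}" for j in range(4)])
    calls = ck.integrate_expression(
        {"G1": 2, "G2": 3, "G3": 2}, expr,
        [f"T{j}" for j in range(4)], [f"N{j}" for j in range(4)],
    )
    np.testing.assert_allclose(calls["expression_ratio"], 1.0, atol=1e-9)
    assert not calls["downregulated"].any()


def test_exact_half_expression_is_flagged(rng):
    normal = np.tile(np.array([100.0, 100.0, 100.0, 100.0]), (1, 1))
    tumor = 0.5 * normal + rng.normal(0, 1e-3, size=normal.shape)
    expr = _expr(np.column_stack([tumor, normal]), ["G1"],
                 ["T0", "T1", "T2", "T3", "N0", "N1", "N2", "N3"])
    calls = ck.integrate_expression(
        {"G1": 2}, expr, ["T0", "T1", "T2", "T3"], ["N0", "N1", "N2", "N3"]
    )
    assert calls.loc["G1", "expression_ratio"] == pytest.approx(0.5, abs=1e-4)
    assert bool(calls.loc["G1", "downregulated"])


def test_zero_normal_mean_is_unevaluable_not_error():
    expr = _expr([[0.0, 0.0, 0.0, 0.0], [5, 5, 5, 5]], ["G0", "G1"],
                 ["T0", "T1", "N0", "N1"])
    # G0 has zero normal mean; tumor/normal split: T* vs N*
    calls = ck.integrate_expression({"G0": 2, "G1": 2}, expr, ["T0", "T1"], ["N0", "N1"])
    assert not bool(calls.loc["G0", "evaluable"])
    assert not bool(calls.loc["G0", "downregulated"])


def test_gene_absent_from_expression_is_unevaluable():
    expr = _expr([[5, 5, 5, 5]], ["G1"], ["T0", "T1", "N0", "N1"])
    calls = ck.integrate_expression({"G1": 2, "G9": 2}, expr, ["T0", "T1"], ["N0", "N1"])
    assert not bool(calls.loc["G9", "evaluable"])


def test_planted_downregulation_recovered(default_cohort):
    cohort = default_cohort
    ss = cohort.samples
    planted = cohort.truth.methylated_genes["HLRCC"]
    all_genes = set(cohort.expression.gene_symbols)
    calls = ck.integrate_expression(
        all_genes, cohort.expression,
        list(ss.tumors("HLRCC")), list(ss.normals("HLRCC")),
    )
    flagged = set(calls.index[calls["downregulated"]])
    assert len(flagged & planted) / len(planted) >= 0.90
    unplanted = all_genes - planted
    assert len(flagged & unplanted) / len(unplanted) <= 0.05


# ---------------------------------------------------------------------------
# cross-cohort overlap
# ---------------------------------------------------------------------------

def _result_with(probes, universe, cohort):
    table = pd.DataFrame(
        {
            "normal_max_beta": 0.1,
            "tumor_mean": 0.8,
            "normal_mean": 0.1,
            "region": "island",
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ck.TsHyperResult(
        cohort=cohort, table=table, universe=pd.Index(universe),
        normal_max=0.2, delta=0.4, tumor_samples=("t",), normal_samples=("n",),
    )


def test_identical_sets_overlap_fully():
    universe = [f"cg{i}" for i in range(10)]
    a = _result_with(["cg1", "cg2"], universe, "A")
    b = _result_with(["cg1", "cg2"], universe, "B")
    out = ck.cross_cohort_overlap([a, b])
    assert out["intersection_all"] == 2
    assert out["per_set"] == {"A": 2, "B": 2}


def test_three_way_overlap_hand_case():
    universe = ["A", "B", "C", "D", "E"]
    r1 = _result_with(["A", "B"], universe, "s1")
    r2 = _result_with(["B", "C"], universe, "s2")
    r3 = _result_with(["B", "D"], universe, "s3")
    out = ck.cross_cohort_overlap([r1, r2, r3])
    assert out["intersection_all"] == 1
    assert out["union"] == 4
    assert out["exclusive"]["s1&s2&s3"] == 1          # {B}
    assert out["exclusive"]["s1"] == 1                # {A}
    assert out["pairwise"]["s1&s2"] == 1
    assert sum(out["exclusive"].values()) == out["union"]


def test_universes_intersected_before_counting():
    r1 = _result_with(["A", "B"], ["A", "B", "C"], "s1")
    r2 = _result_with(["B", "C"], ["B", "C", "D"], "s2")  # A not assessable
    out = ck.cross_cohort_overlap([r1, r2])
    assert out["universe_size"] == 2
    # A is not assessable in s2's universe, so s1 keeps only {B}
    assert out["per_set"] == {"s1": 1, "s2": 2}
    assert out["intersection_all"] == 1


def test_disjoint_universes_rejected():
    r1 = _result_with(["A"], ["A", "B"], "s1")
    r2 = _result_with(["C"], ["C", "D"], "s2")
    with pytest.raises(ck.ValidationError, match="disjoint"):
        ck.cross_cohort_overlap([r1, r2])
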