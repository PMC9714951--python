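import dataclasses

import numpy as np
import pytest

import cimpkit as ck

from _oracles import panel_candidates
from conftest import make_annotation, make_beta, resimulate


def _island_annotation(beta, every_other=False):
    regions = {}
    for i, p in enumerate(beta.probe_ids):
        regions[p] = "other" if (every_other and i % 2) else "island"
    return make_annotation(regions)


def test_all_zero_matrix_gives_empty_panel_with_warning():
    beta = make_beta(np.zeros((10, 6)))
    ann = _island_annotation(beta)
    with pytest.warns(UserWarning, match="no probes"):
        panel = ck.select_panel(beta, ["S0", "S1", "S2"], ["S3", "S4", "S5"], ann)
    assert panel.is_empty


def test_toy_candidates_match_brute_force(rng):
    # 10 probes, engineered so exactly 3 satisfy both clauses
    values = rng.uniform(0.25, 0.45, size=(10, 8))        # neither clause
    values[0] = [0.9, 0.8, 0.7, 0.9, 0.05, 0.1, 0.12, 0.02]
    values[4] = [0.6, 0.95, 0.8, 0.55, 0.01, 0.19, 0.15, 0.1]
    values[7] = [0.51, 0.52, 0.7, 0.9, 0.0, 0.0, 0.1, 0.19]
    values[8] = [0.9, 0.9, 0.9, 0.4, 0.1, 0.1, 0.1, 0.1]   # one positive too low
    values[9] = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.3]   # one negative too high
    beta = make_beta(values)
    ann = _island_annotation(beta)
    positives, negatives = ["S0", "S1", "S2", "S3"], ["S4", "S5", "S6", "S7"]
    panel = ck.select_panel(beta, positives, negatives, ann)
    expected = panel_candidates(
        beta.df, dict(ann.df["region_class"]), positives, negatives
    )
    assert set(panel.probes) == expected == {"cg000", "cg004", "cg007"}


def test_non_island_probes_never_selected(rng):
    values = np.tile([[0.9, 0.9, 0.05, 0.05]], (10, 1))
    beta = make_beta(values)
    ann = _island_annotation(beta, every_other=True)
    panel = ck.select_panel(beta, ["S0", "S1"], ["S2", "S3"], ann)
    regions = ann.df.loc[list(panel.probes), "region_class"]
    assert (regions == "island").all()
    assert len(panel) == 5


def test_tightening_clauses_never_grows_candidates(rng):
    beta = make_beta(rng.random((300, 10)))
    ann = _island_annotation(beta)
    positives = [f"S{j}" for j in range(5)]
    negatives = [f"S{j}" for j in range(5, 10)]

    def members(high, low):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty panels are fine here
            return set(
                ck.select_panel(
                    beta, positives, negatives, ann,
                    high_beta=high, low_beta=low, min_high_count=3,
                ).probes
            )

    base = members(0.5, 0.2)
    assert members(0.6, 0.2) <= base     # raising high_beta
    assert members(0.5, 0.15) <= base    # lowering low_beta


def test_ranking_is_deterministic_and_respects_top_k(rng):
    values = np.clip(rng.normal(0.8, 0.05, size=(50, 6)), 0, 1)
    values[:, 3:] = np.clip(rng.normal(0.05, 0.03, size=(50, 3)), 0, 1)
    beta = make_beta(values)
    ann = _island_annotation(beta)
    full = ck.select_panel(beta, ["S0", "S1", "S2"], ["S3", "S4", "S5"], ann)
    top = ck.select_panel(beta, ["S0", "S1", "S2"], ["S3", "S4", "S5"], ann, top_k=5)
    assert list(top.probes) == list(full.probes)[:5]
    assert (top.stats["p_value"].diff().dropna() >= 0).all()


# ---------------------------------------------------------------------------
# restriction
# ---------------------------------------------------------------------------

def test_restrict_to_full_universe_is_identity(rng, small_cohort):
    ss = small_cohort.samples
    positives = list(ss.tumors("CIMP-like"))
    negatives = [s for s in small_cohort.beta.sample_ids if s not in set(positives)]
    full = ck.select_panel(small_cohort.beta, positives, negatives,
                           small_cohort.annotation, top_k=10)
    restricted = ck.restrict_panel(
        small_cohort.beta, small_cohort.beta.probe_ids, positives, negatives,
        small_cohort.annotation, top_k=10,
    )
    assert restricted.probes == full.probes


def test_restrict_excluding_panel_members_yields_disjoint_panel(small_cohort):
    ss = small_cohort.samples
    positives = list(ss.tumors("CIMP-like"))
    negatives = [s for s in small_cohort.beta.sample_ids if s not in set(positives)]
    full = ck.select_panel(small_cohort.beta, positives, negatives,
                           small_cohort.annotation, top_k=10)
    universe = small_cohort.beta.probe_ids.difference(full.probes)
    with np.errstate(all="ignore"):
        reduced = ck.restrict_panel(
            small_cohort.beta, universe, positives, negatives,
            small_cohort.annotation, top_k=10,
        )
    assert set(reduced.probes).isdisjoint(full.probes)


def test_restriction_commutes_with_pre_subsetting(rng, small_cohort):
    ss = small_cohort.samples
    positives = list(ss.tumors("CIMP-like"))
    negatives = [s for s in small_cohort.beta.sample_ids if s not in set(positives)]
    universe = rng.choice(
        small_cohort.beta.probe_ids, size=small_cohort.beta.shape[0] // 10,
        replace=False,
    )
    via_restrict = ck.restrict_panel(
        small_cohort.beta, universe, positives, negatives,
        small_cohort.annotation, min_high_count=5,
    )
    pre_subset = small_cohort.beta.select(
        probes=[p for p in small_cohort.beta.probe_ids if p in set(universe)]
    )
    via_subset = ck.select_panel(
        pre_subset, positives, negatives, small_cohort.annotation, min_high_count=5
    )
    assert via_restrict.probes == via_subset.probes


def test_empty_restriction_universe_rejected(small_cohort):
    with pytest.raises(ck.ValidationError, match="empty"):
        ck.restrict_panel(
            small_cohort.beta, [], ["x"], ["y"], small_cohort.annotation
        )


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def _panel_of(probes, name="p"):
    import pandas as pd

    stats = pd.DataFrame(
        {"p_value": 0.0, "mean_difference": 0.5, "n_high_pos": 1},
        index=pd.Index(probes, name="probe_id"),
    )
    return ck.PanelDefinition(name, tuple(probes), stats, 0.5, 0.2, 1, None,
                              "group_p_value")


def test_all_zero_sample_is_non_cimp():
    beta = make_beta(np.zeros((4, 1)), samples=["X"])
    scores = ck.score_and_classify(beta, _panel_of(["cg000", "cg001"]),
                                   _panel_of(["cg002", "cg003"]))
    assert scores.loc["X", "sample_class"] == "non_CIMP"


def test_fully_methylated_sample_is_subtype_a():
    beta = make_beta(np.ones((4, 1)), samples=["X"])
    scores = ck.score_and_classify(beta, _panel_of(["cg000", "cg001"]),
                                   _panel_of(["cg002", "cg003"]))
    assert scores.loc["X", "sample_class"] == "CIMP_subtypeA_like"


def test_high_cimp_low_subtype_is_subtype_b():
    values = np.array([[0.9], [0.9], [0.1], [0.1]])
    beta = make_beta(values, samples=["X"])
    scores = ck.score_and_classify(beta, _panel_of(["cg000", "cg001"]),
                                   _panel_of(["cg002", "cg003"]))
    assert scores.loc["X", "sample_class"] == "CIMP_subtypeB_like"


def test_between_cutoffs_is_indeterminate():
    values = np.array([[0.27], [0.27], [0.1], [0.1]])
    beta = make_beta(values, samples=["X"])
    scores = ck.score_and_classify(beta, _panel_of(["cg000", "cg001"]),
                                   _panel_of(["cg002", "cg003"]))
    assert scores.loc["X", "sample_class"] == "indeterminate"


def test_low_panel_coverage_is_unscorable():
    values = np.array([[0.9], [np.nan], [np.nan], [np.nan]])
    beta = make_beta(values, samples=["X"])
    panel = _panel_of(["cg000", "cg001", "cg002", "cg003"])
    scores = ck.score_and_classify(beta, panel, _panel_of(["cg000"]))
    assert scores.loc["X", "sample_class"] == "unscorable"
    assert scores.loc["X", "cimp_coverage"] == pytest.approx(0.25)


def test_missing_panel_probes_shrink_the_denominator():
    values = np.array([[0.8], [0.4]])
    beta = make_beta(values, samples=["X"])
    # panel has 3 probes but only 2 are measured; mean over present = 0.6
    panel = _panel_of(["cg000", "cg001", "cg999"])
    scores = ck.score_and_classify(beta, panel, _panel_of(["cg000"]))
    assert scores.loc["X", "cimp_mean"] == pytest.approx(0.6)
    assert scores.loc["X", "cimp_coverage"] == pytest.approx(2 / 3)


def test_training_cohort_classification_is_self_consistent(small_cohort):
    beta, ann, ss = small_cohort.beta, small_cohort.annotation, small_cohort.samples
    positives = list(ss.tumors("CIMP-like"))
    negatives = [s for s in beta.sample_ids if s not in set(positives)]
    cimp_panel = ck.select_panel(beta, positives, negatives, ann, top_k=25)
    subtype_panel = cimp_panel  # single CIMP cohort: same panel on both axes
    scores = ck.score_and_classify(beta, cimp_panel, subtype_panel)
    for sample, row in scores.iterrows():
        if sample in set(positives):
            assert row["sample_class"] == "CIMP_subtypeA_like"
        else:
            assert row["sample_class"] == "non_CIMP"


def test_held_out_cohort_classified_correctly(small_config):
    train = ck.simulate_cohort(small_config)
    ss = train.samples
    positives = list(ss.tumors("CIMP-like"))
    negatives = [s for s in train.beta.sample_ids if s not in set(positives)]
    panel = ck.select_panel(train.beta, positives, negatives, train.annotation,
                            top_k=25)
    held_out = resimulate(small_config, 555)
    scores = ck.score_and_classify(held_out.beta, panel, panel)
    truth = held_out.samples.df
    for sample, row in scores.iterrows():
        expect_cimp = bool(truth.loc[sample, "is_tumor"]) and truth.loc[
            sample, "cohort"
        ] == "CIMP-like"
        assert row["sample_class"].startswith("CIMP") == expect_cimp


def test_empty_cimp_panel_rejected():
    beta = make_beta(np.zeros((2, 1)), samples=["X"])
    import pandas as pd

    empty = ck.PanelDefinition(
        "e", (), pd.DataFrame(columns=["p_value"]), 0.5, 0.2, 1, None,
        "group_p_value",
    )
    with pytest.raises(ck.ValidationError, match="empty"):
        ck.score_and_classify(beta, empty, empty)
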