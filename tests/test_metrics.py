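"""Senescence statistics: normalization, S-index, LAF, Rd, summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from senescan import (
    EventTable,
    MetricsConfig,
    ReferenceStats,
    compute_reference,
    default_spec,
    fisher_rd,
    rank_features,
    s_index,
    sample_summary,
    senescence_scores,
    simulate_events,
)
from senescan.errors import RankingError, ReferenceStatsError, SummaryError
from senescan.gating import GateLabels
from senescan.pipeline import live_singles


def _table(af, d, sample_id="s", **extra):
    return EventTable(
        pd.DataFrame({
            "event_id": range(len(af)), "sample_id": sample_id,
            "af": af, "diameter": d, **extra,
        })
    )


# ---------------------------------------------------------------- reference

def test_reference_arithmetic():
    t = _table([900.0, 900.0, 921.0], [26.0, 27.0, 27.1])
    ref = compute_reference(t, min_events=1)
    assert ref.mean_af == pytest.approx(907.0)
    assert ref.mean_d == pytest.approx(26.7, abs=0.05)


def test_reference_requires_minimum_events():
    with pytest.raises(ReferenceStatsError):
        compute_reference(_table([], []))


def test_reference_recovery_on_synthetic_prolif(huvec_prolif):
    live, _ = live_singles(huvec_prolif.table)
    ref = compute_reference(live)
    assert ref.mean_af == pytest.approx(907.0, rel=0.01)
    assert ref.mean_d == pytest.approx(26.7, rel=0.01)


# ---------------------------------------------------------------- S-index

def test_si_zero_at_unity_both_variants():
    assert s_index(1.0, 1.0, variant="reconciled") == 0.0
    assert s_index(1.0, 1.0, variant="as_printed") == 0.0


def test_printed_population_means_reproduce_reported_si():
    """The published HUVEC means (AF 1915 vs 907; D 32.2 vs 26.7 µm) give a
    reconciled SI of ~2.14 (reported mean 2.1); the halved as-printed
    variant gives ~1.07 and does not match the reported value."""
    naf, nd = 1915.0 / 907.0, 32.2 / 26.7
    assert naf == pytest.approx(2.111, abs=0.001)
    assert nd == pytest.approx(1.206, abs=0.001)
    assert s_index(naf, nd) == pytest.approx(2.141, abs=0.001)
    assert s_index(naf, nd, variant="as_printed") == pytest.approx(1.071, abs=0.001)


def test_laf_threshold_logic():
    ref = ReferenceStats(mean_af=1000.0, mean_d=25.0, n=100)
    t = _table([1600.0, 1600.0, 1500.0], [26.25, 28.75, 27.5])  # nD 1.05/1.15/1.1
    scores = senescence_scores(t, ref)
    assert list(scores.per_event["laf"]) == [False, True, True]  # inclusive >=


def test_self_normalization_is_exact(huvec_sen):
    df = huvec_sen.table.data
    ref = compute_reference(huvec_sen.table)
    scores = senescence_scores(huvec_sen.table, ref)
    assert scores.per_event["naf"].mean() == pytest.approx(1.0, abs=1e-12)
    assert scores.per_event["nd"].mean() == pytest.approx(1.0, abs=1e-12)
    assert scores.mean_si == pytest.approx(0.0, abs=1e-9)


def test_pct_laf_monotone_in_thresholds(huvec_sen, huvec_prolif):
    live, _ = live_singles(huvec_prolif.table)
    ref = compute_reference(live)
    base = senescence_scores(huvec_sen.table, ref).pct_laf
    for cfg in (MetricsConfig(laf_naf_threshold=2.0), MetricsConfig(laf_nd_threshold=1.3)):
        assert senescence_scores(huvec_sen.table, ref, cfg).pct_laf <= base


@settings(deadline=None, derandomize=True)
@given(
    naf=st.floats(0.1, 5.0), nd=st.floats(0.1, 3.0),
    dn=st.floats(0.0, 1.0), dd=st.floats(0.0, 1.0),
)
def test_si_monotone_in_both_arguments(naf, nd, dn, dd):
    assert s_index(naf + dn, nd + dd) >= s_index(naf, nd)


# ---------------------------------------------------------------- Fisher Rd

def test_rd_identical_groups_is_zero():
    assert fisher_rd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_rd_on_printed_huvec_stats():
    """(1915−907)/(148+69) ≈ 4.65, built from two-point groups with the
    exact printed means and SDs."""
    sen = [1915 - 148 / np.sqrt(2), 1915 + 148 / np.sqrt(2)]
    prolif = [907 - 69 / np.sqrt(2), 907 + 69 / np.sqrt(2)]
    assert fisher_rd(sen, prolif) == pytest.approx(1008 / 217, abs=1e-9)


def test_rd_gaussian_closed_form(rng):
    a = rng.normal(3, 1, 10000)
    b = rng.normal(0, 1, 10000)
    assert fisher_rd(a, b) == pytest.approx(1.5, abs=0.05)


def test_rd_zero_spread_saturates():
    assert fisher_rd([1.0, 1.0], [1.0, 1.0]) == 0.0
    assert fisher_rd([2.0, 2.0], [1.0, 1.0]) == np.inf


@settings(deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
def test_rd_invariant_to_common_affine_rescaling(scale, shift):
    a = np.array([1.0, 2.0, 4.0, 5.5])
    b = np.array([6.0, 7.5, 9.0])
    base = fisher_rd(a, b)
    assert fisher_rd(scale * a + shift, scale * b + shift) == pytest.approx(base, rel=1e-6)


# ---------------------------------------------------------------- ranking

def test_rank_features_area_extremes(huvec_prolif, huvec_sen):
    """Merged proliferating+senescent truth built from 20 events at each
    area extreme: AF and diameter both discriminate at |Rd| >= 1.5."""
    prolif_live, _ = live_singles(huvec_prolif.table)
    sen_live, _ = live_singles(huvec_sen.table)
    df = pd.concat(
        [prolif_live.data.sample(2500, random_state=0),
         sen_live.data.sample(2500, random_state=0)],
        ignore_index=True,
    ).assign(event_id=lambda d: np.arange(len(d)))
    order = df["area"].rank(method="first")
    labels = pd.Series([None] * len(df), dtype=object)
    labels[order <= 20] = "true_nonsenescent"
    labels[order > len(df) - 20] = "true_senescent"
    ranked = rank_features(EventTable(df), labels, ["af", "diameter", "area", "aspect_ratio"])
    by_name = dict(ranked)
    # diameter separates sharply; AF separates too, though a 20-cell gallery
    # leaves its Rd noisy given the heavy per-cell AF spread
    assert abs(by_name["diameter"]) >= 1.5
    assert abs(by_name["af"]) >= 1.0
    assert {ranked[0][0], ranked[1][0], ranked[2][0]} >= {"diameter", "af"} or \
        abs(by_name["af"]) > abs(by_name["aspect_ratio"])


def test_constant_feature_ranked_last():
    df = pd.DataFrame({
        "event_id": range(40), "af": np.r_[np.zeros(20), np.ones(20)],
        "flat": np.ones(40),
    })
    labels = ["a"] * 20 + ["b"] * 20
    ranked = rank_features(EventTable(df), labels, ["af", "flat"])
    assert ranked[-1] == ("flat", 0.0)


def test_single_class_ranking_error():
    df = pd.DataFrame({"event_id": range(10), "af": np.arange(10.0)})
    with pytest.raises(RankingError):
        rank_features(EventTable(df), ["only"] * 10, ["af"])


# ---------------------------------------------------------------- summaries

def _manual_labels(n, n_live, n_apop, n_dead):
    pop = pd.Series(["single"] * n)
    via = pd.Series(["live"] * n_live + ["apoptotic"] * n_apop + ["dead"] * n_dead)
    return GateLabels(pop, via)


def test_summary_viability_arithmetic():
    t = _table(np.full(100, 1000.0), np.full(100, 25.0))
    labels = _manual_labels(100, 80, 10, 10)
    ref = ReferenceStats(mean_af=1000.0, mean_d=25.0, n=100)
    scores = senescence_scores(t, ref)
    summary = sample_summary(t, labels, scores).loc["s"]
    assert summary["pct_live"] == 80.0
    assert summary["pct_apoptotic"] == 10.0
    assert summary["mean_si"] == 0.0
    assert summary["pct_laf"] == 0.0


def test_summary_zero_singles_is_error():
    t = _table([1000.0], [25.0])
    labels = GateLabels(pd.Series(["excluded"]), pd.Series(["unassigned"]))
    scores = senescence_scores(t, ReferenceStats(1000.0, 25.0, 100))
    with pytest.raises(SummaryError):
        sample_summary(t, labels, scores)


def test_senolytic_pattern_on_survivors():
    """Senolytic-treated senescent culture: %live drops, %apoptotic rises,
    but SI of the surviving live cells is unchanged within noise."""
    def _spec(apop, seed):
        spec = default_spec("MearF", "senescent", seed=seed)
        sen = spec.phenotypes["senescent"]
        spec.phenotypes = {
            "proliferating": dataclasses.replace(spec.phenotypes["proliferating"], fraction=0.0),
            "senescent": dataclasses.replace(sen, fraction=1.0 - apop - 0.1),
            "apoptotic": dataclasses.replace(spec.phenotypes["apoptotic"], fraction=apop),
            "dead": dataclasses.replace(spec.phenotypes["dead"], fraction=0.1),
        }
        return spec

    untreated = simulate_events(_spec(0.1, 61), 8000)
    treated = simulate_events(_spec(0.4, 62), 8000)
    ref = ReferenceStats(mean_af=1309.0, mean_d=24.4, n=1000)

    results = {}
    for name, sample in (("untreated", untreated), ("treated", treated)):
        live, labels = live_singles(sample.table)
        scores = senescence_scores(
            EventTable(sample.table.data), ref
        )
        results[name] = sample_summary(sample.table, labels, scores).iloc[0]
    assert results["treated"]["pct_live"] < results["untreated"]["pct_live"] - 20
    assert results["treated"]["pct_apoptotic"] > results["untreated"]["pct_apoptotic"] + 20
    assert results["treated"]["mean_si"] == pytest.approx(
        results["untreated"]["mean_si"], abs=0.15
    )
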