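"""MLSC training, scoring, joint decision rule, second pass, clipped rule."""

import numpy as np
import pandas as pd
import pytest

from senescan import (
    EventTable,
    TruthConfig,
    build_truth,
    classify_joint,
    compute_reference,
    default_spec,
    flag_clipped,
    render_cells,
    score_events,
    senescence_scores,
    simulate_events,
    train_mlsc,
    train_mlsc2,
)
from senescan.classifier import NONS_TRUTH, S_TRUTH
from senescan.errors import NoSignalError, TrainingError, TruthError
from senescan.pipeline import live_singles


def _toy_table(si=None, condition=None, **cols):
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"event_id": range(n), "af": np.ones(n), **cols})
    if condition is not None:
        df["condition"] = condition
    return EventTable(df)


# ------------------------------------------------------------- truth sets

def test_truth_thresholds_and_source_constraint():
    t = _toy_table(
        x=np.zeros(4),
        condition=["proliferating", "senescent", "senescent", "proliferating"],
    )
    si = [0.5, 1.5, 0.5, 1.0]
    labels = build_truth(t, si)
    assert labels.iloc[0] == NONS_TRUTH  # control, SI <= 0.8
    assert labels.iloc[1] == S_TRUTH  # induced, SI >= 1.2
    assert labels.iloc[2] is None  # induced with low SI: source constraint
    assert labels.iloc[3] is None  # between the thresholds


def test_empty_truth_set_raises():
    t = _toy_table(x=np.zeros(2), condition=["proliferating", "proliferating"])
    with pytest.raises(TruthError):
        build_truth(t, [0.5, 0.6])


@pytest.fixture(scope="module")
def trained_huvec(huvec_pair_small):
    """Merged HUVEC pair with SI, truth labels and a 70/30 split classifier."""
    prolif, sen = huvec_pair_small
    prolif_live, _ = live_singles(prolif.table)
    sen_live, _ = live_singles(sen.table)
    merged = pd.concat([prolif_live.data, sen_live.data], ignore_index=True)
    merged["event_id"] = np.arange(len(merged))
    table = EventTable(merged)
    ref = compute_reference(prolif_live)
    si = senescence_scores(table, ref).per_event["si"]
    truth = build_truth(table, si)
    rng = np.random.default_rng(77)
    is_train = rng.random(len(merged)) < 0.7
    train_labels = truth.copy()
    train_labels[~is_train] = None
    clf = train_mlsc(table, train_labels)
    return table, si, truth, is_train, clf


def test_truth_sets_are_substantial(trained_huvec):
    table, _, truth, _, _ = trained_huvec
    df = table.data
    n_s = (truth == S_TRUTH).sum()
    n_n = (truth == NONS_TRUTH).sum()
    assert n_s >= 0.1 * (df.condition == "senescent").sum()
    assert n_n >= 0.1 * (df.condition == "proliferating").sum()


# ------------------------------------------------------------- training

def test_1d_toy_boundary_matches_closed_form(rng):
    """Equal-variance 1-D LDA: the decision boundary is the midpoint of the
    class sample means (closed form), and held-out sign accuracy >= 95%."""
    a = rng.normal(0, 1, 500)
    b = rng.normal(4, 1, 500)
    df = pd.DataFrame({"event_id": range(1000), "af": np.r_[a, b].clip(0), "x": np.r_[a, b]})
    labels = pd.Series([NONS_TRUTH] * 500 + [S_TRUTH] * 500)
    clf = train_mlsc(EventTable(df), labels, feature_set=["x"])
    w, b0 = clf.weights[0], clf.offset
    boundary_raw = clf.means[0] + clf.sds[0] * (-b0 / w)
    midpoint = (a.mean() + b.mean()) / 2
    assert boundary_raw == pytest.approx(midpoint, abs=1e-9)
    # held-out draws
    hold_a = rng.normal(0, 1, 500)
    hold_b = rng.normal(4, 1, 500)
    hold = pd.DataFrame({"event_id": range(1000), "af": np.ones(1000), "x": np.r_[hold_a, hold_b]})
    scores = score_events(EventTable(hold), clf)
    acc = ((scores[:500] < 0).mean() + (scores[500:] > 0).mean()) / 2
    assert acc >= 0.95


def test_identical_classes_give_no_signal(rng):
    x = rng.normal(0, 1, 400)
    df = pd.DataFrame({"event_id": range(400), "af": np.ones(400), "x": x})
    labels = pd.Series([S_TRUTH] * 200 + [NONS_TRUTH] * 200)
    with pytest.raises(NoSignalError):
        train_mlsc(EventTable(df), labels, feature_set=["x"])


def test_synthetic_truth_heldout_sign_accuracy(trained_huvec):
    table, _, truth, is_train, clf = trained_huvec
    scores = score_events(table, clf)
    hold_s = scores[(truth == S_TRUTH).to_numpy() & ~is_train]
    hold_n = scores[(truth == NONS_TRUTH).to_numpy() & ~is_train]
    assert hold_s.mean() > 0
    assert hold_n.mean() < 0
    accuracy = ((hold_s > 0).sum() + (hold_n < 0).sum()) / (len(hold_s) + len(hold_n))
    assert accuracy >= 0.95


def test_training_events_rescore_identically(trained_huvec):
    table, _, truth, is_train, clf = trained_huvec
    scores1 = score_events(table, clf)
    scores2 = score_events(table, clf)
    np.testing.assert_array_equal(scores1, scores2)


def test_affine_feature_rescaling_preserves_decisions(trained_huvec):
    table, _, _, _, clf = trained_huvec
    scores = score_events(table, clf)
    rescaled = table.data.copy()
    rescaled["af"] = 3.5 * rescaled["af"] + 100.0
    rescaled["diameter"] = 0.25 * rescaled["diameter"] + 1.0
    # re-train on rescaled features with the same truth induces the same
    # standardized problem; scoring with adjusted standardization is identical
    clf2 = type(clf)(
        features=clf.features,
        means=np.array([
            3.5 * m + 100.0 if f == "af" else (0.25 * m + 1.0 if f == "diameter" else m)
            for f, m in zip(clf.features, clf.means)
        ]),
        sds=np.array([
            3.5 * s if f == "af" else (0.25 * s if f == "diameter" else s)
            for f, s in zip(clf.features, clf.sds)
        ]),
        weights=clf.weights,
        offset=clf.offset,
    )
    scores2 = score_events(EventTable(rescaled), clf2)
    np.testing.assert_allclose(scores2, scores, rtol=1e-9, atol=1e-9)


def test_label_swap_negates_scores(trained_huvec):
    table, _, truth, _, _ = trained_huvec
    swapped = truth.map({S_TRUTH: NONS_TRUTH, NONS_TRUTH: S_TRUTH})
    clf_a = train_mlsc(table, truth)
    clf_b = train_mlsc(table, swapped)
    s1 = score_events(table, clf_a)
    s2 = score_events(table, clf_b)
    np.testing.assert_allclose(s2, -s1, rtol=1e-6, atol=1e-6)


def test_boundary_converges_to_midpoint_with_n(rng):
    errs = []
    for n in (100, 1000, 10000):
        a = rng.normal(0, 1, n)
        b = rng.normal(2, 1, n)
        df = pd.DataFrame({"event_id": range(2 * n), "af": np.ones(2 * n), "x": np.r_[a, b]})
        labels = pd.Series([NONS_TRUTH] * n + [S_TRUTH] * n)
        clf = train_mlsc(EventTable(df), labels, feature_set=["x"])
        boundary = clf.means[0] + clf.sds[0] * (-clf.offset / clf.weights[0])
        errs.append(abs(boundary - 1.0))
    assert errs[-1] < 0.05


# ------------------------------------------------------------- joint rule

def test_quadrant_rule():
    res = classify_joint([1.0, -0.5, -0.5, 0.0], [2.0, 2.0, -1.0, 0.0])
    assert list(res.decision) == ["senescent", "ambiguous", "non_senescent", "ambiguous"]


def test_all_zero_scores_are_ambiguous():
    res = classify_joint(np.zeros(5), np.zeros(5))
    assert (res.decision == "ambiguous").all()
    assert res.fraction_senescent == 0.0


def test_joint_rule_more_conservative_than_mlsc(trained_huvec):
    table, si, _, _, clf = trained_huvec
    mlsc = score_events(table, clf)
    res = classify_joint(si, mlsc)
    called = res.decision == "senescent"
    assert (mlsc[called.to_numpy()] > 0).all()


def test_mixture_fraction_recovered(trained_huvec):
    table, si, _, _, clf = trained_huvec
    df = table.data
    # balanced mixture of live singles from both conditions
    n = min((df.condition == "proliferating").sum(), (df.condition == "senescent").sum())
    idx = np.r_[np.where(df.condition == "proliferating")[0][:n],
                np.where(df.condition == "senescent")[0][:n]]
    mlsc = score_events(table, clf)[idx]
    res = classify_joint(si.iloc[idx], mlsc)
    truth_frac = (df.iloc[idx].true_phenotype == "senescent").mean()
    sen = (df.iloc[idx].true_phenotype == "senescent").to_numpy()
    # the boundary is calibrated between the truth extremes, so borderline
    # senescent cells score negative: the senescent-zone fraction is a
    # conservative estimate of the true mixture, never an overestimate
    assert truth_frac - 0.15 <= res.fraction_senescent <= truth_frac + 0.03
    assert mlsc[sen].mean() > 0 > mlsc[~sen].mean()
    # false-positive side stays clean
    assert (res.decision[~sen] == "senescent").mean() <= 0.05


# ------------------------------------------------------------- second pass

def test_mlsc2_agrees_on_separated_mixture():
    rng = np.random.default_rng(99)
    n = 2000
    x = np.r_[rng.normal(0, 1, n), rng.normal(6, 1, n)]  # cleanly separated
    df = pd.DataFrame({"event_id": range(2 * n), "af": np.ones(2 * n), "x": x})
    labels = pd.Series([NONS_TRUTH] * n + [S_TRUTH] * n)
    t = EventTable(df)
    clf = train_mlsc(t, labels, feature_set=["x"])
    mlsc = score_events(t, clf)
    clf2 = train_mlsc2(t, mlsc, feature_set=["x"])
    mlsc2 = score_events(t, clf2)
    assert (np.sign(mlsc2) == np.sign(mlsc)).mean() >= 0.98


def test_mlsc2_zero_extremes_raises(trained_huvec):
    table, _, _, _, clf = trained_huvec
    with pytest.raises(TrainingError):
        train_mlsc2(table, score_events(table, clf), extreme_fraction=0.0)


def test_mlsc2_margin_on_overlapping_mixture():
    """With the effect size halved (overlapping classes), retraining on the
    confident extremes does not shrink the margin on the truth events."""
    rng = np.random.default_rng(88)
    n = 3000
    a = rng.normal(0, 1, n)
    b = rng.normal(1.0, 1, n)  # heavy overlap
    df = pd.DataFrame({"event_id": range(2 * n), "af": np.ones(2 * n), "x": np.r_[a, b]})
    labels = pd.Series([NONS_TRUTH] * n + [S_TRUTH] * n)
    t = EventTable(df)
    clf = train_mlsc(t, labels, feature_set=["x"])
    mlsc = score_events(t, clf)
    clf2 = train_mlsc2(t, mlsc, feature_set=["x"])
    mlsc2 = score_events(t, clf2)
    assert np.abs(mlsc2).mean() >= np.abs(mlsc).mean()


# ------------------------------------------------------------- clipped rule

def test_clipped_rule_on_rendered_gallery():
    spec = default_spec("HUVEC", "mixed", seed=91)
    spec.clipped_rate, spec.doublet_rate, spec.multiplet_rate = 0.1, 0.0, 0.0
    sample = render_cells(spec, 120)
    flags = flag_clipped(images=sample.images)
    truth = (sample.table["true_structure"] == "clipped").to_numpy()
    recall = flags[truth].mean() if truth.any() else 1.0
    assert recall >= 0.99
    assert flags[~truth].mean() <= 0.05


def test_clipped_from_feature_table(huvec_prolif):
    flags = flag_clipped(table=huvec_prolif.table)
    truth = (huvec_prolif.table["true_structure"] == "clipped").to_numpy()
    np.testing.assert_array_equal(flags, truth)
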