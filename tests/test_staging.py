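"""Epoch features, rule-based and tree stagers, metrics and summaries."""

import numpy as np
import pandas as pd
import pytest

import somnokit as sk

from _oracles import naive_roc_auc


def _features_row(**kw):
    row = {"epoch_index": 0, "toss_turn_rate": 0.0, "toss_turn_duration_s": 0.0,
           "snore_count": 0, "snore_regular_frac": 0.5,
           "snore_mean_intensity_db": np.nan, "body_temp_mean_c": 36.5,
           "body_temp_std_c": 0.0, "room_temp_mean_c": 22.5,
           "co2_mean_ppm": 500.0, "posture": "supine", "posture_code": 0}
    row.update(kw)
    return row


# ---------------------------------------------------------------------------
# epoch features

def test_event_free_epoch_zero_rates(night_products):
    f = night_products["features"]
    quiet = f[(f.toss_turn_rate == 0) & (f.snore_count == 0)]
    assert (quiet.toss_turn_duration_s == 0).all()


def test_snore_attributed_to_onset_epoch(tiny_session):
    n = 180
    session = sk.SessionRecord(
        pressure=np.full((n, 8), 30.0), sound_db=np.full(n, 25.0),
        body_temp=np.full(n, 36.5), room_temp=np.full(n, 22.5),
        humidity=np.full(n, 45.0), co2=np.full(n, 500.0))
    snore = [sk.Event(sk.EventKind.SNORE, 55, 70, {"peak_db": 40.0})]
    segments = [sk.PostureSegment(sk.Posture.SUPINE, 0, n)]
    f = sk.epoch_features(session, [], snore, segments)
    assert list(f.snore_count) == [1, 0, 0]  # onset epoch only


def test_features_match_brute_force_recount(night_products):
    f = night_products["features"]
    toss, epoch_len = night_products["toss"], 60
    for k in (0, 50, 137, 300):
        lo, hi = k * epoch_len, (k + 1) * epoch_len
        n_toss = sum(1 for e in toss if lo <= e.start < hi)
        overlap = sum(max(0, min(e.end, hi) - max(e.start, lo)) for e in toss)
        assert f.toss_turn_rate[k] == pytest.approx(n_toss / 1.0)
        assert f.toss_turn_duration_s[k] == overlap
        sess = night_products["session"]
        assert f.co2_mean_ppm[k] == pytest.approx(sess.co2[lo:hi].mean())


def test_epoch_len_must_fit():
    session = sk.SessionRecord(
        pressure=np.full((30, 8), 30.0), sound_db=np.full(30, 25.0),
        body_temp=np.full(30, 36.5), room_temp=np.full(30, 22.5),
        humidity=np.full(30, 45.0), co2=np.full(30, 500.0))
    with pytest.raises(sk.ValidationError, match="epoch_len"):
        sk.epoch_features(session, [], [],
                          [sk.PostureSegment(sk.Posture.SUPINE, 0, 30)],
                          epoch_len=60)


def test_hr_columns_absent_without_channel(night_products):
    session = night_products["session"]
    segments = night_products["segments"]
    stripped = sk.SessionRecord(
        pressure=session.pressure, sound_db=session.sound_db,
        body_temp=session.body_temp, room_temp=session.room_temp,
        humidity=session.humidity, co2=session.co2)
    f = sk.epoch_features(stripped, [], [], segments)
    assert "hr_mean_bpm" not in f.columns


# ---------------------------------------------------------------------------
# rule-based staging

def test_rule_maximal_nrem_case():
    f = pd.DataFrame([_features_row(snore_count=10, snore_regular_frac=1.0)])
    hyp, score = sk.stage_rule_based(f)
    assert score[0] == pytest.approx(1.0)
    assert hyp.labels == [sk.Stage.NREM]


def test_rule_hand_evaluated_rem_case():
    # 6 toss events/min, no snoring, temp std 1.0:
    # 0.5/(1+6) + 0.3*0.5 + 0.2/(1+1)
    f = pd.DataFrame([_features_row(toss_turn_rate=6.0, snore_count=0,
                                    body_temp_std_c=1.0)])
    hyp, score = sk.stage_rule_based(f)
    assert score[0] == pytest.approx(0.5 / 7 + 0.15 + 0.1)
    assert hyp.labels == [sk.Stage.REM]


def test_rule_monotone_in_movement_and_regularity():
    base = _features_row(snore_count=5, snore_regular_frac=0.5)
    scores = []
    for rate in (0.0, 1.0, 3.0, 10.0):
        _, s = sk.stage_rule_based(pd.DataFrame([dict(base,
                                                      toss_turn_rate=rate)]))
        scores.append(s[0])
    assert all(a >= b for a, b in zip(scores, scores[1:]))
    scores = []
    for frac in (0.0, 0.4, 0.8, 1.0):
        _, s = sk.stage_rule_based(pd.DataFrame(
            [dict(base, snore_regular_frac=frac)]))
        scores.append(s[0])
    assert all(a <= b for a, b in zip(scores, scores[1:]))


def test_rule_recovers_simulated_hypnogram(night_products):
    """Parameter recovery: >= 80% epoch agreement with simulator truth."""
    hyp, _ = sk.stage_rule_based(night_products["features"])
    truth = night_products["truth"].hypnogram
    agree = np.mean([
        p == t or (t == sk.Stage.WAKE and p == sk.Stage.REM)
        for p, t in zip(hyp.labels, truth.labels)])
    assert agree >= 0.80


# ---------------------------------------------------------------------------
# heart-rate reference

def test_hr_reference_constant_rates():
    assert set(sk.hr_reference_hypnogram(np.full(300, 58.0)).labels) == \
        {sk.Stage.NREM}
    assert set(sk.hr_reference_hypnogram(np.full(300, 85.0)).labels) == \
        {sk.Stage.REM}


def test_hr_reference_alternating_epochs():
    hr = np.concatenate([np.full(60, 58.0), np.full(60, 85.0)] * 3)
    hyp = sk.hr_reference_hypnogram(hr)
    assert hyp.labels == [sk.Stage.NREM, sk.Stage.REM] * 3


def test_hr_reference_requires_channel():
    with pytest.raises(sk.ValidationError):
        sk.hr_reference_hypnogram(None)


def test_hr_reference_independent_of_rule_inputs(night_products):
    """The reference and the rule scorer consume disjoint channels, so
    their agreement on simulated nights is a real validation statistic."""
    ref = sk.hr_reference_hypnogram(night_products["session"].heart_rate)
    hyp, _ = sk.stage_rule_based(night_products["features"])
    agree = np.mean([a == b for a, b in zip(ref.labels, hyp.labels)])
    assert agree >= 0.75


# ---------------------------------------------------------------------------
# tree classifiers

def test_tree_perfect_on_separable_features():
    rows = [_features_row(toss_turn_rate=0.0) for _ in range(20)] + \
           [_features_row(toss_turn_rate=9.0) for _ in range(20)]
    f = pd.DataFrame(rows)
    labels = [sk.Stage.NREM] * 20 + [sk.Stage.REM] * 20
    for model in ("decision_tree", "random_forest"):
        sm = sk.train_stage_classifier(f, labels, model=model, seed=0)
        pred = sm.predict(f)
        assert pred.labels == labels


def test_tree_rejects_single_class():
    f = pd.DataFrame([_features_row() for _ in range(10)])
    with pytest.raises(sk.ValidationError, match="single class"):
        sk.train_stage_classifier(f, [sk.Stage.NREM] * 10)


def test_tree_never_sees_heart_rate(night_products):
    f = night_products["features"]
    assert "hr_mean_bpm" in f.columns
    assert not any(c.startswith("hr_") for c in sk.PREDICTOR_COLUMNS)
    truth = night_products["truth"].hypnogram
    sm = sk.train_stage_classifier(f, truth, seed=0)
    # scoring is invariant to arbitrary heart-rate values
    f2 = f.copy()
    f2["hr_mean_bpm"] = 999.0
    assert np.array_equal(sm.predict_proba_rem(f), sm.predict_proba_rem(f2))


def test_label_shuffled_auc_near_half(night_products):
    """Permutation null: shuffled training labels give chance-level AUC."""
    f = night_products["features"]
    truth = night_products["truth"].hypnogram
    rng = np.random.default_rng(0)
    shuffled = list(rng.permutation([l.value for l in truth.labels]))
    sm = sk.train_stage_classifier(f, shuffled, seed=0)
    rep = sk.evaluate(sm.predict_proba_rem(f), truth)
    assert abs(rep.auc - 0.5) < 0.15


# ---------------------------------------------------------------------------
# evaluation metrics

def test_perfect_scores_perfect_metrics():
    ref = [sk.Stage.REM] * 5 + [sk.Stage.NREM] * 5
    scores = np.array([0.9] * 5 + [0.1] * 5)
    rep = sk.evaluate(scores, ref)
    assert (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.auc) == \
        (1.0, 1.0, 1.0, 1.0, 1.0)


def test_hand_confusion_matrix_metrics():
    # TP=3 FP=1 FN=2 TN=4 with REM positive
    ref = [sk.Stage.REM] * 5 + [sk.Stage.NREM] * 5
    scores = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1])
    rep = sk.evaluate(scores, ref)
    assert rep.accuracy == pytest.approx(0.7)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_reversed_scores_flip_auc():
    rng = np.random.default_rng(1)
    ref = [sk.Stage.REM if v else sk.Stage.NREM
           for v in rng.integers(0, 2, size=50)]
    scores = rng.random(50)
    a = sk.evaluate(scores, ref).auc
    b = sk.evaluate(1.0 - scores, ref).auc
    assert a + b == pytest.approx(1.0)


def test_single_class_reference_rejected():
    with pytest.raises(sk.ValidationError, match="single class"):
        sk.evaluate(np.array([0.2, 0.8]), [sk.Stage.NREM, sk.Stage.NREM])


def test_roc_matches_brute_force_enumeration():
    """AUC equals an all-thresholds enumeration oracle, ties included."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = int(rng.integers(20, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        ref = [sk.Stage.REM if v else sk.Stage.NREM for v in labels]
        rep = sk.evaluate(scores, ref)
        assert rep.auc == pytest.approx(naive_roc_auc(scores, labels))
        fprs = [p[0] for p in rep.roc_points]
        tprs = [p[1] for p in rep.roc_points]
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))


def test_wake_reference_counts_as_rem():
    ref = [sk.Stage.WAKE, sk.Stage.NREM]
    rep = sk.evaluate(np.array([0.9, 0.1]), ref)
    assert rep.accuracy == 1.0


# ---------------------------------------------------------------------------
# night summary

def test_summary_conserves_duration(night_products):
    session = night_products["session"]
    truth = night_products["truth"]
    events = {sk.EventKind.TOSS_TURN: night_products["toss"],
              sk.EventKind.SNORE: night_products["snore"]}
    summary = sk.summarize_night(session, night_products["segments"], events,
                                 truth.hypnogram)
    assert summary.minutes.sum() * 60 == pytest.approx(session.duration_s)
    posture_cols = [c for c in summary.columns if c.endswith("_min")
                    and c != "minutes"]
    for _, row in summary.iterrows():
        assert sum(row[c] for c in posture_cols) == pytest.approx(row.minutes)


def test_summary_matches_brute_force_recount(night_products):
    session = night_products["session"]
    truth = night_products["truth"]
    snore = night_products["snore"]
    events = {sk.EventKind.SNORE: snore}
    summary = sk.summarize_night(session, night_products["segments"], events,
                                 truth.hypnogram).set_index("stage")
    per_sec = [s.value for s in truth.hypnogram.stage_per_second(
        session.duration_s)]
    for stage in ("nrem", "rem"):
        n_snore = sum(1 for e in snore if per_sec[e.start] == stage)
        assert summary.loc[stage, "snore_count"] == n_snore
        mask = np.array(per_sec) == stage
        assert summary.loc[stage, "hr_mean_bpm"] == pytest.approx(
            session.heart_rate[mask].mean())


def test_all_nrem_night_single_row():
    n = 120
    session = sk.SessionRecord(
        pressure=np.full((n, 8), 30.0), sound_db=np.full(n, 25.0),
        body_temp=np.full(n, 36.5), room_temp=np.full(n, 22.5),
        humidity=np.full(n, 45.0), co2=np.full(n, 500.0))
    hyp = sk.Hypnogram([sk.Stage.NREM, sk.Stage.NREM])
    summary = sk.summarize_night(
        session, [sk.PostureSegment(sk.Posture.SUPINE, 0, n)], {}, hyp)
    assert list(summary.stage) == ["nrem"]
    assert np.isnan(summary.hr_mean_bpm[0])  # absent channel renders n/a
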