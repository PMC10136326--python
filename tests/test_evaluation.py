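"""Event-based scoring, metric identities, rater statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearseiz.events import AnnotationEvent, DetectionEvent, overlaps
from wearseiz.evaluation import (CohortRecord, MatchResult, cohen_kappa,
                                 compute_metrics, detection_sensitivity,
                                 harmonic_f1, match_events, mcnemar,
                                 mcnemar_from_sequences, score_cohort,
                                 score_reader, stratify)


def _alarm(s, e):
    return DetectionEvent(s, e, "eeg")


def _gt(s, e):
    return AnnotationEvent(s, e, "seizure", "ground_truth")


def naive_match(alarms, truth, duration):
    """O(n*m) all-pairs oracle."""
    tp = fp = 0
    hit = [False] * len(truth)
    for a in alarms:
        any_hit = False
        for i, g in enumerate(truth):
            if overlaps(a.start_s, a.end_s, g.start_s, g.end_s):
                any_hit = True
                hit[i] = True
        tp += any_hit
        fp += not any_hit
    return MatchResult(tp, fp, sum(hit), len(truth) - sum(hit), duration)


# ---- match_events --------------------------------------------------------

def test_contained_alarm_is_tp():
    m = match_events([_alarm(110, 130)], [_gt(100, 160)], 1000.0)
    assert (m.tp_detections, m.fp_detections, m.detected_seizures,
            m.missed_seizures) == (1, 0, 1, 0)


def test_multiple_alarms_on_one_seizure_inflate_tp_not_detected():
    m = match_events([_alarm(105, 120), _alarm(140, 155)], [_gt(100, 160)],
                     1000.0)
    assert m.tp_detections == 2
    assert m.detected_seizures == 1


def test_disjoint_alarm_is_fp_and_seizure_missed():
    m = match_events([_alarm(200, 260)], [_gt(100, 160)], 1000.0)
    assert (m.tp_detections, m.fp_detections, m.missed_seizures) == (0, 1, 1)


def test_nonpositive_duration_rejected():
    with pytest.raises(ValueError):
        match_events([], [], 0.0)


@settings(max_examples=250, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 900, allow_nan=False),
                          st.floats(0.1, 80, allow_nan=False)), max_size=10),
       st.lists(st.tuples(st.floats(0, 900, allow_nan=False),
                          st.floats(0.1, 80, allow_nan=False)), max_size=8))
def test_match_events_agrees_with_allpairs_oracle(alarm_ivs, truth_ivs):
    alarms = [_alarm(s, s + d) for s, d in alarm_ivs]
    truth = [_gt(s, s + d) for s, d in truth_ivs]
    assert match_events(alarms, truth, 1000.0) == \
        naive_match(alarms, truth, 1000.0)


# ---- metrics -------------------------------------------------------------

def test_ppv_identity_from_detection_counts():
    """230 TP over 7951 detections gives the 2.9% PPV."""
    m = MatchResult(230, 7721, 196, 25, 5284 * 3600.0)
    rep = compute_metrics(m)
    assert rep.ppv == pytest.approx(230 / 7951)
    assert round(100 * rep.ppv, 1) == 2.9


def test_f1_identity_from_sensitivity_and_ppv():
    assert round(harmonic_f1(0.906, 0.029), 2) == 0.06


def test_detection_sensitivity_uses_tp_detections():
    m = MatchResult(230, 7721, 196, 24, 5284 * 3600.0)
    assert detection_sensitivity(m) == pytest.approx(230 / 254)
    assert round(100 * detection_sensitivity(m), 1) == 90.6


def test_fd_rate_one_day():
    rep = compute_metrics(MatchResult(0, 10, 0, 1, 86400.0))
    assert rep.fd_per_24h == pytest.approx(10.0)


def test_fd_rate_scales_with_fp_and_inverse_duration():
    base = compute_metrics(MatchResult(0, 5, 0, 1, 86400.0)).fd_per_24h
    assert compute_metrics(MatchResult(0, 10, 0, 1, 86400.0)).fd_per_24h \
        == pytest.approx(2 * base)
    assert compute_metrics(MatchResult(0, 5, 0, 1, 2 * 86400.0)).fd_per_24h \
        == pytest.approx(base / 2)


def test_undefined_ratios_are_flagged_not_zero():
    rep = compute_metrics(MatchResult(0, 0, 0, 0, 1000.0))
    assert math.isnan(rep.ppv) and math.isnan(rep.sensitivity)
    assert {"ppv", "sensitivity", "f1"} <= set(rep.undefined)


def test_f1_zero_when_either_term_zero():
    assert harmonic_f1(0.0, 0.5) == 0.0
    assert harmonic_f1(0.5, 0.0) == 0.0
    # harmonic mean lies between its two terms
    assert 0.3 <= harmonic_f1(0.3, 0.9) <= 0.9


# ---- reader scoring ------------------------------------------------------

def _reader_setup():
    alarms = {"a1": _alarm(110, 130),   # overlaps the seizure
              "a2": _alarm(400, 420),   # false alarm
              "a3": _alarm(600, 615)}   # false alarm
    truth = [_gt(100, 160), _gt(800, 850)]  # second seizure has no alarm
    return alarms, truth


def test_perfect_reader():
    alarms, truth = _reader_setup()
    labels = [("a1", "seizure"), ("a2", "artifact"), ("a3", "other")]
    rep = score_reader(labels, alarms, truth, duration_s=86400.0)
    assert rep.sensitivity == 1.0
    assert rep.match.fp_detections == 0


def test_reader_false_positive_and_false_negative():
    alarms, truth = _reader_setup()
    labels = [("a1", "artifact"), ("a2", "seizure")]
    rep = score_reader(labels, alarms, truth)
    assert rep.match.fp_detections == 1   # a2 labelled seizure, no overlap
    assert rep.match.missed_seizures == 1  # a1 overlapped but not labelled
    assert rep.sensitivity == 0.0


def test_algorithm_misses_never_enter_reader_counts():
    alarms, truth = _reader_setup()
    labels = [("a1", "seizure"), ("a2", "artifact"), ("a3", "artifact")]
    rep = score_reader(labels, alarms, truth)
    # seizure [800,850) has no alarm: denominators only see the one alarm hit
    assert rep.match.tp_detections + rep.match.missed_seizures == 1


def test_reader_label_for_unknown_alarm_rejected():
    alarms, truth = _reader_setup()
    with pytest.raises(ValueError, match="unknown alarm"):
        score_reader([("zz", "seizure")], alarms, truth)


def test_all_seizure_reader_reduces_to_algorithm_scoring():
    """A reader who calls every alarm a seizure scores exactly like the
    algorithm's own alarms restricted to the alarm set."""
    alarms, truth = _reader_setup()
    labels = [(k, "seizure") for k in alarms]
    rep = score_reader(labels, alarms, truth, duration_s=1000.0)
    alg = match_events(list(alarms.values()), truth, 1000.0)
    assert rep.match.tp_detections == alg.tp_detections
    assert rep.match.fp_detections == alg.fp_detections


# ---- stratification ------------------------------------------------------

def _cohort():
    return [
        CohortRecord("p1", [_alarm(10, 25)], [_gt(5, 30)], 600.0,
                     localization="Temp", tachy_status="responder"),
        CohortRecord("p2", [_alarm(100, 115)], [_gt(200, 230)], 600.0,
                     localization="Front", tachy_status="nonresponder"),
    ]


def test_strata_keys_and_partition():
    records = _cohort()
    strata = stratify(records)
    assert set(strata["tachy_status"]) == {"responder", "nonresponder"}
    assert set(strata["localization"]) == {"Temp", "Front"}
    glob = score_cohort(records).match
    for attr in ("localization", "tachy_status"):
        tp = sum(r.match.tp_detections for r in strata[attr].values())
        fp = sum(r.match.fp_detections for r in strata[attr].values())
        missed = sum(r.match.missed_seizures for r in strata[attr].values())
        assert (tp, fp, missed) == (glob.tp_detections, glob.fp_detections,
                                    glob.missed_seizures)


def test_stratum_metrics_match_direct_subset_recomputation():
    records = _cohort()
    strata = stratify(records, by=("localization",))["localization"]
    for key, rep in strata.items():
        subset = [r for r in records if r.localization == key]
        direct = score_cohort(subset)
        assert rep.match == direct.match


# ---- Cohen's kappa -------------------------------------------------------

def test_kappa_perfect_agreement():
    assert cohen_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"]) == 1.0


def test_kappa_hand_computed_2x2_table():
    """Agreement table a=20, b=5, c=10, d=15: p_o=0.7, p_e=0.5, kappa=0.4."""
    a = ["s"] * 20 + ["s"] * 5 + ["n"] * 10 + ["n"] * 15
    b = ["s"] * 20 + ["n"] * 5 + ["s"] * 10 + ["n"] * 15
    assert cohen_kappa(a, b) == pytest.approx(0.4)


def test_kappa_matches_sklearn_on_random_tables():
    from sklearn.metrics import cohen_kappa_score
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(10, 200))
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert cohen_kappa(list(a), list(b)) == \
            pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_near_zero_for_independent_raters():
    rng = np.random.default_rng(1)
    a = list(rng.integers(0, 2, 20000))
    b = list(rng.permutation(a))  # marginals preserved, pairing random
    assert abs(cohen_kappa(a, b)) < 0.03


def test_kappa_length_mismatch():
    with pytest.raises(ValueError):
        cohen_kappa(["a"], ["a", "b"])


def test_kappa_degenerate_marginals():
    # both raters constant on the same category: chance agreement is 1 and
    # observed agreement is 1, so kappa is defined as 1
    assert cohen_kappa(["x", "x"], ["x", "x"]) == 1.0
    # constant vs nearly-constant rater: p_e < 1, kappa well defined (0 here)
    assert cohen_kappa(["x", "x", "x"], ["x", "x", "y"]) == pytest.approx(0.0)


# ---- McNemar -------------------------------------------------------------

def test_mcnemar_symmetric_counts_give_p_one():
    _, p = mcnemar(7, 7)
    assert p == pytest.approx(1.0)


def test_mcnemar_exact_tail():
    _, p = mcnemar(10, 0)
    assert p == pytest.approx(2 * 0.5 ** 10)


def test_mcnemar_degenerate_zero_zero():
    stat, p = mcnemar(0, 0)
    assert (stat, p) == (0.0, 1.0)


def test_mcnemar_negative_counts_rejected():
    with pytest.raises(ValueError):
        mcnemar(-1, 3)


def test_mcnemar_large_sample_matches_statsmodels():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
    b, c = 40, 18
    stat, p = mcnemar(b, c)
    res = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True)
    assert stat == pytest.approx(res.statistic)
    assert p == pytest.approx(res.pvalue)


def test_mcnemar_from_paired_sequences():
    a = [True, True, False, True, False]
    b = [True, False, True, True, False]
    stat, p = mcnemar_from_sequences(a, b)
    assert stat == 1.0  # b=1 (A right/B wrong), c=1
    assert p == pytest.approx(1.0)
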