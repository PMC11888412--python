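"""Chamber-count scoring: arithmetic, identities and round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ymazeqtl import (ChamberCounts, PlaceTrial, UndefinedScoreError,
                      choice_score, classify_override, climbing_score,
                      from_fly_records, place_pi, pool_counts, ppd,
                      score_table, sucrose_acuity, summarize_rils,
                      to_fly_records)
from ymazeqtl.scoring import counts_to_frame

counts_st = st.builds(
    ChamberCounts,
    n_plus=st.integers(0, 200), n_minus=st.integers(0, 200),
    n_nc=st.integers(0, 200), n_censored=st.just(0))


@pytest.mark.parametrize("c,expected", [
    (ChamberCounts(10, 5, 5), 0.75),
    (ChamberCounts(0, 0, 20), 0.0),
    (ChamberCounts(7, 3, 0), 1.0),
])
def test_climbing_score(c, expected):
    assert climbing_score(c) == pytest.approx(expected)


@pytest.mark.parametrize("c,expected", [
    (ChamberCounts(10, 10, 3), 0.5),
    (ChamberCounts(20, 0, 5), 1.0),
    (ChamberCounts(0, 10, 0), 0.0),
])
def test_choice_score(c, expected):
    assert choice_score(c) == pytest.approx(expected)


def test_no_climbers_is_undefined_not_a_number():
    with pytest.raises(UndefinedScoreError):
        choice_score(ChamberCounts(0, 0, 12))
    with pytest.raises(UndefinedScoreError):
        climbing_score(ChamberCounts(0, 0, 0, n_censored=5))


def test_preference_complement_identity():
    # on the same baseline counts, OCT preference = 1 - MCH preference
    c = ChamberCounts(13, 7, 4, assay="baseline")
    flipped = ChamberCounts(7, 13, 4, assay="baseline")
    assert choice_score(c) == pytest.approx(1.0 - choice_score(flipped))


@given(counts_st)
@settings(deadline=None, max_examples=100)
def test_choice_score_scale_invariance(c):
    if c.n_plus + c.n_minus == 0:
        return
    scaled = ChamberCounts(3 * c.n_plus, 3 * c.n_minus, 3 * c.n_nc)
    assert choice_score(scaled) == pytest.approx(choice_score(c))


@given(counts_st)
@settings(deadline=None, max_examples=100)
def test_conservation_of_flies(c):
    if c.n_plus + c.n_minus + c.n_nc == 0:
        return
    total = c.n_plus + c.n_minus + c.n_nc
    assert climbing_score(c) * total + c.n_nc == pytest.approx(total)


@pytest.mark.parametrize("perf,pref,expected", [
    (0.5, 0.5, 0.0),
    (1.0, 0.0, 1.0),
    (0.3, 0.7, -0.4),
])
def test_ppd(perf, pref, expected):
    assert ppd(perf, pref) == pytest.approx(expected)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(deadline=None, max_examples=50)
def test_ppd_antisymmetry(p, q):
    assert ppd(p, q) == pytest.approx(-ppd(q, p))


@pytest.mark.parametrize("perf,pref,expected", [
    (0.6, 0.4, True),
    (0.5, 0.4, False),   # boundary: strictly above 0.5 required
    (0.6, 0.5, False),   # boundary: strictly below 0.5 required
    (0.51, 0.49, True),
])
def test_override_rule_is_strict(perf, pref, expected):
    assert classify_override(perf, pref) is expected


def test_sucrose_acuity_excludes_censored():
    c = ChamberCounts(30, 20, 0, n_censored=10, assay="sugar_acuity")
    assert sucrose_acuity(c) == pytest.approx(0.6)
    assert sucrose_acuity(ChamberCounts(0, 10, 0, 0)) == 0.0


@given(counts_st, st.integers(0, 50))
@settings(deadline=None, max_examples=100)
def test_sucrose_acuity_censoring_invariance(c, extra):
    if c.n_plus + c.n_minus == 0:
        return
    more = ChamberCounts(c.n_plus, c.n_minus, c.n_nc, c.n_censored + extra)
    assert sucrose_acuity(more) == pytest.approx(sucrose_acuity(c))


@pytest.mark.parametrize("trial,expected", [
    (PlaceTrial(300.0, 0.0, 300.0), 1.0),    # total avoidance of hot side
    (PlaceTrial(0.0, 300.0, 300.0), -1.0),   # total preference for hot side
    (PlaceTrial(100.0, 100.0, 300.0), 0.0),
])
def test_place_pi(trial, expected):
    assert place_pi(trial) == pytest.approx(expected)


def test_fly_record_expansion():
    c = ChamberCounts(2, 1, 1, ril_id="r1", replicate_id="v1")
    recs = to_fly_records(c)
    assert len(recs) == 4
    assert sum(r.correct == 1 for r in recs) == 2
    assert sum(r.correct == 0 for r in recs) == 1
    assert sum(r.climbed == 0 for r in recs) == 1


@given(counts_st)
@settings(deadline=None, max_examples=100)
def test_fly_record_round_trip(c):
    if c.total == 0:
        return
    back = from_fly_records(to_fly_records(c))
    assert (back.n_plus, back.n_minus, back.n_nc) == (c.n_plus, c.n_minus, c.n_nc)


@given(counts_st)
@settings(deadline=None, max_examples=100)
def test_mean_correct_among_climbers_equals_choice_score(c):
    if c.n_plus + c.n_minus == 0:
        return
    recs = to_fly_records(c)
    climbers = [r.correct for r in recs if r.climbed == 1]
    assert np.mean(climbers) == pytest.approx(choice_score(c))


def test_pooled_score_is_fly_weighted_mean_of_replicates():
    reps = [ChamberCounts(10, 5, 5, ril_id="r", replicate_id=f"v{i}")
            for i, _ in enumerate(range(3))]
    reps[1] = ChamberCounts(40, 10, 2, ril_id="r", replicate_id="v1")
    pooled = pool_counts(reps)
    climbers = [c.n_plus + c.n_minus for c in reps]
    weighted = sum(choice_score(c) * w for c, w in zip(reps, climbers)) / sum(climbers)
    assert choice_score(pooled) == pytest.approx(weighted)
    totals = [c.n_plus + c.n_minus + c.n_nc for c in reps]
    weighted_climb = sum(climbing_score(c) * t for c, t in zip(reps, totals)) / sum(totals)
    assert climbing_score(pooled) == pytest.approx(weighted_climb)


def _toy_counts():
    rows = []
    for ril, (perf_plus, base_plus) in {"A": (12, 4), "B": (6, 14),
                                        "C": (15, 5), "D": (5, 15)}.items():
        for odor in ("OCT", "MCH"):
            plus = perf_plus if odor == "OCT" else 20 - perf_plus
            rows.append(ChamberCounts(plus, 20 - plus, 5, ril_id=ril,
                                      replicate_id="v1", trained_odor=odor,
                                      assay="learning"))
            rows.append(ChamberCounts(plus, 20 - plus, 5, ril_id=ril,
                                      replicate_id="v1", trained_odor=odor,
                                      assay="memory"))
        rows.append(ChamberCounts(base_plus, 20 - base_plus, 2, ril_id=ril,
                                  replicate_id="v1", trained_odor="none",
                                  assay="baseline"))
    return counts_to_frame(rows)


def test_score_table_override_uses_trained_odor_preference():
    scores = score_table(_toy_counts())
    oct_learn = scores[(scores.assay == "learning") & (scores.trained_odor == "OCT")]
    by_ril = oct_learn.set_index("ril")
    # A: performance .6 > .5, OCT preference .2 < .5 -> override
    assert bool(by_ril.loc["A"].override)
    # B: performance .3 -> no
    assert not bool(by_ril.loc["B"].override)
    # D: performance .25, preference .75 -> no; MCH-trained D: perf .75, pref .25 -> yes
    mch_learn = scores[(scores.assay == "learning")
                       & (scores.trained_odor == "MCH")].set_index("ril")
    assert bool(mch_learn.loc["D"].override)
    assert by_ril.loc["A"].ppd == pytest.approx(0.6 - 0.2)


def test_summarize_override_tallies_set_algebra():
    scores = pd.DataFrame({
        "ril": ["A", "B", "C", "D"] * 2,
        "assay": ["learning"] * 4 + ["memory"] * 4,
        "trained_odor": ["OCT"] * 8,
        "choice_score": [0.6] * 8,
        "override": [True, True, True, False, False, True, True, True],
    })
    s = summarize_rils(scores)
    assert s["override"]["OCT"] == {"learning_only": 1, "memory_only": 1, "both": 2}


def test_summarize_single_ril_mean_min_max_coincide():
    scores = pd.DataFrame({
        "ril": ["A"], "assay": ["learning"], "trained_odor": ["OCT"],
        "choice_score": [0.61], "override": [False]})
    ph = summarize_rils(scores)["phenotypes"]["OCT_learning"]
    assert ph["mean"] == ph["min"] == ph["max"] == pytest.approx(0.61)
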