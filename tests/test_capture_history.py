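"""Exclusion rules, capture-history construction and survey tallies."""

import datetime as dt
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scr_camtrap import (
    DetectionRecord,
    SurveyConfig,
    TrapSite,
    apply_exclusions,
    build_capture_history,
    summarize_survey,
)
from scr_camtrap.capture_history import history_to_long
from scr_camtrap.synthetic_data import RECAPTURE_PATTERNS, recapture_fixture

D0 = dt.date(2021, 1, 1)


def rec(ind, site, day, flank="both", age="independent", mother=None):
    return DetectionRecord(
        individual_id=ind,
        site_id=site,
        date=D0 + dt.timedelta(days=day - 1),
        flank=flank,
        age_class=age,
        mother_id=mother,
    )


def traps_2(usage2=(1, 1)):
    return [
        TrapSite("S1", 0.0, 0.0, np.ones(2, dtype=int)),
        TrapSite("S2", 1.0, 0.0, np.array(usage2)),
    ]


def cfg_days(k, **kw):
    return SurveyConfig(
        occasion_start=D0, occasion_end=D0 + dt.timedelta(days=k - 1), M=100, **kw
    )


# --- exclusion rules -------------------------------------------------------


def test_unidentified_events_removed_and_counted():
    records = [rec("unknown", "S1", 1) for _ in range(10)] + [rec("A", "S1", 1)]
    kept, log = apply_exclusions(records)
    assert [r.individual_id for r in kept] == ["A"]
    assert log["unidentified_events"] == 10


def test_juvenile_reassigned_to_mother():
    records = [
        rec("F1", "S1", 1),
        rec("J1", "S2", 2, age="juvenile", mother="F1"),
    ]
    kept, log = apply_exclusions(records)
    assert {r.individual_id for r in kept} == {"F1"}
    assert sum(r.individual_id == "F1" for r in kept) == 2
    assert log["juveniles_merged"] == 1
    assert log["juvenile_events_reassigned"] == 1


def test_juvenile_without_known_mother_excluded():
    records = [rec("J2", "S1", 1, age="juvenile"), rec("A", "S2", 1)]
    kept, log = apply_exclusions(records)
    assert {r.individual_id for r in kept} == {"A"}
    assert log["juveniles_dropped"] == 1
    assert log["juvenile_events_dropped"] == 1


def test_single_flank_individuals_dropped_under_default_policy():
    records = (
        [rec(f"L{i}", "S1", i, flank="left") for i in (1, 2, 3)]
        + [rec("R1", "S1", 1, flank="right"),
           rec("R1", "S1", 2, flank="right"),
           rec("R1", "S2", 3, flank="right"),
           rec("R2", "S2", 4, flank="right"),
           rec("R3", "S2", 5, flank="right")]
        + [rec("B1", "S1", 6)]
    )
    kept, log = apply_exclusions(records)
    assert {r.individual_id for r in kept} == {"B1"}
    assert log["single_flank_individuals_dropped"] == 6
    assert log["single_flank_events_dropped"] == 8


def test_keep_left_policy_retains_left_only_catalogue():
    records = [
        rec("L1", "S1", 1, flank="left"),
        rec("R1", "S1", 2, flank="right"),
        rec("B1", "S2", 3),
    ]
    kept, _ = apply_exclusions(records, flank_policy="keep-left")
    assert {r.individual_id for r in kept} == {"L1", "B1"}
    kept, _ = apply_exclusions(records, flank_policy="keep-right")
    assert {r.individual_id for r in kept} == {"R1", "B1"}
    with pytest.raises(ValueError):
        apply_exclusions(records, flank_policy="keep-both")


def test_individual_seen_on_both_flanks_separately_is_kept():
    records = [rec("A", "S1", 1, flank="left"), rec("A", "S2", 2, flank="right")]
    kept, log = apply_exclusions(records)
    assert len(kept) == 2
    assert log["single_flank_individuals_dropped"] == 0


# --- capture-history construction -----------------------------------------


def test_hand_fixture_builds_exact_tensor():
    traps = traps_2(usage2=(1, 0))
    records = [
        rec("A", "S1", 1),
        rec("A", "S1", 1),  # same day duplicate: collapses
        rec("A", "S2", 1),
        rec("B", "S1", 2),
        rec("B", "S2", 2),  # S2 inactive on day 2: dropped
        rec("A", "S1", 3),  # outside the 2-day window: dropped
    ]
    h = build_capture_history(records, traps, cfg_days(2))
    assert h.individuals == ["A", "B"]
    expected = np.zeros((2, 2, 2), dtype=int)
    expected[0, 0, 0] = 1  # A at S1 day 1
    expected[0, 1, 0] = 1  # A at S2 day 1
    expected[1, 0, 1] = 1  # B at S1 day 2
    assert np.array_equal(h.y, expected)
    assert h.exclusion_log["events_at_inactive_sites"] == 1
    assert h.exclusion_log["events_outside_window"] == 1


def test_unknown_site_raises():
    with pytest.raises(ValueError, match="unknown site"):
        build_capture_history([rec("A", "S9", 1)], traps_2(), cfg_days(2))


def test_total_detections_equal_unique_events():
    rng = random.Random(0)
    records = [
        rec(rng.choice("ABC"), rng.choice(["S1", "S2"]), rng.randint(1, 5))
        for _ in range(60)
    ]
    traps = [
        TrapSite("S1", 0.0, 0.0, np.ones(5, dtype=int)),
        TrapSite("S2", 1.0, 0.0, np.ones(5, dtype=int)),
    ]
    h = build_capture_history(records, traps, cfg_days(5))
    unique = {(r.individual_id, r.site_id, r.date) for r in records}
    assert int(h.y.sum()) == len(unique)


def test_long_format_export_round_trips_counts():
    traps, records = recapture_fixture([(4, 2), (1, 1)], n_sites=5, K=10, start=D0)
    h = build_capture_history(records, traps, cfg_days(10))
    long = history_to_long(h)
    assert len(long) == int(h.y.sum())


# --- survey summaries ------------------------------------------------------


@pytest.mark.parametrize(
    "area,n,total,spatial",
    [("sbnp", 5, 22, 10), ("ucez", 22, 24, 19), ("bpp", 14, 65, 13)],
)
def test_summary_matches_survey_tallies(area, n, total, spatial):
    layout = RECAPTURE_PATTERNS[area]
    traps, records = recapture_fixture(
        layout["pattern"], layout["n_sites"], layout["K"], layout["start"]
    )
    config = SurveyConfig(
        occasion_start=layout["start"],
        occasion_end=layout["start"] + dt.timedelta(days=layout["K"] - 1),
        M=300,
    )
    kept, log = apply_exclusions(records)
    summary = summarize_survey(build_capture_history(kept, traps, config, log))
    assert summary.n_individuals == n
    assert summary.total_recaptures == total
    assert summary.spatial_recaptures == spatial
    assert summary.n_sites == layout["n_sites"]
    assert summary.K == layout["K"]


def test_single_capture_individual_has_no_recaptures():
    traps, records = recapture_fixture([(1, 1)], n_sites=4, K=3, start=D0)
    h = build_capture_history(records, traps, cfg_days(3))
    s = summarize_survey(h)
    assert (s.n_individuals, s.total_recaptures, s.spatial_recaptures) == (1, 0, 0)


def test_empty_history_errors():
    h = build_capture_history([], traps_2(), cfg_days(2))
    with pytest.raises(ValueError, match="empty"):
        summarize_survey(h)


@given(st.randoms(use_true_random=False))
def test_summary_invariant_to_record_order(rnd):
    layout = RECAPTURE_PATTERNS["sbnp"]
    traps, records = recapture_fixture(
        layout["pattern"], layout["n_sites"], layout["K"], layout["start"]
    )
    config = SurveyConfig(
        occasion_start=layout["start"],
        occasion_end=layout["start"] + dt.timedelta(days=layout["K"] - 1),
        M=100,
    )
    base = summarize_survey(build_capture_history(records, traps, config))
    shuffled = list(records)
    rnd.shuffle(shuffled)
    perm = summarize_survey(build_capture_history(shuffled, traps, config))
    assert perm == base


def test_spatial_recaptures_two_computations_agree(demo_run):
    _, _, result = demo_run
    h = result.history
    per_individual = int(((h.y.sum(axis=2) > 0).sum(axis=1) - 1).sum())
    flattened = sum(
        len({j for j, k in zip(*np.nonzero(h.y[i]))}) - 1 for i in range(h.n)
    )
    assert per_individual == flattened == result.summary.spatial_recaptures
    assert result.summary.spatial_recaptures <= result.summary.total_recaptures
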