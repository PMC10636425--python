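"""Identification rules and capture-history construction.

Photo-identification of individuals from coat patterns is treated as
already done upstream and encoded in the individual ids.  This module
applies the survey's filtering rules (unidentifiable events dropped but
counted, juveniles merged into their mothers where known, single-flank
individuals discarded under the default policy), collapses the remaining
records into the binary individuals x sites x occasions tensor, and
computes the survey-level tallies used to judge how informative the
data are (recaptures, spatial recaptures, skewness of recaptures).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .types import (
    CaptureHistory,
    DetectionRecord,
    SurveyConfig,
    SurveySummary,
    TrapSite,
    is_unidentified,
)

FLANK_POLICIES = ("drop-single-flank", "keep-left", "keep-right")


def apply_exclusions(
    records: Sequence[DetectionRecord],
    flank_policy: str = "drop-single-flank",
) -> tuple[list[DetectionRecord], dict]:
    """Filter detection records and log what was excluded.

    Three rules, applied in order:

    1. Events whose individual could not be identified are removed and
       counted (they carry no capture-history information).
    2. Juveniles (<1 year) are not independent units: their detections
       are re-assigned to the mother when ``mother_id`` is known, which
       adds recaptures for her.  A juvenile without a known mother is
       excluded and counted.
    3. Individuals ever photographed on one flank only can not be
       matched against the two-flank catalogue; one animal could
       otherwise be counted twice.  The default policy drops them
       (counted); ``keep-left``/``keep-right`` retain the corresponding
       single-flank catalogue for sensitivity runs.

    Returns the retained records and an exclusion log with counts.
    """
    if flank_policy not in FLANK_POLICIES:
        raise ValueError(f"flank_policy must be one of {FLANK_POLICIES}")

    log = {
        "unidentified_events": 0,
        "juveniles_merged": 0,
        "juvenile_events_reassigned": 0,
        "juveniles_dropped": 0,
        "juvenile_events_dropped": 0,
        "single_flank_individuals_dropped": 0,
        "single_flank_events_dropped": 0,
    }

    identified: list[DetectionRecord] = []
    for rec in records:
        if rec.unidentified:
            log["unidentified_events"] += 1
        else:
            identified.append(rec)

    # juveniles: merge into mother where known, otherwise drop
    merged: list[DetectionRecord] = []
    merged_ids: set[str] = set()
    dropped_juveniles: set[str] = set()
    for rec in identified:
        if rec.age_class == "juvenile":
            if rec.mother_id is not None and not is_unidentified(rec.mother_id):
                merged_ids.add(rec.individual_id)
                log["juvenile_events_reassigned"] += 1
                merged.append(
                    replace(rec, individual_id=rec.mother_id, age_class="independent",
                            mother_id=None)
                )
            else:
                dropped_juveniles.add(rec.individual_id)
                log["juvenile_events_dropped"] += 1
        else:
            merged.append(rec)
    log["juveniles_merged"] = len(merged_ids)
    log["juveniles_dropped"] = len(dropped_juveniles - {r.individual_id for r in merged})

    # flank rule: which sides has each individual ever been seen on?
    sides: dict[str, set[str]] = {}
    for rec in merged:
        s = sides.setdefault(rec.individual_id, set())
        if rec.flank == "both":
            s.update(("left", "right"))
        else:
            s.add(rec.flank)

    def _kept(ind: str) -> bool:
        if len(sides[ind]) == 2:
            return True
        (side,) = sides[ind]
        if flank_policy == "drop-single-flank":
            return False
        return side == ("left" if flank_policy == "keep-left" else "right")

    out: list[DetectionRecord] = []
    dropped_inds: set[str] = set()
    for rec in merged:
        if _kept(rec.individual_id):
            out.append(rec)
        else:
            dropped_inds.add(rec.individual_id)
            log["single_flank_events_dropped"] += 1
    log["single_flank_individuals_dropped"] = len(dropped_inds)
    return out, log


def build_capture_history(
    records: Sequence[DetectionRecord],
    traps: Sequence[TrapSite],
    config: SurveyConfig,
    exclusion_log: dict | None = None,
) -> CaptureHistory:
    """Collapse filtered records into the binary detection tensor.

    Occasions are the one-day intervals of the configured window.
    Repeat photographs of the same individual at the same site on the
    same day collapse to a single detection (at most one per
    individual-site-occasion, so per-cell outcomes are Bernoulli).
    Records outside the window, or at a site-day with no effort, are
    dropped and logged.
    """
    K = config.n_occasions
    site_ids = [t.site_id for t in traps]
    if len(set(site_ids)) != len(site_ids):
        raise ValueError("duplicate site_id in trap list")
    site_index = {sid: j for j, sid in enumerate(site_ids)}

    usage = np.zeros((len(traps), K), dtype=np.int8)
    for j, t in enumerate(traps):
        if t.usage.shape[0] != K:
            raise ValueError(
                f"site {t.site_id!r}: usage length {t.usage.shape[0]} != K = {K}"
            )
        usage[j] = t.usage

    log = dict(exclusion_log or {})
    log.setdefault("events_outside_window", 0)
    log.setdefault("events_at_inactive_sites", 0)
    log.setdefault("unidentified_events", 0)

    events: set[tuple[str, int, int]] = set()
    for rec in records:
        if rec.unidentified:  # defensive; apply_exclusions normally ran first
            log["unidentified_events"] += 1
            continue
        if rec.site_id not in site_index:
            raise ValueError(f"detection references unknown site {rec.site_id!r}")
        k = config.occasion_of(rec.date)
        if k is None:
            log["events_outside_window"] += 1
            continue
        j = site_index[rec.site_id]
        if usage[j, k - 1] == 0:
            log["events_at_inactive_sites"] += 1
            continue
        events.add((rec.individual_id, j, k - 1))

    individuals = sorted({ind for ind, _, _ in events})
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    y = np.zeros((len(individuals), len(traps), K), dtype=np.int8)
    for ind, j, k in events:
        y[ind_index[ind], j, k] = 1

    return CaptureHistory(
        individuals=individuals,
        sites=site_ids,
        K=K,
        y=y,
        usage=usage,
        trap_xy=np.array([[t.x, t.y] for t in traps], dtype=float),
        exclusion_log=log,
        survey_period=(config.occasion_start.isoformat(), config.occasion_end.isoformat()),
    )


def summarize_survey(history: CaptureHistory) -> SurveySummary:
    """Tally individuals, recaptures, spatial recaptures and effort.

    recaptures_i = detections of individual i minus one; spatial
    recaptures sum (distinct sites of i - 1), i.e. sites at which an
    individual was *only* recaptured.  The per-individual recapture
    multiset is reported so the skewness of recaptures can be inspected.
    """
    if history.n == 0:
        raise ValueError("empty capture history")
    det_per_ind = history.y.sum(axis=(1, 2))
    sites_per_ind = (history.y.sum(axis=2) > 0).sum(axis=1)
    recaptures = det_per_ind - 1
    return SurveySummary(
        n_individuals=history.n,
        total_recaptures=int(recaptures.sum()),
        spatial_recaptures=int((sites_per_ind - 1).sum()),
        per_individual_recaptures=sorted((int(r) for r in recaptures), reverse=True),
        effective_trap_nights=int(history.usage.sum()),
        n_sites=history.J,
        K=history.K,
        survey_period=history.survey_period,
        exclusion_log=dict(history.exclusion_log),
    )


def history_to_long(history: CaptureHistory):
    """Capture history as a long-format table (individual, site, occasion)."""
    import pandas as pd

    idx = np.argwhere(history.y == 1)
    return pd.DataFrame(
        {
            "individual_id": [history.individuals[i] for i in idx[:, 0]],
            "site_id": [history.sites[j] for j in idx[:, 1]],
            "occasion": idx[:, 2] + 1,
        }
    ).sort_values(["individual_id", "occasion", "site_id"], ignore_index=True)
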