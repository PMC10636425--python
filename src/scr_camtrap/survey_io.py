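"""Readers, writers and the end-to-end analysis entry point.

Tabular inputs are plain CSV: a trap-deployment table (site id, planar
x/y in km, per-occasion usage) and a detection-record table (individual,
site, date, flank, age class, optional mother).  The run configuration
is YAML.  ``run_analysis`` chains the whole pipeline: exclusion rules ->
capture history -> state space -> MCMC -> diagnostics -> density
products, writing all artifacts when an output directory is given.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .capture_history import apply_exclusions, build_capture_history, summarize_survey
from .density_maps import activity_center_raster, mcp_density, mcp_polygon, raster_to_ascii
from .diagnostics import (
    convergence_report,
    density_estimate,
    hpd_interval,
    plot_traces,
    precision_label,
)
from .scr_core import make_state_space, run_mcmc, suggest_buffer
from .types import (
    CaptureHistory,
    ConvergenceReport,
    DensityEstimate,
    DensityRaster,
    DetectionRecord,
    MCMCConfig,
    MCPResult,
    PosteriorChains,
    StateSpace,
    SurveyConfig,
    SurveySummary,
    TrapSite,
    is_unidentified,
)

__all__ = [
    "read_traps",
    "write_traps",
    "read_detections",
    "write_detections",
    "load_config",
    "save_config",
    "run_analysis",
    "AnalysisResult",
]


# ---------------------------------------------------------------------------
# traps


def read_traps(path, window) -> list[TrapSite]:
    """Read a trap-deployment table, expanding usage over the survey window.

    Required columns: ``site_id``, ``x_km``, ``y_km``.  Effort comes
    from, in order of precedence: a ``usage`` column (a 0/1 string of
    length K), ``active_from``/``active_to`` dates (clipped to the
    window; blanks mean the window bounds), or — with neither — full
    effort on every occasion.  ``window`` is a (start, end) date pair or
    a :class:`SurveyConfig`.
    """
    start, end = _window(window)
    K = (end - start).days + 1
    rows = _read_csv(path)
    if not rows:
        return []
    _require(rows[0], ("site_id", "x_km", "y_km"), path)

    traps: list[TrapSite] = []
    seen: set[str] = set()
    for ln, row in enumerate(rows, start=2):
        sid = row["site_id"].strip()
        if sid in seen:
            raise ValueError(f"{path}: duplicate site_id {sid!r} (line {ln})")
        seen.add(sid)
        try:
            x, y = float(row["x_km"]), float(row["y_km"])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric coordinates for site {sid!r} (line {ln})") from exc
        usage_str = (row.get("usage") or "").strip()
        if usage_str:
            if len(usage_str) != K or set(usage_str) - {"0", "1"}:
                raise ValueError(
                    f"{path}: usage for site {sid!r} must be a 0/1 string of length K = {K}"
                )
            usage = np.frombuffer(usage_str.encode(), dtype=np.uint8) - ord("0")
        else:
            a_from = _parse_date(row.get("active_from")) or start
            a_to = _parse_date(row.get("active_to")) or end
            usage = np.zeros(K, dtype=np.int8)
            k0 = max((a_from - start).days, 0)
            k1 = min((a_to - start).days, K - 1)
            if k1 >= k0:
                usage[k0 : k1 + 1] = 1
        traps.append(TrapSite(site_id=sid, x=x, y=y, usage=usage))
    return traps


def write_traps(traps: Sequence[TrapSite], path) -> None:
    """Write traps with usage as a compact 0/1 string (exact round trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "x_km", "y_km", "usage"])
        for t in traps:
            w.writerow([t.site_id, repr(t.x), repr(t.y), "".join(map(str, t.usage))])


# ---------------------------------------------------------------------------
# detections


def read_detections(path, traps: Optional[Sequence[TrapSite]] = None) -> list[DetectionRecord]:
    """Read detection records; unknown individual ids are kept (flagged).

    With ``traps`` given, a record referencing an unknown site is an
    error naming the offending row.
    """
    rows = _read_csv(path)
    if not rows:
        return []
    _require(rows[0], ("individual_id", "site_id", "date", "flank", "age_class"), path)
    known = {t.site_id for t in traps} if traps is not None else None

    records: list[DetectionRecord] = []
    for ln, row in enumerate(rows, start=2):
        sid = row["site_id"].strip()
        if known is not None and sid not in known:
            raise ValueError(f"{path}: line {ln} references unknown site_id {sid!r}")
        mother = (row.get("mother_id") or "").strip() or None
        records.append(
            DetectionRecord(
                individual_id=row["individual_id"].strip(),
                site_id=sid,
                date=_dt.date.fromisoformat(row["date"].strip()),
                flank=row["flank"].strip(),
                age_class=row["age_class"].strip(),
                mother_id=mother,
            )
        )
    return records


def write_detections(records: Sequence[DetectionRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual_id", "site_id", "date", "flank", "age_class", "mother_id"])
        for r in records:
            w.writerow(
                [r.individual_id, r.site_id, r.date.isoformat(), r.flank, r.age_class,
                 r.mother_id or ""]
            )


def _read_csv(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def _require(row: dict, cols, path) -> None:
    missing = [c for c in cols if c not in row]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _parse_date(value) -> Optional[_dt.date]:
    if value is None or not str(value).strip():
        return None
    return _dt.date.fromisoformat(str(value).strip())


def _window(window) -> tuple[_dt.date, _dt.date]:
    if isinstance(window, SurveyConfig):
        return window.occasion_start, window.occasion_end
    start, end = window
    if isinstance(start, str):
        start = _dt.date.fromisoformat(start)
    if isinstance(end, str):
        end = _dt.date.fromisoformat(end)
    return start, end


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> SurveyConfig:
    """Load a YAML run configuration (``survey:`` and ``mcmc:`` sections)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    survey = dict(raw.get("survey", raw))
    mcmc = MCMCConfig(**raw.get("mcmc", {}))
    survey.pop("mcmc", None)
    return SurveyConfig(mcmc=mcmc, **survey)


def save_config(config: SurveyConfig, path) -> None:
    doc = {
        "survey": {
            "occasion_start": config.occasion_start.isoformat(),
            "occasion_end": config.occasion_end.isoformat(),
            "M": config.M,
            "buffer_km": config.buffer_km,
            "raster_pixel_km": config.raster_pixel_km,
            "raster_extent": config.raster_extent,
            "flank_policy": config.flank_policy,
            "include_burnin_maps": config.include_burnin_maps,
            "seed": config.seed,
        },
        "mcmc": {
            "n_chains": config.mcmc.n_chains,
            "n_iter": config.mcmc.n_iter,
            "burn_in": config.mcmc.burn_in,
            "thin_maps": config.mcmc.thin_maps,
            "adapt": config.mcmc.adapt,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class AnalysisResult:
    """Everything one survey analysis produces."""

    history: CaptureHistory
    summary: SurveySummary
    state_space: StateSpace
    buffer_km: float
    chains: PosteriorChains
    convergence: ConvergenceReport
    density: DensityEstimate
    parameter_summaries: dict
    mcp: MCPResult
    raster: DensityRaster
    converged: bool

    def estimates_dict(self) -> dict:
        return {
            "density": self.density.as_dict(),
            "precision": precision_label(self.density.cv),
            "parameters": self.parameter_summaries,
            "mcp_area_km2": self.mcp.area_km2,
            "mcp_density_per_100km2": self.mcp.density_per_100km2,
            "state_space_area_km2": self.state_space.area_km2,
            "buffer_km": self.buffer_km,
            "M": self.chains.M,
            "n_detected": self.chains.n_detected,
            "converged": self.converged,
            "acceptance_rates": self.chains.acceptance,
        }


def run_analysis(
    config: SurveyConfig,
    traps: Sequence[TrapSite],
    detections: Sequence[DetectionRecord],
    out_dir=None,
    verbose: bool = False,
) -> AnalysisResult:
    """Run the full SCR pipeline on one survey.

    Fully reproducible given ``config.seed`` (chains use independent,
    seed-derived streams).  Non-convergence (any 95% upper R-hat >= 1.1)
    flags the result and warns; it never suppresses output.
    """
    records, exclusion_log = apply_exclusions(list(detections), config.flank_policy)
    history = build_capture_history(records, traps, config, exclusion_log)
    if history.n == 0:
        raise ValueError("no capture histories: no identified individuals in the window")
    summary = summarize_survey(history)
    _say(verbose, f"{history.n} individuals, {summary.total_recaptures} recaptures "
                  f"({summary.spatial_recaptures} spatial)")

    buffer_km = (
        suggest_buffer(history) if config.buffer_km == "auto" else float(config.buffer_km)
    )
    state_space = make_state_space(traps, buffer_km)
    _say(verbose, f"state space {state_space.area_km2:.0f} km2 (buffer {buffer_km:.2f} km)")

    mcmc_cfg = replace(config.mcmc, seed=config.seed,
                       map_from_start=config.include_burnin_maps)
    chains = run_mcmc(history, mcmc_cfg, state_space, config.M)
    report = convergence_report(chains)
    if not report.converged:
        warnings.warn("MCMC did not converge (some 95% upper R-hat >= 1.1); "
                      "results are flagged, inspect traces")

    density = density_estimate(chains.pooled("D"))
    params = {}
    for name in ("g0", "sigma", "psi", "N"):
        x = chains.pooled(name)
        lo, hi = hpd_interval(x, 0.95)
        params[name] = {"mean": float(x.mean()), "hpd95_low": lo, "hpd95_high": hi}

    draws = chains.all_map_draws()
    mcp = mcp_polygon(traps)
    mcp.density_per_100km2 = mcp_density(draws, mcp)
    extent = mcp if config.raster_extent == "mcp" else state_space
    raster = activity_center_raster(draws, extent, config.raster_pixel_km)

    result = AnalysisResult(
        history=history,
        summary=summary,
        state_space=state_space,
        buffer_km=buffer_km,
        chains=chains,
        convergence=report,
        density=density,
        parameter_summaries=params,
        mcp=mcp,
        raster=raster,
        converged=report.converged,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
        _say(verbose, f"artifacts written to {out_dir}")
    return result


def write_artifacts(result: AnalysisResult, out_dir) -> None:
    """Write summary/estimates/diagnostics JSON, chain files, map products."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _dump_json(result.summary.as_dict(), out / "summary.json")
    _dump_json(result.estimates_dict(), out / "estimates.json")
    _dump_json(result.convergence.as_dict(), out / "diagnostics.json")

    chains = result.chains
    names = ("g0", "sigma", "psi", "N", "D")
    for c in range(chains.n_chains):
        with open(out / f"chain{c + 1}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("iter",) + names)
            for j in range(chains.n_kept):
                w.writerow(
                    [chains.burn_in + j + 1]
                    + [repr(float(chains.params[k][c, j])) for k in names]
                )
    with open(out / "activity_centres.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "draw", "x", "y"])
        for c, chain_draws in enumerate(chains.map_draws):
            for d, s in enumerate(chain_draws):
                for x, y in np.asarray(s).reshape(-1, 2):
                    w.writerow([c + 1, d + 1, repr(float(x)), repr(float(y))])

    _dump_json(result.mcp.as_geojson(), out / "mcp.geojson")
    raster_to_ascii(result.raster, out / "raster.asc")
    plot_traces(chains, out / "traces.png")


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _say(verbose: bool, msg: str) -> None:
    if verbose:
        print(f"[scr-camtrap] {msg}")
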