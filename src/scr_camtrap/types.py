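"""Domain types shared across the pipeline.

Coordinates are planar kilometres in a metric projection; the package
never reprojects.  Occasions are one-day sampling intervals numbered
1..K from the configured survey start (1-based, inclusive); dates are
ISO-8601 calendar dates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

FLANKS = ("left", "right", "both")
AGE_CLASSES = ("independent", "juvenile", "unknown")

#: individual_id values treated as "could not be identified"
UNIDENTIFIED_IDS = ("", "unknown", "unidentified", "na", "nan")


def is_unidentified(individual_id: Optional[str]) -> bool:
    """True when an individual id marks an unidentifiable event."""
    return individual_id is None or str(individual_id).strip().lower() in UNIDENTIFIED_IDS


@dataclass
class TrapSite:
    """A camera-trapping site (paired cameras collapse to one site).

    ``usage`` is the per-occasion operational indicator; stolen or broken
    cameras are encoded as zeros from the loss date onward.
    """

    site_id: str
    x: float
    y: float
    usage: np.ndarray

    def __post_init__(self) -> None:
        self.usage = np.asarray(self.usage, dtype=np.int8)
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for site {self.site_id!r}")
        if self.usage.ndim != 1:
            raise ValueError("usage must be a 1-D per-occasion indicator")
        if not np.isin(self.usage, (0, 1)).all():
            raise ValueError("usage entries must be 0/1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrapSite):
            return NotImplemented
        return (
            self.site_id == other.site_id
            and self.x == other.x
            and self.y == other.y
            and np.array_equal(self.usage, other.usage)
        )


@dataclass(frozen=True)
class DetectionRecord:
    """One photo-identification event of an individual at a site on a date."""

    individual_id: str
    site_id: str
    date: _dt.date
    flank: str = "both"
    age_class: str = "independent"
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.flank not in FLANKS:
            raise ValueError(f"flank must be one of {FLANKS}, got {self.flank!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}")

    @property
    def unidentified(self) -> bool:
        return is_unidentified(self.individual_id)


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults mirror a standard production run: three chains of 10,000
    iterations with a 2,000-iteration burn-in.  Proposal scales are
    starting values; with ``adapt=True`` they are tuned during burn-in
    only (Robbins-Monro toward 0.44 acceptance for scalar parameters,
    0.25 for the bivariate activity-centre moves) and frozen afterwards.
    """

    n_chains: int = 3
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin_maps: int = 10
    proposal_s: float = 2.0
    proposal_g0: float = 0.5
    proposal_sigma: float = 0.15
    adapt: bool = True
    map_from_start: bool = False  # thin (z, s) from iteration 1, not post burn-in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for convergence checks")
        if self.thin_maps < 1:
            raise ValueError("thin_maps must be >= 1")


@dataclass
class SurveyConfig:
    """End-to-end run configuration for one survey."""

    occasion_start: _dt.date
    occasion_end: _dt.date
    M: int
    buffer_km: float | str = "auto"
    raster_pixel_km: float = 1.0
    raster_extent: str = "mcp"  # or "statespace"
    flank_policy: str = "drop-single-flank"
    include_burnin_maps: bool = False
    seed: int = 0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if isinstance(self.occasion_start, str):
            self.occasion_start = _dt.date.fromisoformat(self.occasion_start)
        if isinstance(self.occasion_end, str):
            self.occasion_end = _dt.date.fromisoformat(self.occasion_end)
        if self.occasion_end < self.occasion_start:
            raise ValueError("occasion_end must not precede occasion_start")
        if self.M <= 0:
            raise ValueError("M must be a positive integer")
        if self.raster_extent not in ("mcp", "statespace"):
            raise ValueError("raster_extent must be 'mcp' or 'statespace'")
        if isinstance(self.buffer_km, str) and self.buffer_km != "auto":
            raise ValueError("buffer_km must be a positive number or 'auto'")

    @property
    def n_occasions(self) -> int:
        """Number of one-day occasions K in the configured window."""
        return (self.occasion_end - self.occasion_start).days + 1

    def occasion_of(self, date: _dt.date) -> Optional[int]:
        """1-based occasion index of a date, or None outside the window."""
        k = (date - self.occasion_start).days + 1
        return k if 1 <= k <= self.n_occasions else None

    def date_of(self, occasion: int) -> _dt.date:
        return self.occasion_start + _dt.timedelta(days=occasion - 1)


@dataclass
class StateSpace:
    """Rectangular state space: trap bounding box buffered on all sides.

    Activity centres are assumed uniformly distributed over this region;
    realised density divides the realised population size by its area.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("state space must have positive extent")

    @property
    def area_km2(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def half_width(self) -> float:
        """Half the smaller side; used as the upper prior bound for sigma."""
        return 0.5 * min(self.xmax - self.xmin, self.ymax - self.ymin)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Reflect coordinates at the boundaries back into the rectangle."""
        out = np.array(xy, dtype=float, copy=True)
        for dim, (lo, hi) in enumerate(((self.xmin, self.xmax), (self.ymin, self.ymax))):
            span = hi - lo
            v = np.mod(out[..., dim] - lo, 2.0 * span)
            out[..., dim] = lo + np.where(v > span, 2.0 * span - v, v)
        return out

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass
class SCRParams:
    """Augmented-model state: (g0, sigma, psi) and the latent (z, s).

    ``z`` flags which of the M augmented rows are real individuals
    (always 1 for detected ones); ``s`` holds the M activity centres.
    """

    g0: float
    sigma: float
    psi: float
    z: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=float)
        if not 0.0 <= self.g0 <= 1.0:
            raise ValueError("g0 must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.psi < 1.0:
            raise ValueError("psi must lie in (0, 1)")
        if self.s.shape != (self.z.shape[0], 2):
            raise ValueError("s must be M x 2")


@dataclass
class CaptureHistory:
    """Binary detection tensor (individuals x sites x occasions) plus effort.

    ``y[i, j, k] = 1`` iff individual ``i`` was photographed at site ``j``
    on occasion ``k``; at most one detection per cell by construction.
    ``usage`` is the per-site, per-occasion effort mask and ``trap_xy``
    the site coordinates in km, aligned with ``sites``.
    """

    individuals: list[str]
    sites: list[str]
    K: int
    y: np.ndarray
    usage: np.ndarray
    trap_xy: np.ndarray
    exclusion_log: dict = field(default_factory=dict)
    survey_period: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.usage = np.asarray(self.usage, dtype=np.int8)
        self.trap_xy = np.asarray(self.trap_xy, dtype=float)
        n, J, K = self.y.shape
        if (J, K) != self.usage.shape or K != self.K:
            raise ValueError("inconsistent capture-history dimensions")
        if self.trap_xy.shape != (J, 2):
            raise ValueError("trap_xy must be J x 2")
        if np.any(self.y & ~self.usage[None, :, :]):
            raise ValueError("detection recorded at an inactive site-occasion")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def counts(self) -> np.ndarray:
        """Per individual-site detection counts, summed over occasions."""
        return self.y.sum(axis=2)

    @property
    def effort(self) -> np.ndarray:
        """Trap-nights per site (usage summed over occasions)."""
        return self.usage.sum(axis=1)


@dataclass
class SurveySummary:
    """Survey-level tallies of individuals, recaptures and effort.

    A recapture is any detection of an individual beyond its first; a
    spatial recapture is a capture at a site additional to those the
    individual already used, i.e. per-individual distinct sites minus one.
    """

    n_individuals: int
    total_recaptures: int
    spatial_recaptures: int
    per_individual_recaptures: list[int]
    effective_trap_nights: int
    n_sites: int
    K: int
    survey_period: tuple[str, str] | None = None
    exclusion_log: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "total_recaptures": self.total_recaptures,
            "spatial_recaptures": self.spatial_recaptures,
            "per_individual_recaptures": list(self.per_individual_recaptures),
            "effective_trap_nights": self.effective_trap_nights,
            "n_sites": self.n_sites,
            "n_occasions": self.K,
            "survey_period": list(self.survey_period) if self.survey_period else None,
            "exclusions": dict(self.exclusion_log),
        }


@dataclass
class PosteriorChains:
    """Retained MCMC draws, one row of arrays per chain.

    ``params`` maps each monitored scalar ("g0", "sigma", "psi", "N",
    "D") to an (n_chains, n_kept) array; D is realised density per
    100 km2, an exact transform of N.  ``map_draws`` holds thinned
    realised activity centres for mapping: per chain a list of (n_i, 2)
    arrays, one per thinned iteration, containing the centres of rows
    with z = 1.
    """

    params: dict[str, np.ndarray]
    map_draws: list[list[np.ndarray]]
    area_km2: float
    M: int
    n_detected: int
    burn_in: int
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params["D"].shape[0]

    @property
    def n_kept(self) -> int:
        return self.params["D"].shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.params[name].reshape(-1)

    def all_map_draws(self) -> list[np.ndarray]:
        return [d for chain in self.map_draws for d in chain]


@dataclass
class ConvergenceReport:
    """Gelman-Rubin diagnostics per parameter with the 95% upper bound."""

    rhat: dict[str, tuple[float, float]]

    @property
    def converged(self) -> bool:
        return all(upper < 1.1 for _, upper in self.rhat.values())

    def as_dict(self) -> dict:
        return {
            "rhat": {k: {"point": p, "upper95": u} for k, (p, u) in self.rhat.items()},
            "converged": self.converged,
        }


@dataclass
class DensityEstimate:
    """Posterior summary of realised density (individuals / 100 km2)."""

    mean: float
    hpd_low: float
    hpd_high: float
    cv: float

    def as_dict(self) -> dict:
        return {
            "mean_per_100km2": self.mean,
            "hpd95_low": self.hpd_low,
            "hpd95_high": self.hpd_high,
            "cv": self.cv,
        }


@dataclass
class MCPResult:
    """Minimum convex polygon of the trap array, with its area."""

    vertices: np.ndarray
    area_km2: float
    density_per_100km2: Optional[float] = None

    def as_geojson(self) -> dict:
        ring = [[float(x), float(y)] for x, y in self.vertices]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        props = {"area_km2": self.area_km2}
        if self.density_per_100km2 is not None:
            props["density_per_100km2"] = self.density_per_100km2
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        }


@dataclass
class DensityRaster:
    """Expected realised activity centres per pixel per posterior draw.

    ``values[iy, ix]`` covers the half-open pixel
    [x0 + ix*pixel, x0 + (ix+1)*pixel) x [y0 + iy*pixel, y0 + (iy+1)*pixel),
    with row 0 at the southern edge.  With 1-km pixels the values are
    densities in individuals per km2.
    """

    x0: float
    y0: float
    pixel_km: float
    values: np.ndarray

    @property
    def total_mass(self) -> float:
        """Sum over pixels = mean realised N over draws (full extent)."""
        return float(self.values.sum())
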