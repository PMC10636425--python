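"""Closed-population SCR model M0 with data augmentation, and its sampler.

Model
-----
A super-population of M rows is created by data augmentation; row i is a
real individual when the latent indicator z_i = 1, with z_i ~
Bernoulli(psi).  Each row has a latent activity centre s_i uniform over
the rectangular state space S (trap bounding box plus buffer).  Given
z_i = 1, the detection of row i at trap j on occasion k is Bernoulli
with half-normal probability

    p_ij = g0 * exp(-||s_i - x_j||^2 / (2 sigma^2)),

masked by the per-site-per-occasion usage indicator.  Detection is
constant across individuals and occasions (model M0), so occasions are
exchangeable and the per-site Bernoulli product collapses to a Binomial
with the site's trap-nights as index — mathematically identical and much
faster; partial effort enters exactly through the usage-weighted
exponent.

Priors: g0 ~ U(0,1), sigma ~ U(0, half the smaller state-space side),
psi ~ U(0,1), s_i ~ U(S).

Sampler: Metropolis-within-Gibbs.  z (undetected rows) and psi have
conjugate Gibbs updates; activity centres move by random-walk Metropolis
with reflection at the boundary (rows with z = 0 are redrawn from their
uniform full conditional); g0 and sigma move on logit/log scales.
Proposal scales adapt during burn-in only, so retained draws come from a
fixed transition kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    CaptureHistory,
    MCMCConfig,
    PosteriorChains,
    SCRParams,
    StateSpace,
    TrapSite,
)

__all__ = [
    "detection_prob",
    "make_state_space",
    "rpsv",
    "suggest_buffer",
    "log_likelihood",
    "run_mcmc",
]


def detection_prob(g0, sigma, d):
    """Half-normal detection probability g0 * exp(-d^2 / (2 sigma^2)).

    Maximum g0 at the activity centre (d = 0), monotonically
    non-increasing in the centre-to-trap distance d.  Accepts scalars or
    arrays broadcast together.
    """
    g0 = np.asarray(g0, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any((g0 < 0) | (g0 > 1)):
        raise ValueError("g0 must lie in [0, 1]")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = g0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def make_state_space(traps, buffer_km: float) -> StateSpace:
    """Square-buffered rectangle around the trap array.

    The buffer should be two to three times the detection-function scale
    so that no individual with a non-negligible detection probability
    has its activity centre outside S.
    """
    if buffer_km is None or not np.isfinite(buffer_km) or buffer_km <= 0:
        raise ValueError("buffer_km must be a positive, finite number")
    xy = _trap_xy(traps)
    if xy.shape[0] < 1:
        raise ValueError("at least one trap is required")
    return StateSpace(
        xmin=float(xy[:, 0].min() - buffer_km),
        xmax=float(xy[:, 0].max() + buffer_km),
        ymin=float(xy[:, 1].min() - buffer_km),
        ymax=float(xy[:, 1].max() + buffer_km),
    )


def _trap_xy(traps) -> np.ndarray:
    if isinstance(traps, np.ndarray):
        return np.asarray(traps, dtype=float).reshape(-1, 2)
    if traps and isinstance(traps[0], TrapSite):
        return np.array([[t.x, t.y] for t in traps], dtype=float)
    return np.asarray(traps, dtype=float).reshape(-1, 2)


def rpsv(history: CaptureHistory) -> float:
    """Root pooled spatial variance of capture locations.

    RPSV^2 = sum_i sum_captures [(x - xbar_i)^2 + (y - ybar_i)^2]
             / (2 * sum_i (m_i - 1)),

    where m_i is the capture count of individual i and (xbar_i, ybar_i)
    the centroid of its capture locations; individuals captured once
    contribute nothing.  RPSV estimates the movement scale sigma when
    detection is half-normal.
    """
    num = 0.0
    den = 0
    any_spatial = False
    counts = history.counts  # n x J detections
    for i in range(history.n):
        m_i = int(counts[i].sum())
        if m_i < 2:
            continue
        locs = np.repeat(history.trap_xy, counts[i], axis=0)
        centroid = locs.mean(axis=0)
        num += float(((locs - centroid) ** 2).sum())
        den += m_i - 1
        if (counts[i] > 0).sum() > 1:
            any_spatial = True
    if den == 0 or not any_spatial or num <= 0.0:
        raise ValueError(
            "no spatial recaptures: movement scale cannot be estimated; "
            "set the buffer width manually"
        )
    return math.sqrt(num / (2.0 * den))


def suggest_buffer(history: CaptureHistory, traps=None) -> float:
    """Heuristic buffer width: 4 x RPSV.

    With a half-normal detection function, detection probability at
    4 sigma is ~3e-4 of g0, so a 4 x RPSV buffer comfortably contains
    the activity centres of detectable individuals.  ``traps`` is
    accepted for interface symmetry; coordinates are taken from the
    history, which was built against the same trap list.
    """
    return 4.0 * rpsv(history)


# ---------------------------------------------------------------------------
# likelihood


def _log_p_terms(g0: float, sigma: float, s: np.ndarray, trap_xy: np.ndarray):
    """log p and log(1-p) for all row-trap pairs; -inf handled, not raised."""
    d2 = ((s[:, None, :] - trap_xy[None, :, :]) ** 2).sum(axis=2)
    p = g0 * np.exp(-d2 / (2.0 * sigma**2))
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-np.minimum(p, 1.0))
    return log_p, log_q


def _row_loglik(counts: np.ndarray, effort: np.ndarray, log_p: np.ndarray,
                log_q: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row log-likelihood given z = 1.

    Detected rows (first n): Binomial(effort_j, p_ij) at the observed
    per-site counts (coefficient omitted; it matches the Bernoulli
    product over occasions).  Remaining rows: all-zero history.
    Returns (ll_detected (n,), ll_zero (M,)); ll_zero is the all-zero
    probability for *every* row, needed by the z update.
    """
    ll_zero = (effort[None, :] * log_q).sum(axis=1)
    with np.errstate(invalid="ignore"):  # 0 * -inf where a site has no captures
        lp = np.where(counts > 0, log_p[:n] * counts, 0.0)
    ll_det = lp.sum(axis=1) + ((effort[None, :] - counts) * log_q[:n]).sum(axis=1)
    return ll_det, ll_zero


def log_likelihood(
    history: CaptureHistory,
    params: SCRParams,
    state_space: StateSpace,
    conditional_only: bool = False,
) -> float:
    """Log joint of the detection data and z given (g0, sigma, psi, s).

    ``conditional_only=True`` returns only the detected rows' detection
    term (no augmented rows, no psi-z term).  Zero-probability
    configurations return -inf rather than raising.
    """
    n = history.n
    M = params.z.shape[0]
    if M < n:
        raise ValueError("augmented size M smaller than number detected")
    if np.any(params.z[:n] != 1):
        raise ValueError("detected individuals must have z = 1")
    if not state_space.contains(params.s).all():
        raise ValueError("activity centres must lie inside the state space")

    counts = history.counts.astype(float)
    effort = history.effort.astype(float)
    log_p, log_q = _log_p_terms(params.g0, params.sigma, params.s, history.trap_xy)
    ll_det, ll_zero = _row_loglik(counts, effort, log_p, log_q, n)

    total = float(ll_det.sum())
    if conditional_only:
        return total
    z_aug = params.z[n:].astype(float)
    total += float((z_aug * ll_zero[n:]).sum())
    nz = float(params.z.sum())
    total += nz * math.log(params.psi) + (M - nz) * math.log1p(-params.psi)
    return total


# ---------------------------------------------------------------------------
# sampler


def _update_psi(rng: np.random.Generator, z: np.ndarray, M: int) -> float:
    """Gibbs draw of psi from its Beta(1 + sum z, 1 + M - sum z) conditional."""
    nz = int(z.sum())
    return float(rng.beta(1 + nz, 1 + M - nz))


def _update_z(rng: np.random.Generator, ll_zero_aug: np.ndarray, psi: float) -> np.ndarray:
    """Gibbs draw of z for undetected rows.

    P(z_i = 1 | ...) = psi * p0_i / (psi * p0_i + 1 - psi) with p0_i the
    probability of the observed all-zero history for row i.
    """
    p0 = np.exp(ll_zero_aug)
    prob = psi * p0 / (psi * p0 + (1.0 - psi))
    return (rng.random(ll_zero_aug.shape[0]) < prob).astype(np.int8)


@dataclass
class _Adapter:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    scale: float
    target: float
    batch: int = 50
    _acc: float = 0.0
    _count: int = 0
    _nbatch: int = 0

    def update(self, acc_rate: float) -> None:
        self._acc += acc_rate
        self._count += 1
        if self._count == self.batch:
            self._nbatch += 1
            rate = self._acc / self.batch
            step = min(0.5, 2.0 / math.sqrt(self._nbatch))
            self.scale *= math.exp(step * (rate - self.target))
            self._acc = 0.0
            self._count = 0


def _init_state(rng, history, state_space, M, sigma0):
    n = history.n
    counts = history.counts
    s = np.column_stack(
        [
            rng.uniform(state_space.xmin, state_space.xmax, M),
            rng.uniform(state_space.ymin, state_space.ymax, M),
        ]
    )
    for i in range(n):
        w = counts[i].astype(float)
        centroid = (history.trap_xy * w[:, None]).sum(axis=0) / w.sum()
        s[i] = state_space.reflect(centroid + rng.normal(0.0, 0.5, 2))
    z = np.zeros(M, dtype=np.int8)
    z[:n] = 1
    psi = float(rng.beta(1 + n, 1 + M - n))
    z[n:] = rng.random(M - n) < psi
    g0 = float(rng.uniform(0.02, 0.2))
    sigma = float(np.clip(sigma0 * math.exp(rng.normal(0.0, 0.3)),
                          1e-3, state_space.half_width * 0.99))
    return g0, sigma, psi, z, s


def _run_chain(rng, history, cfg: MCMCConfig, state_space, M, sigma0, sigma_max):
    n = history.n
    counts = history.counts.astype(float)
    effort = history.effort.astype(float)
    X = history.trap_xy
    area = state_space.area_km2

    g0, sigma, psi, z, s = _init_state(rng, history, state_space, M, sigma0)
    log_p, log_q = _log_p_terms(g0, sigma, s, X)
    ll_det, ll_zero = _row_loglik(counts, effort, log_p, log_q, n)

    ad_s = _Adapter(cfg.proposal_s, target=0.25)
    ad_g0 = _Adapter(cfg.proposal_g0, target=0.44)
    ad_sig = _Adapter(cfg.proposal_sigma, target=0.44)

    n_kept = cfg.n_iter - cfg.burn_in
    out = {k: np.empty(n_kept, dtype=float) for k in ("g0", "sigma", "psi", "N", "D")}
    map_draws: list[np.ndarray] = []
    acc_post = {"s": [0, 0], "g0": [0, 0], "sigma": [0, 0]}

    for it in range(cfg.n_iter):
        adapting = cfg.adapt and it < cfg.burn_in

        # --- activity centres -------------------------------------------
        live = z.astype(bool)
        prop = s + rng.normal(0.0, ad_s.scale, size=(M, 2))
        prop = state_space.reflect(prop)
        # z = 0 rows: full conditional is the uniform prior
        dead = ~live
        if dead.any():
            s[dead, 0] = rng.uniform(state_space.xmin, state_space.xmax, dead.sum())
            s[dead, 1] = rng.uniform(state_space.ymin, state_space.ymax, dead.sum())
        log_p_prop, log_q_prop = _log_p_terms(g0, sigma, prop, X)
        ll_det_prop, ll_zero_prop = _row_loglik(counts, effort, log_p_prop, log_q_prop, n)
        ll_row = np.concatenate([ll_det, ll_zero[n:]])
        ll_row_prop = np.concatenate([ll_det_prop, ll_zero_prop[n:]])
        with np.errstate(invalid="ignore"):
            log_r = ll_row_prop - ll_row
        accept = live & (np.log(rng.random(M)) < np.nan_to_num(log_r, nan=-np.inf))
        s[accept] = prop[accept]
        moved = accept | dead
        if moved.any():
            log_p, log_q = _log_p_terms(g0, sigma, s, X)
            ll_det, ll_zero = _row_loglik(counts, effort, log_p, log_q, n)
        acc_rate_s = float(accept[live].mean()) if live.any() else 1.0
        if adapting:
            ad_s.update(acc_rate_s)
        else:
            acc_post["s"][0] += accept[live].sum()
            acc_post["s"][1] += int(live.sum())

        # --- g0 (logit scale) and sigma (log scale) ---------------------
        z_aug = z[n:].astype(float)

        def _total(ll_d, ll_z):
            return float(ll_d.sum() + (z_aug * ll_z[n:]).sum())

        cur = _total(ll_det, ll_zero)

        lo = math.log(g0 / (1.0 - g0)) + rng.normal(0.0, ad_g0.scale)
        g0_prop = 1.0 / (1.0 + math.exp(-lo))
        log_p_p, log_q_p = _log_p_terms(g0_prop, sigma, s, X)
        ll_det_p, ll_zero_p = _row_loglik(counts, effort, log_p_p, log_q_p, n)
        log_r = (_total(ll_det_p, ll_zero_p) - cur
                 + math.log(g0_prop * (1 - g0_prop)) - math.log(g0 * (1 - g0)))
        acc = math.log(rng.random()) < log_r
        if acc:
            g0 = g0_prop
            log_p, log_q, ll_det, ll_zero = log_p_p, log_q_p, ll_det_p, ll_zero_p
            cur = _total(ll_det, ll_zero)
        if adapting:
            ad_g0.update(float(acc))
        else:
            acc_post["g0"][0] += int(acc)
            acc_post["g0"][1] += 1

        sigma_prop = sigma * math.exp(rng.normal(0.0, ad_sig.scale))
        acc = False
        if sigma_prop < sigma_max:
            log_p_p, log_q_p = _log_p_terms(g0, sigma_prop, s, X)
            ll_det_p, ll_zero_p = _row_loglik(counts, effort, log_p_p, log_q_p, n)
            log_r = (_total(ll_det_p, ll_zero_p) - cur
                     + math.log(sigma_prop) - math.log(sigma))
            acc = math.log(rng.random()) < log_r
            if acc:
                sigma = sigma_prop
                log_p, log_q, ll_det, ll_zero = log_p_p, log_q_p, ll_det_p, ll_zero_p
        if adapting:
            ad_sig.update(float(acc))
        else:
            acc_post["sigma"][0] += int(acc)
            acc_post["sigma"][1] += 1

        # --- latent membership and inclusion probability ----------------
        z[n:] = _update_z(rng, ll_zero[n:], psi)
        psi = _update_psi(rng, z, M)

        # --- record ------------------------------------------------------
        if it >= cfg.burn_in:
            j = it - cfg.burn_in
            N = int(z.sum())
            out["g0"][j] = g0
            out["sigma"][j] = sigma
            out["psi"][j] = psi
            out["N"][j] = N
            out["D"][j] = N / area * 100.0
        map_phase = it if cfg.map_from_start else it - cfg.burn_in
        if map_phase >= 0 and map_phase % cfg.thin_maps == 0:
            map_draws.append(s[z.astype(bool)].copy())

    rates = {k: (a / t if t else float("nan")) for k, (a, t) in acc_post.items()}
    return out, map_draws, rates


def run_mcmc(
    history: CaptureHistory,
    config: MCMCConfig,
    state_space: StateSpace,
    M: int,
) -> PosteriorChains:
    """Run the Metropolis-within-Gibbs sampler.

    Chains are sequential but statistically independent: each gets its
    own generator spawned from the configured seed, so results are
    reproducible and identical runs are byte-identical.
    """
    n = history.n
    if n == 0:
        raise ValueError("no capture histories")
    if M <= n:
        raise ValueError(f"M = {M} must exceed the number detected ({n})")
    if history.usage.sum() == 0:
        raise ValueError("all-zero usage: no survey effort")

    try:
        sigma0 = rpsv(history)
    except ValueError:
        sigma0 = 0.25 * state_space.half_width
    sigma_max = state_space.half_width

    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    params = {k: [] for k in ("g0", "sigma", "psi", "N", "D")}
    map_draws = []
    rates_all = []
    for ss in streams:
        rng = np.random.Generator(np.random.PCG64(ss))
        out, draws, rates = _run_chain(rng, history, config, state_space, M, sigma0, sigma_max)
        for k in params:
            params[k].append(out[k])
        map_draws.append(draws)
        rates_all.append(rates)

    acceptance = {
        k: float(np.mean([r[k] for r in rates_all])) for k in ("s", "g0", "sigma")
    }
    return PosteriorChains(
        params={k: np.vstack(v) for k, v in params.items()},
        map_draws=map_draws,
        area_km2=state_space.area_km2,
        M=M,
        n_detected=n,
        burn_in=config.burn_in,
        acceptance=acceptance,
    )
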