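"""Convergence assessment and posterior summaries.

Convergence uses the classic multi-chain Gelman-Rubin potential scale
reduction factor with the Brooks-Gelman 95% upper bound; the run is
declared converged when every monitored parameter's upper bound is
below 1.1.  Point estimates are posterior means with 95% highest
posterior density (HPD) intervals; precision is the coefficient of
variation (posterior SD / posterior mean) of realised density, with
0.20 the conventional high-precision boundary.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .types import ConvergenceReport, DensityEstimate, PosteriorChains

#: CV at or below this is conventionally called high precision
CV_HIGH_PRECISION = 0.20

_LARGE_RHAT = 1e6


def gelman_rubin(chains, split: bool = False) -> tuple[float, float]:
    """Gelman-Rubin R-hat point estimate and Brooks-Gelman 95% upper bound.

    ``chains`` is an (m, n) array of m >= 2 chains of length n >= 2.
    With W the mean within-chain variance and B/n the between-chain
    variance of chain means,

        point = sqrt(((n-1)/n * W + B/n) / W)

    and the upper bound replaces the between-chain term by its 97.5%
    sampling quantile (an F quantile with method-of-moments degrees of
    freedom for W).  ``split=True`` first halves every chain (the modern
    variant, more sensitive to within-chain trends).

    All chains constant and equal gives (1, 1) with a warning; constant
    but unequal chains diverge and are returned as a large finite value.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need an (m >= 2, n >= 2) array of chains")
    if split:
        half = c.shape[1] // 2
        c = np.vstack([c[:, :half], c[:, half : 2 * half]])
    m, n = c.shape

    s2 = c.var(axis=1, ddof=1)
    W = float(s2.mean())
    xbar = c.mean(axis=1)
    B = n * float(xbar.var(ddof=1))

    if W == 0.0:
        if B == 0.0:
            warnings.warn("all chains constant and equal; R-hat = 1 by convention")
            return 1.0, 1.0
        warnings.warn("zero within-chain variance with distinct chains; R-hat diverges")
        return _LARGE_RHAT, _LARGE_RHAT

    point = math.sqrt(((n - 1) / n * W + B / n) / W)

    # Brooks-Gelman: 97.5% quantile of the between-chain contribution
    var_s2 = float(s2.var(ddof=1))
    if var_s2 > 0:
        df_w = 2.0 * W**2 / var_s2
        q = float(stats.f.ppf(0.975, m - 1, df_w))
    else:
        q = float(stats.chi2.ppf(0.975, m - 1)) / (m - 1)
    upper = math.sqrt((n - 1) / n + (1.0 + 1.0 / m) * q * B / (n * W))
    return point, max(point, upper)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples.

    Over the sorted draws, every window of ceil(mass * n) consecutive
    points is a candidate; the narrowest wins, ties broken by the lowest
    start.  Suitable for the unimodal posteriors produced here.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    nsamp = x.shape[0]
    if nsamp < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    k = int(math.ceil(mass * nsamp))
    widths = x[k - 1 :] - x[: nsamp - k + 1]
    j = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[j]), float(x[j + k - 1])


def coefficient_of_variation(samples) -> float:
    """Posterior SD (n-1 denominator) divided by the posterior mean."""
    x = np.asarray(samples, dtype=float).ravel()
    mean = float(x.mean())
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1)) / mean


def precision_label(cv: float) -> str:
    """Conventional wording: <= 0.20 high, <= 0.35 moderate, else low."""
    if cv <= CV_HIGH_PRECISION:
        return "high"
    return "moderate" if cv <= 0.35 else "low"


def density_estimate(samples) -> DensityEstimate:
    """Posterior mean, 95% HPD and CV of a (density) chain."""
    x = np.asarray(samples, dtype=float).ravel()
    low, high = hpd_interval(x, 0.95)
    return DensityEstimate(
        mean=float(x.mean()),
        hpd_low=low,
        hpd_high=high,
        cv=coefficient_of_variation(x),
    )


def convergence_report(
    chains: PosteriorChains,
    parameters: tuple[str, ...] = ("g0", "sigma", "psi", "N", "D"),
    split: bool = False,
) -> ConvergenceReport:
    """R-hat point and 95% upper bound for each monitored parameter."""
    rhat = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant N chains possible in tiny runs
        for name in parameters:
            rhat[name] = gelman_rubin(chains.params[name], split=split)
    return ConvergenceReport(rhat=rhat)


def plot_traces(chains: PosteriorChains, path, parameters=("g0", "sigma", "N", "D")):
    """Trace plots per chain for visual inspection; saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(parameters), 1, figsize=(8, 2.2 * len(parameters)),
                             sharex=True)
    for ax, name in zip(np.atleast_1d(axes), parameters):
        for c in range(chains.n_chains):
            ax.plot(chains.params[name][c], lw=0.5)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("retained iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
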