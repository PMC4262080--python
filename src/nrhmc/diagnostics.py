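"""Sample-quality diagnostics.

The central quantity is the integrated autocorrelation length tau_int of a
scalar chain series (here conventionally the log-likelihood), estimated with
the Gamma-method: normalised autocovariances are summed up to a window chosen
automatically by balancing truncation bias against accumulated noise.  Under
the convention used throughout this package an uncorrelated series has
tau_int = 0.5, and the effective sampling speed of a chain is

    v = N / (2 tau_int t_E)

(effectively independent samples per second of sampling time t_E).  Only the
relative speeds ``v_r`` — each ``v`` divided by the smallest observed one —
are hardware independent and used for method comparisons.

For two-parameter problems the module also supports posterior-shape
comparisons: the exact posterior evaluated on a regular grid versus a Gaussian
kernel density estimate of a sample, summarised by total-variation distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .posterior import SteadyStatePosterior

__all__ = [
    "AutocorrelationReport",
    "SpeedReport",
    "DiagnosticsError",
    "integrated_autocorrelation",
    "effective_speed",
    "relative_speeds",
    "posterior_grid",
    "kde_2d",
    "total_variation",
    "credible_region_covers",
]


class DiagnosticsError(ValueError):
    """Raised for degenerate or too-short input series."""


@dataclass
class AutocorrelationReport:
    """Integrated autocorrelation length of a scalar series (Gamma-method)."""

    tau_int: float
    tau_err: float
    window: int
    n: int

    def __str__(self):
        return f"tau_int = {self.tau_int:.3g} +/- {self.tau_err:.2g} (W={self.window}, N={self.n})"


@dataclass
class SpeedReport:
    """Autocorrelation-corrected effective sampling speed."""

    v: float  # effectively independent samples per second
    n: int
    tau_int: float
    t_elapsed: float
    v_r: float | None = None  # filled by relative_speeds


def integrated_autocorrelation(series, s_param: float = 1.5, w_max: int | None = None) -> AutocorrelationReport:
    """Gamma-method estimate of tau_int with automatic windowing.

    The summation window W is the first lag where
    ``g(W) = exp(-W / tau_exp(W)) - tau_exp(W) / sqrt(W N)`` turns negative,
    with ``tau_exp`` derived from the running tau_int estimate and the window
    parameter ``s_param`` (default 1.5, the cited tool's default).  The
    reported error follows the standard Gamma-method variance
    ``sigma^2(tau) ~= 4/N (W + 1/2 - tau) tau^2``.

    Raises :class:`DiagnosticsError` for series shorter than 100 points,
    non-finite values, or a constant series (undefined autocorrelation).
    """
    a = np.asarray(series, dtype=float).ravel()
    n = a.size
    if n < 100:
        raise DiagnosticsError(f"series too short for tau_int estimation (n={n} < 100)")
    if not np.all(np.isfinite(a)):
        raise DiagnosticsError("series contains non-finite values")
    d = a - a.mean()
    if np.max(np.abs(d)) == 0.0:
        raise DiagnosticsError("constant series: autocorrelation undefined")

    # autocovariance Gamma(t) via FFT, unbiased normalisation 1/(n-t)
    nfft = 1 << (2 * n - 1).bit_length()
    fa = np.fft.rfft(d, nfft)
    acov = np.fft.irfft(fa * np.conj(fa), nfft)[:n]
    acov /= n - np.arange(n)
    gamma0 = acov[0]
    if gamma0 <= 0:
        raise DiagnosticsError("zero variance series")
    rho = acov / gamma0

    if w_max is None:
        w_max = min(n // 2, 20000)
    w_opt = None
    tsum = 0.5
    for w in range(1, w_max):
        tsum += rho[w]
        tau_w = max(tsum, 1e-12)
        if tau_w <= 0.5:
            tau_exp = 1e-8
        else:
            tau_exp = s_param / math.log((2.0 * tau_w + 1.0) / (2.0 * tau_w - 1.0))
        g = math.exp(-w / tau_exp) - tau_exp / math.sqrt(w * n)
        if g < 0.0:
            w_opt = w
            break
    if w_opt is None:
        w_opt = w_max - 1

    tau_raw = 0.5 + float(np.sum(rho[1 : w_opt + 1]))
    # bias correction: the estimator of Gamma is biased by -C_F/n
    cf = 2.0 * gamma0 * tau_raw
    acov_c = acov[: w_opt + 1] + cf / n
    tau_int = float(0.5 + np.sum(acov_c[1:]) / acov_c[0])
    tau_err = 2.0 * tau_int * math.sqrt(max(w_opt + 0.5 - tau_int, 0.25) / n)
    return AutocorrelationReport(tau_int=tau_int, tau_err=tau_err, window=w_opt, n=n)


def effective_speed(n: int, tau_int: float, t_elapsed: float) -> SpeedReport:
    """Effective sampling speed ``v = N / (2 tau_int t_E)``.

    ``tau_int`` below the uncorrelated limit 0.5 (estimator noise) is clipped
    to 0.5 with a warning.
    """
    if n <= 0 or t_elapsed <= 0:
        raise ValueError("n and t_elapsed must be positive")
    if tau_int < 0.5:
        import warnings

        warnings.warn(
            f"tau_int={tau_int:.3g} < 0.5 is estimator noise; clipping to 0.5",
            stacklevel=2,
        )
        tau_int = 0.5
    return SpeedReport(v=n / (2.0 * tau_int * t_elapsed), n=n, tau_int=tau_int, t_elapsed=t_elapsed)


def relative_speeds(reports: list[SpeedReport]) -> list[SpeedReport]:
    """Normalise each speed by the lowest observed one (slowest method gets 1)."""
    v_min = min(r.v for r in reports)
    for r in reports:
        r.v_r = r.v / v_min
    return reports


def posterior_grid(model, dataset, prior, bounds, resolution: int = 100, backend: str = "newton"):
    """Normalised posterior density on a regular grid (2-parameter models only).

    ``bounds = ((lo1, hi1), (lo2, hi2))``.  Returns ``(axis1, axis2, density)``
    where density integrates to 1 against the grid cell area.  This removes
    sampling error entirely and serves as the reference in sampler
    validations.
    """
    if model.n_parameters != 2:
        raise ValueError(
            f"posterior_grid requires exactly 2 free parameters, model has {model.n_parameters}"
        )
    (lo1, hi1), (lo2, hi2) = bounds
    ax1 = np.linspace(lo1, hi1, resolution)
    ax2 = np.linspace(lo2, hi2, resolution)
    target = SteadyStatePosterior(model, dataset, prior, backend=backend)
    logp = np.full((resolution, resolution), -np.inf)
    for i, t1 in enumerate(ax1):
        for j, t2 in enumerate(ax2):
            ev = target.evaluate(np.array([t1, t2]), order=0)
            if ev.ok:
                logp[i, j] = ev.logpost
    return ax1, ax2, _normalise_grid(logp, ax1, ax2)


def _normalise_grid(logp, ax1, ax2):
    cell = (ax1[1] - ax1[0]) * (ax2[1] - ax2[0])
    p = np.exp(logp - np.max(logp[np.isfinite(logp)]))
    p[~np.isfinite(logp)] = 0.0
    return p / (p.sum() * cell)


def kde_2d(samples, ax1, ax2, bw_method: str = "silverman"):
    """Gaussian kernel density estimate evaluated on a given grid geometry.

    Uses the sample-covariance-scaled Gaussian kernel with the Silverman
    factor, which adapts the kernel to strongly correlated (ridge-shaped)
    posteriors.  The returned density is renormalised to integrate to 1 over
    the grid.  Requires at least 500 samples and non-degenerate spread.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be (n, 2)")
    if samples.shape[0] < 500:
        raise ValueError(f"need >= 500 samples for a stable KDE, got {samples.shape[0]}")
    spread = np.std(samples, axis=0)
    if np.any(spread <= 1e-12 * (1.0 + np.abs(samples).max())):
        raise DiagnosticsError("degenerate (zero-variance) sample")
    try:
        kde = gaussian_kde(samples.T, bw_method=bw_method)
    except np.linalg.LinAlgError as exc:  # perfectly collinear sample
        raise DiagnosticsError(f"degenerate sample covariance: {exc}") from None
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")
    dens = kde(np.vstack([g1.ravel(), g2.ravel()])).reshape(len(ax1), len(ax2))
    cell = (ax1[1] - ax1[0]) * (ax2[1] - ax2[0])
    return dens / (dens.sum() * cell)


def total_variation(p, q, cell_area: float) -> float:
    """Total-variation distance between two gridded densities."""
    return 0.5 * float(np.sum(np.abs(np.asarray(p) - np.asarray(q)))) * cell_area


def credible_region_covers(samples, theta_true, level: float = 0.95) -> bool:
    """Whether the central Gaussian-approximation credible region covers a point.

    The region is the Mahalanobis ellipsoid of the sample mean/covariance at
    the chi-squared quantile for the sample dimension.
    """
    from scipy.stats import chi2

    samples = np.asarray(samples, dtype=float)
    mu = samples.mean(axis=0)
    cov = np.cov(samples.T)
    d = np.atleast_1d(np.asarray(theta_true, dtype=float) - mu)
    cov = np.atleast_2d(cov)
    m2 = float(d @ np.linalg.solve(cov, d))
    return m2 <= chi2.ppf(level, df=samples.shape[1])


def plot_density_comparison(ax1, ax2, grids, labels, path=None):
    """Side-by-side contour plots of gridded densities (grid vs KDEs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(grids), figsize=(4 * len(grids), 4), squeeze=False)
    for ax, dens, lab in zip(axes[0], grids, labels):
        ax.contourf(ax1, ax2, dens.T, levels=20)
        ax.set_title(lab)
        ax.set_xlabel("theta_1")
        ax.set_ylabel("theta_2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
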