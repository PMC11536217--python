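"""Gaussian decomposition of a weekly epidemic incidence series.

An epidemic season is modelled as a sum of K Gaussian pulses
``rate(t) = sum_w A_w * exp(-(t - mu_w)^2 / (2 sigma_w^2))`` with no
baseline offset (incidence is assumed to decay to ~0 between waves; a
constant offset can be enabled).  Each wave's duration is delineated by
its full width at half maximum, ``FWHM = 2*sqrt(2*ln 2)*sigma``, giving
the interval ``[mu - FWHM/2, mu + FWHM/2]``.

Fitting is bounded nonlinear least squares (trust region reflective),
initialised from the K most prominent local maxima of the series with
each sigma seeded from the peak's half-height span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_widths

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GaussianWave:
    """One fitted wave: amplitude (rate units), centre mu and s.d. sigma (years)."""

    amplitude: float
    mu: float
    sigma: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-((t - self.mu) ** 2) / (2.0 * self.sigma**2))


def fwhm(wave: "GaussianWave | float") -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2*ln 2)*sigma."""
    sigma = wave.sigma if isinstance(wave, GaussianWave) else float(wave)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_FACTOR * sigma


@dataclass
class WaveSet:
    """Fitted waves ordered by centre, with FWHM intervals and fit RSS."""

    waves: list
    fit_rss: float = 0.0
    offset: float = 0.0

    def __post_init__(self):
        self.waves = sorted(self.waves, key=lambda w: w.mu)

    @property
    def intervals(self) -> list:
        return wave_intervals(self)

    def __len__(self) -> int:
        return len(self.waves)

    def __iter__(self):
        return iter(self.waves)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        total = np.full_like(t, self.offset, dtype=float)
        for w in self.waves:
            total = total + w(t)
        return total


def wave_intervals(waveset: WaveSet) -> list:
    """Per-wave [mu - FWHM/2, mu + FWHM/2], in the mu ordering."""
    out = []
    for w in waveset.waves:
        half = fwhm(w) / 2.0
        out.append((w.mu - half, w.mu + half))
    return out


def _initial_guess(t: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    peaks, props = find_peaks(y, prominence=(None, None))
    if len(peaks) < k:
        raise ValueError(
            f"only {len(peaks)} prominent local maxima found; "
            f"try a smaller wave count than k={k}"
        )
    order = np.argsort(props["prominences"])[::-1][:k]
    chosen = np.sort(peaks[order])
    dt = float(np.median(np.diff(t)))
    widths = peak_widths(y, chosen, rel_height=0.5)[0] * dt  # half-height span
    p0 = []
    for idx, w in zip(chosen, widths):
        sigma0 = max(w / FWHM_FACTOR, dt / 2.0)
        p0.extend([max(y[idx], 1e-12), t[idx], sigma0])
    return np.asarray(p0)


def fit_waves(
    times,
    rates,
    k: int,
    init: WaveSet | None = None,
    fit_offset: bool = False,
    max_nfev: int = 50000,
) -> WaveSet:
    """Fit a K-Gaussian mixture to a (time, rate) series.

    ``init`` overrides the peak-based initialisation.  Raises on
    non-convergence (reporting the best residual sum of squares) and when
    fewer than K prominent maxima exist to seed the fit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(rates, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and rates must be matching 1-d arrays")
    if k < 1:
        raise ValueError("k must be >= 1")
    if t.size < 3 * k:
        raise ValueError(f"series of length {t.size} cannot identify {k} waves")

    if init is not None:
        p0 = np.asarray(
            [v for w in init.waves for v in (w.amplitude, w.mu, w.sigma)], float
        )
        if p0.size != 3 * k:
            raise ValueError("init wave count does not match k")
    else:
        p0 = _initial_guess(t, y, k)
    if fit_offset:
        p0 = np.append(p0, max(float(np.min(y)), 0.0))

    span = float(t[-1] - t[0])
    dt = float(np.median(np.diff(t)))
    lb = np.tile([1e-12, t[0] - span, dt / 10.0], k)
    ub = np.tile([np.inf, t[-1] + span, span], k)
    if fit_offset:
        lb = np.append(lb, 0.0)
        ub = np.append(ub, np.inf)
    p0 = np.clip(p0, lb, ub)

    def model(params):
        total = np.zeros_like(t)
        for j in range(k):
            a, mu, s = params[3 * j : 3 * j + 3]
            total = total + a * np.exp(-((t - mu) ** 2) / (2.0 * s * s))
        if fit_offset:
            total = total + params[-1]
        return total

    res = least_squares(
        lambda p: model(p) - y, p0, bounds=(lb, ub), max_nfev=max_nfev, xtol=1e-14,
        ftol=1e-14, gtol=1e-14,
    )
    rss = float(np.sum(res.fun**2))
    if res.status <= 0:
        raise RuntimeError(f"wave fit did not converge (best RSS {rss:.4g})")
    waves = [
        GaussianWave(
            amplitude=float(res.x[3 * j]),
            mu=float(res.x[3 * j + 1]),
            sigma=float(res.x[3 * j + 2]),
        )
        for j in range(k)
    ]
    offset = float(res.x[-1]) if fit_offset else 0.0
    return WaveSet(waves=waves, fit_rss=rss, offset=offset)
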