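"""Multitaper spectra, Lorentzian aperiodic fits, and corrected gamma power.

The power spectrum of resting neural activity mixes an aperiodic 1/f-like
background with oscillatory peaks.  The background is modelled in
semi-log space as a Lorentzian,

    log10 P(f) = b - log10(k + f**chi),

with offset ``b``, knee ``k`` and exponent ``chi``.  Gamma power
(30-50 Hz) is the mean log10 residual after subtracting the fitted
background, so a flat (purely aperiodic) spectrum scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal.windows import dpss

__all__ = [
    "SpectrumEstimate",
    "AperiodicFit",
    "multitaper_psd",
    "fit_aperiodic",
    "gamma_power",
    "regress_gamma_on_hfc",
    "aperiodic_model",
]


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    n_tapers: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")


@dataclass
class AperiodicFit:
    offset_b: float
    knee_k: float
    exponent_chi: float
    fit_residual_rms: float
    n_masked: int = 0

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return aperiodic_model(freqs, self.offset_b, self.knee_k, self.exponent_chi)


def aperiodic_model(f: np.ndarray, b: float, k: float, chi: float) -> np.ndarray:
    """Lorentzian aperiodic background in log10-power units."""
    return b - np.log10(k + np.asarray(f, dtype=float) ** chi)


def multitaper_psd(
    series: np.ndarray,
    fs: float,
    n_tapers: int = 29,
    band: tuple[float, float] = (1.0, 50.0),
    nw: float | None = None,
) -> SpectrumEstimate:
    """Thomson multitaper PSD restricted to a band.

    Uses ``n_tapers`` Slepian tapers with time-bandwidth NW =
    (n_tapers + 1) / 2 unless ``nw`` is given, and averages the tapered
    periodograms with eigenvalue weights.  One-sided density: the
    integral over [0, fs/2] equals the series variance (Parseval).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if nw is None:
        nw = (n_tapers + 1) / 2.0
    if n_tapers > 2 * nw - 1:
        raise ValueError(f"{n_tapers} tapers infeasible for NW={nw} (max {int(2 * nw - 1)})")
    n = x.size
    tapers, eigvals = dpss(n, nw, Kmax=n_tapers, return_ratios=True)
    x = x - x.mean()
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    pxx = (np.abs(spec) ** 2) / fs
    psd = np.average(pxx, axis=0, weights=eigvals)
    # one-sided scaling (DC and Nyquist not doubled)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return SpectrumEstimate(freqs=freqs[sel], psd=psd[sel], fs=fs, n_tapers=n_tapers)


def fit_aperiodic(
    spectrum: SpectrumEstimate,
    mask_sd: float = 2.5,
    max_nfev: int = 10000,
) -> AperiodicFit:
    """Fit the Lorentzian aperiodic background in semi-log space.

    Robust masked nonlinear least squares on log10 power: after an
    initial fit, points lying more than ``mask_sd`` residual scales
    *above* the fit (oscillatory peaks) are masked and the fit
    repeated until the mask stabilizes.  Because peaks only ever add
    power, the residual scale is estimated from the below-fit side
    only, which stays uncontaminated by broad peaks.  The knee and
    exponent are constrained nonnegative.
    """
    f = spectrum.freqs
    if f.size < 20:
        raise ValueError("need at least 20 frequency points")
    logp = np.log10(np.maximum(spectrum.psd, 1e-300))

    def resid(theta, fsel, ysel):
        b, logk, chi = theta
        return aperiodic_model(fsel, b, 10.0 ** logk - 1e-12, chi) - ysel

    # exponent guess from end-to-end log-log slope, offset from first point
    chi0 = max(
        0.1,
        (logp[0] - logp[-1]) / max(np.log10(f[-1]) - np.log10(f[0]), 1e-9),
    )
    theta0 = np.array([logp[0] + chi0 * np.log10(f[0]), -12.0, chi0])
    lb = [-np.inf, -12.0, 0.0]
    ub = [np.inf, 10.0, 10.0]

    def solve(fsel, ysel, start):
        best = None
        for knee_start in (start[1], 0.0, 2.0):
            t0 = np.clip(np.array([start[0], knee_start, start[2]]), lb, ub)
            sol = least_squares(
                resid, t0, bounds=(lb, ub), args=(fsel, ysel), max_nfev=max_nfev
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    sol = solve(f, logp, theta0)
    keep = np.ones(f.size, dtype=bool)
    for _ in range(8):
        excess = -resid(sol.x, f, logp)  # data - model: peaks are positive
        below = excess[excess <= 0]
        scale = np.sqrt(np.mean(below**2)) if below.size else 0.0
        new_keep = excess <= mask_sd * max(scale, 1e-12)
        if new_keep.sum() < 20 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        sol = solve(f[keep], logp[keep], sol.x)
    n_masked = int((~keep).sum())
    r = resid(sol.x, f[keep], logp[keep])
    if not sol.success and sol.status <= 0:
        raise RuntimeError(f"aperiodic fit did not converge: {sol.message}")
    b, logk, chi = sol.x
    return AperiodicFit(
        offset_b=float(b),
        knee_k=float(max(10.0 ** logk - 1e-12, 0.0)),
        exponent_chi=float(chi),
        fit_residual_rms=float(np.sqrt(np.mean(r ** 2))),
        n_masked=n_masked,
    )


def gamma_power(
    spectrum: SpectrumEstimate,
    fit: AperiodicFit,
    band: tuple[float, float] = (30.0, 50.0),
) -> float:
    """Aperiodic-corrected band power: mean log10 residual over the band."""
    f = spectrum.freqs
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ValueError("band outside the spectrum's frequency range")
    resid = np.log10(np.maximum(spectrum.psd[sel], 1e-300)) - fit.model(f[sel])
    return float(resid.mean())


def regress_gamma_on_hfc(gamma_values, hfc_counts):
    """OLS of per-subject gamma power on intratumoural HFC node counts."""
    from .stats import linear_regression

    return linear_regression(np.asarray(hfc_counts, float), np.asarray(gamma_values, float))
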