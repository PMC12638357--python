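"""Relaxometry fits: R1 from inversion recovery, R2 from multi-echo spin
echo, R2*/PDFF from magnitude-only multi-peak fitting, and T2 correction of
spectroscopic fat-peak amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import FatSpectrum, ValidationError

__all__ = [
    "RelaxFitResult",
    "PeakAreaSeries",
    "fit_r1_ir",
    "fit_r2_se",
    "fit_r2s_pdff_magnitude",
    "fit_r2s_pdff_voxels",
    "correct_spectrum_amplitudes",
]


@dataclass(frozen=True)
class RelaxFitResult:
    """Outcome of a single relaxation fit."""

    rate: float  # 1/s
    amplitude: float
    rss: float
    n_points: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0 or self.rss < 0:
            raise ValidationError("rate and residual sum of squares must be non-negative")


@dataclass(frozen=True)
class PeakAreaSeries:
    """Per-peak spectroscopic areas across a STEAM echo-time series."""

    te_s: np.ndarray  # (n_te,)
    areas: np.ndarray  # (n_peaks, n_te)
    delta_ppm: np.ndarray  # (n_peaks,) chemical shifts relative to water

    def __post_init__(self) -> None:
        te = np.atleast_1d(np.asarray(self.te_s, dtype=float))
        ar = np.atleast_2d(np.asarray(self.areas, dtype=float))
        dp = np.atleast_1d(np.asarray(self.delta_ppm, dtype=float))
        if te.size < 3:
            raise ValidationError("need at least 3 echo times per peak")
        if ar.shape != (dp.size, te.size):
            raise ValidationError("areas must be (n_peaks, n_te)")
        object.__setattr__(self, "te_s", te)
        object.__setattr__(self, "areas", ar)
        object.__setattr__(self, "delta_ppm", dp)


def fit_r1_ir(signal, ti_s) -> RelaxFitResult:
    """R1 from magnitude inversion-recovery data.

    Fits |a (1 - b exp(-TI R1))| with the inversion efficiency b free
    (b = 2 for a perfect inversion and long TR). Magnitude polarity is
    restored by trying every sign-flip split point along the TI axis and
    keeping the lowest-residual fit.
    """
    s = np.asarray(signal, dtype=float).ravel()
    ti = np.asarray(ti_s, dtype=float).ravel()
    if s.size != ti.size or s.size < 4:
        raise ValidationError("need >= 4 (TI, signal) samples")
    if np.ptp(s) <= 1e-12 * max(1.0, np.abs(s).max()):
        raise ValidationError("signal constant over TI; R1 fit is degenerate")

    def model(p, t):
        a, b, r1 = p
        return a * (1.0 - b * np.exp(-t * r1))

    scale = np.abs(s).max()
    best = None
    for split in range(s.size + 1):
        signed = s.copy()
        signed[:split] *= -1.0
        r1_0 = np.log(2.0) / ti[min(split, s.size - 1)] if split > 0 else 1.0 / ti.mean()
        p0 = (scale, 2.0, max(r1_0, 1e-3))
        try:
            fit = least_squares(
                lambda p: model(p, ti) - signed,
                p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(fit.fun**2))
        if best is None or rss < best[0]:
            best = (rss, fit.x, split)
    if best is None:
        raise ValidationError("inversion-recovery fit failed for every polarity split")
    rss, (a, b, r1), split = best
    if rss > 0.5 * np.sum(s**2) and b < 1e-3:
        raise ValidationError("no inversion recovery detectable; fit degenerate")
    return RelaxFitResult(
        rate=float(r1),
        amplitude=float(a),
        rss=rss,
        n_points=s.size,
        extras={"inversion_efficiency": float(b), "polarity_split": split},
    )


def fit_r2_se(signal, te_s) -> RelaxFitResult:
    """R2 from multi-echo spin-echo magnitudes by ordinary least squares on
    the log signal. Non-positive samples are dropped with a warning; a
    negative slope estimate is clipped to R2 = 0 and flagged."""
    s = np.asarray(signal, dtype=float).ravel()
    te = np.asarray(te_s, dtype=float).ravel()
    if s.size != te.size or s.size < 2:
        raise ValidationError("need >= 2 (TE, signal) samples")
    keep = s > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} non-positive spin-echo samples", stacklevel=2)
        s, te = s[keep], te[keep]
        if s.size < 2:
            raise ValidationError("fewer than 2 positive samples remain")
    slope, intercept = np.polyfit(te, np.log(s), 1)
    clipped = slope > 0
    r2 = max(-slope, 0.0)
    resid = np.log(s) - (slope * te + intercept)
    return RelaxFitResult(
        rate=float(r2),
        amplitude=float(np.exp(intercept)),
        rss=float(np.sum(resid**2)),
        n_points=s.size,
        extras={"clipped_at_zero": bool(clipped)},
    )


def fit_r2s_pdff_magnitude(
    signal,
    te_s,
    spectrum: FatSpectrum,
    r2s_max: float = 1000.0,
) -> tuple[float, float, float, float]:
    """(R2*, PDFF %, rho_w, rho_f) from a magnitude-only multi-echo decay.

    Minimizes sum(|S_model(TE)| - s(TE))^2 over (rho_w, rho_f, R2*) with the
    analytic modulus of the multi-peak model (phi0 and f_B drop out of the
    magnitude). The water/fat magnitude ambiguity is handled by multi-start
    over PDFF in {5, 50, 95}% with lowest-residual selection; residual ties
    go to the lower-PDFF solution.
    """
    s = np.asarray(signal, dtype=float).ravel()
    te = np.asarray(te_s, dtype=float).ravel()
    if s.size != te.size or s.size < 3:
        raise ValidationError("need >= 3 magnitude samples")
    if np.all(s == 0):
        raise ValidationError("all-zero magnitude signal")
    c = spectrum.fat_modulation(te)

    def model(p):
        rho_w, rho_f, r2s = p
        return np.abs(rho_w + rho_f * c) * np.exp(-r2s * te)

    scale = s.max()
    best = None
    for pdff0 in (0.05, 0.50, 0.95):
        p0 = (scale * (1 - pdff0), scale * pdff0, 50.0)
        fit = least_squares(
            lambda p: model(p) - s,
            p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, r2s_max]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        rss = float(np.sum(fit.fun**2))
        rho_w, rho_f, r2s = fit.x
        tot = rho_w + rho_f
        pdff = 100.0 * rho_f / tot if tot > 0 else 0.0
        cand = (rss, pdff, r2s, rho_w, rho_f)
        if best is None or rss < best[0] * (1 - 1e-9) or (
            abs(rss - best[0]) <= 1e-9 * max(best[0], 1e-30) and pdff < best[1]
        ):
            best = cand
    rss, pdff, r2s, rho_w, rho_f = best
    return float(r2s), float(pdff), float(rho_w), float(rho_f)


def fit_r2s_pdff_voxels(signals: np.ndarray, te_s, spectrum: FatSpectrum) -> np.ndarray:
    """Magnitude R2*/PDFF fit over an (n_voxel, n_echo) stack; returns an
    (n_voxel, 4) array of (R2*, PDFF, rho_w, rho_f)."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    out = np.empty((signals.shape[0], 4))
    for i, s in enumerate(signals):
        out[i] = fit_r2s_pdff_magnitude(s, te_s, spectrum)
    return out


def correct_spectrum_amplitudes(series: PeakAreaSeries, f0_hz: float | None = None) -> FatSpectrum:
    """T2-corrected relative amplitudes from a STEAM echo-time series.

    Each peak's area decay is fit log-linearly and extrapolated to TE = 0;
    the TE = 0 areas are then normalized to relative amplitudes. Peaks with
    non-positive areas are dropped with a warning.
    """
    areas0 = []
    keep = []
    for p in range(series.delta_ppm.size):
        a = series.areas[p]
        if np.any(a <= 0):
            warnings.warn(
                f"peak at {series.delta_ppm[p]:.2f} ppm has non-positive areas; dropped",
                stacklevel=2,
            )
            continue
        slope, intercept = np.polyfit(series.te_s, np.log(a), 1)
        areas0.append(np.exp(intercept))
        keep.append(p)
    if not keep:
        raise ValidationError("no usable peaks after dropping non-positive areas")
    areas0 = np.asarray(areas0)
    kwargs = {} if f0_hz is None else {"f0_hz": f0_hz}
    return FatSpectrum(series.delta_ppm[keep], areas0 / areas0.sum(), **kwargs)
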