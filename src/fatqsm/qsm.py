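"""Phase-to-susceptibility chain: Laplacian (least-squares) phase
unwrapping, multi-echo field combination, V-SHARP background-field removal,
TKD single-orientation dipole inversion, multi-orientation (COSMOS-style)
inversion, and referencing to a zero-point region.

Unit convention: raw fields enter in Hz, local fields and susceptibility
maps are carried in ppb of B0 (chi and relative field share units, so the
dipole inversion is a unitless spectral division).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .core import (
    F0_DEFAULT_HZ,
    ComplexEchoSeries,
    ValidationError,
    VolumeGrid,
    dipole_kernel,
    hz_to_ppb,
)
from .fatwater import FieldMap

__all__ = [
    "LocalFieldMap",
    "SusceptibilityMap",
    "unwrap_phase",
    "unwrap_echo_series",
    "combine_echo_fields",
    "field_from_echoes_uncorrected",
    "sharp_local_field",
    "invert_single",
    "invert_cosmos",
    "invert_cosmos_masked",
    "reference_to_region",
]


@dataclass
class LocalFieldMap:
    """Background-free field perturbation (ppb) inside an eroded mask."""

    values: VolumeGrid
    eroded_mask: np.ndarray
    kernel_radii_mm: tuple
    cutoff_mm: float
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.values.unit != "ppb":
            raise ValidationError("local field must carry unit ppb")

    @property
    def mean_inside(self) -> float:
        return float(self.values.values[self.eroded_mask].mean())


@dataclass
class SusceptibilityMap:
    """chi map in ppb with its reconstruction provenance."""

    values: VolumeGrid
    method: str  # {"single_orientation", "cosmos"}
    fat_corrected: bool = True
    reference_label: int | None = None


# ---------------------------------------------------------------------------
# unwrapping and echo combination
# ---------------------------------------------------------------------------


def _wrap(x):
    return np.mod(x + np.pi, 2 * np.pi) - np.pi


def _poisson_solve_neumann(rho: np.ndarray) -> np.ndarray:
    """Solve the discrete Poisson equation with zero-flux boundaries via
    DCT-II diagonalization; the DC component is set to zero."""
    shape = rho.shape
    rhat = sp_fft.dctn(rho, type=2, norm="ortho")
    eig = np.zeros(shape)
    for ax, n in enumerate(shape):
        lam = 2.0 * np.cos(np.pi * np.arange(n) / n) - 2.0
        eig = eig + lam.reshape([-1 if a == ax else 1 for a in range(3)])
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(eig != 0, rhat / eig, 0.0)
    return sp_fft.idctn(phat, type=2, norm="ortho")


def unwrap_phase(phase: np.ndarray, congruent: bool = True) -> np.ndarray:
    """Least-squares 3D phase unwrapping (DCT Poisson solve).

    The divergence of the wrapped phase gradients is inverted with Neumann
    boundaries, which recovers smooth non-periodic fields (e.g. linear
    ramps) up to a global constant. With ``congruent=True`` the wrapped
    difference to the input is added back so the output equals the input
    modulo 2 pi at every voxel.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.ndim != 3:
        raise ValidationError("phase must be a 3D volume")
    rho = np.zeros_like(phase)
    for ax in range(3):
        d = _wrap(np.diff(phase, axis=ax))
        pad = [(0, 0)] * 3
        pad[ax] = (1, 0)
        dpad = np.pad(d, pad)  # zero-flux boundary
        rho += np.diff(np.pad(dpad, [(0, 1) if a == ax else (0, 0) for a in range(3)]), axis=ax)
    ls = _poisson_solve_neumann(rho)
    # align the undetermined constant by the circular mean of the difference
    # (keeps the congruence wrap far from the +-pi discontinuity)
    ls = ls + np.angle(np.mean(np.exp(1j * (phase - ls))))
    if congruent:
        return ls + _wrap(phase - ls)
    return ls


def unwrap_echo_series(series: ComplexEchoSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Unwrap each echo's phase and anchor its unknown 2-pi offset so the
    median unwrapped phase inside the mask lies within (-pi, pi]."""
    if mask is None:
        mag1 = np.abs(series.data[0])
        mask = mag1 > 0.25 * np.percentile(mag1, 99)
    out = np.empty(series.data.shape, dtype=float)
    for e in range(series.n_echoes):
        u = unwrap_phase(np.angle(series.data[e]))
        med = np.median(u[mask])
        u -= 2 * np.pi * np.round(med / (2 * np.pi))
        out[e] = u
    return out


def combine_echo_fields(
    unwrapped: np.ndarray,
    te_s,
    magnitude: np.ndarray | None = None,
    voxel_mm=(1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> FieldMap:
    """Fat-uncorrected field map (Hz) from per-echo unwrapped phases.

    Per-voxel weighted least-squares line of phase versus 2 pi TE with an
    intercept (absorbing phi0); weights are proportional to TE. Passing the
    per-echo ``magnitude`` adds magnitude^2 SNR weighting, which favors
    early echoes in fast-decaying voxels and thereby changes how the
    residual chemical-shift oscillation aliases into the slope — the
    TE-only default reproduces the expected sign of the fat bias (apparent
    frequency, hence susceptibility, biased low in fatty voxels). A single
    echo falls back to phase/(2 pi TE) with a warning.
    """
    unwrapped = np.asarray(unwrapped, dtype=float)
    te = np.atleast_1d(np.asarray(te_s, dtype=float))
    if unwrapped.shape[0] != te.size:
        raise ValidationError("echo axis of unwrapped phases must match te_s")
    if te.size == 1:
        warnings.warn("single echo: field = phase/(2 pi TE), phi0 not separable", stacklevel=2)
        f = unwrapped[0] / (2 * np.pi * te[0])
    else:
        if magnitude is None:
            w = np.broadcast_to(te[:, None, None, None], unwrapped.shape)
        else:
            w = te[:, None, None, None] * np.asarray(magnitude, dtype=float) ** 2
        t = 2 * np.pi * te[:, None, None, None]
        y = unwrapped
        sw = w.sum(0)
        swt = (w * t).sum(0)
        swtt = (w * t * t).sum(0)
        swy = (w * y).sum(0)
        swty = (w * t * y).sum(0)
        denom = sw * swtt - swt**2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, (sw * swty - swt * swy) / np.where(denom > 0, denom, 1.0), 0.0)
    grid = VolumeGrid(f, voxel_mm, "Hz", mask)
    return FieldMap(values=grid, corrected="uncorrected")


def field_from_echoes_uncorrected(
    series: ComplexEchoSeries, mask: np.ndarray | None = None
) -> FieldMap:
    """Convenience: unwrap all echoes of a complex series and combine them
    into the fat-uncorrected field map."""
    if mask is None:
        mag1 = np.abs(series.data[0])
        mask = mag1 > 0.25 * np.percentile(mag1, 99)
    unwrapped = unwrap_echo_series(series, mask)
    return combine_echo_fields(unwrapped, series.acq.te_s, None, series.acq.voxel_mm, mask)


# ---------------------------------------------------------------------------
# SHARP background removal
# ---------------------------------------------------------------------------


def _wrapped_distance_mm(shape, voxel_mm):
    coords = []
    for n, d in zip(shape, voxel_mm):
        idx = (np.arange(n) + n // 2) % n - n // 2
        coords.append(idx * d)
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    return np.sqrt(x**2 + y**2 + z**2)


def _smv_kernel_ft(shape, voxel_mm, radius_mm, antialias=True):
    """FFT of a normalized spherical-mean-value kernel centered at index 0."""
    d = _wrapped_distance_mm(shape, voxel_mm)
    ref = float(np.min(voxel_mm))
    if antialias:
        k = np.clip((radius_mm + 0.5 * ref - d) / ref, 0.0, 1.0)
    else:
        k = (d <= radius_mm).astype(float)
    total = k.sum()
    if total == 0:
        raise ValidationError(f"SMV radius {radius_mm} mm resolves no voxels")
    return np.fft.fftn(k / total)


def sharp_local_field(
    fieldmap: FieldMap | VolumeGrid,
    mask: np.ndarray | None = None,
    radii_vox=tuple(range(1, 11)),
    cutoff_mm: float = 0.02,
    f0_hz: float = F0_DEFAULT_HZ,
    b0_dir=(0.0, 0.0, 1.0),
) -> LocalFieldMap:
    """Variable-kernel SHARP background-field removal.

    Every voxel is high-pass filtered with the largest spherical-mean-value
    kernel whose support stays inside the mask (radii given in voxels of the
    smallest voxel edge); the combined map is deconvolved by the
    (delta - SMV) operator of the largest radius. The deconvolution is
    regularized at the high-pass cutoff: the inverse-filter gain is capped
    at its value at |k| = cutoff, so frequencies below the cutoff are passed
    at bounded gain instead of amplified without limit (k = 0 stays zero).
    The output mask is the input mask eroded by the smallest radius and the
    local field is in ppb.
    """
    if isinstance(fieldmap, FieldMap):
        grid = fieldmap.values
    else:
        grid = fieldmap
    if grid.unit == "Hz":
        grid = hz_to_ppb(grid, f0_hz)
    elif grid.unit != "ppb":
        raise ValidationError("field must be in Hz or ppb")
    if mask is None:
        mask = grid.mask
    mask = np.asarray(mask, dtype=bool)
    voxel = grid.voxel_mm
    ref = float(np.min(voxel))
    radii_mm = sorted(float(r) * ref for r in radii_vox)
    if not radii_mm or radii_mm[0] <= 0:
        raise ValidationError("kernel radii must be positive")

    maskf = mask.astype(float)
    maskf_ft = np.fft.fftn(maskf)
    fieldv = np.where(mask, grid.values, 0.0)
    field_ft = np.fft.fftn(fieldv)

    # largest usable radius per voxel
    best_radius = np.zeros(mask.shape)
    filtered = np.zeros(mask.shape)
    smv_ft_by_r = {}
    for r_mm in radii_mm:
        smv_ft = _smv_kernel_ft(mask.shape, voxel, r_mm)
        smv_ft_by_r[r_mm] = smv_ft
        inside = np.fft.ifftn(maskf_ft * smv_ft).real > 1.0 - 1e-6
        inside &= mask
        hp = fieldv - np.fft.ifftn(field_ft * smv_ft).real
        filtered = np.where(inside, hp, filtered)
        best_radius = np.where(inside, r_mm, best_radius)
    eroded = best_radius >= radii_mm[0]
    if not eroded.any():
        raise ValidationError("mask too thin: smallest SMV kernel fits nowhere")

    # deconvolve with the largest-radius (delta - SMV) operator, gain-capped
    # at the filter's response at the cutoff frequency
    r_dec = radii_mm[-1] if (best_radius == radii_mm[-1]).any() else float(best_radius.max())
    c = np.real(1.0 - smv_ft_by_r[r_dec])
    xcut = 2 * np.pi * cutoff_mm * r_dec
    c_cut = 1.0 - 3.0 * (np.sin(xcut) - xcut * np.cos(xcut)) / xcut**3
    c_cut = max(abs(c_cut), 1e-3)
    inv_c = np.sign(c) / np.maximum(np.abs(c), c_cut)
    inv_c[0, 0, 0] = 0.0  # mean left to referencing
    local = np.fft.ifftn(np.fft.fftn(np.where(eroded, filtered, 0.0)) * inv_c).real
    local = np.where(eroded, local, 0.0)

    return LocalFieldMap(
        values=VolumeGrid(local, voxel, "ppb", eroded),
        eroded_mask=eroded,
        kernel_radii_mm=tuple(radii_mm),
        cutoff_mm=float(cutoff_mm),
        b0_dir=np.asarray(b0_dir, dtype=float),
    )


# ---------------------------------------------------------------------------
# dipole inversion
# ---------------------------------------------------------------------------


def invert_single(
    local: LocalFieldMap,
    kernel: np.ndarray | None = None,
    delta: float = 0.2,
    fat_corrected: bool = True,
) -> SusceptibilityMap:
    """Thresholded k-space division (TKD).

    chi(k) = B(k)/D(k) where |D| >= delta; where |D| < delta the division is
    clamped to sign(D) * B(k)/delta (zero on the exact cone D = 0).
    """
    if not 0 < delta < 2.0 / 3.0:
        raise ValidationError("TKD threshold must lie in (0, 2/3)")
    grid = local.values
    if kernel is None:
        kernel = dipole_kernel(grid.shape, grid.voxel_mm, local.b0_dir)
    bk = np.fft.fftn(grid.values)
    inv = np.where(np.abs(kernel) >= delta, 1.0 / np.where(kernel == 0, 1.0, kernel), np.sign(kernel) / delta)
    chi = np.fft.ifftn(bk * inv).real
    chi = np.where(local.eroded_mask, chi, 0.0)
    return SusceptibilityMap(
        values=VolumeGrid(chi, grid.voxel_mm, "ppb", local.eroded_mask),
        method="single_orientation",
        fat_corrected=fat_corrected,
    )


def invert_cosmos(
    locals_: list[LocalFieldMap],
    b0_dirs=None,
    eps: float = 0.01,
    fat_corrected: bool = True,
) -> SusceptibilityMap:
    """Multi-orientation least-squares dipole inversion.

    Per spatial frequency chi(k) = sum_i D_i B_i / sum_i D_i^2, zeroed where
    sum_i D_i^2 < eps. At least two orientations are required; three or more
    non-coplanar B0 directions condition the whole spectrum.
    """
    if len(locals_) < 2:
        raise ValidationError("multi-orientation inversion needs >= 2 orientations")
    if b0_dirs is None:
        b0_dirs = [lf.b0_dir for lf in locals_]
    if len(b0_dirs) != len(locals_):
        raise ValidationError("one B0 direction per local field is required")
    shape = locals_[0].values.shape
    voxel = locals_[0].values.voxel_mm
    for lf in locals_:
        if lf.values.shape != shape:
            raise ValidationError("all local fields must share a common grid")
    num = np.zeros(shape, dtype=complex)
    den = np.zeros(shape)
    common = np.ones(shape, dtype=bool)
    for lf, b0 in zip(locals_, b0_dirs):
        d = dipole_kernel(shape, voxel, b0)
        num += d * np.fft.fftn(lf.values.values)
        den += d * d
        common &= lf.eroded_mask
    chi = np.fft.ifftn(np.where(den >= eps, num / np.where(den == 0, 1.0, den), 0.0)).real
    chi = np.where(common, chi, 0.0)
    return SusceptibilityMap(
        values=VolumeGrid(chi, voxel, "ppb", common),
        method="cosmos",
        fat_corrected=fat_corrected,
    )


def invert_cosmos_masked(
    locals_: list[LocalFieldMap],
    b0_dirs=None,
    pad_factor: int = 2,
    iters: int = 50,
    tol: float = 1e-7,
    fat_corrected: bool = True,
) -> SusceptibilityMap:
    """Multi-orientation dipole inversion as masked least squares.

    The per-k division assumes the field is observed everywhere; with MR
    data the field exists only inside the object, and sources near the
    boundary lose their external dipole lobes, biasing the division low.
    This variant solves

        min_chi  sum_i || M (d_i * chi - b_i) ||^2,  supp(chi) in M,

    by conjugate gradients on the normal equations, with the convolutions
    evaluated on a zero-padded grid to avoid periodic wrap-around. The
    data misfit is only evaluated where the field was measured, so
    truncated lobes no longer penalize boundary-near sources.
    """
    if len(locals_) < 2:
        raise ValidationError("multi-orientation inversion needs >= 2 orientations")
    if b0_dirs is None:
        b0_dirs = [lf.b0_dir for lf in locals_]
    shape = locals_[0].values.shape
    voxel = locals_[0].values.voxel_mm
    pshape = tuple(int(np.ceil(s * pad_factor)) for s in shape)
    sl = tuple(slice(0, s) for s in shape)
    # real-input FFTs: keep only the non-negative last-axis frequencies
    kernels = [
        dipole_kernel(pshape, voxel, b0)[..., : pshape[2] // 2 + 1] for b0 in b0_dirs
    ]
    masks = [lf.eroded_mask for lf in locals_]
    support = np.zeros(shape, dtype=bool)
    for m in masks:
        support |= m

    def conv(x, d):
        xp = np.zeros(pshape)
        xp[sl] = x
        return np.fft.irfftn(np.fft.rfftn(xp) * d, s=pshape, axes=(0, 1, 2))[sl]

    def normal_op(x):
        out = np.zeros(shape)
        for d, m in zip(kernels, masks):
            out += conv(np.where(m, conv(x, d), 0.0), d)
        return np.where(support, out, 0.0)

    rhs = np.zeros(shape)
    for lf, d, m in zip(locals_, kernels, masks):
        rhs += conv(np.where(m, lf.values.values, 0.0), d)
    rhs = np.where(support, rhs, 0.0)

    x = np.zeros(shape)
    r = rhs.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rs0 = rs
    for _ in range(iters):
        if rs <= tol * rs0:
            break
        ap = normal_op(p)
        alpha = rs / float(np.vdot(p, ap).real)
        x += alpha * p
        r -= alpha * ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    return SusceptibilityMap(
        values=VolumeGrid(np.where(support, x, 0.0), voxel, "ppb", support),
        method="cosmos",
        fat_corrected=fat_corrected,
    )


def reference_to_region(
    smap: SusceptibilityMap, labels: np.ndarray, ref_label: int
) -> SusceptibilityMap:
    """Shift the map so the reference region's mean susceptibility is zero.

    Idempotent; offsets added before referencing are removed exactly.
    """
    labels = np.asarray(labels)
    grid = smap.values
    sel = (labels == ref_label) & grid.mask
    if not sel.any():
        raise ValidationError(f"reference region {ref_label} is empty inside the mask")
    shifted = np.where(grid.mask, grid.values - grid.values[sel].mean(), 0.0)
    return SusceptibilityMap(
        values=grid.with_values(shifted),
        method=smap.method,
        fat_corrected=smap.fat_corrected,
        reference_label=int(ref_label),
    )
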