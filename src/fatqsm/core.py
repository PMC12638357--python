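"""Shared physics: multi-peak GRE signal model, dipole kernel, forward field.

The complex gradient-echo signal of a voxel containing water and fat is

    S(t) = (rho_w + rho_f * sum_p alpha_p exp(i 2 pi f_p t))
           * exp(i (phi0 + 2 pi f_B t)) * exp(-R2* t)

where f_p are the lipid resonance offsets relative to water (negative for the
aliphatic peaks, i.e. upfield of water), alpha_p their relative amplitudes
(sum alpha_p = 1), f_B the susceptibility/shim-induced frequency shift and
R2* the effective transverse relaxation rate.

The field perturbation of a susceptibility distribution chi(r) is the
convolution with the unit dipole response, evaluated here as a multiplication
in the spatial-frequency domain with

    D(k) = 1/3 - (k . b0_hat)^2 / |k|^2 ,   D(0) := 0

(Lorentz-sphere convention: the interior field of a uniform sphere vanishes).
Field maps are carried in ppb of B0 internally; Hz is a view via the scanner
frequency f0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "F0_DEFAULT_HZ",
    "FatSpectrum",
    "AcquisitionParams",
    "VolumeGrid",
    "ComplexEchoSeries",
    "gre_signal",
    "dipole_kernel",
    "forward_field_ppb",
    "ppb_to_hz",
    "hz_to_ppb",
    "tilted_b0_dir",
]

#: 3 T scanner frequency used throughout (Hz).
F0_DEFAULT_HZ = 123_195_000.0

_VALID_UNITS = ("ppb", "Hz", "s^-1", "%", "dimensionless")


class ValidationError(ValueError):
    """Raised when a physical precondition on inputs is violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak lipid spectrum: chemical shifts (ppm relative to water,
    negative = upfield/aliphatic) and normalized relative amplitudes."""

    delta_ppm: np.ndarray
    alpha: np.ndarray
    f0_hz: float = F0_DEFAULT_HZ

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_ppm", np.atleast_1d(np.asarray(self.delta_ppm, dtype=float)))
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        if self.delta_ppm.shape != self.alpha.shape or self.delta_ppm.ndim != 1:
            raise ValidationError("delta_ppm and alpha must be 1D arrays of equal length")
        if np.any(self.alpha < 0):
            raise ValidationError("relative amplitudes must be non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"relative amplitudes must sum to 1 (got {self.alpha.sum():.12g})"
            )
        if self.f0_hz <= 0:
            raise ValidationError("scanner frequency must be positive")

    @property
    def f_hz(self) -> np.ndarray:
        """Lipid peak frequency offsets in Hz at the scanner frequency."""
        return self.delta_ppm * self.f0_hz * 1e-6

    @property
    def n_peaks(self) -> int:
        return self.delta_ppm.size

    @property
    def peaks(self) -> list[tuple[float, float, float]]:
        """(delta_ppm, f_hz, alpha) triples."""
        return list(zip(self.delta_ppm.tolist(), self.f_hz.tolist(), self.alpha.tolist()))

    def fat_modulation(self, t_s) -> np.ndarray:
        """Complex fat dephasing factor c(t) = sum_p alpha_p exp(i 2 pi f_p t).

        Broadcasts over an arbitrary-shaped echo-time array; |c(0)| = 1.
        """
        t = np.asarray(t_s, dtype=float)
        phase = 2j * np.pi * self.f_hz * t[..., None]
        return np.sum(self.alpha * np.exp(phase), axis=-1)

    @classmethod
    def single_peak(cls, delta_ppm: float = -3.4, f0_hz: float = F0_DEFAULT_HZ) -> "FatSpectrum":
        """One-peak spectrum at the dominant methylene resonance."""
        return cls(np.array([delta_ppm]), np.array([1.0]), f0_hz)

    @classmethod
    def default_liver(cls, f0_hz: float = F0_DEFAULT_HZ) -> "FatSpectrum":
        """Standard six-peak liver/oil triglyceride spectrum.

        Chemical shifts relative to water and amplitudes follow the widely
        used six-peak condensation of the in-vivo liver lipid spectrum
        (dominant methylene at -3.40 ppm). Fully overridable via JSON config.
        """
        delta = np.array([-3.80, -3.40, -2.60, -1.94, -0.39, 0.60])
        alpha = np.array([0.087, 0.693, 0.128, 0.004, 0.039, 0.048])
        return cls(delta, alpha / alpha.sum(), f0_hz)

    @classmethod
    def from_config(cls, cfg: dict) -> "FatSpectrum":
        f0 = float(cfg.get("f0_mhz", F0_DEFAULT_HZ / 1e6)) * 1e6
        delta = np.array([p["delta_ppm"] for p in cfg["peaks"]], dtype=float)
        alpha = np.array([p["alpha"] for p in cfg["peaks"]], dtype=float)
        return cls(delta, alpha, f0)

    def to_config(self) -> dict:
        return {
            "f0_mhz": self.f0_hz / 1e6,
            "peaks": [
                {"delta_ppm": d, "alpha": a}
                for d, a in zip(self.delta_ppm.tolist(), self.alpha.tolist())
            ],
        }


@dataclass(frozen=True)
class AcquisitionParams:
    """Echo times, scanner frequency, B0 direction and voxel size."""

    te_s: np.ndarray
    f0_hz: float = F0_DEFAULT_HZ
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    voxel_mm: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0]))

    def __post_init__(self) -> None:
        te = np.atleast_1d(np.asarray(self.te_s, dtype=float))
        if te.ndim != 1 or np.any(np.diff(te) <= 0):
            raise ValidationError("echo times must be strictly increasing")
        b0 = np.asarray(self.b0_dir, dtype=float)
        if b0.shape != (3,) or abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            raise ValidationError("b0_dir must be a unit 3-vector")
        vox = np.asarray(self.voxel_mm, dtype=float)
        if vox.shape != (3,) or np.any(vox <= 0):
            raise ValidationError("voxel_mm must be a positive 3-vector")
        object.__setattr__(self, "te_s", te)
        object.__setattr__(self, "b0_dir", b0)
        object.__setattr__(self, "voxel_mm", vox)

    @property
    def n_echoes(self) -> int:
        return self.te_s.size

    @classmethod
    def gre_protocol(
        cls,
        n_echoes: int = 6,
        te1_ms: float = 1.17,
        dte_ms: float = 1.71,
        f0_hz: float = F0_DEFAULT_HZ,
        b0_dir=(0.0, 0.0, 1.0),
        voxel_mm=(1.0, 1.0, 1.0),
    ) -> "AcquisitionParams":
        """Six-echo 3 T GRE protocol (TE1 = 1.17 ms, dTE = 1.71 ms)."""
        te = (te1_ms + dte_ms * np.arange(n_echoes)) * 1e-3
        return cls(te, f0_hz, np.asarray(b0_dir, float), np.asarray(voxel_mm, float))

    def with_b0_dir(self, b0_dir) -> "AcquisitionParams":
        return replace(self, b0_dir=np.asarray(b0_dir, dtype=float))


@dataclass
class VolumeGrid:
    """3D scalar field with voxel size (mm), unit tag and mask."""

    values: np.ndarray
    voxel_mm: np.ndarray
    unit: str = "dimensionless"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be a 3D array")
        self.voxel_mm = np.broadcast_to(np.asarray(self.voxel_mm, dtype=float), (3,)).copy()
        if np.any(self.voxel_mm <= 0):
            raise ValidationError("voxel_mm must be positive")
        if self.unit not in _VALID_UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}; expected one of {_VALID_UNITS}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VolumeGrid":
        return VolumeGrid(values, self.voxel_mm, unit or self.unit, self.mask.copy())


@dataclass
class ComplexEchoSeries:
    """4D complex multi-echo data, echo axis first, plus acquisition params."""

    data: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(complex)
        if self.data.ndim != 4:
            raise ValidationError("data must be 4D (echo, x, y, z)")
        if self.data.shape[0] != self.acq.n_echoes:
            raise ValidationError(
                f"{self.data.shape[0]} echo volumes but {self.acq.n_echoes} echo times"
            )

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def gre_signal(rho_w, rho_f, fb_hz, r2s, phi0, spectrum: FatSpectrum, t_s):
    """Evaluate the multi-peak water/fat GRE signal model.

    All parameter arguments broadcast; ``t_s`` may be scalar or an array of
    echo times (result broadcasts accordingly).
    """
    rho_w = np.asarray(rho_w, dtype=float)
    rho_f = np.asarray(rho_f, dtype=float)
    if np.any(rho_w < 0) or np.any(rho_f < 0):
        raise ValidationError("signal amplitudes must be non-negative")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("echo times must be non-negative")
    fat = spectrum.fat_modulation(t)
    fb_hz = np.asarray(fb_hz, dtype=float)
    r2s = np.asarray(r2s, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    return (rho_w + rho_f * fat) * np.exp(1j * (phi0 + 2 * np.pi * fb_hz * t)) * np.exp(-r2s * t)


def dipole_kernel(shape, voxel_mm, b0_dir) -> np.ndarray:
    """k-space unit dipole response D(k) = 1/3 - (k.b0_hat)^2/|k|^2, D(0)=0.

    Returned on the unshifted FFT grid matching ``np.fft.fftn`` of a volume
    with the given shape and voxel size.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValidationError("shape must be three ints, all >= 2")
    b0 = np.asarray(b0_dir, dtype=float)
    nrm = np.linalg.norm(b0)
    if nrm < 1e-12:
        raise ValidationError("b0_dir must have non-zero length")
    b0 = b0 / nrm
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    ks = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, voxel_mm)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[0, 0, 0] = 0.0  # undetermined mean; absolute zero-point set by referencing
    return d


def forward_field_ppb(
    chi: VolumeGrid,
    kernel: np.ndarray | None = None,
    b0_dir=(0.0, 0.0, 1.0),
    pad_factor: int = 2,
    demean: bool = True,
) -> VolumeGrid:
    """Relative field perturbation B~/B0 (ppb) induced by chi (ppb).

    Computed as chi * D(k) in the spatial-frequency domain on a grid
    zero-padded by ``pad_factor`` to suppress periodic wrap-around. If a
    precomputed ``kernel`` is supplied it must match the padded shape. The
    output mean over the grid is removed (the k=0 component of the dipole
    response is undetermined; the zero point is set later by referencing).
    """
    if chi.unit != "ppb":
        raise ValidationError(f"chi must be tagged ppb, got {chi.unit!r}")
    if not np.all(np.isfinite(chi.values)):
        raise ValidationError("chi must be finite")
    shape = chi.shape
    pshape = tuple(int(np.ceil(s * pad_factor)) for s in shape)
    if kernel is None:
        kernel = dipole_kernel(pshape, chi.voxel_mm, b0_dir)
    elif kernel.shape != pshape:
        raise ValidationError(
            f"kernel shape {kernel.shape} does not match padded shape {pshape}"
        )
    padded = np.zeros(pshape)
    padded[: shape[0], : shape[1], : shape[2]] = chi.values
    fieldp = np.fft.ifftn(np.fft.fftn(padded) * kernel).real
    out = fieldp[: shape[0], : shape[1], : shape[2]].copy()
    if demean:
        out -= out.mean()
    return chi.with_values(out, unit="ppb")


def ppb_to_hz(field_ppb: VolumeGrid, f0_hz: float = F0_DEFAULT_HZ) -> VolumeGrid:
    """Convert a relative field map (ppb of B0) to frequency offsets (Hz)."""
    if field_ppb.unit != "ppb":
        raise ValidationError(f"expected unit ppb, got {field_ppb.unit!r}")
    return field_ppb.with_values(field_ppb.values * f0_hz * 1e-9, unit="Hz")


def hz_to_ppb(field_hz: VolumeGrid, f0_hz: float = F0_DEFAULT_HZ) -> VolumeGrid:
    """Convert a frequency-offset map (Hz) to ppb of B0."""
    if field_hz.unit != "Hz":
        raise ValidationError(f"expected unit Hz, got {field_hz.unit!r}")
    return field_hz.with_values(field_hz.values / f0_hz * 1e9, unit="ppb")


def tilted_b0_dir(plane: str, angle_deg: float) -> np.ndarray:
    """B0 direction after tilting the magnet axis by ``angle_deg`` within a
    coordinate plane ('y-z' or 'x-z'); 0 degrees is the +z axis.

    Rotating the B0 direction while keeping the object fixed is equivalent to
    the physical tilt of the object in the magnet, which avoids any need for
    image registration of multi-orientation data.
    """
    a = np.deg2rad(angle_deg)
    if plane == "y-z":
        return np.array([0.0, np.sin(a), np.cos(a)])
    if plane == "x-z":
        return np.array([np.sin(a), 0.0, np.cos(a)])
    raise ValidationError(f"unknown tilt plane {plane!r}; expected 'y-z' or 'x-z'")


def load_acquisition_config(path) -> tuple[FatSpectrum, AcquisitionParams]:
    """Read a JSON config with keys peaks[], te_ms[], f0_mhz, b0_dir, voxel_mm."""
    cfg = json.loads(Path(path).read_text())
    spectrum = FatSpectrum.from_config(cfg)
    acq = AcquisitionParams(
        te_s=np.asarray(cfg["te_ms"], dtype=float) * 1e-3,
        f0_hz=float(cfg.get("f0_mhz", F0_DEFAULT_HZ / 1e6)) * 1e6,
        b0_dir=np.asarray(cfg.get("b0_dir", [0.0, 0.0, 1.0]), dtype=float),
        voxel_mm=np.asarray(cfg.get("voxel_mm", [1.0, 1.0, 1.0]), dtype=float),
    )
    return spectrum, acq
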