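"""Unwrapping, echo combination, SHARP, dipole inversion, referencing."""

import numpy as np
import pytest

from fatqsm.core import (
    ValidationError,
    VolumeGrid,
    dipole_kernel,
    forward_field_ppb,
    tilted_b0_dir,
)
from fatqsm.qsm import (
    LocalFieldMap,
    SusceptibilityMap,
    combine_echo_fields,
    invert_cosmos,
    invert_cosmos_masked,
    invert_single,
    reference_to_region,
    sharp_local_field,
    unwrap_phase,
)
from tests.conftest import sphere_grid


def _wrap(x):
    return np.mod(x + np.pi, 2 * np.pi) - np.pi


def make_local(values, mask, b0_dir=(0.0, 0.0, 1.0), vox=1.0):
    return LocalFieldMap(
        values=VolumeGrid(np.where(mask, values, 0.0), vox, "ppb", mask),
        eroded_mask=mask,
        kernel_radii_mm=(),
        cutoff_mm=0.0,
        b0_dir=np.asarray(b0_dir, float),
    )


class TestUnwrap:
    def test_smooth_field_passthrough(self):
        rng = np.random.default_rng(0)
        base = np.cumsum(rng.normal(size=24)) * 0.01
        smooth = base[:, None, None] * np.ones((1, 24, 24))
        out = unwrap_phase(smooth)
        out -= np.median(out - smooth)
        np.testing.assert_allclose(out, smooth, atol=1e-9)

    def test_wrapped_ramp_recovered(self):
        n = 48
        ramp = np.linspace(0, 6 * np.pi, n)[:, None, None] * np.ones((1, n, n))
        out = unwrap_phase(_wrap(ramp))
        dev = out - ramp
        dev -= np.round(np.median(dev) / (2 * np.pi)) * 2 * np.pi
        dev -= np.median(dev)
        assert np.abs(dev[4:-4, 4:-4, 4:-4]).max() < 0.1

    def test_congruent_with_input(self):
        rng = np.random.default_rng(1)
        phase = _wrap(rng.normal(scale=2.0, size=(16, 16, 16)))
        out = unwrap_phase(phase)
        assert np.abs(_wrap(out - phase)).max() < 1e-9

    def test_constant_stays_constant(self):
        out = unwrap_phase(np.full((12, 12, 12), 0.7))
        np.testing.assert_allclose(out, 0.7, atol=1e-9)


class TestCombineEchoes:
    def test_exact_linear_phase(self):
        te = np.array([1.17e-3, 2.88e-3, 4.59e-3])
        phases = 2 * np.pi * 10.0 * te[:, None, None, None] * np.ones((1, 8, 8, 8))
        fm = combine_echo_fields(phases, te)
        np.testing.assert_allclose(fm.values.values, 10.0, atol=1e-9)
        assert fm.corrected == "uncorrected"

    def test_phi0_absorbed_by_intercept(self):
        te = np.array([1.17e-3, 2.88e-3, 4.59e-3, 6.3e-3])
        phases = (
            0.8 + 2 * np.pi * -25.0 * te[:, None, None, None] * np.ones((1, 4, 4, 4))
        )
        fm = combine_echo_fields(phases, te)
        np.testing.assert_allclose(fm.values.values, -25.0, atol=1e-9)

    def test_single_echo_fallback_warns(self):
        te = np.array([2e-3])
        phases = np.full((1, 4, 4, 4), 2 * np.pi * 5.0 * 2e-3)
        with pytest.warns(UserWarning, match="single echo"):
            fm = combine_echo_fields(phases, te)
        np.testing.assert_allclose(fm.values.values, 5.0, atol=1e-12)


class TestSharp:
    def test_harmonic_field_suppressed(self):
        # field of a source OUTSIDE the mask is harmonic inside it
        n = 64
        ax, x, y, z, r = sphere_grid(n)
        mask = r <= 20
        src = np.where(np.sqrt((x - 28.0) ** 2 + y**2 + z**2) <= 4, 2000.0, 0.0)
        fld = forward_field_ppb(VolumeGrid(src, 1.0, "ppb"))
        lf = sharp_local_field(VolumeGrid(fld.values, 1.0, "ppb"), mask)
        em = lf.eroded_mask
        ratio = np.sqrt(np.mean(lf.values.values[em] ** 2)) / np.sqrt(
            np.mean(fld.values[em] ** 2)
        )
        assert ratio < 0.01

    def test_internal_source_preserved(self):
        n = 64
        ax, x, y, z, r = sphere_grid(n)
        mask = r <= 20
        src = np.where(r <= 6, 500.0, 0.0)
        fld = forward_field_ppb(VolumeGrid(src, 1.0, "ppb"))
        lf = sharp_local_field(VolumeGrid(fld.values, 1.0, "ppb"), mask)
        em = lf.eroded_mask
        a = fld.values[em] - fld.values[em].mean()
        b = lf.values.values[em] - lf.values.values[em].mean()
        assert np.corrcoef(a, b)[0, 1] > 0.95

    def test_zero_in_zero_out(self):
        n = 32
        ax, x, y, z, r = sphere_grid(n)
        mask = r <= 12
        lf = sharp_local_field(VolumeGrid(np.zeros((n, n, n)), 1.0, "ppb"), mask)
        assert np.abs(lf.values.values).max() < 1e-12

    def test_mask_too_thin_rejected(self):
        mask = np.zeros((24, 24, 24), bool)
        mask[12, :, :] = True  # a single plane cannot host any SMV sphere
        with pytest.raises(ValidationError):
            sharp_local_field(VolumeGrid(np.zeros((24, 24, 24)), 1.0, "ppb"), mask)

    def test_output_masked_and_unit(self):
        n = 48
        ax, x, y, z, r = sphere_grid(n)
        mask = r <= 18
        fld = forward_field_ppb(VolumeGrid(np.where(r <= 5, 300.0, 0.0), 1.0, "ppb"))
        lf = sharp_local_field(VolumeGrid(fld.values, 1.0, "ppb"), mask)
        assert lf.values.unit == "ppb"
        assert np.all(lf.values.values[~lf.eroded_mask] == 0.0)
        assert lf.eroded_mask.sum() < mask.sum()


class TestInvertSingle:
    def test_round_trip_on_well_conditioned_spectrum(self):
        # chi built only from frequencies with |D| >= delta: exact recovery
        n = 32
        rng = np.random.default_rng(7)
        kernel = dipole_kernel((n, n, n), (1, 1, 1), (0, 0, 1))
        raw = rng.normal(size=(n, n, n))
        chi_hat = np.fft.fftn(raw) * (np.abs(kernel) >= 0.25)
        chi = np.fft.ifftn(chi_hat).real * 100
        mask = np.ones((n, n, n), bool)
        field = np.fft.ifftn(np.fft.fftn(chi) * kernel).real
        sm = invert_single(make_local(field, mask), delta=0.2)
        rel = np.linalg.norm(sm.values.values - chi) / np.linalg.norm(chi)
        assert rel < 1e-9

    def test_sphere_underestimation_bounded(self):
        # clamped TKD at delta=0.2 underestimates a uniform sphere by ~20%
        n = 64
        ax, x, y, z, r = sphere_grid(n)
        chi = np.where(r <= 8, 300.0, 0.0)
        field = forward_field_ppb(VolumeGrid(chi, 1.0, "ppb")).values
        sm = invert_single(make_local(field, np.ones((n, n, n), bool)), delta=0.2)
        voi = sm.values.values[r <= 6].mean()
        assert 0.70 * 300 < voi < 300

    def test_zero_field_zero_map(self):
        sm = invert_single(make_local(np.zeros((16, 16, 16)), np.ones((16, 16, 16), bool)))
        assert np.all(sm.values.values == 0.0)
        assert sm.method == "single_orientation"

    def test_delta_range_enforced(self):
        lf = make_local(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool))
        with pytest.raises(ValidationError):
            invert_single(lf, delta=0.8)


class TestInvertCosmos:
    def _fields(self, chi, dirs, mask):
        out = []
        for d in dirs:
            f = forward_field_ppb(VolumeGrid(chi, 1.0, "ppb"), b0_dir=d, pad_factor=1)
            out.append(make_local(f.values, mask, b0_dir=d))
        return out

    def test_orthogonal_identity_off_singular_set(self):
        # with consistent periodic fields, the per-k least squares is exact
        # wherever the summed squared kernels are nonzero
        n = 24
        rng = np.random.default_rng(11)
        dirs = [np.array([0.0, 0, 1]), np.array([0.0, 1, 0]), np.array([1.0, 0, 0])]
        den = sum(dipole_kernel((n, n, n), (1, 1, 1), d) ** 2 for d in dirs)
        chi_hat = np.fft.fftn(rng.normal(size=(n, n, n))) * (den >= 0.01)
        chi = np.fft.ifftn(chi_hat).real * 50
        mask = np.ones((n, n, n), bool)
        cm = invert_cosmos(self._fields(chi, dirs, mask), eps=0.01)
        rel = np.linalg.norm(cm.values.values - chi) / np.linalg.norm(chi)
        assert rel < 1e-9
        assert cm.method == "cosmos"

    def test_five_orientation_scheme_near_exact(self):
        # the neutral + four +-60 deg tilts have no common kernel zeros:
        # a sphere is recovered to within a percent
        n = 48
        ax, x, y, z, r = sphere_grid(n)
        chi = np.where(r <= 8, 300.0, 0.0)
        dirs = [np.array([0.0, 0, 1])] + [
            tilted_b0_dir(p, a) for p, a in (("y-z", 60), ("y-z", -60), ("x-z", 60), ("x-z", -60))
        ]
        mask = r <= 22
        lfs = []
        for d in dirs:
            f = forward_field_ppb(VolumeGrid(chi, 1.0, "ppb"), b0_dir=d)
            lfs.append(make_local(f.values, mask, b0_dir=d))
        cm = invert_cosmos(lfs)
        v = cm.values.values
        contrast = v[r <= 6].mean() - v[(r > 14) & mask].mean()
        assert contrast == pytest.approx(300.0, rel=0.01)

    def test_repeated_orientation_equals_single_division(self):
        n = 16
        rng = np.random.default_rng(3)
        kernel = dipole_kernel((n, n, n), (1, 1, 1), (0, 0, 1))
        chi_hat = np.fft.fftn(rng.normal(size=(n, n, n))) * (np.abs(kernel) >= 0.15)
        chi = np.fft.ifftn(chi_hat).real * 10
        field = np.fft.ifftn(np.fft.fftn(chi) * kernel).real
        mask = np.ones((n, n, n), bool)
        lf = make_local(field, mask)
        cm = invert_cosmos([lf, lf], eps=1e-4)
        # where |D|^2 is well above eps the result is plain division = chi
        np.testing.assert_allclose(cm.values.values, chi, atol=1e-9 * np.abs(chi).max() + 1e-9)

    def test_too_few_orientations_rejected(self):
        lf = make_local(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool))
        with pytest.raises(ValidationError):
            invert_cosmos([lf])

    def test_masked_lsq_recovers_boundary_near_source(self):
        # a source near the mask boundary loses its external lobes; the
        # masked least-squares inversion still recovers it, the per-k
        # division underestimates it
        n = 48
        ax, x, y, z, r = sphere_grid(n)
        mask = r <= 20
        chi = np.where(np.sqrt((x - 11.0) ** 2 + y**2 + z**2) <= 5, 300.0, 0.0)
        dirs = [np.array([0.0, 0, 1])] + [
            tilted_b0_dir(p, a) for p, a in (("y-z", 60), ("y-z", -60), ("x-z", 60), ("x-z", -60))
        ]
        lfs = []
        for d in dirs:
            f = forward_field_ppb(VolumeGrid(chi, 1.0, "ppb"), b0_dir=d)
            vals = np.where(mask, f.values, 0.0)
            vals[mask] -= vals[mask].mean()
            lfs.append(make_local(vals, mask, b0_dir=d))
        voi = np.sqrt((x - 11.0) ** 2 + y**2 + z**2) <= 5
        masked = invert_cosmos_masked(lfs, iters=40)
        division = invert_cosmos(lfs)

        def contrast(sm):
            v = sm.values.values
            return v[voi].mean() - v[mask & ~voi & (np.sqrt((x - 11.0) ** 2 + y**2 + z**2) > 9)].mean()

        assert contrast(masked) == pytest.approx(300.0, rel=0.02)
        assert abs(contrast(division) - 300.0) > abs(contrast(masked) - 300.0)


class TestReferencing:
    def _map(self, values, mask=None):
        mask = np.ones(values.shape, bool) if mask is None else mask
        return SusceptibilityMap(
            values=VolumeGrid(values, 1.0, "ppb", mask), method="single_orientation"
        )

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 10, 10))
        labels = np.full(vals.shape, 10)
        a = reference_to_region(self._map(vals), labels, 10)
        b = reference_to_region(self._map(vals + 50.0), labels, 10)
        np.testing.assert_allclose(a.values.values, b.values.values, atol=1e-12)

    def test_constant_map_zeroed_and_idempotent(self):
        labels = np.full((6, 6, 6), 10)
        a = reference_to_region(self._map(np.full((6, 6, 6), 3.3)), labels, 10)
        np.testing.assert_allclose(a.values.values, 0.0, atol=1e-12)
        twice = reference_to_region(a, labels, 10)
        np.testing.assert_allclose(twice.values.values, a.values.values, atol=1e-12)
        assert abs(a.values.values[labels == 10].mean()) < 1e-6

    def test_empty_region_rejected(self):
        labels = np.zeros((6, 6, 6), int)
        with pytest.raises(ValidationError):
            reference_to_region(self._map(np.zeros((6, 6, 6))), labels, 10)
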