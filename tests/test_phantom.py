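"""Digital phantom: composition defaults, rasterization, simulated series."""

import numpy as np
import pytest

from fatqsm.core import AcquisitionParams, FatSpectrum, gre_signal
from fatqsm.phantom import (
    BACKGROUND_LABEL,
    InclusionSpec,
    PhantomSpec,
    ValidationError,
    default_phantom_spec,
    rasterize_maps,
    simulate_echoes,
    simulate_ir_series,
    simulate_orientations,
    simulate_se_series,
)


class TestPhantomSpec:
    def test_iron_composition(self):
        spec = default_phantom_spec("iron")
        by_label = {inc.label: inc for inc in spec.inclusions}
        assert by_label[9].fe_mM == 0.26 and by_label[9].fat_pct == 20.0
        assert by_label[1].fe_mM == 0.0 and by_label[1].fat_pct == 4.0
        assert [by_label[i].fe_mM for i in (4, 5, 6)] == [0.13, 0.19, 0.26]
        assert [by_label[i].fat_pct for i in (1, 2, 3)] == [4.0, 10.0, 20.0]

    def test_manganese_composition(self):
        spec = default_phantom_spec("manganese")
        by_label = {inc.label: inc for inc in spec.inclusions}
        assert by_label[6].mn_mM == 4.5 and by_label[6].fe_mM == 0.0
        assert [by_label[i].mn_mM for i in (7, 8, 9)] == [2.5, 3.5, 4.5]

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValidationError):
            default_phantom_spec("gadolinium")

    def test_overlapping_inclusions_rejected(self):
        incs = (
            InclusionSpec(label=1, center_mm=(0, 0, 0)),
            InclusionSpec(label=2, center_mm=(10, 0, 0)),
        )
        with pytest.raises(ValidationError):
            PhantomSpec(inclusions=incs)

    def test_chi_assignment_from_calibration(self):
        spec = default_phantom_spec("iron")
        by_label = {inc.label: inc for inc in spec.inclusions}
        assert spec.chi_ppb(by_label[6]) == pytest.approx(1088 * 0.26)  # 282.9 ppb
        assert spec.chi_ppb(by_label[3]) == pytest.approx(4.83 * 20)
        assert spec.chi_ppb(by_label[9]) == pytest.approx(1088 * 0.26 + 4.83 * 20)


class TestRasterize:
    def test_maps_content(self, small_truth_maps):
        maps = small_truth_maps
        assert maps.chi.values[maps.labels == BACKGROUND_LABEL].max() == 0.0
        assert maps.r2s.values[maps.labels == 9].mean() == pytest.approx(211.3)
        assert maps.pdff.values[maps.labels == 2].mean() == pytest.approx(10.0)
        sel6 = maps.labels == 6
        assert maps.chi.values[sel6].mean() == pytest.approx(1088 * 0.26)

    def test_inclusion_volumes(self):
        spec = default_phantom_spec("iron")
        maps = rasterize_maps(spec, shape=(150, 150, 150), voxel_mm=1.0)
        expected = 4.0 / 3.0 * np.pi * 15.0**3
        for inc in spec.inclusions:
            vol = (maps.labels == inc.label).sum() * 1.0
            assert abs(vol - expected) / expected < 0.10

    def test_unresolvable_inclusion_rejected(self):
        with pytest.raises(ValidationError):
            rasterize_maps(default_phantom_spec("iron"), shape=(16, 16, 16), voxel_mm=9.0)

    def test_deterministic(self):
        a = rasterize_maps(default_phantom_spec("iron"), shape=(32, 32, 32), voxel_mm=4.5)
        b = rasterize_maps(default_phantom_spec("iron"), shape=(32, 32, 32), voxel_mm=4.5)
        np.testing.assert_array_equal(a.chi.values, b.chi.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_optional_air_void(self):
        from dataclasses import replace

        from fatqsm.phantom import AIR_CHI_PPB

        spec = replace(default_phantom_spec("iron"), air_voids=(((0.0, 0.0, 50.0), 5.0),))
        maps = rasterize_maps(spec, shape=(48, 48, 48), voxel_mm=3.0)
        ax = (np.arange(48) - 23.5) * 3.0
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        void = x**2 + y**2 + (z - 50.0) ** 2 <= 25.0
        assert np.all(maps.chi.values[void] == AIR_CHI_PPB)
        assert np.all(maps.labels[void] == 0)  # voids carry no signal
        assert not maps.mask[void].any()

    def test_field_dipole_lobes(self, small_truth_maps):
        # around an iron inclusion: positive lobes along B0, negative lateral
        maps = small_truth_maps
        field = maps.field_ppb((0, 0, 1)).values
        spec = default_phantom_spec("iron")
        inc = {i.label: i for i in spec.inclusions}[6]
        vox = maps.voxel_mm[0]
        c = np.array(maps.labels.shape) / 2 - 0.5 + np.asarray(inc.center_mm) / vox
        ci, cj, ck = np.round(c).astype(int)
        off = int(round((inc.radius_mm + 2 * vox) / vox))
        assert field[ci, cj, ck + off] > 0  # above, along B0
        assert field[ci, cj, ck - off] > 0  # below
        assert field[ci + off, cj, ck] < 0  # lateral
        assert field[ci, cj + off, ck] < 0
        assert abs(field.mean()) < 1e-9


class TestSimulateEchoes:
    def test_voxelwise_matches_scalar_model(self, small_truth_maps, two_peak_spectrum, acq6):
        maps = small_truth_maps
        from fatqsm.core import ppb_to_hz

        series = simulate_echoes(maps, acq6, two_peak_spectrum, snr=None)
        fb = ppb_to_hz(maps.field_ppb(acq6.b0_dir), acq6.f0_hz).values
        idx = tuple(np.argwhere(maps.labels == 7)[0])
        pdff = maps.pdff.values[idx]
        expected = gre_signal(
            1 - pdff / 100,
            pdff / 100,
            fb[idx],
            maps.r2s.values[idx],
            0.0,
            two_peak_spectrum,
            acq6.te_s,
        )
        np.testing.assert_allclose(series.data[(slice(None),) + idx], expected, atol=1e-12)

    def test_constant_magnitude_without_decay(self, two_peak_spectrum, acq6):
        from fatqsm.phantom import GroundTruthMaps
        from fatqsm.core import VolumeGrid

        n = 12
        labels = np.full((n, n, n), BACKGROUND_LABEL, dtype=np.int16)
        zeros = np.zeros((n, n, n))
        mk = lambda v, u: VolumeGrid(v, 2.0, u)
        maps = GroundTruthMaps(
            chi=mk(zeros, "ppb"),
            pdff=mk(zeros, "%"),
            r2s=mk(zeros, "s^-1"),
            r2=mk(zeros, "s^-1"),
            r1=mk(zeros + 1, "s^-1"),
            labels=labels,
        )
        series = simulate_echoes(maps, acq6, two_peak_spectrum, snr=None)
        mags = np.abs(series.data[:, n // 2, n // 2, n // 2])
        np.testing.assert_allclose(mags, 1.0, atol=1e-12)

    def test_seed_reproducibility(self, small_truth_maps, two_peak_spectrum, acq6):
        a = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=50, seed=11)
        b = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=50, seed=11)
        np.testing.assert_array_equal(a.data, b.data)
        c = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=50, seed=12)
        assert not np.array_equal(a.data, c.data)

    def test_noise_level_matches_snr(self, small_truth_maps, two_peak_spectrum, acq6):
        snr = 40.0
        clean = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=None)
        noisy = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=snr, seed=5)
        bg = small_truth_maps.labels == BACKGROUND_LABEL
        sigma_obs = (noisy.data - clean.data).real[0][bg].std()
        sigma_exp = np.abs(clean.data[0][bg]).mean() / snr
        assert abs(sigma_obs / sigma_exp - 1) < 0.05


class TestOrientations:
    def test_counts_and_neutral(self, small_truth_maps, two_peak_spectrum, acq6):
        only = simulate_orientations(small_truth_maps, acq6, two_peak_spectrum, tilts=[], snr=None)
        assert len(only) == 1
        ref = simulate_echoes(small_truth_maps, acq6, two_peak_spectrum, snr=None)
        np.testing.assert_array_equal(only[0].data, ref.data)

    def test_default_scheme_has_five_series(self, small_truth_maps, two_peak_spectrum, acq6):
        series = simulate_orientations(small_truth_maps, acq6, two_peak_spectrum, snr=None)
        assert len(series) == 5
        np.testing.assert_allclose(series[1].acq.b0_dir, [0, np.sin(np.pi / 3), 0.5])

    def test_extreme_tilt_warns(self, small_truth_maps, two_peak_spectrum, acq6):
        with pytest.warns(UserWarning, match="ill-conditioned"):
            simulate_orientations(
                small_truth_maps, acq6, two_peak_spectrum, tilts=[("y-z", 95.0)], snr=None
            )


class TestRelaxSeries:
    def test_ir_null_point_and_recovery(self, small_truth_maps):
        maps = small_truth_maps
        r1_bg = 2.8
        null_ti = np.log(2) / r1_bg
        sig = simulate_ir_series(maps, [0.05, null_ti, 5.0])
        bg = maps.labels == BACKGROUND_LABEL
        assert np.abs(sig[1][bg]).max() < 1e-9  # null point
        assert sig[2][bg].mean() == pytest.approx(1.0, abs=1e-4)  # TI >> T1

    def test_se_closed_form(self, small_truth_maps):
        sig = simulate_se_series(small_truth_maps, [0.1])
        sel = small_truth_maps.labels == 1  # R2 = 15.5
        np.testing.assert_allclose(sig[0][sel], np.exp(-1.55), atol=1e-12)
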