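"""Susceptibility mapping: single-orientation TKD vs multi-orientation
least squares on the digital phantom.

Simulates the neutral orientation plus the four ±60 degree tilts, estimates
fat-corrected field maps, inverts them to susceptibility both ways, and
compares inclusion VOI means with ground truth.
"""

import pandas as pd

from fatqsm.analysis import ols_line, voi_stats
from fatqsm.core import AcquisitionParams, FatSpectrum
from fatqsm.fatwater import estimate_field_fatwater
from fatqsm.phantom import BACKGROUND_LABEL, default_phantom_spec, rasterize_maps, simulate_orientations
from fatqsm.pipeline import local_field_without_background
from fatqsm.qsm import invert_cosmos, invert_cosmos_masked, invert_single, reference_to_region

maps = rasterize_maps(default_phantom_spec("iron"), shape=(64, 64, 64), voxel_mm=3.0)
acq = AcquisitionParams.gre_protocol(voxel_mm=(3.0, 3.0, 3.0))
spectrum = FatSpectrum.default_liver(acq.f0_hz)

series = simulate_orientations(maps, acq, spectrum, snr=100.0, seed=3)
locals_ = []
for s in series:
    fm, _ = estimate_field_fatwater(s, spectrum, mask=maps.mask)
    locals_.append(local_field_without_background(fm, maps.mask, s.acq.b0_dir, acq.f0_hz))

tkd = reference_to_region(invert_single(locals_[0], delta=0.2), maps.labels, BACKGROUND_LABEL)
cos_div = reference_to_region(invert_cosmos(locals_), maps.labels, BACKGROUND_LABEL)
cos_lsq = reference_to_region(invert_cosmos_masked(locals_, iters=40), maps.labels, BACKGROUND_LABEL)

truth = voi_stats(maps.chi, maps.labels).set_index("label")["mean"]
est_tkd = voi_stats(tkd.values, maps.labels).set_index("label")["mean"]
est_div = voi_stats(cos_div.values, maps.labels).set_index("label")["mean"]
est_lsq = voi_stats(cos_lsq.values, maps.labels).set_index("label")["mean"]
print(
    pd.DataFrame(
        {
            "chi_true_ppb": truth.round(1),
            "tkd_ppb": est_tkd.round(1),
            "cosmos_division_ppb": est_div.round(1),
            "cosmos_masked_lsq_ppb": est_lsq.round(1),
        }
    ).to_string()
)

labels = list(range(1, 10))
for name, est in (("division", est_div), ("masked lsq", est_lsq)):
    fit = ols_line([truth[l] for l in labels], [est[l] for l in labels])
    print(f"multi-orientation ({name}) vs truth: slope {fit.slope:.3f}, R^2 {fit.r_squared:.4f}")
print()
print("Single-orientation TKD underestimates (spectral content near the")
print("dipole cone is clamped). The per-k division is nearly exact for")
print("central inclusions but loses the external dipole lobes of")
print("boundary-near ones; the masked least-squares inversion evaluates")
print("the misfit only where field data exist and recovers them all.")
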