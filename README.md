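# fatqsm

Fat-aware quantitative susceptibility mapping (QSM) and relaxometry for
liver-like phantoms, with a fully synthetic "digital twin" of a spherical
fat/iron agar phantom so every stage of the processing chain can be
exercised and validated without any scanner data.

## The problem

Liver iron content is a key clinical quantity, and tissue magnetic
susceptibility χ is an attractive way to measure it: unlike R2*-based
methods, χ is insensitive to how the iron is microscopically distributed.
But abdominal tissue contains fat, and lipid protons resonate at offsets of
up to ~3.4 ppm from water. That chemical shift contaminates the
gradient-echo phase from which field maps — and then susceptibility maps —
are computed, and fat is itself slightly paramagnetic relative to water. A
χ-based iron estimate that ignores fat is therefore biased twice: once by
phase contamination (streaking and wrong field values) and once by fat's own
susceptibility contribution.

`fatqsm` implements the full chain to study this interplay:

* **Signal model** — the multi-peak water/fat gradient-echo signal

  `S(t) = (ρ_W + ρ_F Σ_p α_p e^{i2πf_p t}) e^{i(φ0 + 2πf_B t)} e^{−R2* t}`

  with a configurable lipid spectrum (Σ α_p = 1, f_p the peak offsets at
  f0 = 123.195 MHz).
* **Digital phantom** — a 14 cm sphere with nine 3 cm inclusions: fat only
  (4/10/20 vol%), Fe₃O₄ only (0.13/0.19/0.26 mM) or MnCl₂
  (2.5/3.5/4.5 mM), and iron + 20% fat. Ground-truth χ, PDFF, R1/R2/R2*
  maps; six-echo complex GRE series (TE1 1.17 ms, ΔTE 1.71 ms) in any B0
  orientation; inversion-recovery and spin-echo magnitude series.
* **Water–fat separation** — VARPRO over a discretized field-map grid with
  an ICM-smoothed label field (graph-cut-style objective), yielding the
  fat-corrected field map, PDFF and R2*.
* **Relaxometry** — R1 (inversion recovery with polarity restoration), R2
  (log-linear spin-echo fit), magnitude-only multi-peak R2*/PDFF fit, and
  T2 correction of spectroscopic fat-peak amplitudes.
* **QSM** — least-squares (Laplacian) phase unwrapping, multi-echo field
  combination, V-SHARP background removal
  (`D(k) = 1/3 − (k·b̂0)²/|k|²` dipole kernel), TKD single-orientation
  inversion, multi-orientation inversion (per-k least squares and a masked
  CG variant), referencing to the agar background.
* **Analysis** — VOI statistics, χ-vs-iron / χ-vs-PDFF / χ-vs-R2*
  regressions, and the fat-compensated iron calibration
  `c_Fe(χ, PDFF) = (χ − i_ff − χ_fat(PDFF))/1088 ppb/mM` with
  `χ_fat(PDFF) = 4.83 ppb/% · PDFF − 6.49 ppb`.

## Worked example

```bash
python examples/05_iron_calibration.py
```

```
susceptibility shift: 200 ppb
  fat-free line      -> 0.175 mM iron
  20%-fat line       -> 0.105 mM iron
  (a ~40% reduction: fat itself contributes susceptibility)

  fat-compensated at PDFF    0%: chi_fat =   -6.49 ppb, c_Fe = 0.181 mM
  fat-compensated at PDFF   20%: chi_fat =   90.11 ppb, c_Fe = 0.093 mM
  fat-compensated at PDFF   35%: chi_fat =  162.56 ppb, c_Fe = 0.026 mM
```

The same 200 ppb susceptibility shift means very different iron
concentrations depending on the fat fraction: at 20% fat roughly half of
the naive fat-free estimate, at 35% fat almost nothing — fat accounts for
nearly the entire shift.

A full simulated study (simulate → water–fat → SHARP → dipole inversion →
multi-orientation → VOI reports) is one call:

```python
from fatqsm.pipeline import run_phantom_study
result = run_phantom_study(agent="iron", seed=7, snr=100.0, out_dir="reports/")
print(result.tables["iron_estimates"])
```

It writes `voi_stats.csv`, `regressions.csv`, `iron_estimates.csv` and
`recovery.csv`, byte-identical for a fixed seed. The other scripts in
`examples/` walk through the individual capabilities (signal/dipole model,
phantom ground truth, water–fat separation, single- vs multi-orientation
inversion) at small problem sizes, each printing what the numbers mean.

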