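# ramanclear

Depth- and time-resolved **optical-clearing kinetics from confocal Raman
micro-spectroscopy**, for tissue-biophotonics work on collagenous tissues
(dura mater, sclera, dermis) treated with a clearing agent such as
glycerol.

When a clearing agent is dropped onto tissue, every Raman band recorded
below the surface grows for two entangled reasons: the agent physically
arrives at the probed depth, and the layers above it scatter less, so
more excitation light reaches the focus.  `ramanclear` separates the two,
quantifies the agent's diffusion, and tracks the dehydration that drives
clearing:

1. **Clearing-efficiency correction.**  Collagen is immobile, so the rise
   of a collagen band relative to its untreated value measures the purely
   optical gain, `OC_eff(t) = I_OC(t) / I_0`.  The corrected
   ("reconstructed") glycerol signal is `TRGC = I_gly / OC_eff`, computed
   per collagen reference band (938, 1003, 1247, 1270, 1665 cm⁻¹), and is
   converted to a volume-fraction concentration through a linear
   calibration of the glycerol 485 cm⁻¹ band against known standards.

2. **Diffusion fitting.**  The concentration time series at each depth is
   fitted with the semi-infinite solution of Fick's second law,

   *C(x, t) = C₀ · erfc( x / (2 √(D t)) )*,

   by bounded multi-start least squares, giving the diffusion coefficient
   *D* (cm²/s) and saturation concentration *C₀* (%) per band and depth,
   with per-depth averages.  The closed form is cross-validated against a
   finite-difference solution of the PDE.

3. **Water-state deconvolution.**  The high-wavenumber OH-stretch region
   is decomposed into ten Gaussian lines; the four water lines (tightly
   bound 3005, strongly bound 3277, weakly bound 3458, free 3604 cm⁻¹)
   are normalised to the 2940 cm⁻¹ protein line, and their sum is the
   total water content — a direct readout of clearing-induced
   dehydration.

A fully parameterised synthetic-experiment generator
(`ramanclear.synth`) emulates the measurement design (four depths
50–200 µm, spectra every 30 s from 0–390 s, 15 calibration standards),
so every stage is testable against known ground truth.

## Worked example

Simulate a default experiment, calibrate, and fit the diffusion model:

```sh
$ ramanclear simulate --seed 1 --out demo/data
wrote dataset to demo/data
$ ramanclear calibrate --manifest demo/data/calibration.csv --out demo/cal.json
calibration: slope=1.486, intercept=-0.03818, R^2=0.9995 (n=15)
$ ramanclear fit-diffusion --manifest demo/data/manifest_fp.csv \
      --calibration demo/cal.json --out demo/results
wrote demo/results/table1.csv
$ head -8 demo/results/table1.csv
depth_um,band,D_cm2_s,C0_pct
50.0,938 cm-1,7.4e-06,20.0
50.0,1003 cm-1,7.2e-06,20.0
50.0,1247 cm-1,7.3e-06,20.0
50.0,1270 cm-1,7.8e-06,20.0
50.0,1665 cm-1,7.9e-06,20.0
50.0,Average,7.5e-06,20.0
100.0,938 cm-1,1.4e-05,3.0
```

The calibration line is recovered with R² ≈ 0.9995 (the generative slope
is 1.5 counts per % glycerol).  At 50 µm the saturation concentration C₀
is recovered at 20% exactly and D within the scatter expected at 2%
measurement noise; the same library calls are available directly
(`fit_calibration`, `analyze_fp_experiment`, `fit_diffusion`,
`summarize_depth`) for scripted use.  Water-state kinetics run the same
way:

```sh
ramanclear water-states --manifest demo/data/manifest_hwn.csv --out demo/water
ramanclear report --dir demo/water
```

which tabulates the four water-state ratios per depth and time and a
before/after summary (default "after" time 90 s).

## Layout

| Module | Purpose |
| --- | --- |
| `ramanclear.spectra` | spectrum model, text I/O, baseline/smoothing/PCA preprocessing, band extraction |
| `ramanclear.calibration` | linear 485 cm⁻¹ intensity ↔ concentration calibration |
| `ramanclear.kinetics` | OC_eff, TRGC, and the per-depth clearing-kinetics pipeline |
| `ramanclear.diffusion` | erfc model, finite-difference oracle, (D, C₀) fitting, per-depth summary |
| `ramanclear.water` | ten-Gaussian OH-stretch deconvolution and water-state ratios |
| `ramanclear.synth` | synthetic experiment generator (ground-truth round trips) |
| `ramanclear.cli` | `ramanclear` command: simulate / calibrate / fit-diffusion / water-states / report |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
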