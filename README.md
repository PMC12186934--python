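# magdensity

Cross-scanner quantitative breast density from fat–water MRI.

Breast density (BD) — the proportion of fibroglandular, water-rich tissue in
the breast — is a major breast-cancer risk factor, and longitudinal BD change
is used as an endpoint in prevention trials. **MagDensity** is an MRI-based BD
measure: multi-echo gradient-echo (Dixon) data are decomposed into fat and
water signal maps, the fat-fraction map is corrected for known signal biases,
and the mean bias-corrected volumetric water fraction over the segmented
breast, in percent, is reported per breast. Because women may be scanned on
different systems over time, the measure is only clinically useful if it is
consistent across scanner models, vendors and field strengths — or can be
made consistent by calibration.

This package implements the full measurement and harmonization chain as a
tested, simulation-backed pipeline:

1. **phantom** — a digital bilateral breast phantom (adipose,
   fibroglandular, subcutaneous fat, pectoral muscle) and a multi-echo
   spoiled-GRE simulator with scanner presets for the three study systems
   (3T "prisma", 3T "mmr", 1.5T "signa"), including T1/proton-density bias,
   residual water in adipose tissue, B0 inhomogeneity, echo-phase errors and
   complex Gaussian noise.
2. **recon** — complex image formation from magnitude+phase, estimation and
   removal of constant + linear (per-echo-index) phase errors, and IDEAL
   fat–water decomposition (iterative least squares with joint field-map
   estimation), yielding water, fat, field-map and fat-fraction volumes.
3. **density** — signal-bias correction. At each voxel a linear model links
   signals to volumes:

   ```
   S_fat   = a·V_fat + b·V_water
   S_water = c·V_fat + d·V_water
   ```

   The factors are estimated per image from "pure" fat (subcutaneous fat)
   and "pure" water (pectoral muscle) reference regions on the fat-fraction
   map, averaged into a scanner-specific set. With the normalization
   a+c = b+d = 1 and V_fat + V_water = 1, the corrected water fraction is
   FraWater = (a − s)/(a − b) for measured fat signal fraction s, and
   MagDensity = 100 × mean FraWater over the breast mask.
4. **harmonize** — cross-scanner agreement (mean differences, paired
   two-tailed t-tests, Pearson correlation, Bland–Altman bias and 95% limits
   of agreement) and removal of inter-scanner bias by ordinary-least-squares
   linear calibration fitted under leave-one-out cross-validation (whole
   subjects held out, so no breast of a subject informs its own model).
5. **io / cli** — NIfTI volumes with YAML sidecars, CSV/XLSX density tables,
   JSON reports, and a `magdensity` command with `simulate`, `recon`,
   `density`, `compare`, `calibrate` and `run-all` subcommands.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic cohort
(6 subjects × 3 scanners, 48×48×12 voxel grids, noise sd 0.01):

```
python analysis/01_simulate_cohort.py
python analysis/02_reconstruct.py
python analysis/03_density.py
python analysis/04_agreement_calibration.py
```

`03_density.py` prints the scanner-averaged correction factors and the
accuracy against simulation ground truth:

```
scanner-averaged correction factors:
  mmr: a=0.9185 b=0.0050 (n=6)
  prisma: a=0.9185 b=0.0050 (n=6)
  signa: a=0.9772 b=0.0140 (n=6)
36 per-breast measurements -> results/densities.csv; error vs truth: mean 0.087 pp, max 0.243 pp
```

`a` is the fat-fraction a pure-fat voxel actually shows under each scanner's
T1 weighting and residual adipose water (well below 1, and different between
the 3T and 1.5T presets — exactly the bias the correction removes); `b` is
the same for pure water. `04_agreement_calibration.py` then prints the
cross-scanner agreement:

```
  mmr_vs_prisma                delta= +0.004 p=0.164 r=1.0000 LoA=[-0.01, +0.02]
  mmr_vs_signa                 delta= +0.159 p=0.000 r=1.0000 LoA=[+0.11, +0.21]
  prisma_vs_signa              delta= +0.156 p=0.000 r=1.0000 LoA=[+0.12, +0.20]
  mmr_vs_signa_calibrated      delta= +0.001 p=0.943 r=1.0000 LoA=[-0.05, +0.05]
  prisma_vs_signa_calibrated   delta= -0.003 p=0.547 r=1.0000 LoA=[-0.04, +0.03]
```

The two same-field-strength scanners agree to hundredths of a percentage
point; the cross-vendor pair shows a small systematic offset that the
leave-one-out linear calibration removes (mean Δ → ≈0, p ≫ 0.05).

The same pipeline runs in one step on a fresh cohort with
`magdensity run-all --subjects 10 --seed 1 --out results/study`.

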