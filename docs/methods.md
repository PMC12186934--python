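# Methods

## Signal model and simulator

Each voxel contains water and fat volume fractions V_water + V_fat = 1.
The complex multi-echo spoiled-GRE signal at echo time TE_n (seconds) is

    S_n = (A_w + A_f · exp(i·2π·Δf·TE_n)) · exp(i·2π·ψ·TE_n)
          · exp(−TE_n·R2*) · exp(i·(φ0 + φ1·n)) + ε_n

with a single-peak fat resonance at Δf = −3.4 ppm × 42.577 MHz/T × B0
(−217 Hz at 1.5 T, −434 Hz at 3 T), off-resonance field ψ (Hz), constant and
per-echo-index phase errors φ0, φ1 (rad), and complex Gaussian noise ε of
per-channel standard deviation `noise_sd`. The single-peak model matches the
original IDEAL formulation; multi-peak fat spectra, R2* estimation, coil
sensitivities and k-space effects are out of scope.

Amplitudes encode the three signal-bias sources the density correction must
remove:

    A_w = V_water · ρ_w,   A_f = V_fat · ρ_f · W(T1_fat)/W(T1_water)

where W(T1) = sin α (1 − E1)/(1 − cos α · E1), E1 = exp(−TR/T1), is the
spoiled-GRE steady-state factor at the scanner's flip angle α and repetition
time TR. Amplitudes are normalized by the water steady-state weight so pure
water tissue has unit amplitude; `noise_sd` is therefore a fraction of unit
tissue signal (0.01 ≈ SNR 100 at the first echo). Adipose tissue carries a
residual water volume fraction (default 0.10), shared between the phantom
truth and the scanner presets so the theoretically implied correction
factors are consistent.

Scanner presets use the study acquisition parameters: the 3T pair with TEs
1.37–8.81 ms, flip 6°, TR 21.0 ms; the 1.5T system with TEs 2.88–18.66 ms,
flip 12°, TR 22.4 ms. T1 defaults are 385/1450 ms (fat/water, 3T) and
365/1300 ms (1.5T); proton densities 1.0 except the 1.5T preset's effective
water proton density (0.35), a deliberate emulation knob that puts the
*uncorrected* density readings of the cross-vendor pair a few percentage
points apart — the bias scale the harmonization stage exists to handle —
without claiming those values describe any real scanner. Each preset also
carries small distinct (φ0, φ1) echo-phase errors. R2* defaults to 0 so
noiseless runs are exactly invertible.

## Phantom geometry

Two half-ellipsoid breasts in prone, axial orientation on a chest-wall slab
(pectoral muscle), with a one-voxel skin shell and a two-voxel subcutaneous
adipose layer. The breast interior — the region a whole-breast segmentation
would analyze — is split between fibroglandular and adipose voxels by
thresholding a smoothed random texture (biased toward the breast center) at
the quantile that realizes the requested fibroglandular fraction, so the
realized per-breast fraction equals the target up to voxel rounding. The
subcutaneous layer provides the pure-fat reference ROI and a muscle block
the pure-water ROI; segmentation itself is treated as an upstream input and
not modeled. The B0 field is a low-order random polynomial rescaled to a
±30 Hz peak by default. The ground-truth table records the realized
fibroglandular voxel percentage per breast: under the reference-region
definition of the correction (pure adipose, including its residual water,
maps to FraWater = 0), the quantity the corrected pipeline estimates is the
fibroglandular volume fraction, and that is what truth must record for the
end-to-end comparison to be meaningful. Cohort simulation draws per-subject
target densities uniformly from 40–80% (the study population was
high-density) with ±1.5 pp left/right jitter.

## Echo-phase estimation

The constant + linear-in-echo-index phase error is estimated by nonlinear
least squares over (φ0, φ1), where for each trial value every
high-magnitude voxel (top decile, capped at 1500) is fitted by a
*real-amplitude* water/fat pair with its own field ψ — variable projection
with an inner Gauss–Newton update of ψ, clamped to the swap-unambiguous
window (below). Constraining amplitudes to be real is what identifies φ0 at
all: an unconstrained complex fit absorbs any constant phase. φ1 is
identified by the *non-uniformity* of the echo spacing, because a linear
phase in echo index over uniformly spaced echoes is indistinguishable from
a frequency shift. Consequently the estimates are sharp for the 3T protocol
(irregular spacing; errors ~1e-3 rad at noise sd 0.01) and sloppy for the
near-uniform 1.5T protocol (~0.1 rad wander along the degenerate valley).
This is a physical identifiability limit, not an implementation artifact,
and it is benign: the degenerate direction trades φ1 against a uniform
field-map shift, which the downstream decomposition absorbs without
affecting fat fractions — confirmed by the density accuracy tests.

## IDEAL decomposition

Per voxel, the solver alternates (a) complex least squares for the
water/fat amplitudes given ψ, using the design matrix with rows
(1, exp(i·2π·Δf·TE_n)) after demodulating exp(i·2π·ψ·TE_n), and (b) a
variable-projection Gauss–Newton update of ψ, until |Δψ| < 0.01 Hz or 50
iterations. Echo configurations with a numerically singular design (all
echoes effectively in-phase) are rejected.

Fat–water swap handling. A pure-fat voxel at field ψ produces nearly the
same signal as pure water at ψ + Δf + k/ΔTE (k integer, ΔTE the mean echo
spacing); with near-uniform spacing the closest swap branch differs from
the truth only through the small spacing irregularity, so under noise the
residual cannot reliably rank the branches. The solver therefore runs from
four starts (0, Δf/2, ± the unambiguity radius), computes the *swap
unambiguity radius* — half the distance to the nearest swap branch
(~119 Hz for the 3T protocol, ~50 Hz for the 1.5T protocol) — and prefers
candidates inside that window unless an outside candidate's residual is
decisively lower (below 0.1× the inside residual, as happens for noiseless
data whose true field genuinely lies outside). Ties go to the smaller |ψ|.
Fields beyond the window are thus recoverable only when noiseless or when
an explicit larger bound plus the optional inter-sweep Gaussian smoothing
of ψ (off by default) is used; the study's ±30 Hz fields sit comfortably
inside. No region growing or graph-cut regularization is attempted.

## Bias correction and MagDensity

The measured fat signal fraction s = S_fat/(S_fat+S_water) of each ROI is
summarized by a 20%-trimmed mean (robust to partial-volume voxels at ROI
edges). The two pure-region observations determine only two degrees of
freedom of the four correction factors, so the closure a + c = 1,
b + d = 1 (each pure tissue's total signal normalized to one) is adopted,
giving a = FF(pure fat), b = FF(pure water) and the affine correction
FraWater = (a − s)/(a − b), clamped to [0, 1]. Per-image factors are
averaged per scanner before the correction is applied. MagDensity is
100 × mean FraWater over valid voxels of the breast mask.

Clamping note: with noise, voxels of pure tissue sit *at* the corrected
bounds, so roughly half of them are clamped by a noise-scale amount; the
reported clamp fraction is therefore large under noise yet each excursion
is tiny, while on noiseless data the fraction is ~0. The fraction is
reported alongside the map rather than bounded.

## Agreement and calibration

Paired per-breast values from two scanners are compared by the mean signed
difference (former − latter), the paired two-tailed t-test
(t = mean/ (sd/√n), df = n−1, Student-t tail), Pearson correlation, and
Bland–Altman bias ± 1.96 × sd limits of agreement; identical sequences are
flagged (zero-variance) instead of producing an undefined test. The 20
breasts are treated as 20 independent pairs, mirroring the study analysis;
within-subject correlation of left and right breasts is acknowledged but
not modeled.

Calibration is a single pathway: an OLS line mapping the 1.5T values onto
the 3T mMR scale (the two 3T scanners show no significant difference, so
one anchor suffices), fitted under leave-one-out cross-validation with the
*subject* as the default fold unit so both breasts of a woman leave the
training set together (per-breast folds are selectable). Calibrated values
are compared against both 3T scanners.

## Problem sizes and numerical defaults

Default study runs use 64×64×16 voxel grids, 10 subjects × 3 scanners,
noise sd 0.01; the analysis scripts use 6 subjects on 48×48×12 grids, and
the unit tests 32×32×12 — sizes at which every stage's behavior is already
asymptotic while a full run stays in the minutes range on one CPU. Field
map tolerance 0.01 Hz, max 50 iterations, ψ initialized at 0; the
acceptance replicate counts (20 noisy acquisitions for factor recovery,
200 tabular cohorts for calibration) match the precision the tolerances
require.

## What the simulation does and does not show

The phantom reproduces the features the method's logic depends on: distinct
pure-tissue compartments, reference regions, scanner-specific multiplicative
signal bias, smooth B0 fields, echo-phase errors and additive complex noise.
It omits partial-volume mixing at tissue boundaries, multi-peak fat
spectra, T2*/R2* decay (available in the simulator but zero by default),
motion, coil shading and segmentation error. Passing tests therefore
demonstrate the correctness and internal consistency of the estimation
chain under its stated model — not the in-vivo accuracy of the measure,
which the underlying study established with scanned volunteers.
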