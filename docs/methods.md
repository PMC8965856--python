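# Methods

This note documents the models, conventions and design choices behind
`qeeg-attention`: what is computed, why the defaults are what they are,
and what the synthetic-data tests do and do not demonstrate.

## Spectral estimation

**Welch PSD.** Each 60-s epoch (12 000 samples at 200 Hz) is split into
1-s blocks with 50 % overlap — 119 blocks, `floor((N−L)/(L/2)) + 1`. Each
block is mean-subtracted, Hann-windowed, and periodogram-scaled with
window power compensation (division by `fs · Σw²`); one-sided spectra
double all non-DC, non-Nyquist bins. Per-bin power (µV² per 1-Hz bin) is
the density times the 1-Hz bin width; at 1-s blocks the two coincide
numerically. This scaling satisfies a Parseval contract: the 0–Nyquist
per-bin sum approximates the signal variance (within ~5 % for white
noise, ~2 % for an in-bin sinusoid; the residual is window spectral
leakage). Blocks are *averaged* by default. A `sum` aggregate (multiply
by 119) is provided for pipelines that accumulate rather than average
block periodograms; the constant cancels in every normalized quantity,
the TBR and the alpha ratio, so only absolute-power reports differ.

**Per-block mean removal.** Bin 0 therefore carries ≈ 0 power, but the
0–50 Hz total deliberately *includes* bin 0, so DC offsets in the
recording hardware cannot dominate the normalization.

**Bands.** Inclusive integer bins at 1-Hz resolution: delta 0–3, theta
4–7, alpha 8–12, beta 13–25. Together with 26–50 these tile 0–50 Hz with
no overlap. Delta is not needed for the headline features and exists for
simulation and per-frequency reporting. Frequencies are addressed by
integer Hz value everywhere, never by array index.

**Normalized spectrum.** Per-bin share of the total 0–50 Hz power; each
channel sums to 1 (tolerance 1e-9) and is invariant to positive rescaling
of the input signal — as are the TBR and the alpha ratio, which is why no
absolute calibration of the synthetic signals is needed.

**Alpha ratio mode.** The attention-to-resting alpha ratio defaults to
*normalized* spectra, because group comparison of dynamic changes is done
on normalized power; a *raw*-power mode is a config switch
(`RunConfig.ratio_mode`). Raw mode is the one with a closed-form planted
value in the simulator (see below), so the recovery studies use it; both
modes are tested and the mode is recorded in the report provenance.

## Epoch selection

Visual artifact screening is replaced by an automated, deterministic
stand-in: the 60-s window minimizing the fraction of time samples where
any electrode of interest exceeds ±100 µV (earliest window on ties;
failure if the best window still exceeds the configured maximum
fraction, default 0.1). The rule is reported in provenance as an explicit
stand-in. Signals are analyzed as recorded — no filtering, ICA,
re-referencing or montage transformation.

## Statistics

- **Chi-square (2×2):** Pearson, *without* continuity correction —
  the variant that reproduces the reference worked examples
  (4/6 vs 5/5 → p = 0.653; 7/3 vs 4/6 → p = 0.178). Yates' correction is
  available as a flag.
- **Mann–Whitney U:** exact null enumeration when both groups have
  n ≤ 10 and no ties; otherwise the tie-corrected normal approximation
  without continuity correction (the behaviour of the classic clinical
  statistics packages). The exact mode is verified against full
  enumeration of rank splits for all n ≤ 7 fixtures.
- **Spearman:** rho is the Pearson correlation of average ranks; the
  two-sided p uses t = rho·√((n−2)/(1−rho²)) with n−2 df. At n = 20 this
  reproduces the reference conversions 0.547 → 0.013, 0.524 → 0.018,
  0.534 → 0.015, 0.329 → 0.157. (A published value of p = 0.027 for
  rho = 0.506 at n = 20 is *not* reproduced by this formula, which gives
  0.023; a permutation option exists for small samples.)
- **Per-frequency t-tests:** two-sided independent t-tests of normalized
  power at each 0–50 Hz bin, pooled-variance by default (Welch variant
  flagged). Zero pooled variance is flagged degenerate with p = NA. No
  multiple-testing correction is applied by default across the 51 bins;
  an optional Benjamini–Hochberg annotation is provided as a labelled
  extension.
- **Stepwise regression:** forward entry at p ≤ 0.05, backward removal at
  p > 0.10 (both configurable), ordinary least squares throughout.
  The report always contains *both* the selected model and the full-entry
  model's coefficients: published stepwise tables often print all
  candidates, and the full-entry coefficient is the unbiased one for
  effect-size recovery (selection-conditional coefficients are biased
  upward). With both thresholds at 1 the procedure reduces exactly to the
  full OLS fit. Entry stops when the included model fits to machine
  precision, since partial tests on a numerically zero residual are
  meaningless. The regression's "genotype" candidate is coded
  control = 0 / PWS = 1 — i.e. a group indicator, following the coding
  convention of the tables this layout mirrors.
- **BMI z-score:** z = (BMI − mean)/SD from an age- and sex-specific
  reference band; overweight is z > 1, obesity z > 2, both strict. The
  bundled `synthetic_norm_table()` is a smooth synthetic stand-in (adult
  means ≈ 21.5 kg/m², SD ≈ 2.4), *not* a population norm; real analyses
  should supply their reference as a CSV (`sex, age_lo, age_hi, mean, sd`).

## The synthetic generator

**EEG sessions.** Each channel is an independent sum of

- a 1/f^β Gaussian background (spectral shaping of white noise; β = 1,
  flattened below 0.5 Hz, total RMS 7 µV), and
- narrow-band stochastic oscillators — Gaussian spectral envelopes with
  bandwidth = 2σ, so ≥ 95 % of an oscillator's power stays in its nominal
  band: delta (2 ± 1.5 Hz, 5 µV RMS), theta (6 ± 2, 8 µV), alpha
  (10 ± 2, 20 µV), beta (20 ± 6, 5 µV).

Oscillators are filtered noise rather than sinusoids so alpha power
fluctuates naturally across Welch blocks. The resting alpha dominance
(alpha is the modal normalized band at Cz in ≥ 95 % of seeds) emulates
the eyes-closed baseline. The background RMS of 7 µV is calibrated to the
generator's own design target that background leakage into 8–12 Hz stays
below 5 % of normalized power when the alpha oscillator is silenced; the
absolute scale is otherwise arbitrary because every published-style
output is scale-invariant.

**Attention effect.** The attention session multiplies the alpha
amplitude by √(1−s), planting a fractional alpha *power* suppression s:
controls draw s ~ Uniform[0.60, 0.70]; patients draw s from a truncated
Normal(0.30, 0.12) on [0, 0.6]. The patient spread is a design choice —
real patient cohorts show wide within-group variability, and a nontrivial
within-group spread is what makes the ratio separable from the bare group
indicator in the regression. Controls additionally receive a +50 % delta
and theta power boost during attention (the existence of this
low-frequency increase is established; its size is not, so the value is
config-exposed); patient attention sessions change nothing but alpha.
Rest and task share the same noise realizations within a participant, so
the measured raw-mode ratio concentrates tightly around its analytic
value r(s) = ((1−s)·P_α + B_α)/(P_α + B_α), where P_α is the alpha
oscillator's in-band power and B_α the background leakage
(r(0.65) ≈ 0.36, r(0.30) ≈ 0.70).

**Cohorts.** Two groups of 10 by default. Ages are truncated normal
(PWS 18.5 ± 8.0 y, controls 19.8 ± 5.8 y, bounds 6–55); sex (4 M/6 F vs
5 M/5 F), genotype (6 deletion/4 non-deletion) and intelligence category
(7 of 10 patients moderate-to-severe, 3 mild; controls normal) are fixed
counts, so small cohorts match the design margins exactly (other group
sizes allocate proportionally). BMI is drawn per group (25.7 ± 5.9 vs
23.6 ± 3.5 kg/m²) and z-scored against the synthetic reference. Seven of
the nine CPT-3 T-score variables are drawn directly from the published
group means/SDs. The remaining two are generated through couplings:

- commission T = a + 25.04 · r_i + N(0, 3), with r_i the participant's
  planted analytic raw-mode Cz ratio and a set so the control mean matches
  its table value (≈ 50.9);
- omission T = 49.3 + 14.41 · intelligence + N(0, 5).

The coupling-noise SDs are deliberately *smaller* than the printed
marginal SDs of those two variables (which at the published values would
make the commission coefficient essentially unrecoverable at n = 20: the
ratio co-varies strongly with the group indicator, inflating the
coefficient's sampling variance ~3.7× the noise SD per fit). The
generator therefore prioritizes recoverable couplings over matching those
two marginal SDs; the means still match. A JSON manifest records every
planted value (suppressions, analytic ratios, coupling coefficients) for
recovery testing.

**Determinism.** All randomness flows through a `SeedSequence` tree:
identical seeds give bit-identical sessions, pairs and cohorts, and the
cohort table does not depend on whether EEG synthesis is enabled.

## What the synthetic tests show — and what they do not

Passing recovery tests show that the *pipeline* is correct: planted
suppressions, group differences and coupling coefficients survive the
EDF round trip, epoch selection, Welch estimation and the statistics
layer, at the study's sample size. They do not show that real EEG behaves
like the generator: real recordings have eye-blink and EMG topographies,
non-stationary background, inter-channel correlation, and alpha peaks
that drift in frequency — none of which are simulated. Absolute powers
are arbitrary. The per-frequency localization property (smallest p at the
suppressed bins) is exercised on raw per-bin power, because on normalized
spectra an alpha-only difference necessarily propagates into every other
bin (the fractions sum to 1), and the lowest-variance off-band bins can
then carry the smallest p.

## Problem sizes and run times

Monte-Carlo sizes used by the test suite and the acceptance script, all
on the three analyzed midline channels (channels are independent, so this
affects run time only): 20 seeded session pairs per planted-suppression
recovery; 100 end-to-end cohort runs for the detection rate; 200 for the
regression-coefficient recoveries (per-fit coefficient SD ≈ 11, so the
200-run mean has a standard error ≈ 0.8 against the ±10 % acceptance
band around 25.04). A full single-cohort run (simulate → EDF → analyze →
report) takes a few seconds; the whole suite runs in ~2½ minutes on one
CPU.

## Known limitations

- Sessions other than eyes-closed rest and the attention task are
  accepted on input but never analyzed (tags exist for eyes-open and
  noise-stress protocols).
- The EDF writer emits a fixed nominal start date; synthetic data carries
  no real clock, and reports must be byte-reproducible under a seed.
- The stepwise procedure is the classic p-value-driven one, provided for
  fidelity with the clinical-statistics convention it mirrors; it is not
  a recommendation of stepwise selection for inference.
- `cohort_compare` formats mean ± SD to one decimal for display; the
  underlying test statistics are computed on full precision.
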