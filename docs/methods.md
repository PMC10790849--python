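# Methods

`drivefc` models the degree of distracted driving as the per-driver
relationship between pre-stimulus functional brain connectivity and brake
reaction time (BRT).  This note documents the model and its assumptions,
the synthetic-data generator the package is validated on, the numerical
conventions, and the design choices made where the procedure was
genuinely open.

## The behavioral index

During a 15-minute drive, beep tones occur at uniformly random 20–40 s
intervals and the driver brakes as quickly as possible.  The BRT is the
time from beep onset to brake onset in milliseconds.  Brakes more than
3 s after the beep are treated as unrelated braking and the trial is
invalid; each brake onset can be credited to at most one beep, and a
brake falling after the next beep is never attributed to the earlier one.
Valid BRTs are screened once with a 3-sample-SD rule (strict inequality,
n−1 SD).  The rule is deliberately single-pass and non-iterative: the
regime it emulates contains at most one extreme value per driver, and a
lone 4–6 SD value is reliably caught, whereas iterating the rule would
progressively trim the tails of a clean sample.

## From light to connectivity

Raw dual-wavelength (760/850 nm) intensities pass through a fixed chain:

1. **Optical density.** OD(t) = −log₁₀(I(t)/I_ref) with I_ref the
   channel's geometric-mean intensity, so OD is zero-mean in log space.
   (An arithmetic-mean reference would leave a Jensen-gap offset and
   break the exact forward/inverse roundtrip.)
2. **Modified Beer–Lambert law.** Per sample and channel, the 2×2 system
   ΔOD_λ = d·DPF_λ·(ε_λ,HbO ΔHbO + ε_λ,HbR ΔHbR) is inverted.
   Extinction coefficients default to standard base-10 literature values
   in 1/(mM·mm) — (0.0586, 0.1548) at 760 nm and (0.1058, 0.0691) at
   850 nm for (HbO, HbR) — with DPF (6.2, 5.6) and source–detector
   separations of 30 mm (long) and 8 mm (short).  All are configuration,
   not fitted quantities.
3. **Band-pass 0.01–0.1 Hz.** Zero-phase (forward–backward) 4th-order
   Butterworth; zero phase matters because windows are event-locked and
   any group delay would shift signal relative to the beep.
4. **Short-separation regression (SSR).** Each 30 mm channel is
   regressed on [intercept, its paired 8 mm channel] and replaced by the
   residual, removing scalp/systemic physiology.  The pairing comes from
   the montage file; the regression is per-channel univariate, the
   simplest SSR variant.

Only oxy-Hb is analysed downstream (it is the more robust chromophore
for fNIRS connectivity); deoxy-Hb is computed and stored.

For each beep, the oxy-Hb window of 10, 15 or 20 s immediately preceding
the beep (half-open, exactly ⌊W·fs⌋ samples strictly before the beep
sample — prediction uses only pre-event data) yields a 44×44 Pearson
correlation matrix, Fisher Z-transformed (atanh, |r| clipped to 1−10⁻⁷)
and vectorized to its strict lower triangle in row-major order:
C(44,2) = 946 edge values.  A zero-variance channel sets its edges to 0
(with a warning) rather than dropping the trial, keeping trial counts
aligned with the behavioral table.

## The regression model

For one driver with N usable trials (valid, non-outlier, full window
history), the design is the N×946 matrix of Fisher-z edges and the
response the N BRTs.

**Stability selection.**  NB subsets of round-half-away(BP·N) trials are
drawn without replacement (the procedure is subsampling, not a true
bootstrap, and is implemented literally).  Within each subset every edge
is screened by its two-sided Spearman correlation with BRT; edges with
p < 0.05 (strict) are hits.  Edges whose hit frequency across the NB
subsets is ≥ FP are selected; the ≥ convention makes FP = 1.0 (the
intersection of all subsets) attainable, which the hyperparameter grid
requires.  No multiple-testing correction is applied across the 946
edges — stability thresholding is the only control.  Spearman p-values
use the exact permutation null for tie-free samples of size ≤ 9 and the
t approximation with n−2 df otherwise; ties get average ranks.

**OLS.**  BRT is regressed on the selected edges with an intercept by
least squares; when the number of selected edges reaches N−1 the
minimum-norm solution is returned (training residuals ≈ 0, the
interpolation regime in which training correlations of 1.00 arise).  An
empty selection degrades to an intercept-only model with a warning.

**Leave-one-out CV.**  Feature selection and OLS are re-run inside every
fold on the N−1 training trials only; the held-out trial is predicted
once.  Pooled predictions are scored by Spearman ρ with a
no-correlation test, by the mean absolute error of BRT, and by the SD of
the absolute errors; the average in-fold training ρ and the average
selected-edge count are also recorded.  A leakage probe (perturbing a
held-out BRT can never change its prediction) is part of the test suite.

**Grid search.**  The full grid is windows {10, 15, 20} s × NB
{10, 20, 50, 100, 300} × BP {0.6, 0.8} × FP {0.5 … 1.0}: 180
combinations.  Hyperparameter tuning sits outside the CV loop (nested CV
is not affordable at N ≈ 30), so two selection criteria are reported
side by side: the combination maximizing the average training-fold ρ,
and the combination maximizing the held-out ρ.  The latter is
optimistically biased — it peeks at the test folds — and the
documentation and results objects flag it as such; the former reliably
overfits (training ρ up to 1.00 with near-zero held-out ρ), a phenomenon
the test suite reproduces on pure-noise data.  Ties break by fixed grid
order (window, NB, BP, FP ascending).

Seeding: a standalone LOOCV run seeds fold f with `seed + f`.  Inside
the grid search, per-(window, NB, BP) fold seeds derive from
`SeedSequence([seed, window_idx, NB, 100·BP, fold])`; screening is
FP-independent, so all FP thresholds share one screening pass per fold,
which is what makes the 180-point grid tractable.

## Interpretation across drivers

Each driver's selected edges (by default from one stability-selection
fit on the full trial set at the chosen hyperparameters;
`pattern_source="fold_union"` uses the union over CV folds instead) are
projected onto the 116-region AAL parcellation as a symmetric binary
matrix — a channel pair maps to its (region, region) entry, within-region
pairs to the diagonal.  Drivers with significant models are compared by
the Jaccard distance between these binary patterns and clustered by
UPGMA (average linkage); the tree is cut at a fixed count of 5 clusters
by default.  Per cluster, the intersection of member patterns gives the
common edges, each annotated by the (network, network) pair of its
regions over {DAN, DMN, SMN, VAN, FPN, SN}; unmapped regions are labeled
"unassigned".

## The synthetic-data generator

No raw recordings are distributed, so the package ships a seeded
generator whose defaults are the study conditions: 900 s sessions at
4.36 Hz, 44 long + 16 short channels, ISIs uniform in 20–40 s (the first
beep delayed to ≥ 20 s so the largest window always has history),
BRT mean 800 ms and SD 150 ms, and an outlier probability of 0.03 per
trial, which yields roughly one outlier per affected session.

Connectivity structure: each trial has a latent attentional state
u ~ U(0,1); all five planted channel pairs (spanning DAN–SMN and DAN–VAN
region pairs in the default montage) take the target correlation
r = 0.1 + 0.7·u for that trial's pre-beep window.  A single shared
latent state, rather than five independent draws, reflects coherent
network-level modulation by the attentional state — the construct the
analysis assumes — and is what makes each individual edge carry a
recoverable marginal signal at effect sizes around 0.6.  Windows are
realized as multivariate Gaussian draws from the target correlation
matrix (background correlation 0.1 elsewhere) projected to the nearest
positive-definite correlation; between-window stretches use the
background matrix.  The noise-free BRT is affine in the Fisher-z of the
planted target correlations, scaled so the planted signal explains
exactly `effect_size` of the BRT variance in expectation; Gaussian noise
supplies the rest.  With probability `outlier_rate` a session's BRT
contains one extreme value at mean + U(4,6)·SD — at most one per
session, because simultaneous extremes inflate the sample SD and can
mask each other under the single-pass 3-SD rule, a regime the emulated
study does not contain.  A shared 0.08 Hz systemic oscillation is mixed
into the long channels (per-channel gains) and carried by the short
channels plus their own noise floor, so SSR has a realistic job.

The generator emits hemoglobin-dialect sessions on an effective-sample
scale: window samples are white conditional on the trial's correlation
matrix, so each sample is an independent degree of freedom and a 20 s
window (87 samples) estimates the planted correlation to about ±0.1.
Consequently the default analysis path for these sessions applies SSR
but not the band-pass (band-passing a white-structured series would
collapse its effective degrees of freedom without adding realism).  The
band-pass stage is exercised end-to-end on the intensity-level forward
model, where in-band neural signals, multiplicative drift and systemic
oscillation are synthesized explicitly and the full chain
(OD → MBLL → band-pass → SSR) must recover the planted correlations to
±0.1 per edge.  What passing tests show is therefore that the pipeline
recovers planted structure under the generator's idealized noise; real
fNIRS data add motion artifacts, serial correlation within windows,
channel-quality variation and non-sinusoidal physiology that the
generator deliberately does not emulate.

A second generator builds planted region-level binary patterns (five
groups, all sharing DAN–SMN and DAN–VAN pairs) for validating the
clustering stage, and `generate_raw_intensity` forward-models any
session to dual-wavelength intensities for preprocessing tests.

## Numerical conventions and degenerate inputs

- Subset size: round-half-away-from-zero of BP·N; subsets below 3
  samples are rejected (correlation undefined).
- Hit-frequency comparison uses a 10⁻⁹ tolerance so e.g. 7/10 ≥ 0.7
  holds in floating point.
- Constant BRT within a subset screens nothing (warning); a constant
  short channel reduces SSR to mean removal (warning); both-empty edge
  patterns have Jaccard distance 0 (warning).
- |r| = 1 is clipped before atanh; zero-variance channels produce r = 0
  edges, not NaNs.
- The no-correlation test requires at least 4 pairs; LOOCV requires at
  least 5 trials.
- Significance of a correlation is always two-sided.

## Problem sizes

The shipped validation runs use a 12-participant synthetic cohort at
effect size 0.6 (~30 trials each) with a reduced 12-point grid
(windows {10, 20} s × NB {20, 100} × BP {0.8} × FP {0.5, 0.7, 0.9})
that contains the stability-selection reference point
(NB = 100, BP = 0.8, FP = 0.5); the full 180-point grid is enumerated
and exercised on single participants.  These sizes keep a complete
cohort run in the low minutes on one CPU while preserving every
qualitative phenomenon of the full design.

## Known limitations

- The generator's window samples are serially independent; real
  hemodynamics are band-limited, so real windows carry far fewer
  effective degrees of freedom and noisier FC estimates.
- The test-criterion model selection is optimistically biased by
  construction; it is reported because the emulated workflow reports it,
  with the bias documented.
- Montage geometry is nominal (no probe registration); the channel→AAL
  and region→network maps ship as an editable table and are a plausible
  but synthetic assignment.
- No motion-artifact correction or channel-quality pruning is
  implemented; the generator produces neither.
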