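# Methods

## Signals and alignment

The package operates on event series, one value per physiological event:
beat-to-beat interval (BBI, ms), systolic and diastolic pressure (SBP/DBP,
mmHg) per heartbeat, and breathing-cycle length (RESP, s) per breath.
BBI/SBP/DBP are treated as beat-synchronous — in the intended acquisition
setting all three derive from the same continuous pressure waveform — so
the beat grid is the onset times of the first per-beat series listed,
intersected (exact time match) with the others. Inputs are assumed clean;
ectopic-beat and artifact filtering is out of scope and must happen
upstream.

How breath-wise RESP pairs with beat-wise series into single points is a
genuinely open design choice. The default is a **previous-event hold**:
each beat carries the cycle length of the breath ongoing at that beat. It
is causal and parameter-free. Linear interpolation of cycle length between
breath onsets is available as an option; beats before the first breath are
dropped in both schemes, and the hold/interpolant is clamped at the last
breath. The choice changes RESP-axis values by at most one between-breath
difference and did not change any qualitative behaviour in the test
cohorts.

## The cubic box model

The aligned cloud of N points is binned into a 12×12×12 box (fine model,
1728 cubelets) or, by summing each 2×2×2 block of the fine model, a 6×6×6
box (coarse model, 216 cubelets). Cells are half-open `[lo, hi)`; a point
exactly on an interior boundary goes to the higher-index cell and the
global top edge is exclusive (standard histogram convention, deterministic
under ties). Points outside the box are excluded from every cubelet but
kept in N, so `sum(probs) + out_of_range = 1` holds to machine precision by
construction.

**Adapted grids.** Only "adapted to the SD" is fixed by the method's
description; the proportionality constant is not. This implementation uses
edge = SD/2 at 12 cells (edge = SD at 6 cells), so the box always spans the
centroid ± 3·SD: about 99.7 % of a Gaussian axis falls inside, whereas
edge = SD at 12 cells would span ±6·SD and leave the outer half of the box
structurally empty. SDs use the sample convention (ddof = 1). A
zero-variance axis is a hard error naming the signal. Note the coarse
*pipeline* variant is always the block-sum of the fine box; constructing a
6-cell adapted grid directly gives the same box here (same ±3·SD span), but
the two constructions are conceptually distinct and only the block-sum
route is used downstream.

**Predefined grids.** Fixed physiological axes identical for all subjects:
BBI 400–1300 ms in 75-ms steps, SBP 50–206 mmHg in 13-mmHg steps, DBP
22–130 mmHg in 9-mmHg steps, RESP 1.25-s steps from 0.5 s. The nominal
RESP maximum of 15 s is not an integer multiple of 1.25 s above 0.5 s
((15 − 0.5)/1.25 = 11.6), so the axis is extended to 15.5 s to obtain 12
equal cells. At 6 cells the edges double and the origins are unchanged.

**Rotation.** The rotated variant normalises the cloud's orientation:
least-squares regression in each coordinate plane gives α = atan(slope of
Y on X), β = atan(slope of Z on Y), γ = atan(slope of X on Z); the cloud is
rotated rigidly about its centroid by −α about the Z direction, then −β
about X, then −γ about Y. All three angles are estimated from the original
cloud and applied in that fixed order; sequential 3D rotations do not
commute, so fixing the order is what makes results reproducible.
Re-estimating angles after each partial rotation would be an equally valid
reading and is not implemented. A zero-variance predictor axis yields angle
0 (it carries no orientation information). The univariate variant rotates
by a fixed 45° in all three planes — the main diagonal of a strongly
autocorrelated lag embedding has unit slope — rather than fitting
regressions.

Grid/rotation interaction: in the rotated **adapted** multivariate variant
the grid adapts to the rotated cloud (the centroid is rotation-invariant).
This matters because regression slopes between axes of heterogeneous units
(ms against s) are numerically huge, the fitted angles approach ±90°, and a
grid sized from the un-rotated SDs would miss almost the whole rotated
cloud. The rotated **predefined** variant keeps its fixed box, and large
out-of-range fractions there are an inherent property of rotating a
raw-unit cloud inside fixed physiological axes. The rotated **univariate**
variant keeps the pre-rotation column SDs (homogeneous units; the 45°
rotation stretches the diagonal by at most √2).

## Univariate embedding

One series x of length L is embedded as rows (x_i, x_{i+1}, x_{i+2}),
i = 1 … L−2 (lags τ = 1, 2 only; embedding dimension fixed at 3). Grids
adapt to the SDs of the three embedding columns, or reuse the signal's
predefined axis on all three axes — the only consistent reading, since all
axes carry the same physical quantity. Labels repeat the signal name
(`SBP5_SBP5_SBP2`).

## Screening and classification

Per cubelet, per-subject probabilities of two groups are compared with the
two-sided Mann–Whitney U-test (scipy): exact null when min(n) ≤ 8 and the
data are tie-free, normal approximation with tie correction and continuity
otherwise. Completely tied samples — typical for cubelets that are empty in
every subject — short-circuit to p = 1 rather than NaN, so empty cubelets
can never appear significant. Tiers: significant (0.01 ≤ p < 0.05), highly
significant (p < 0.01), Bonferroni p < 0.00003; the last is stored as the
literal one-significant-figure constant that 0.05/1728 rounds to, not
recomputed per run. Ten fixed group contrasts are provided (I: CON vs PREG
… IX: PREG+CH+PIH vs PE, X: PREG vs CH+PIH+PE).

Classification uses a per-fold-refit Fisher linear discriminant under
leave-one-out cross-validation: pooled within-class covariance, weight
vector normalised to unit length (so 1D scores are a signed copy of the
feature and relabelling the classes negates scores exactly), and a
diagonal-covariance fallback, with a logged warning, when the pooled
covariance is singular in a fold. The held-out scores define the ROC
(scikit-learn), AUC by the trapezoidal rule, and SENS/SPEC at the ROC point
minimising the Euclidean distance to (FPR 0, TPR 1). Which discriminant the
original protocol used is unstated; pooled-covariance linear DA is the
standard reading of SPSS-era usage, and computing the ROC on LOOCV scores
(rather than raw index values) follows from the cross-validation being
described as the basis of the ROC analysis. The two-index search pairs one
univariate with one multivariate candidate among cubelets at the
highly-significant tier or better (an `all_pairs` flag lifts the mixing
restriction); ranking is by AUC, then SENS+SPEC, then label.

## Synthetic cohorts

No public recordings exist for this problem, so the generator stands in
for them. Per subject it simulates `duration_s` = 1800 s (a 30-minute
recording, ≈ 1800–2400 beats at the default means): respiratory cycle
lengths are AR(1) around `mean_resp`; beat times accumulate from the
generated intervals; and

    BBI_n = μ + a·(BBI_{n−1} − μ) + g_rsa·sin(2π·φ_n)
              + g_brs·(SBP_{n−1} − μ_SBP) + ε_n

with φ_n the phase of the ongoing breath, while SBP/DBP are AR(1) with the
pulse-pressure constraint SBP > DBP enforced. Each `sd_*` parameter is the
marginal SD of the AR component (innovations are scaled by √(1−a²)); the
coupling terms add variance on top. Parameter combinations that are
non-physical in expectation (non-positive mean BBI, mean SBP ≤ mean DBP)
are rejected before simulation, and hard floors (BBI ≥ 250 ms, RESP cycle
≥ 0.2 s, pulse pressure ≥ 1 mmHg) keep individual samples physical.

Group presets (sizes 10/66/13/14/19 for CON/PREG/CH/PIH/PE, scalable with
ceiling): blood pressure rises across CON → PREG → CH → PIH → PE (mean SBP
112 → 150 mmHg); the pre-eclampsia preset additionally has a raised mean
interval (780 ms vs 700–720 ms in the other pregnant groups), short
breathing cycles (2.7 s vs 3.4 s), and tapered coupling gains (RSA 6 ms,
baroreflex 0.3 ms/mmHg) reflecting impaired cardiorespiratory regulation.
These values were chosen once as physiologically plausible defaults inside
the predefined axis ranges; they are study conditions, not tuning knobs.

What the generator does *not* emulate: waveform-level dynamics, ectopic
beats and artifacts, nonstationarity over the recording, gestational-age
trends, and realistic spectral shapes beyond AR(1) + one sinusoid. Passing
pipeline tests on these cohorts therefore demonstrates that the machinery
detects the couplings and group differences it encodes — not that the
clinical effect sizes of real pregnant-women recordings are reproduced, and
the clinical AUC values reported for the original patient data are
deliberately out of scope.

## Numerical choices and problem sizes

Reproducibility: every stochastic step takes a seed; per-subject and
per-replicate seeds derive from a master seed via `numpy.random.
SeedSequence.spawn`. Probability conservation is validated at 1e-12,
rigid-motion properties at 1e-9. The calibration/power experiments in the
test suite and the reproduction script use 20 replicate cohorts of 10 + 10
subjects at the default 30-minute duration — large enough for stable
medians, small enough to run in seconds per replicate; the CLI demo uses a
scaled-down cohort (scale 0.3, 10-minute recordings) for the same reason.

## Known limitations

* The adapted-edge proportionality (SD/2 at 12 cells) and the rotation
  order are fixed conventions for reproducibility, not uniquely determined
  by the method's published description.
* The asymptotic Mann–Whitney p cannot fall below ≈1.6e-4 at 10-vs-10
  group sizes, so the Bonferroni tier is attainable only for larger groups
  (or the exact test at small, tie-free samples).
* LOOCV-score ROC with per-fold refit can be optimistic relative to fully
  nested evaluation when the index itself was selected by screening on the
  same cohort; the best-index tables are exploratory rankings, not unbiased
  performance estimates.
* Rotated predefined boxes discard most points for heterogeneous-unit
  couplings (see above); their features are correspondingly sparse.
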