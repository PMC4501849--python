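# Methods

This note documents the models, conventions and numerical choices behind
`lineatime`, and what the synthetic validation does and does not establish.

## Recordings and lineage reconstruction

A recording is one embryo's curated tracking table: one row per (cell,
frame), 1-based frames at a default interval of 1.5 min, positions
converted to micrometres on read (defaults: 1.0 µm/pixel in xy, 0.71 µm
per z plane — the plane spacing of the confocal stacks this format comes
from). A cell's lifetime is the closed frame interval [birth, last]; its
division is stamped at its daughters' birth frame = last + 1. Lineage
reconstruction needs no positional information: names follow Sulston's
rules (founder table for P0–P4/EMS, otherwise suffix letters a/p, l/r,
d/v), so each cell's mother is implied by its name and validated against
frame adjacency. Cells present at the first frame are accepted as roots —
imaging starts at the two-to-four-cell stage, so AB and P1 (or the four
cells) are never observed from birth. Death events are supplied as a
per-recording name list and censor the affected timings; non-lineage
objects (polar bodies, segmentation artifacts named `Nuc*`) are dropped on
read and counted.

## Timing statistics

Cycle length: (daughters' birth − own birth) × Δt. Censor reasons, in
precedence order: `early-round-excluded` (AB, P1, ABa, ABp, EMS, P2 — the
first two division rounds straddle the start of imaging),
`not-observed-from-birth` (other roots), `dead`, `undivided-at-cutoff`.
The analysis cutoff is the frame at which the embryo first reaches 350
cells, or the last curated frame if it never does.

ADS of a parent is the absolute difference of its daughters' division
frames × Δt; a signed variant (first daughter in lineal order minus the
second) is kept for diagnostics. Pairs whose parent is one of the six
early cells are excluded from ADS tables — their daughters' timings are
measurable but the early rounds are outside the screen's scope.

Cohort summaries: pairwise Pearson r of cycle lengths over cells
uncensored in both embryos (entries with < 3 shared cells are missing and
imputed by row mean before clustering); complete-linkage agglomeration on
Manhattan distances between matrix rows; and the per-generation mean of
across-embryo per-cell SDs (cells present in ≥ 3 embryos).

## Wild-type reference and the normal model

Per monitored pair the wild-type ADS sample (one value per embryo,
minimum 8) is summarized by mean and SD and tested for normality with
D'Agostino's K² (sum of the squared standardized skewness and kurtosis
statistics, χ² with 2 df; implemented from the standard transformations
and verified against an independent implementation to 1e-8). The screen
proceeds with the normal model regardless of the test outcome but the
flag is persisted so reports can caveat non-normal pairs — on quantized
data the asynchronies of synchronous pairs (folded, discrete) fail
normality often, which mirrors the partial pass rates seen in real
curated data. Monitored pairs are those with mean ADS strictly greater
than 5 min. Tail probabilities are plain normal tails; two-sided =
2·min(lower, upper). No multiple-testing correction is applied across
pairs; reports state this.

## Hit calling

Per replicate and pair, a flag at level α requires: uncensored ADS,
ADS ≤ (1 − reduction)·μ_WT with reduction = 0.5, ADS < μ_WT (explicit
direction), and two-sided tail p < α. A pair's hit level is 0.01 if ≥ 2
replicates flag at 0.01, else 0.05 by the same rule, else none. Embryo QC
precedes everything: fewer than 300 cells at the last editable frame
fails; if curation reaches frame 240, failing to reach 350 cells by then
also fails (recordings ending earlier are judged by the first clause
alone — the two clauses cannot both bind a short recording). A gene with
no QC-passing replicate is reported `unscreenable` rather than silently
dropped.

## Buffering (capacitor) detection

For each generation g of the AB sublineage, deviations
d(c, e) = T(c, e) − mean_WT(c) are pooled over cells c and embryos e for
the perturbed and the wild-type side, and Var_perturbed > Var_WT is
tested one-sided against an F distribution. Three numerical choices
matter and are ours:

* **Per-embryo centring** (default): each embryo's mean deviation within
  the generation is removed (df reduced by one per embryo). Embryos carry
  a shared pace component — in the generator explicitly, in real data as
  the global speed variation the screen's own QC acknowledges — which
  correlates deviations within an embryo and wrecks the F-test's
  calibration if left in. An uncentred mode is kept for literal fidelity.
* **Finite-cohort standardization**: a perturbed deviation from a mean
  estimated on n wild-type embryos has variance σ²(1 + 1/n); a
  self-included wild-type deviation has σ²(1 − 1/n). Both are rescaled to
  σ², and cells supported by fewer than 3 wild-type embryos are dropped.
  Without this the null flag rate ran at 3–5× nominal for realistic
  cohort sizes (12–20 embryos). With it, the measured null rate per
  generation at α = 0.01 is ~1% and the pooled null p-values are
  KS-uniform.
* **Signed deviations**: the variance is taken over signed deviations;
  an option computes the test on absolute deviations instead (the
  deviation-magnitude phrasing some descriptions use), which is
  statistically awkward and not the default.

The gene flag is min-p over generations < 0.01 with no correction across
generations; with ~6 generations tested the gene-level null rate is ~6%,
and any perturbation that systematically shifts particular cells' cycle
lengths (an asynchrony collapse, a strong slowdown) also inflates
deviation variance and can flag — the statistic detects departure from
the wild-type timing programme, not noise inflation exclusively.

## Spatial statistics

Axes come from the last frame at which exactly {ABa, ABp, EMS, P2} are
present: A-P is the unit vector ABa→P2, the second axis (labelled L-R,
following the field's convention for this construction) is ABp→EMS
orthogonalized against A-P, and D-V completes a right-handed frame; the
origin is the four-cell centroid. After rigid rotation, each axis is
affinely mapped so the embryo's global min/max over all frames spans
[−1, 1] (per-frame scaling would make trajectories discontinuous), and
frames are re-based so the reference frame is 0. The construction is
exactly invariant to rigid motions of the raw coordinates (verified to
1e-9 under random rotations/translations).

Positional deviation of a cell: Euclidean distance from the wild-type
centroid of its final positions, assigned an upper-tail p under a normal
fit to the wild-type distances; per-coordinate K² normality is reported
alongside. Division angles are computed in the rotated but *unscaled*
frame (anisotropic scaling would distort angles): the angle of the
daughter-separation vector v to a plane with unit normal n is
arcsin(|v·n|/‖v‖) ∈ [0°, 90°]. Wild-type angle samples are Box–Cox
transformed — λ by profile MLE on [−5, 5], bounded scalar optimization to
1e-6, angles clamped to ≥ 0.1° first — then de-noised by a single pass
removing points ≥ 3 SD from the transformed mean (λ is fitted before
removal, matching the transform-then-de-noise order), and the perturbed
angle is tested on the same scale with a two-sided normal tail.

λ is weakly identified when the sample's coefficient of variation is
small: for N(50, 5²) at n = 91 the MLE's sampling SD is ≈ 0.83 (the
profile likelihood is nearly flat), so λ̂ scatters widely around 1 no
matter the optimizer. The verification suite reports this recovery rate
as measured; on standard-lognormal samples, where λ is well identified,
recovery of λ ≈ 0 exceeds 95%.

## The synthetic embryo generator

The generator produces recordings with the statistical structure the
analysis assumes — it is a model of curated lineaging *output*, not of
morphogenesis. Defaults define the study conditions used throughout the
tests and verification:

* **Lineage template** (9 division rounds): canonical founder skeleton;
  generic divisions along a/p (ABa/ABp along l/r). Mean cycle lengths
  μ(c) = (10 + 3.2·g) × pace(founder) min at generation g, with a
  deterministic per-pair 10% jitter; sisters share the baseline so only
  designated pairs are asynchronous. Pace factors (AB 0.92, MS 1.0,
  E 1.45, C 1.2, D 1.35, P4 1.1) mirror the slow intestine and posterior
  lineages of the real embryo and give the cycle-length vector the large
  across-cell spread that makes between-embryo correlations high
  (r ≈ 0.95 here). Early-cell means (AB 16, P1 18, ABa 17, ABp 17.5,
  EMS 16.5, P2 17.5 min) give a two-cell start and a four-cell stage
  ~10 frames long.
* **Designated asynchronous pairs**: 12 parents with offsets 8–40 min
  added to the second daughter's mean — largest (40 min) for P3's
  daughters D and P4, reflecting the delayed germline division; all other
  sister pairs have mean ADS ≲ 1.7 min (noise only), so the 5-minute
  monitoring threshold separates them with overwhelming margin.
* **Noise**: cycle = slowdown × (μ(c)·(1 + u) + ε) with a shared
  per-embryo pace factor u ~ N(0, ρ²), ρ = 0.02, and
  ε ~ N(0, σ(c)²), σ(c) = 0.3 + 0.12·g min — variability grows with
  generation, as observed. The slowdown multiplies the whole noisy cycle
  so a slowed embryo is an affine rescaling of its matched wild type and
  correlations survive it.
* **Quantization**: division times are rounded half-up to 1.5-min frames
  and daughters appear one frame after the mother. A realized cycle
  length therefore carries two rounding errors (variance 2·Δt²/12 ≈
  0.375 min²) — the ±1-frame noise floor of real curated data. Empirical
  per-cell SDs match √(σ(c)² + 0.375) within 10% over 200 embryos; at
  small σ the quantization floor, and with ρ > 0 the shared factor,
  dominate the raw σ(c), so the trend test for "flat" profiles (κ = 0)
  is run with ρ = 0.
* **Positions**: canonical diamond at the four-cell stage; daughters
  placed at parent ± r/2 along a letter-derived direction with jitter,
  clamped inside a 2:1:1 ellipsoid (semi-axes 24, 12, 12 µm); a random
  in-plane rigid placement mimics arbitrary mounting orientation. This is
  deliberately simple — it exercises the spatial statistics, nothing
  more.
* **Marker**: intensity = background |N(50, 15)| plus 1000 inside the E
  sublineage; knockouts zero the sublineage signal.
* **Truncation**: first frame reaching 350 cells + 5 frames, capped at
  frame 240, or the arrest condition.
* **Perturbations**: ads_factor scales a pair's daughter mean-difference
  about its midpoint; variance_inflation multiplies σ² within a
  sublineage; position shifts (in normalized units, converted through the
  ellipsoid semi-axes) and division-axis rotations apply to a named
  subtree; arrest truncates.

What passing tests show — and do not. The generator realizes exactly the
distributional assumptions the statistics make (normal noise, invariant
lineage, unbiased quantization), so the validation establishes internal
correctness and calibration: selection thresholds, error rates, power,
geometric invariances. It does not establish robustness to what real
recordings add: curation errors, missed or misnamed cells, non-normal and
heteroscedastic timing noise, fate transformations that change the
lineage topology, drifting marker background, or optical distortion of
positions. The normality flags, censor reasons and QC reports exist
precisely so those departures are visible on real data.

## Problem sizes in tests and verification

The verification suite uses the sizes its properties are stated at: a
91-embryo wild-type cohort for reference recovery; 200 pseudo-genes × 3
replicates for the null screen and 200 generator runs for detection; 100
runs for buffering power and 1,000 null runs spread over 25 independent
20-embryo wild-type cohorts (rotating cohorts keeps the *marginal* null
rate nominal — conditional on any single finite cohort the rate is only
approximately so); 100 seeds for the λ-recovery and oracle checks. Unit
tests use a shared 12-embryo cohort for speed. The full suite runs in a
few minutes on one CPU.

## Known limitations

* The pipeline consumes curated tables; no segmentation, tracking, or
  automated naming is attempted, and raw archive formats are not parsed.
* The normal ADS model is used for all pairs, including flagged
  non-normal ones, by design; interpret tail p-values for those pairs
  with the recorded caveat.
* The buffering statistic flags any systematic timing change, not only
  variance inflation (see above).
* Division-angle conventions (plane labels, the L-R naming of the
  ABp→EMS axis) follow the construction described above; anatomical
  handedness is not resolved from positions.
* The generator's death, fate and category annotations are carried as
  template metadata for testing the plumbing; they encode no biology.
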