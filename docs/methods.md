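# Methods

This note documents the models, estimation procedures and design
choices behind `focidyn`, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The measurement model

The pipeline analyses 2-D grayscale time-lapse stacks of single cell
nuclei expressing a GFP-tagged DSB marker, recorded at a fixed optical
plane at one frame per minute for 75 minutes (the defaults; both are
configurable). Four experimental conditions are distinguished by a
label: `control`, `alpha` (clustered damage), `xray` (dispersed
damage), and `mixed` (half dose of each, delivered simultaneously).

Per recording the pipeline estimates, in order: a rigid-body motion
trajectory of the whole nucleus; a nucleus mask; per-frame focus
detections (position, area, mean intensity); focus tracks;
merge/split events; and, pooled across recordings, kinetics tables,
fading-corrected relative statistics, intensity distributions, and
confined-diffusion mobility parameters.

## 2. Synthetic recordings and their ground truth

No public image data accompany the analysis this package implements,
so the generator in `focidyn.synthetic` is a first-class component: it
produces recordings with the statistical structure the analysis
assumes, plus the complete ground truth needed to test every stage.

### 2.1 Focus-count kinetics

The expected foci-per-cell (FPC) profile of each condition is anchored
at reference values (initial, peak with its time, final):
control flat at 1.5; alpha 6.4 → 8.1 (11 min) → 6.9; X-ray
9.7 → 15.3 (16 min) → 8.7; mixed 7.6 → 10.3 (9 min) → 9.1. The rise is
a monotone shape-preserving (PCHIP) segment; the decline is an
exponential relaxation toward the final anchor with three e-foldings
over the post-peak window, hit exactly at the last frame. This one
rule yields a sharp drop for the peaked X-ray-like profile and a
near-plateau for the alpha/mixed-like profiles, whose peak and final
anchors are close. No mechanistic repair model is implied; the profile
is a descriptive curve through the anchors.

Counts are realised by a birth–death process: deaths are exponential
with mean lifetime 25 min (default), and per-step birth means are
chosen so the expected count equals the profile at every frame
(births at step *t* have mean `max(0, m(t) − m(t−1)·e^{−μΔt})`). The
initial count is Poisson at the profile start unless fixed.

### 2.2 Confined motion

Each focus moves as a stationary Ornstein–Uhlenbeck (OU) process per
dimension, with per-dimension stationary SD `σ = r_c/2` and relaxation
time `τ = r_c²/(2·d·D_c)` (d = 2). With the exact discrete-time OU
update, the ensemble MSD equals

    MSD(Δt) = r_c² (1 − exp(−2 d D_c Δt / r_c²))

exactly in expectation at every lag, which makes parameter recovery a
clean oracle: any bias seen downstream is attributable to the
estimator, not the simulator. Initial positions are drawn from the
stationary distribution; anchors are placed uniformly in the nucleus
disc with a minimum pair separation of 3.0 µm (so that independent
foci render as resolvable spots) and trajectories are radially clipped
to the nucleus (negligibly rare under the defaults).

Per-condition mobility defaults (D_c in µm²/min, r_c in µm): alpha
(0.014, 0.62) > control (0.010, 0.55) > xray (0.007, 0.48) > mixed
(0.004, 0.40). These are synthetic choices that respect the reported
mobility *ordering* of the four conditions; no published numeric
mobility values are asserted.

### 2.3 Merging and splitting

Merges are steered: a triggered focus and its nearest free partner
within 3.5 µm are blended linearly onto their midpoint over five
frames and then share one OU trajectory. Splits either re-separate a
fused pair (the merging-and-splitting pathway) or fork a free focus
into two identities diverging to 3 µm. Trigger probabilities per focus
per minute are condition defaults calibrated once, by simulation over
50–60 nuclei, so the ground-truth fraction of foci in durable merges
approximates the reported levels (~24% alpha, ~17% X-ray, ~16% mixed,
<5% control): control 0.004, alpha 0.025, xray 0.0055, mixed 0.0078;
split rate 0.0015 everywhere.

The ground-truth event log is *topological*: per frame, foci form
blob clusters by single linkage with hysteresis (a pair bonds below
1.45 µm and unbonds above 1.85 µm, matching the measured distance at
which rendered spot labels fuse and separate under the default
renderer and segmenter). Cluster-composition changes between frames
are logged as merging/splitting events, so chance proximity fusions
are recorded exactly like steered merges — they are what a label-image
analysis sees. A truth-side pairing mirrors the classifier: a merge
followed by a later split of the same foci is one
merging-and-splitting event, so "durable merge" means the same thing
on both sides of a comparison.

### 2.4 Rendering

Each live focus is a symmetric 2-D Gaussian (σ = 0.4 µm) of amplitude
139.3 AU on a disc-shaped nuclear background (30 AU) over a small
camera offset; the pixel grid defaults to 128×128 at 0.2 µm/px with an
8 µm nucleus radius. Fluorescent signal is multiplied by a linear
fade, 139.3 AU at minute 0 to 104.6 AU at minute 75 — the reported
control fading under repeated illumination — so the frame-75/frame-0
intensity ratio of a static spot is 104.6/139.3 ≈ 0.75. A rigid drift
(per-frame dx, dy in px and dθ in degrees, accumulated linearly) warps
the whole frame; Poisson shot noise and additive Gaussian read noise
(SD 2 AU) are applied last. Bit depth, pixel size and PSF width are
not reported quantities; the defaults are documented choices, exposed
in `SimulationConfig`, and stacks are written as 16-bit TIFF.

## 3. Estimation procedures

### 3.1 Rigid registration

Consecutive frame pairs are registered — for a candidate rotation the
residual translation comes from subpixel phase cross-correlation, and
the rotation is found by a coarse grid (±4°) plus bounded local search
on the normalised cross-correlation (NCC) — and the pairwise motions
are composed back to frame 0. Because chaining lets pairwise errors
random-walk over 75 frames, every frame is then re-registered directly
against the reference in a ±1° window around the chained estimate.
Application uses the inverse transform with bilinear interpolation and
median-border fill; identity transforms are returned bit-exact.
Blank or pure-noise frames (weak correlation optimum, NCC < 0.5) are
flagged low-confidence.

Characterisation on synthetic data: a single pair with known shift and
rotation is recovered to ≲0.05 px and ≲0.05°; over a long drifting
recording the post-registration nucleus centroid SD stays below 0.5 px.
Rotation is the weakly identified degree of freedom — a nearly
circular nucleus with a handful of spots constrains θ only through the
spot constellation, so per-frame rotation errors of a few tenths of a
degree (sparse scenes: up to ~0.6°) are intrinsic to this scene type,
not to the optimiser.

### 3.2 Segmentation

The nucleus mask is the largest connected component above a global
Otsu threshold of the Gaussian-smoothed frame (smoothing σ = 1 px
default). Foci are connected components of the smoothed, ROI-masked
frame above `nuclear mean + k·nuclear SD` with k = 3 by default — a
reproducible surrogate for an interactively chosen threshold — with an
area filter (0.15–25 µm²). Per focus, the area is pixel count × pixel
area and the mean intensity is taken from the *unsmoothed* pixels
under the label; centroids are intensity-weighted. Foci touching the
mask border are flagged, not discarded. Because the threshold is a
surrogate, absolute counts on real data are calibratable rather than
reproducible; accuracy is therefore assessed against synthetic ground
truth (zero-noise frame-exact count agreement ≥95%, in practice 100%
on resolvable scenes).

### 3.3 Tracking and events

Linking is frame-to-frame nearest-neighbour with conflict resolution
(closest pairs assigned first), a linking radius of 3·√(4·D_c·Δt) by
default, and one-frame gap bridging. Merges are detected when two or
three labels at frame t each overlap a single label at t+1 by at least
30% of the smaller label's area; splits are the exact time-reverse
(so reversing a recording swaps the two raw counts); a merge followed
by a later split of the fused track is reclassified as one
merging-and-splitting event. Events with ≥4 participants are returned
unclassified. All merge participants are flagged
`merge-contaminated` and excluded from mobility analysis, as are
tracks entering at the ROI border mid-recording (`roi-migrant`).

Participation fractions divide the foci taking part in each class — a
merge's parents, a split's children — by the per-nucleus focus count,
where tracks that begin life as the continuation of an event (the
fused blob, or a re-separated focus) are not counted as new foci.

### 3.4 MSD and the confined-diffusion fit

The MSD is time-and-ensemble averaged: all valid position pairs of all
non-excluded tracks are pooled per lag (per-track curves remain
available by calling `compute_msd` per track). The maximum lag
defaults to one third of the track length to limit pair starvation.
The model is fitted by weighted nonlinear least squares (weights ∝
pair count per lag; `scipy.optimize.curve_fit` with D_c ≥ 0, r_c > 0),
initialised from the plateau (last quartile mean → r_c²) and the
initial slope (MSD(Δt₁)/(2·d·Δt₁) → D_c). Non-convergence is flagged
rather than raised; flat curves carry a D_c-unidentifiable warning,
plateau-free curves an r_c warning. Recovery characterisation (OU
truth, 75-frame tracks): exact to ≤0.1% on noiseless curves, ≤5% on
the 10⁴-track ensemble MSD per lag, and within 15% (typically ≤7%) for
both parameters from 150-track experiments across 20 seeds.

### 3.5 Kinetics statistics

Per-minute FPC means and sample SDs (ddof = 1 throughout) are
aggregated across nuclei; the "fitted" curve is a local-quadratic
(Savitzky–Golay) smoother whose window spans 12% of the series. The
span is deliberately modest: on these asymmetric kinetics profiles a
wide or locally linear smoother displaces the peak by several minutes,
whereas the default shifts a noiseless peak by ≤1 min (a tested
property) while still suppressing counting noise.

Summary rows report initial/highest(+time)/final FPC; the maximum
focus increase divides the highest FPC by the overall control mean,
and the peak-to-final ratio divides the highest by the final FPC (both
reported to one decimal). From the anchor profiles these reproduce
5.4/10.2 (increase, alpha/X-ray) and 1.2/1.8/1.1 (peak-to-final,
alpha/X-ray/mixed). The mixed-beam increase computes as
10.3/1.5 = 6.87 → 6.9.

The additive mixed-beam expectation is half of the sum of the fitted
alpha and X-ray curves, pointwise. Its *summary entries* are computed
column-wise — the mean of the alpha and X-ray entries: initial 8.05,
highest 11.7, final 7.8 — with the peak time read off the pointwise
curve; the pointwise maximum of smoothed curves would depend on the
smoother, while the column-wise rule is pure arithmetic on the
anchors. The pointwise expected curve peaks at minute 16 (the X-ray
peak dominates); with broader smoothing the maximum sits at 15–16 min.

Fading correction ratios treated series against the simultaneously
recorded control series (photobleaching cancels in the ratio), with
first-order SEM propagation; the control fading itself is an OLS line
whose percent loss over the 75-min window is
100·(ŷ(0) − ŷ(75))/ŷ(0) ≈ 25% for the reference line. Coefficients of
variation are sample SD/mean over the minute-1..75 window and are
scale-invariant. Intensity distributions are Gaussian-kernel density
estimates evaluated on a uniform grid spanning the data ± 3h and
renormalised to unit trapezoid area (the ±3h truncation carries ~0.3%
mass); the default bandwidth is Silverman's rule
0.9·min(SD, IQR/1.34)·n^(−1/5). Group comparisons use one-way ANOVA
and the Pearson chi-square on 2×2 tables without continuity
correction, at α = 0.05.

## 4. Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at the following sizes, chosen to match the recording design
while keeping a full run to a few minutes on one CPU: 75 frames per
nucleus at 1 min/frame; 25 simulated nuclei per irradiated condition
and 60 controls where condition-level statistics are computed; 150
tracks per confined-diffusion fit (the per-condition order of
magnitude of analysed foci) and 10⁴ tracks for the ensemble-MSD
check; 128×128 px frames at 0.2 µm/px.

## 5. Known limitations

* The generator renders idealised Gaussian spots on a uniform nuclear
  disc: no chromatin texture, no nucleoli, no cell-shape changes, no
  focal-plane drift, no spot-size or amplitude heterogeneity beyond
  bleaching. Passing tests therefore demonstrate correctness of the
  estimators under the stated generative model, not robustness to
  every real-microscopy artifact.
* Everything is 2-D at a fixed optical plane; foci moving axially
  through the plane are not modelled, and 3-D mobility is out of
  scope.
* Rotation estimation is intrinsically weak on sparse, nearly
  circularly symmetric scenes (§3.1).
* The merge/split ground truth and the label-overlap classifier use
  different fusion criteria (a distance rule with hysteresis vs.
  connected-component topology under an adaptive threshold); they
  agree statistically — recovered durable-merge fractions track the
  ground truth within Monte-Carlo error — but individual marginal
  encounters near the fusion distance can be attributed differently.
* Event classification caps participants at three; denser pile-ups
  are logged but unclassified.
* Tracking is greedy nearest-neighbour, adequate at the simulated
  densities (link accuracy ≥98% under the default mobility); crowded
  scenes would need probabilistic multi-hypothesis linking, which is
  out of scope.
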