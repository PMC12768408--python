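# Methods

## Session model and geometry

A session is 30 min (default) of tracking at 30 Hz, a trial event log,
and per-unit spike timestamp lists (PL or IL). The arena is an
80 × 48 cm rectangle: the nest (N) zone lies behind a gated wall at
x = 20 cm, the encounter (E) zone is a semicircle of radius 25 cm around
the reward port at the far-wall midpoint, and everything else is the
foraging (F) zone. The E semicircle takes precedence where it overlaps
F, so zone assignment is a partition. The E radius is a package default
(configurable): it is chosen to cover the licking posture region in
front of the port. Distance-to-goal is the Euclidean distance from the
head position to the E-zone center, in cm.

Quality control: units with session-mean rate < 0.5 Hz, or at the 60 Hz
mains frequency within ±0.05 Hz (exact float equality being
meaningless), are artifacts; sessions need ≥ 10 units and ≥ 20 approach
trials per 30 min (prorated by duration). Missing tracking frames are
linearly interpolated up to 0.5 s; longer gaps stay missing and their
bins are dropped from label pairing. Time zero is the first tracking
timestamp.

## Preprocessing

Each spike train is serialized to a 1 kHz indicator vector and convolved
with a unit-sum Gaussian kernel, SD 100 ms, support 1 s. The kernel uses
1001 taps (±500 ms) so that 'same'-mode convolution is exactly centered;
zero padding at the edges. Unit sum preserves spike-count mass, so the
smoothed vector integrates to the spike count up to edge losses. The
vector is z-scored with its session-wide mean and SD — the same (mean,
SD) pair re-normalizes that unit everywhere, including event windows —
and averaged in 50 ms bins (20 points/s; mean rather than sum, which
differs only by a constant under z-scoring). Each bin is paired with the
distance and zone at the tracking sample nearest the bin center, plus
flags: door_closed (between gate close and the next gate opening),
outbound (gate opening → E entry), inbound (withdrawal → next gate
opening), critical_event (±1 s of entry or withdrawal), and
non_navigational (speed < 2 cm/s while in N).

Event windows for classification span the `window_len` = 2 s ending at
`t_event + offset`; `offset` is the window *end* relative to the event,
so offset 0 is the 2 s immediately preceding head-withdrawal and the
sweep uses offsets −8 … 0 s. Each unit contributes 40 bins; units are
concatenated into one row per trial. Trials whose window leaves the
recording are dropped with a warning.

Visit-count equalization splits the distance range into five equal-width
bins and subsamples each, without replacement, to the smallest bin
count. The spatial firing map averages the z-scored 1 kHz activity per
1 cm pixel and smooths with a 15 px Gaussian via normalized convolution
(smoothing the value map and the visit mask separately and dividing), so
unvisited pixels do not bleed zeros into the estimate.

## Distance regressor

A fully connected network maps one 50 ms ensemble vector (n_units
inputs) to distance: hidden layers (256, 128, 64) with ReLU, dropout 0.5
after the first two hidden layers, linear output; weights initialized
from N(0, 0.2), biases zero; minibatch SGD (batch 256) on MSE. Targets
are standardized internally for numerical stability and predictions
mapped back to cm. Layer-count conventions vary (counting dropout and
the output head separately gives seven layers); the architecture above
is the definition. Training is single-threaded and fully seeded. A
ridge-regression fallback with the same interface exists for fast
tests; the headline analyses use the network.

Evaluation: five-fold cross-validation stratified by zone (each fold
keeps the N/F/E proportions), out-of-fold predictions concatenated, MAE
against the paired labels. The null control shuffles the feature–label
pairing and runs the identical pipeline; since an MSE-trained
uninformative predictor converges to the label mean, the null MAE
approaches the labels' mean absolute deviation — a useful analytic
cross-check. The error heatmap averages |error| per visited pixel,
interpolates to unvisited pixels (piecewise-linear inside the convex
hull, nearest outside; degenerate collinear visit sets fall back to
interpolation along the principal axis), smooths with a 15 px Gaussian,
and reports 25 contour levels. The session-level error model
`error = β0 + β1·n_units + β2·condition + β3·site` (condition 0 =
threat/Lobster, 1 = control; site 0 = PL, 1 = IL) is ordinary least
squares; all-zero predictor columns are dropped (coefficient 0), nonzero
constant columns raise a rank error.

## Population geometry

PCA on the [n_bins × n_units] matrix; component signs are fixed by
making each component's largest-magnitude loading positive. Centroid and
within/between distances are computed in the full component space, where
they equal distances in the original unit space up to rotation;
`n_components` restricts the projection for the plotted 2-D variant
(distances in 2-D are generally smaller, a documented divergence).
Critical-event exclusion removes bins whose centers lie in the union of
[e − 1 s, e + 1 s) windows around head-entries and head-withdrawals.
Representative plotted points are the 2000 bins nearest a zone centroid,
thinned to 200 at random (seeded).

## Event-aligned unit analyses

PETHs: 80 bins of 50 ms spanning ±2 s, trial-averaged spike counts,
z-scored with the mean/SD of the gate-opening-aligned baseline vector
(when the gate opens on the rat's return the rat faces away from the
robot, making that window a neutral reference). A unit is responsive if
any bin exceeds 3σ in either direction. Zero-variance baselines exclude
the unit with a log entry.

Run-and-stop: positions smoothed with a 200 ms moving average, speed by
central differences. A run (≥ 7.5 cm/s for ≥ 2 s) pairs with a stop
(≤ 5 cm/s for ≥ 1 s) if the stop begins within one tracking sample plus
half the smoothing window of the run's end — the smoothing inevitably
produces a 1–3 sample mid-speed ramp at a sharp transition, and a
stricter one-sample rule would make detection depend on the sampling
rate. The event time is the midpoint of run end and stop start, and must
fall outside the E zone.

Clustering: the pair of (pseudo-)units with the highest Pearson
correlation between 80-bin response vectors merges into a pseudo-unit
whose response is the *unweighted* average of the two merged responses —
deliberately not member-count-weighted, so repeated merging is not
centroid linkage — until eight pseudo-units remain (exactly
n_units − 8 merges). Exact ties merge the lexicographically smallest
index pair. Pseudo-units with fewer than 50 members are artifacts.
Cluster ids are ordered by member count (1 = largest); combined types
are Type 1 = HE1∧HW1 and Type 2 = HE2∧HW2, everything else Other.
Regional proportions use a 2 × 2 Pearson chi-square (1 df, no continuity
correction).

## Outcome classification and discrimination index

Bernoulli naive Bayes (Laplace α = 1, uniform prior) on event-window
features binarized at 0 — i.e., above/below the unit's session mean; the
threshold is configurable. Stratified five-fold cross-validation;
out-of-fold predictions pooled; balanced accuracy (mean of per-class
recalls) corrects for AW/EW imbalance. The shuffled control permutes the
class labels and reruns the identical pipeline.

The class discrimination index uses the fitted per-bin Bernoulli class
likelihoods: per fold, the logs of the unit's 40 per-bin likelihoods are
summed into a joint value; the five fold values are averaged; the joint
is mapped into (0, 1) as the per-bin geometric mean before entering the
log-odds formula (the raw joint of 40 densities is far outside (0, 1)).
A `joint` variant applies the formula to the raw joint in log space; the
sign — the scientifically tested property — is identical. Positive
values mean the unit's activity profile is better explained by the AW
model. Group summaries (Type 1 / Type 2 / Other) report mean, SEM and a
two-tailed one-sample t test against zero; single-member groups are
flagged underpowered.

## Permutation importance

A unit's importance is the mean, over seeded repeats, of the error
increase when only that unit's data is permuted across samples: the
single activity column (bin-wise) for the regressor, scored as MAE
increase in cm; the whole 40-bin block (trial-wise) for the classifier,
scored as balanced-accuracy drop. Each fold's already-trained model
scores the permuted copies of its own test rows. Note a structural
property of this estimator: any fitted model places chance-level weight
on even a truly uninformative feature, and permuting that feature then
adds prediction noise, so the expected importance of a noise unit is a
small strictly positive number of order w² rather than exactly zero;
tests therefore check both statistical indistinguishability from zero
and practical negligibility (≤ 2% of a planted informative unit's
score). Ablation removes the ceil(20%) highest-scoring units and reruns
the full cross-validated pipeline against its shuffled null. The
cross-decoder comparison removes round(0.5%) of units from each tail of
each score's marginal (union) before Pearson's r.

## Synthetic generator

The generator defines the benchmark conditions. Defaults: 20 units, 40
trials, 30 min, archetype mix 40% distance-tuned / 20% type 1 / 20%
type 2 / 20% noise (largest-remainder apportionment), attack latency 3 s
with probability 0.30 else 6 s, AW probability 0.65 (the task's observed
AW proportion); `balanced_outcomes` forces exact AW/EW counts for
classification benchmarks. Trials tile the session uniformly
(duration/n_trials per trial, ≥ 14 s); locomotion speed ~ N(25, 5) cm/s
truncated at 10. AW withdrawal is uniform on [first_lick + 0.5 s,
attack − 0.2 s]; EW withdrawal is attack + reaction ~ N(0.3, 0.1) s
truncated at 0.05 s — no empirical distributions exist for these, the
values keep AW and EW kinematically distinct. The trajectory is
piecewise linear through per-trial keyframes (nest → gate → E entry →
lick port → nest) with 0.3 cm jitter; a configurable fraction of
N-zone dwell is spent stationary at a random nest spot
(non-navigational, ground-truth labeled).

Rates, at 1 kHz: distance-tuned units fire
baseline + peak·exp(−(d−d_pref)²/2w²) with baseline 2 Hz, peak 8 Hz,
width 12 cm, d_pref uniform on (5, 60) cm; type-1 units (baseline 4 Hz)
add a 10 Hz Gaussian bump (SD 100 ms) centered 200 ms before head-entry
and are suppressed to 0.4× for 2 s after entry; type-2 units (baseline
3 Hz) add a sustained step from entry to withdrawal — 6 Hz on AW trials
but 2 Hz on EW trials, making them avoidance-selective as well as
event-sustained; noise units are homogeneous 5 Hz. Spikes come from
thinning on the 1 kHz grid, matching the downstream serialization
exactly.

What the generator does *not* emulate: spike-sorting noise and drift,
refractoriness, inter-unit correlations beyond shared behavioral drive,
theta/respiratory rhythms, realistic posture or video artifacts, and
session-to-session unit turnover. Passing tests therefore show that the
pipeline recovers planted structure of the kind the analyses assume —
not that real mPFC data contain that structure, nor the real-data error
magnitudes, which also depend on an ensemble size and network
configuration outside this package's scope.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale, as the package's
own benchmark choices: decoding benchmarks use 12-unit, 14-trial, 10 min
sessions with a (64, 32)-hidden network, 30 epochs, learning rate
3e−3; classification benchmarks use 20 units × 50 balanced trials
(25 min) or 12 units × 30 trials (15 min); clustering recovery uses 300
units at noise SD 0.5; the shuffle-null benchmark averages five label
permutations per session before averaging 20 sessions, the standard
shuffle-null estimator. The importance benchmark draws the lone
informative unit's preferred distance from (20, 45) cm — the densely
sampled span of the trajectory — since a preferred distance the rat
never occupies would make the unit uninformative by construction.
Degenerate inputs are handled explicitly: zero-variance units and
baselines raise typed errors; empty flag subsets are reported missing,
not zero; collinear GLM designs raise; ties in clustering follow the
documented smallest-pair rule.

## Known limitations

Full-space PCA distances may differ from published 2-D-space values by
a scale factor; both are computable. The exact arena wall/opening
coordinates, E-zone radius, network hyperparameters and several
behavioral distributions are package defaults, all exposed in configs.
The error heatmap's scattered interpolation is piecewise-linear rather
than MATLAB's natural-neighbor default. Real-data loaders expect the
documented CSV/JSON bundle; vendor acquisition formats and spike
sorting are out of scope.
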