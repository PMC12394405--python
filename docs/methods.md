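# Methods

`taijikit` analyzes skeleton-based Tai Chi performance in four stages:
multi-view 3D reconstruction, temporal segmentation, neural quality
assessment, and rule-based error detection. This note documents the
models, the numerical choices behind them, and what the synthetic data
does and does not establish.

## Skeleton model and kinematics

The canonical layout has 32 joints (pelvis root, four-link spine to the
head, seven joints per arm, five per leg); a reduced 23-joint chain is
available by dropping the hand/foot/clavicle detail joints, with children
re-parented to the nearest retained ancestor. Positions are world-frame
meters; the ground plane is z = 0 (capture floors are planar).

Velocity and acceleration use symmetric central differences,
v(t) = (p(t+Δt) − p(t−Δt)) / 2Δt, with one-sided differences at the two
endpoint frames so derivative tracks keep the sequence length. Central
differences are exact for quadratics, odd under time reversal (velocity)
and even (acceleration); the tests exploit all three properties.

Joint rotations are compared through unit quaternions with the geodesic
angle Δθ = 2·arccos(|q·q′|), which is double-cover invariant. It is
evaluated through the chord identity Δθ = 4·asin(min(|q−q′|, |q+q′|)/2):
algebraically identical, but exact near zero where arccos loses half the
significant digits (the arccos form bottoms out around 3×10⁻⁸ rad).

The local rotation at a joint is built from the incoming bone u (parent →
joint) and outgoing bone v (joint → child): two Gram–Schmidt frames at
the same joint, one anchored on u and one on v, whose relative rotation
is the joint state. Because a global rigid motion premultiplies both
frames, deviations between performed and reference rotations are exactly
invariant to whole-body placement, while the rotation axis (the u/v
bisector) tracks flexion — a 90° vs 60° elbow reads as exactly π/6. An
earlier single-frame construction (e1 along u, e2 the orthogonalized v)
was rejected: the bend angle lies precisely in the component the
orthogonalization discards, making it flexion-blind. Bone-axis twist is
unobservable from joint positions and is reported as unavailable, never
as zero.

Center of mass is the mass-weighted joint mean with uniform masses by
default (an anthropometric table can be supplied). The base of support is
the convex hull of foot contact points projected to z = 0; signed
point-to-polygon distance (negative inside) comes from shapely.

## Multi-view reconstruction

Cameras are ideal pinholes P = K·R·[I | −C]; calibration inputs are
assumed pre-undistorted. A joint's 3D position minimizes the
confidence-weighted squared pixel reprojection error over views,
initialized by a weighted linear DLT and refined with Gauss–Newton steps
(deterministic; no seed involved). Duplicating a view with weight w is
identical to one view with weight 2w, and the solution is equivariant
under rigid world transforms applied to cameras and points — both are
tested. Near-parallel ray bundles are flagged with a condition metric
(ratio of DLT singular values) rather than silently solved.

Sequence reconstruction minimizes

    E_total = E_data + λ₁·E_smooth + λ₂·E_prior

where E_data is the weighted reprojection error (px²), E_smooth the
summed squared frame-to-frame joint displacement (m²), and E_prior a
hinge penalty max(0, θ−θ_max)² + max(0, θ_min−θ)² on configured joint
bend angles. Note the unit asymmetry: with a ~1000 px focal length at
~3.5 m range, 1 px ≈ 1 mm, so E_data is ~10⁶ × more sensitive per meter²
than E_smooth; meaningful smoothing weights are λ₁ ≈ 10³–10⁵. λ₁ = 10⁴
roughly halves frame-to-frame jitter on 2 px-noise synthetic input while
*improving* 3D accuracy. Optimization is block-coordinate descent over
frames (each frame solved by L-BFGS with its neighbors fixed); per-frame
updates are accepted only if they do not worsen the frame objective, so
the total objective is monotonically non-increasing, and an objective
increase aborts with diagnostics.

## Temporal segmentation

Motion energy E(t) = Σ_j w_j‖v_j(t)‖² with nonnegative per-joint weights
(uniform by default) drives boundary detection. Key frames are local
minima of the smoothed energy (moving average, window = window_min/2,
default 15 frames), unioned across coarser scales up to window_max/2 and
de-duplicated within min_peak_separation; plateau minima keep their first
frame. Candidates are gated to the stillness regime: a minimum qualifies
only if its smoothed energy is below the 25th percentile of the profile
(configurable). The boundary score B(t) = α·dE/dt + β·S(t) + γ·P(t) is
also provided, with S(t) the cosine similarity of the root-centered pose
vector to its value one window earlier and P(t) = exp(−‖v_COM‖); S and P
have no closed definition in the source method and are replaceable
strategy hooks. Defaults α = 1.0, β = γ = 0.5.

Segment labeling uses dynamic time warping over root-centered pose
vectors with Euclidean frame distance, cumulative cost normalized by path
length, and a Sakoe–Chiba band of 20% of the longer length (full dynamic
programming available via `band_fraction=None`; the banded and full
searches can legitimately differ on unrelated sequences, which is why
oracle comparisons use the full mode). The dynamic program is vectorized
over anti-diagonals — every dependency of diagonal s lies on s−1 and s−2.
Frame distances use direct pairwise differences (`scipy cdist`) because
the Gram-matrix expansion loses exact zeros to cancellation.

Candidate segments between consecutive key frames are validated by
minimum duration (default 25 frames), peak joint speed (default 8 m/s)
and non-trivial mean energy; valid segments take the label of the
nearest template. Segments always partition [0, T).

On 100 seeded synthetic concatenations (3–5 template units of 60 frames,
10–20-frame stillness gaps), boundary recall is 100% within ±3 frames at
zero noise and template labeling is ≥ 90% correct under 5 mm position
noise (measured 100% at the tested seeds). The ±3-frame window interacts
with the smoothing window: the first frame of a smoothed zero-plateau
sits up to (gap − window)/2 frames before the gap midpoint, which stays
within 3 frames for gaps ≤ 20 at the default window.

## Assessment network

The classifier is a spatio-temporal graph convolutional network over the
skeleton graph with a three-partition adjacency: physical bones
(symmetric), centripetal edges aggregating limb information toward the
torso root, and the identity (temporal-self) partition. Each partition k
carries a learnable edge-importance mask M_k applied elementwise to the
degree-normalized adjacency; the spatial layer computes
f_out = Σ_k (Â_k ⊙ M_k) f_in Θ_k, followed by a temporal convolution
(kernel 9) with "same-ceil" padding so T strides as 150 → 75 → 38, batch
norm, dropout 0.3 and a residual connection.

The default (full-size) architecture is: input
(32 joints × 3 coords × 150 frames), block groups of 64/128/256 channels
with strides 1/2/2, dual attention, a per-joint bidirectional LSTM
(512 units total, 256 per direction) giving the (32, 512, 38) stage,
attention-weighted pooling to a 512-d embedding, and a 512→256→4
classifier; a linear head on the same embedding provides a continuous
quality score. Attention is additive: softmax(w·tanh(W_v V + W_h H))
over joints per frame (spatial) and over frames (temporal), averaged
over heads (8 by default, dropout 0.1); spatially re-weighted features
are scaled by J so uniform attention is the identity map.

The network and its training loop run on a minimal reverse-mode autodiff
engine written for this package (tape of numpy arrays; broadcast
arithmetic, matmul, strided conv1d via im2col, reductions, softmax
family). Every primitive has a finite-difference gradient test, and the
expert-loss gradients are checked end-to-end to 1e-4.

Two adaptations make small-batch CPU training stable, and both are
implementation choices rather than model changes: (1) an input data
batch-norm over flattened (joint × coordinate) channels — standard in
skeleton-graph networks — which rescales subtle per-joint deviations to
a learnable unit scale; (2) epoch-frozen batch-norm statistics: the
population statistics of the current training pool are recomputed once
per epoch (momentum-0 calibration pass) and used for every optimization
step, so tiny batches optimize the same function evaluation sees. With
per-batch statistics at batch size 2, training-mode and eval-mode
accuracy diverged by 10–20 points.

Training: Adam at learning rate 0.001, halved when the monitored loss
fails to improve by 1e-4 for 10 epochs; batch size 2; curriculum stages
posture → transition → sequence with items added cumulatively; optional
augmentation (temporal scaling 0.9–1.1, vertical-axis rotation ±15°,
uniform scaling 0.9–1.1, Gaussian noise). All randomness flows through
one seeded generator; repeated runs are bit-identical.

The composite loss is L_total = L_acc + α·L_smooth + β·L_style +
γ·L_expert with cross-entropy accuracy, mean squared frame-to-frame
embedding difference (smoothness), one minus pose similarity to a style
reference, and the expert term

    L_expert = 0.3·L_balance + 0.25·L_flow + 0.25·L_alignment + 0.2·L_substantial

encoding weight-distribution tracking (target asymmetry 0 for symmetric
stances, 0.4 for a 70/30 bow stance), small second derivatives of joint
angles (flow), vertical spine with reference shoulder angles (alignment),
and clear substantial/insubstantial force differentiation. The
L_acc/L_smooth/L_style forms are package defaults behind the loss
interface — only the expert components have fixed formulas. The
knowledge-distillation loss is τ²·KL(p_s^τ ‖ p_t^τ); the τ² factor is
calibrated so the loss approaches a finite constant as τ → ∞ while the
raw KL vanishes (tested numerically at τ = 10³).

## Error detection

Six error categories are detected by rules on derived per-frame signals,
each compared against a temporally aligned reference (DTW-warped when
lengths differ): balance-index deviation (weight distribution), spine
inclination from vertical (spine alignment), elbow interior angle (arm
extension), knee projection past the toe line along the foot axis (knee
position), pelvis yaw on the circle (hip rotation; angle differences are
wrapped — the rest-pose yaw sits at the ±180° branch cut), and
shoulder-to-neck height (shoulder tension). Foot weights are proxied by
the COM ground projection's position along the inter-ankle line (no
force plates; a replaceable estimator). A rule fires only when its
signal exceeds the category threshold for a sustained window (0.5 s
default) — single-frame spikes are not errors. Angular thresholds are
5°, mirroring the quality rubric's innermost band; positional categories
use 3 cm (knee) and 2 cm (shoulder), and the balance index 0.2.
Severity maps the threshold-normalized deviation onto the rubric's
±5/10/15° bands (inclusive lower boundaries), so it is monotone in the
deviation by construction. Reports are sorted by normalized magnitude,
most significant first.

Stability is S = w₁·exp(−Var(COM_static)/σ_ref²) +
w₂·exp(−max excursion/d_threshold) with the static variance taken over
the horizontal (ground-plane) sway and the excursion as the maximal
positive signed distance of the dynamic COM projection outside the base
of support (zero inside). Defaults: w₁ = w₂ = 0.5, σ_ref = 5 cm,
d_threshold = 10 cm. Coordination is the mean over paired segment
signals of the maximal Pearson correlation across lags within ±25% of
the signal length.

## Synthetic data

Motion is defined in joint-angle space on a fixed rest skeleton and
realized by forward kinematics, so bone lengths are conserved to
machine precision — the generator cannot produce rubber skeletons. A
movement unit animates a subset of joints (shoulders, elbows, spine,
pelvis yaw, hips, knees) with sums of up to three sinusoids plus a
smooth polynomial drift, all scaled by a sin²(πt/T) envelope so units
begin and end at the rest pose with zero velocity; stillness gaps
between units hold the rest pose and ground-truth boundaries sit at gap
midpoints. Camera synthesis uses the circular rig the capture protocol
describes: eight cameras at 45° intervals, 3.5 m radius, alternating
1.5/2.5 m heights, ~1000 px focal length; observations are exact
projections plus Gaussian pixel noise with confidence exp(−|noise|).

Error injection perturbs a clean sequence geometrically per category
(torso-chain rotation about the pelvis, knee translation along the foot
axis, whole-body-minus-feet lateral shift, shoulder-chain raise, lower
body yaw offset, forearm rotation about the elbow flexion axis — in the
flexing direction, where the deviation stays linear in the magnitude
instead of saturating at a straight arm), confined to a frame interval
with 5-frame cosine ramps. Magnitude 0 is the identity and disjoint
injections commute.

Labeled training sets emulate one school practicing shared standard
forms: canonical movement units per curriculum stage are fixed by an
internal seed, each subject adds small amplitude (±5%) and phase jitter,
and quality classes follow the rubric's structure — worse classes carry
larger injected deviations (Good 6–9°, Fair 11–14°, NeedsImprovement
16–25°, with 6 mm per degree-band unit for positional categories), more
co-occurring error categories (0/1/2/3), and more execution jitter
(0/2/4/7 mm). Items are pelvis-centered and scaled by a fixed 1 m body
extent into [−1, 1]; a per-item maximum scale was rejected because it
destroys the absolute deviation magnitudes that carry the quality
signal.

What passing tests show — and what they do not: the synthetic conditions
establish that the geometry is exact, the segmentation recovers known
boundaries, the network has the capacity and the training loop the
signal path to learn rubric-like quality classes, and the error rules
invert the injection model. They do not establish detector-level 2D
noise statistics, occlusion patterns, soft-tissue artifacts, stylistic
between-school variation, or human rater behavior; accuracy numbers on
synthetic data say nothing quantitative about real recordings.

## Problem sizes and runtime

The shipped experiments are sized for a single CPU: 500 Monte-Carlo
points for the multi-view comparison, 100 concatenations per
segmentation condition, a 40-item training set with a 20-item held-out
draw, and a width-reduced network (16/32/32 channels, 64 LSTM units —
same topology as the full stack, which is exercised in forward mode by
the shape tests). The full acceptance run takes about seven minutes.

## Known limitations

- The engine is numpy-only; wall-clock cost grows quickly with model
  width, and large-scale training is out of scope.
- Joint rotations carry no bone-axis twist.
- The foot-weight and stability estimators are geometric proxies, not
  force measurements.
- The reconstruction prior needs configured joint-angle limits; none are
  shipped as defaults.
- DTW labeling assumes templates are representative; it has no
  open-set rejection beyond the validity rules.
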