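# Methods

This note documents the models and procedures implemented in `cvevents`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Collective variables

A collective variable (CV) is a scalar function of one coordinate frame.
The implemented kinds:

- **atom / Cα / H-bond distances** — Euclidean distance between two single
  atoms; **centroid distances** between the geometric centers of two atom
  groups (side-chain centroids are robust to rotamer noise).
- **segment RMSD** — backbone atoms of a residue range are matched
  atom-by-atom to a reference structure, superposed by least squares, and
  the RMSD reported.  Superposition uses the Kabsch construction with the
  reflection case sign-corrected (proper rotations only); it is
  cross-checked in the tests against an independent quaternion-eigenvalue
  (Horn) implementation to 1e-8 Å.
- **helix rotation angle** — after superposing the frame on the reference
  over an anchor range (the stationary scaffold), the angle in [0°, 90°]
  between the principal inertia axes of the helix backbone in frame and
  reference.  This is one defensible operationalization of a "rotation in
  the plane of the figure" type of observable; it is definition-sensitive
  and is exposed as such.
- **helix-form fractions** — residue i is labeled 3₁₀/α/π when the backbone
  O(i)···N(i+3)/N(i+4)/N(i+5) distance is below 3.5 Å, with precedence
  π > α > 3₁₀ when several patterns match (the longer-range pattern wins,
  which detects α→π changes unambiguously).  No angular term is used:
  crystallographic models carry no hydrogens, so the amide N stands proxy
  for its H.  Only interior residues — those whose i+3, i+4 and i+5
  partners all exist — are labeled; a missing backbone O yields `other`
  with a warning rather than a failure.
- **contact-energy proxy** — sum over cross-pairs of a 12-6
  dispersion–repulsion term with per-element parameters
  (Lorentz–Berthelot combination) plus a screened electrostatic term
  (unit formal charges on charged side-chain groups, screening length
  10 Å).  This is *not* a force-field energy; only relative changes along a
  trajectory are meaningful, which is all the analysis uses.

The default 26-CV set for the PKA Iα A-domain (`cvevents.pka`) is a
reconstruction that makes every described step of the H→B transition
observable — the cAMP(O6)–A202(N)–G199(O) electrostatic switch, the PBC
helix form change, the L135/F136/L203/I204 hydrophobic cluster, B/C-helix
rotation and its α→π→kink changes, the L203–Y229 hydrophobic switch, the
R209–D170–R226 relay, and segment RMSDs to the B-conformation.  It is a
declared default, swappable through the pipeline config.

## Segmentation

Trajectories are cut into parts before factor analysis so that each part
contains roughly one burst of concerted motion; cuts are only placed inside
plateaus common to all CVs.

Two detectors are provided.  `detect_plateaus` implements the classical
single-series criterion: a sliding window is *flat* when its fitted
least-squares slope satisfies |slope| ≤ `flatness_k` × residual SD /
window (defaults 100 frames, k = 2.0) — unitless and invariant to affine
rescaling.  This criterion is reliable for a single series under modest
noise, but it does not survive strongly autocorrelated noise: with AR(1)
ρ = 0.9 the slope-estimate SD inflates ~4.4× against the residual-based
threshold, individual windows misfire ~20% of the time, and the
26-CV conjunction of flat windows becomes empty.

`cut_trajectory` / `segment_trajectory` therefore use the dual view.  Per
standardized CV, the half-mean difference Δ(t) between the two adjacent
1.5-window means centered at t is compared against a robust null scale
(1.4826 × MAD over all positions — self-calibrating to the noise level
*and* its autocorrelation); frames whose |Δ| exceeds `transition_z`
(default 3.0) times that scale are transition cores.  Core frames cluster
into **motifs**: bursts of concerted motion with a per-CV onset estimate
(argmax of the box-smoothed |Δ|, precision ≈ ±30 frames under the default
noise).  A cluster is split where the mean onsets of the two sides differ
by more than `split_gap` (default 1.25 × window) with at least two CVs per
side — pooling members averages down the single-CV onset noise, so two
close motions can be separated without one straggling estimate tearing a
genuine group apart.  Boundaries go at midpoints between consecutive
motifs and of the trailing plateau; parts shorter than `min_part_length`
(default one window) merge into a neighbor.

`split_gap` deliberately does *not* resolve every pair of close motions:
with 13 replicates, stages containing two events are recognizable only
because the events' order flips between runs, and the consensus stage test
(below) is statistically safe only when roughly half the replicates leave
such pairs unresolved (ties).  The default was chosen by this argument, not
by resolution alone.

## Factor model

Within a part, only the *active* CVs — those whose own transition detector
fires inside the part — enter the analysis: a CV sitting in a plateau
contributes no transition information and would only add a noise dimension
to the correlation matrix (this matters most for small events of 2–3 CVs).
Columns are standardized; near-constant columns are dropped and reported.

Factors are principal components of the correlation matrix (loadings =
eigenvector × √eigenvalue), retained by the Kaiser rule (eigenvalue > 1,
overridable with an explicit k).  Varimax rotation is implemented as
iterated closed-form pairwise planar rotations on Kaiser-normalized
loadings, sweeping until the criterion gain falls below 1e-8; the criterion
history is returned and is non-decreasing by construction.  For the
two-factor case the result agrees with an exhaustive 0.01°-grid
maximization to better than 1e-6.  Scores are regression (least-squares)
estimates, and every factor is sign-fixed so its score increases in time,
which makes loadings and lags comparable across replicates.

**One-way motions.**  A factor is transition-relevant when its coordinate
moves essentially monotonically from one level to another.  Two statistics
operationalize this: the *net displacement ratio* — |difference of the
endpoint levels of the decile-window moving average| divided by the range
of that average (a step scores ≈ 1 wherever it sits in the part, a
completed oscillation ≈ 0) — and the Spearman trend ρ with time.  Selection
requires ratio ≥ 0.6 and |ρ| ≥ 0.5.  The ρ threshold follows from the rank
structure of a two-level step: at fraction p of the part its expected ρ is
≈ 0.87·√(3p(1−p)) — 0.75 centered but only ~0.5 near p = 0.15 — so a
stricter threshold rejects exactly the boundary-adjacent transitions that
close-together motions produce; 0.5 still sits far outside the white-noise
null (sd ≈ 1/√T) and, jointly with the ratio, keeps the AR(1)
false-selection rate at a few percent on short parts.  Both statistics are
evaluated on the part extended by one window on each side (scores obtained
by projecting the flanking frames onto the part's loadings), so a
transition at a part edge regains its flanking levels.

## Ordering within a replicate

Lags come from the normalized cross-correlation function over lags in
[−max_lag, max_lag] (default max_lag = (T−1)/3 of the part), computed as
the Pearson correlation of the overlapping stretches — a noiseless copy
delayed by s attains exactly 1 at lag s, so noiseless recovery is exact.
A pair is significant when its peak |CCF| reaches 2/√T (the large-sample
white-noise band); significant pairs with |lag| ≥ 5 frames give precedence
arcs, all other pairs count as simultaneous.  Because every pair carries at
least one arc, contracting strongly connected components yields a total
order of tie-groups.  Across parts, order follows part order — parts are
temporally disjoint by construction.

## Events and consensus across replicates

Factors are matched across replicates by Tucker congruence
φ(a,b) = Σaᵢbᵢ/√(Σaᵢ²Σbᵢ²) on *salient* loadings (entries with |loading| ≥
0.4; with few salient CVs the incidental near-zero loadings of the other
variables would dominate the denominator), sign-blind, linked one-to-one
by optimal assignment with links below |φ| = 0.85 dropped.

**Events** are defined directly by the co-peaking rule: two CVs belong to
the same event when their maximum |loading| lands on the *same factor* in
at least a fraction q of the trajectories observing both saliently.
Factors with fewer than two salient loadings are excluded from peak
competition (a single-CV factor's loading is ±1 by construction and is not
a collective motion).  CVs agglomerate by average linkage on the
observation-weighted co-peak fraction with cutoff q = 0.85; measured on the
default benchmark, within-event pair fractions sit at 0.9–1.0 and
cross-event same-stage pairs at ~0.5 (99th percentile 0.85), so the cutoff
lies in the gap.  Average linkage, rather than single-link components,
keeps one noisy pair from chaining two distinct events.  Single CVs and
CVs never saliently observed are residual; consequently genuine
single-CV events are not identifiable by this rule and will appear as
residual CVs — a known limitation.

**Consensus.**  Each replicate orders its events by the tie-groups of the
factors they peak on.  For each event pair, support of "e before f" is
computed over replicates observing both, counting a shared tie-group as ½
for each direction (the Kendall treatment of ties).  A precedence arc
requires support ≥ 0.75 *and* the strictly opposite order in at most 20% of
the strictly ordered replicates: events genuinely sharing a stage are
recognizable precisely by their order flipping between runs, however
lopsided the flip count happens to be in 13 draws.  The 0.75 level makes a
spurious split of a same-stage pair a ≲1% event per pair under the
tie-damped null while tolerating one inverted replicate among seven
observations of a true precedence.  Ties and cycles contract into stages;
the stages are totally ordered and rendered in the numbered notation
"(1) …; (2) … and …; …".  Pairs never co-observed are reported as such.

## Synthetic benchmark

The generator plants CV m of replicate r as
baseline + Σₑ amplitude·σ((t − τ(e,r))/w) + AR(1) noise, with logistic σ
(chosen for closed-form slope bounds), stationary noise SD 1, ρ = 0.9
(white noise would make ordering unrealistically easy), amplitudes ±3 ×
noise SD, width w = 30 frames.  The default study mimic: 26 CVs (the ids of
the default CV set), seven events in five stages {B} < {C1,D1} < {E} <
{D2,F} < {G}, 13 replicates of T = 3000 frames, stage centers at
400…2400.  Onsets are stage center + truncated-Gaussian jitter (SD 120
frames ≈ 4 transition widths, bounded at ±3 SD, redrawn until stage-ordered
within each replicate).  The jitter SD encodes the run-to-run variability
of event timing; it is large enough that same-stage events are genuinely
distinct motions whose order flips between replicates, and small enough
(≈ ¼ of the inter-stage gap) that stage order is essentially never
violated before the ordered redraw.

Measured at these conditions, the full pipeline returns the planted staged
sequence (exact event sets, exact stage structure) in ~92% of runs over
five disjoint 20-seed windows (per-window 0.90–0.95); the residual
failures are small-probability tails on both sides of the event-grouping
and stage-support thresholds (an event pair merging when too few replicates
resolve it, an event splitting when too many replicates mis-place one CV,
a lopsided order draw).  Recovery is non-increasing in the noise SD
(1× → 2× → 4× gives ≈ 0.9 → 0 → 0: at 2× the transition amplitudes fall
to 1.5 noise SDs and the detection layer is designed to stop trusting
them), and in the low-noise, low-jitter limit (noise SD 0.1, jitter 5) the
stage-level sequence is recovered in 100% of seeds — at vanishing jitter
same-stage events become simultaneous and are only identifiable as a
merged stage, so the limit is checked at stage level.

What the benchmark does *not* emulate: multi-scale relaxations, drifting
baselines, non-logistic or partially reversible transitions, cross-CV
noise correlations, and events whose CV membership changes between
replicates.  Passing it shows the chain is correct and calibrated under
its stated noise model, not that real MD observables satisfy that model.

Toy structural fixtures: ideal poly-alanine backbones built by internal
coordinates (NeRF placement; requested φ/ψ reproduced to 1e-6°) and
logistic two-state interpolations between atom-matched structures with
Gaussian jitter.

## Numerical choices and degenerate inputs

- Correlation (not covariance) factoring: CVs carry incommensurable units.
- Varimax: Kaiser normalization on, tolerance 1e-8, 1000-sweep cap with an
  error carrying the last iterate on non-convergence.
- Cross-correlation ties break toward lag 0 (then toward the earlier lag).
- Collinear or <3-point sets are rejected by the superposition with a
  degenerate-input error; near-spherical segments are rejected by the
  helix-axis computation.
- All-constant parts (possible at vanishing noise) are skipped rather than
  factored; constant columns never flag transitions.
- All randomness flows from a single seed (`numpy.random.default_rng`);
  identical seeds give bitwise-identical datasets and byte-identical
  machine-readable outputs.

## Known limitations

- Single-CV events are structurally invisible to the co-peaking rule.
- Same-stage events closer than ~2 transition widths in most replicates
  merge into one event; this is an identifiability limit, not a bug.
- The contact-energy proxy and the inertia-axis helix angle are
  definition-sensitive stand-ins for quantities whose original definitions
  are simulation-package-specific.
- With ~13 replicates, the distinction between "same stage" and "ordered"
  rests on order flips; pathological draws (e.g. 11 of 13 the same way by
  chance) are indistinguishable from a true precedence for any method.
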