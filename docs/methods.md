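# Methods

`bindnet` implements a graph-theoretic analysis chain for two-condition,
within-subject task fMRI, aimed at the question of how feature binding in
working memory is supported by coordinated activity across brain regions. It
compares a *binding* condition (the conjunction of color and location must be
maintained) against an *either-memory* condition (both features held, only
one retrieved), using per-participant functional networks rather than
univariate activation. This note records the models, the parameter choices,
the numerical conventions, and what the synthetic generator can and cannot
establish.

## Network construction

For each participant and condition, regional time series (voxel averages
within each parcel of a 200-region parcellation by default) are correlated
pairwise (Pearson), giving an N x N FC matrix with unit diagonal. Two-step
thresholding then produces a comparable binary topology per participant:

1. **Spanning-tree backbone.** The maximum-weight spanning tree of the
   correlation graph (equivalently, the minimum spanning tree of distance
   1 − r) guarantees a connected, acyclic N−1-edge scaffold: 199 edges at
   N = 200. Implemented as Kruskal's algorithm over edges sorted by
   (−r, i, j); the lexicographic tie-break makes the output bit-reproducible
   across platforms. Edges are ranked by signed correlation (strongest
   positive first); an absolute-value mode is available via a flag.
2. **Fixed-density densification.** The strongest non-tree edges are added
   until ⌈s·N(N−1)/2⌉ edges are present (s = 0.10 by default: 1990 edges at
   N = 200). Ceiling rounding reproduces that count exactly and never
   under-connects; if the target falls below N−1 the tree itself is returned
   and the density raise is logged. The backbone is always retained, so the
   result is connected at every admissible density.

The binary mask multiplied elementwise with the FC matrix (diagonal zeroed)
gives the weighted thresholded network. No Fisher z-transform is applied
before group statistics — the group comparisons operate on raw connection
weights, matching how such weights are conventionally reported; a
z-transform could be added by the caller before `apply_mask` if desired.

## Local efficiency and the nodal comparison

Local efficiency of node v is computed on the **binary** mask:

    E_loc(v) = 1/(|N(v)|(|N(v)|−1)) · Σ_{i≠j ∈ N(v)} 1/d_ij

with d_ij the unweighted shortest-path length between neighbors i and j
inside the subgraph induced by N(v) (breadth-first search). Unreachable
pairs contribute 0 through the 1/∞ convention, and nodes with fewer than two
neighbors score 0. The formula counts edges, so the weighted matrix plays no
role here; a weighted variant is deliberately out of scope. E_loc is bounded
in [0, 1], invariant under relabeling, and monotone under adding edges among
a node's neighbors — all verified by property tests against an independent
brute-force implementation.

Group inference is a paired t-test per region (binding − either) across
subjects, two-tailed, corrected across all regions with Benjamini–Hochberg
at q = 0.05; a region is called significant when it survives FDR with
positive t. Two-tailed raw p-values with direction read from the sign of t
match a whole-brain search in which either direction would have been
reported; a one-tailed mode is configurable.

## Network-based statistic

On the subnetwork of interest (by default the FDR-significant regions of the
nodal comparison; an explicit node list can override), edge-wise paired
t-tests produce a t-matrix over the edge universe — the union of the
subjects' thresholded-network masks restricted to the subnetwork, with
absent edges carrying weight 0. Edges with p < 0.05 in the configured tail
(default "greater", binding > either, the direction of interest; two-sided
available) are kept and grouped into connected components; a component's
size is its edge count.

Significance is at the component level. Because the design is within-subject,
the exchangeable null swaps each subject's condition labels independently —
a sign flip of that subject's paired differences — sampled uniformly with
replacement from the 2^n possibilities. Each of n_perm (default 10,000)
permutations records the maximal component size under the same primary
threshold; an observed component's p-value is the add-one estimator
(1 + #{null max ≥ size})/(1 + n_perm), which cannot return zero. The engine
is vectorized: under sign flips Σd² per edge is invariant, so the permuted t
depends only on the flipped mean and all permutations are computed in one
matrix product.

Two properties of this test worth knowing: it controls the family-wise error
weakly at the component level, and because component sizes are small
integers its attainable significance levels are discrete — the realized
false-positive rate at α = 0.05 sits slightly **below** 0.05 (the
calibration suite measures ≈ 0.02 at the 12-subject, 20-region scale it
runs), conservative rather than anticonservative. Per-edge follow-up tests
within each component use paired t with BH correction over that component's
edges only.

## Intrinsic neural timescales

For each region the sample autocorrelation function is estimated with the
denominator-T (biased) convention, which guarantees |ρ̂(k)| ≤ 1 and
ρ̂(0) = 1. The intrinsic timescale is

    τ = TR · Σ_{k=0}^{L−1} ρ̂(k),

where L is the first lag at which ρ̂ becomes non-positive. The lag-0 term is
included — the sum is the area under the ACF curve before it hits zero — so
τ ≥ TR always. If the ACF never turns non-positive within max_lag (default
⌊length/2⌋) the whole curve is summed and a truncation warning is raised;
the truncation lag is always reported. For an AR(1) process with coefficient
φ the population value is TR/(1−φ) (e.g. 3.0 s at φ = 0.5, TR = 1.5 s); the
estimator recovers the planted φ ordering and lands within its Monte-Carlo
tolerance of that geometric sum in the acceptance suite, with a small upward
bias from the stochastic truncation lag at moderate series lengths.

In the pipeline, ACFs are computed on trial-averaged series: windows of 10
TRs (15 s, fixation through test onset) starting at the frame nearest each
fixation onset, averaged across trials per region. Per-subject timescales
are computed first and compared across regions afterwards (paired t on every
region pair, BH-corrected) — the alternative of averaging ACFs across
subjects before summing was rejected to keep subject-level variability in
the inference.

## Behavior

Sensitivity is the equal-variance signal-detection d′ = Φ⁻¹(H) − Φ⁻¹(F).
Perfect rates are corrected with the log-linear rule by default (+0.5 to
both numerators, +1 to both denominators, applied unconditionally); a
clamping rule (rates restricted to [1/2n, 1−1/2n]) is available. Mean RT is
taken over correct trials only, the conventional choice for change
detection, and configurable. The 2×2 repeated-measures ANOVA
(condition × set size) uses the classical within-subject sums-of-squares
decomposition; each df-1 effect is tested against its subject-by-effect
interaction, which makes F identical to the squared paired t on the
corresponding within-subject contrast (checked numerically), with partial
η² = SS_effect/(SS_effect + SS_error).

Motion QC uses framewise displacement FD_t = Σ|Δtrans| + 50 mm·Σ|Δrot|
(rotations in radians projected on a 50 mm sphere), with FD_1 = 0 so the
series aligns with frames and the mean taken over frames 2..T; subjects with
mean FD > 0.5 mm are excluded, each decision logged.

Brain–behavior coupling is Spearman correlation (mid-ranks for ties, p from
the t-approximation, appropriate at n = 40; a permutation mode exists for
very small samples) between each component edge's weight and the subject's
mean binding-condition RT, BH-corrected across the tested edges.

## The synthetic generator

The generator defines the study conditions every test runs under: 40
subjects, 200 regions, TR = 1.5 s, 72 trials per condition (three runs of
24; fixation 0.5 s + memory 0.5 s + delay 6.5 s + test 2.0 s + feedback
1.0 s + ITI ∈ {4.5, 6.0, 7.5} s ≈ 792 frames), set sizes 3 and 6 balanced
with 50% change trials per cell.

* **Connectivity.** Innovations are multivariate Gaussian with a target
  correlation matrix: base_r = 0.2 off-diagonal, raised by delta_r = 0.15 on
  the planted edges in the binding condition. The defaults plant the full
  28-edge clique on regions 0–7, emulating a subnetwork of eight core
  regions with stronger coupling during binding. Real FC magnitudes are not
  reported for this paradigm, so base_r and delta_r are generator choices —
  moderate positive background coupling with a detectable but not trivial
  planted increment. If the target matrix is indefinite after planting it is
  repaired by clipping negative eigenvalues at zero and renormalizing to
  unit diagonal (the simplest reproducible repair), and the repair is
  logged.
* **Temporal structure.** Innovations pass through per-region AR(1)
  recursions with coefficients φ linearly spaced 0.2–0.8 (the planted
  heterogeneity the timescale estimator must recover), then each region is
  standardized. AR filtering shrinks the realized zero-lag correlation
  relative to the innovation target by
  √((1−φ_i²)(1−φ_j²))/(1−φ_iφ_j); `ar_filtered_correlation` computes this
  analytically and the moment-fidelity tests use it as the oracle.
* **Behavior.** d′ per cell defaults to 2.8/1.8 (either, set sizes 3/6) and
  2.4/1.2 (binding) — worse for binding and for larger set sizes, the
  qualitative pattern the task produces — with the relative criterion c = 0
  (decision threshold at d′/2, the standard convention; an absolute
  threshold at 0 would push hit rates into the ceiling at realistic trial
  counts and shrink recovered d′). RTs are log-normal, slower for binding
  (medians ≈ 1.05 s vs 0.9 s, σ = 0.25).
* **Individual differences.** Each subject's planted coupling increment is
  scaled by a multiplier ~ 1 + 0.25·z (clipped to [0.25, 1.75]); the binding
  log-RT location shifts by 0.4·(multiplier − 1), planting a positive rank
  correlation between planted-edge weights and RT across subjects — the
  structure the brain–behavior stage is meant to detect.
* **Motion.** Bounded Gaussian random walks on 3 translations (0.01 mm
  steps) and 3 rotations (2·10⁻⁴ rad); the high-motion flag scales steps
  15-fold, which puts mean FD above the 0.5 mm exclusion threshold
  essentially always.
* **Determinism.** One master seed; every (subject, condition, purpose)
  triple draws from its own `numpy` SeedSequence spawn key. This is the
  collision-free equivalent of fixed-offset substreams: panels, motion,
  events and behavior can be regenerated independently and bit-identically,
  and the pipeline's manifest (settings + seed) reproduces every table
  byte-for-byte.

**What the generator does not emulate:** hemodynamic response convolution,
physiological noise, scanner drift, spatial autocorrelation between
neighboring parcels, non-Gaussian BOLD amplitude distributions, and
condition-dependent motion. Passing tests therefore demonstrate that the
*estimators and inference machinery* behave as specified under a faithful
statistical abstraction of the design — not that real BOLD data would yield
these effect sizes.

## Problem sizes in the test and acceptance suites

The suites scale designs down so the full run stays fast while keeping each
statistical claim meaningful: the printed network counts use the full
200-region scale; NBS type-I calibration uses 200 replicate null datasets of
12 subjects × 20 regions with 1000 permutations; NBS power uses 50
replicates of 20 subjects × 10 regions with a planted 3-edge path
(delta_r = 0.5 over base 0.2, 400 frames — long enough that fixed-density
edge selection is stable across subjects, which is what component
recovery requires); nodal recovery uses one seeded 40-subject, 50-region
run with the 8-region planted clique; timescale recovery uses 40 subjects
with φ ∈ {0.2, 0.5, 0.8} over 600 frames. These sizes are the package's
documented operating points for its own validation.

## Known limitations

* E_loc is binary-only by design; weighted local efficiency is not offered.
* The NBS edge universe treats an edge absent from a subject's thresholded
  network as weight 0; edges present in only a handful of subjects produce
  heavy-tailed paired differences, which inflates null component sizes and
  costs power at small samples. Longer series (more stable edge selection)
  or denser networks mitigate this.
* How continuous series should be spliced from correct trials only before
  FC estimation is left to the caller: the pipeline correlates whole
  condition runs. Epoch concatenation would be the alternative and is the
  reason `parcel_average`/`fc_matrix` accept arbitrary frame ranges.
* The trial-averaged ACF in the pipeline uses 10-TR windows, so timescales
  there are truncated at lag 5; the standalone estimator on full series is
  the appropriate tool when absolute timescale values matter.
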