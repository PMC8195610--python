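# Methods

This note documents the models, defaults and numerical choices behind
`xfaces`, and what the synthetic-data tests do and do not establish.

## Style space and morphing

A clip is a marker trajectory: an array of shape (frames × markers × 3) in
the arbitrary units of the capture system, at a fixed frame rate. Morphing is
defined as the frame-wise convex combination of four prototype clips after
uniform time normalization (per-marker linear interpolation over normalized
clip time [0, 1]; default common length 150 frames ≙ 5 s at 30 Hz). The
bilinear weight map from style coordinates (e, s) ∈ [0, 1]² guarantees that
lattice corners reproduce the prototypes bit-for-bit — this corner identity,
together with exact linearity (superposition to 1e-9), is the testable
contract of the morphing operation. The implementation deliberately uses a
deterministic linear space-time morph: no probabilistic trajectory model and
no nonlinear time warping. Prototypes with different expressive peak timings
are therefore blended, not aligned; the synthetic prototypes include peak
timing differences precisely so that downstream measures are exercised under
that regime.

Neutral-morphing is the same operation against a neutral clip with weight
(1−λ). λ = 1 leaves the expression unchanged; λ = 0 gives the neutral clip.

## Synthetic data: what it emulates, and what not

The generator fabricates the two inputs the analysis consumes.

*Prototype clips.* 43 markers in a schematic face layout with named regions
(brows, eyes, nose, cheeks, an 8-marker mouth ring, jaw, chin, ears). Each
prototype displaces a region-specific field scaled by a raised-cosine
activation a(t) = (1 − cos 2πu)/2 with u = t^γ, so every clip runs
neutral → expressive peak → neutral with first and last frames exactly
neutral. The per-prototype patterns encode coarse, qualitative species
differences — monkey prototypes move the ear markers and open the mouth more
strongly; human prototypes are brow-dominated — and peak-timing exponents
γ ∈ [0.75, 1.25] stagger the expressive peaks. Amplitudes (default peak
displacement 10 units on a ~120-unit-wide face) are *not* calibrated to any
real motion-capture statistics; they are placeholders with realistic orders
of magnitude. Passing tests therefore demonstrate correctness of the
computational chain, not fidelity to real facial kinematics.

*Observer responses.* Trial-level four-class responses are drawn from a
ground-truth softmax over (e, s). The default coefficient table points each
class's log-odds at its own corner with slope 4 on centred coordinates,
giving ≈95% correct classification at the corners and maximal ambiguity at
the center — the qualitative structure of trained human observers. Defaults:
20 participants × 10 repetitions per cell, four avatar × view conditions
sharing one ground truth (so condition comparisons are null by construction;
per-condition overrides create alternatives). One integer seed governs both
marker jitter (off by default) and response sampling.

## Expressiveness measures

All three measures are non-negative, zero on static input, and operate on a
2D projection (orthographic drop of z for the front view; an optional
rotation about the vertical axis by 30° mirrors the rotated presentation
view).

* **MF** sums ‖Δ(x, y)‖ over consecutive-frame pairs and markers (a sum, not
  a mean, so units are coordinate units). Against a static neutral it is
  exactly linear in λ and absolutely homogeneous in displacement amplitude.
* **DF** stacks the in-region (x, y) coordinates of a frame into one vector
  and takes the maximum over frames of the Euclidean distance to the stacked
  neutral pose.
* **OF** renders marker clips to grayscale Gaussian-blob frames and sums the
  mean Horn–Schunck flow magnitude over frame pairs. The Horn–Schunck solver
  uses the classic 2×2×2 derivative stencil, the 8-neighbour weighted
  averaging kernel and Jacobi iterations; defaults α = 1.0, 100 iterations.
  Accurate magnitude recovery on sparse blob images needs a weaker smoothness
  prior and more iterations (the translation checks use α = 0.1, 1000
  iterations); with defaults the measure is proportional rather than
  calibrated, which is sufficient for equilibration since only the
  λ-dependence is inverted.

Region masks are marker-id lists (e.g. the mouth ring) so the analysis can be
restricted to a facial region.

## Equilibration

The measure is sampled along λ (default 11 equidistant values in [0, 1]) via
neutral-morphing, fitted with the logistic M(λ) = a₀ + a₁/(1 + exp(a₂λ + a₃))
by least squares (multi-start over four initializations; constant samples are
flagged degenerate with a₁ = 0), and inverted in closed form, with a
bracketed root-finding fallback if the fitted curve is non-monotone on a
101-point grid. Because blending toward neutral can only *reduce* a measure,
the common target is the measure of the least expressive prototype, which
keeps λ = 1; the fitted curve may undershoot a measured value by its
residual, so targets are clipped into the curve's attainable range, and
prototypes already at the target keep λ = 1. The contract is that achieved
measures match the target to 1% relative tolerance.

Note that equilibrating the four prototypes does not equalize the measure
across the whole morph grid: interior morphs average partially opposing
displacement fields and lose motion energy, so the grid standard deviation
shrinks (strictly, whenever prototype measures differ by more than ~5%) but
does not vanish.

## Discriminant model and model selection

The softmax GLM is fitted by maximum likelihood (statsmodels MNLogit, Newton
iterations), with class 4 (monkey-fear) as the zero-coefficient reference;
reported surfaces are invariant to that choice. Complete separation is
detected (non-finite or exploding coefficients, |β| > 50) and handled by a
direct L-BFGS fit with a tiny ridge penalty (1e-6), flagged on the model.
BIC is k·ln n − 2·lnL with k = 3 coefficients per predictor; accuracy is
in-sample argmax accuracy (no cross-validation by default — an explicit
design choice, since the trial counts here make optimism negligible for
nested comparisons).

Stepwise selection walks the candidate sets {1} ⊂ {1,e} / {1,s} ⊂ {1,e,s} ⊂
{1,e,s,e·s} / {1,e,s,flow} in order; a candidate displaces the best accepted
model only if accuracy does not decrease *and* BIC does not increase. On data
with independent e and s effects and no interaction this selects {1,e,s} as
the most compact adequate model. The optional `flow` predictor is the mean
optic flow per stimulus, z-scored across the lattice and joined to trials by
cell.

## Tuning functions

D_M(s) integrates the two monkey-class surfaces over e; D_H(s) integrates the
two human-class surfaces at 1−s, so both category centers sit at s = 0 and
the curves are directly comparable. All integrals use composite Simpson
quadrature on 101 nodes per axis (the node count makes q and the tuning
curves reproducible to fixed precision). The tanh sigmoid
(tanh ω(s−θ) + 1)/2 satisfies D(θ) = 0.5 by construction; fits are
initialized at the interpolated 0.5 crossing with ω from twice the local
finite-difference slope, and samples that never cross 0.5 are flagged
degenerate rather than fitted. The slope at threshold is ω/2; steeper
(larger |ω|) means narrower species tuning.

## Condition comparison

The variance ratio q = Σ_k Σ_j ∬(P_kj − P̄_j)² / (K Σ_j ∬ P̄_j²) · 100 is
evaluated by 2D composite Simpson on the 101×101 surface grid; it is zero iff
all condition surfaces coincide and is invariant to condition order and to
consistent class relabeling. The per-cell contingency test uses the Pearson
χ² p-value when all expected counts are ≥ 5 and otherwise a parametric
bootstrap: each condition's responses are resampled from the pooled class
distribution, the χ² statistic recomputed per replicate (B = 10 000 by
default), and p = (1 + #{χ²* ≥ χ²_obs})/(B + 1). Classes with zero total
count are dropped from the table; a table with all mass in one class is
reported as trivially independent (p = 1). The Bonferroni family is the set
of lattice cells in one comparison (25 for the 5×5 design), at α = 0.05.

## Problem sizes

The default study conditions — 25 cells, 20 participants × 10 repetitions,
four conditions — give 20 000 trials and fit in well under a second per
model. Calibration checks use 100 recovery replicates, 2000 null contingency
tables and B = 10 000 bootstrap replicates; the optic-flow predictor used in
stepwise comparison subsamples clips temporally (every 10th frame) because
flow on the full 150-frame clip adds nothing to the z-scored per-cell
covariate.

## Known limitations

* Morphing is strictly linear in space-time; any nonlinear alignment present
  in the original stimulus-generation machinery is out of scope, and the
  corner-identity property is the contract tested instead.
* The synthetic face is schematic: no mesh, no anatomy, no calibrated
  kinematics; OF operates on blob renderings rather than photoreal frames.
* Equilibration can only scale expressiveness downward (λ ≤ 1); a prototype
  below the target cannot be amplified.
* Mixed-model ANOVAs on θ/ω across experiments and related off-the-shelf
  tests are intentionally not reimplemented; the pipeline exports tidy tables
  for external statistics tools.
* An asymmetry index of the discriminant surfaces about the style axes is
  not computed; no defensible formula was available to implement.
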