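# Methods

## Decision models

A Trustee receiving `I·M2` tokens (investment `I` of a 10-token endowment,
true multiplier `M2`) chooses an integer return `S2 ∈ {0, …, I·M2}`. Three
utility sources are defined per trial:

* payoff fraction `π₂ = (I·M2 − S2)/(I·M2)` — the share of the pot kept;
* guilt `Guilt₂ = ((E₂(E₁(S₂)) − S2)/(E₁(M₁)·I))²` — squared normalized
  shortfall from the Investor's expectation, where `E₁(M₁)` is the
  multiplier the Investor believes applies and the second-order
  expectation is fixed at half the believed pot,
  `E₂(E₁(S₂)) = ½·E₁(M₁)·I`, for every participant;
* inequity `Inequity₂ = ((I·M2 − S2)/(10 − I + I·M2) − ½)²` — squared
  deviation of the Trustee's final share of all tokens in play from an
  even split.

The four models are greed (`U = π₂`, no parameters), inequity aversion
(`U = π₂ − Θ·Inequity₂`), guilt aversion (`U = π₂ − Θ·Guilt₂`), and the
moral-strategy model
`U = Θ·π₂ − (1−Θ)·min(Guilt₂ + Φ, Inequity₂ − Φ)`. In the MS model Θ
(unitless, [0, 0.5]) trades payoff against the moral term and Φ (unitless,
[−0.1, 0.1]) biases the min operator toward guilt (Φ < 0) or inequity
(Φ > 0); at Φ ≈ 0 the Trustee honors whichever obligation is cheaper on
each trial, the moral-opportunist pattern.

**Inequity exponent.** The inequity term is squared, mirroring the
explicitly squared guilt term; a linear deviation would make the term
sign-ambiguous and destroy the zero-at-even-split property.

**Integer strategy space.** Token counts are integral, so predictions are
the exhaustive argmax over `{0, …, I·M2}` — no continuous relaxation, no
optimizer error in the prediction itself. Ties break toward the smallest
`S2` (the Trustee's own payoff), applied with an absolute utility
tolerance of 1e-9: mathematically tied strategies otherwise land ~1e-17
apart depending on floating-point summation order, whereas genuine utility
gaps between integer strategies are ≥ ~1e-5 on this scale. Trials with
`I = 0` leave payoff and guilt undefined (zero denominators) and are
excluded from prediction and fitting; the only feasible action there is
returning nothing.

**Unitary-model bounds.** The MS grid domain fixes Θ ∈ [0, 0.5] and
Φ ∈ [−0.1, 0.1] for fitting. The unitary GA/IA weight lives on a different
scale: a guilt-branch MS Trustee with payoff weight Θ_MS behaves exactly
like a GA Trustee with weight `(1 − Θ_MS)/Θ_MS`. Spanning the MS grid down
to its Θ resolution of 0.005 requires weights up to ≈199, so the unitary
bound is [0, 200]. A tighter bound demonstrably underfits strongly
guilt-averse behavior and would distort AIC comparisons for reasons of the
bound rather than the models.

## Fitting

The SSE objective (squared residuals between argmax predictions and
observed integer returns) is piecewise constant in the parameters, so
gradient-based refinement has a zero numerical Jacobian almost everywhere.
`TrusteeModel` therefore evaluates a dense batch of uniform random starts
within the bounds (default 1000; the batch is vectorized over parameter
rows) and polishes the best start with a pattern search whose step halves
from 1/16th of each bound range down to ~1/8000th. The polish only accepts
strict improvements, so the fit is never worse than the best raw start.
Fits are reproducible: population-level fitting derives a per-participant,
per-model child seed from one top-level seed, so any single fit can be
re-run in isolation.

AIC is `n·ln(SSE/n) + 2k` with `n` the feasible trial count and `k` the
number of free parameters (2 for MS, 1 for GA/IA, 0 for greed).
Participants with any model's SSE below 10 are flagged and omitted from
AIC comparisons (the log degenerates) but remain classifiable.

## Strategy classification

The MS model is simulated at 101 × 101 equidistant (Θ, Φ) points over the
stimulus set of all investments `I ∈ {1..10}` × multiplier conditions
(raw predicted token returns, one 30-dimensional vector per grid point for
a three-condition game). Grid rows are grouped by Ward hierarchical
clustering on Euclidean behavior distance, and each cluster is labelled by
the nearest archetypal pattern: greed returns nothing; guilt aversion
returns `½·E₁(M₁)·I` (half-steps rounded down, matching the argmax
tie-break); inequity aversion returns the even split
`(I·M2 + I − 10)/2`, clipped to the feasible range; opportunism returns
the elementwise cheaper of the two obligations. The dendrogram is cut
adaptively — the smallest cut ≥ 4 whose labels cover all four strategies,
merging same-labelled clusters — which lands at 4 clusters for the
×2/×4/×6 game and 5 (two greedy sub-clusters merged) for ×4/×6/×8 and the
false-belief game. The archetypes are used only to *name* clusters; the
boundaries come from the clustering, which sees model simulations and
never participant data, so rebuilding a map with the same configuration is
bit-identical. Participants are labelled by the nearest grid point to
their fitted (Θ, Φ), exact midpoints resolving toward the lower-Θ, then
lower-Φ point.

The archetype labels describe cluster centers, not every member: because
the payoff term shades behavior everywhere in the parameter space, zone
edges contain graded behavior (a greedy-zone Trustee at Θ = 0.5 still
returns a few tokens on the richest ×6 trials, and guilt-zone points at
moderate Θ switch to the inequity branch on low-investment raised-
multiplier trials). Tests of zone behavior therefore assert the behavioral
claims — near-zero returns, expectation-tracking under a dominant moral
weight — rather than literal archetype identity. Exact zone boundary
shapes depend on the linkage criterion and are not a target of this
package; zone orientation (guilt aversion at low Φ, inequity aversion at
high Φ, opportunism near Φ = 0, greed at high Θ) is asserted.

## Stability statistics

Stuart–Maxwell tests marginal homogeneity of a k×k paired-label table via
`X² = d′S⁻¹d` on the first k−1 marginal differences with
`Sᵢᵢ = rowᵢ + colᵢ − 2nᵢᵢ`, `Sᵢⱼ = −(nᵢⱼ + nⱼᵢ)`, df = k−1; for k = 2 it
reduces exactly to McNemar's statistic. A singular covariance (e.g. an
unused category) falls back to the Moore–Penrose inverse with rank-based
df, flagged in the result. Pearson correlations, chi-square independence
tests (plain Pearson statistic, no continuity correction), paired t-tests
and OLS residualization delegate to scipy/numpy. All p-values are
two-sided; Bonferroni (multiply by the number of pairwise tests, cap at 1)
is the only multiplicity correction. Trait correlations take generic
trait vectors; questionnaire scoring is out of scope.

## Synthetic populations

Agents embody the MS model: each holds a (Θ, Φ) pair drawn uniformly from
the grid points of its strategy's zone that lie at least `margin` grid
steps (default 3, a Chebyshev neighborhood on the 101 × 101 grid) from any
differently-labelled point. The default mixture is 40% inequity-averse,
10% guilt-averse, 40% opportunist, 10% greedy — the composition reported
for student samples on this task family — with counts by largest-remainder
rounding. Blocks have exact condition counts (20/40/20 for the 25/50/25
design), a seeded stratified shuffle, and investments uniform on {1..10}
(the original studies replayed pre-recorded investments whose distribution
is not published; `I = 0` is excluded as degenerate). Returns are the MS
argmax plus additive Gaussian noise (default sd 1 token), rounded and
clipped to the feasible range — additive token noise keeps SSE-based
fitting well-posed, unlike a softmax choice rule, which is out of scope.

Multi-block studies reuse one investment sequence across blocks and sample
agents from the **intersection** of the zone interiors of every block's
map: zone boundaries move with the multiplier set, so an agent sampled
from a single map could sit on the wrong side of another context's
boundary, changing its label deterministically and breaking marginal
homogeneity by construction rather than by behavior.

What the generator does not emulate: heterogeneous second-order
expectations (fixed at the half-pot rule for everyone), investment
distributions skewed toward high trust, learning or sequential effects
across single-shot trials, and within-person motive drift. Passing
recovery tests therefore show that the pipeline inverts its own generative
model at realistic noise — not that human data meet these assumptions.

## Problem sizes and numerical checks

The test suite runs the pipeline at reduced but structurally faithful
sizes: 80-trial blocks throughout; 30 single-strategy agents with 100
restarts for AIC identifiability; 100 mixed agents through both HMTG
contexts for recovery and stability; 10,000 simulated 4×4 tables (n = 200,
symmetric 0.8/0.2-spread confusion over the default mixture) for
Stuart–Maxwell type-I calibration; and an exhaustive McNemar equivalence
over all 2×2 off-diagonal pairs up to 20. The argmax is validated against
an independent pure-Python exhaustive oracle over every investment, all
multipliers in the task family, and a 21 × 21 parameter subgrid.

## Known limitations

* Zone membership does not guarantee model-family membership: a small band
  inside the guilt-averse zone behaves partially opportunistically, so
  AIC comparisons conditioned on zone-sampled agents inherit that
  heterogeneity (see the complexity-penalty test).
* The adaptive cluster-count rule reproduces four correctly-oriented zones
  for all three task configurations, but the exact cut depends on the
  linkage criterion; with Ward linkage no direct 4-cluster cut exists for
  the ×4/×6/×8 game.
* The greed model nests in GA/IA at Θ = 0, but pure payoff maximization
  corresponds to MS Θ = 1, outside the fitted domain [0, 0.5] — hence the
  residual moral behavior at the greedy corner noted above. AIC
  comparisons among these models rely on the SSE-based approximation and
  the normal-error assumption behind it.
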