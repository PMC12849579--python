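# Methods

## The selection model

The unit of decision is a binary vector x ∈ {0,1}ⁿ over the candidate
genotypes.  With standardized, direction-adjusted trait scores
y ∈ ℝ^{n×p₀} and a genomic relationship matrix G ∈ ℝ^{n×n}, the
quadratic index (QPMSI) maximizes

    Z(x) = Σ_i Σ_j y_ji x_i − k · xᵀGx

subject to the cardinality constraint Σ_i x_i = s and per-trait
minimum-gain constraints Σ_i y_ji x_i ≥ l_j, l_j = R_j·s/100.  The
linear index (LPMSI) keeps the constraints and drops the penalty.
Because xᵀGx sums *all* entries of the selected G submatrix — the
self-relatedness diagonal and both off-diagonal triangles — the
penalty controls exactly the quantity the variance-of-mean metric
V = xᵀGx/s² measures, while MR (the mean of the strictly-upper
triangle) isolates average pairwise relatedness.

Assumptions worth stating plainly: BLUEs are taken as given (no
breeding-value estimation happens here); traits are combined after
z-scoring, so each trait contributes on an equal-variance scale and
the only trait weighting mechanism is the R_j constraint system;
G is treated as fixed and exact; selection is a set decision, not a
contribution optimization — candidates are either advanced or not,
which distinguishes this from optimal contribution selection.

Two provable structural facts anchor the test suite.  First, with
both solvers exact and the same feasible set, the LPMSI optimum is
QPMSI-feasible, which forces merit(QPMSI) ≤ merit(LPMSI) and
penalty(QPMSI) ≤ penalty(LPMSI) — hence M and V orderings on every
instance, not just on average.  Second, as k grows the optimal
penalty term is non-increasing and the optimal merit term is
non-increasing (standard scalarization monotonicity); the k grid
therefore traces a gain–relatedness frontier.

## Preprocessing

Traits are z-scored per column; the standard deviation uses the
sample convention (denominator n−1) by default with a `ddof=0` switch,
since nothing downstream depends on the convention beyond a constant
per-trait rescaling of both the objective and the constraints.
Traits flagged `lower_is_better` are negated after scaling so that
larger scores are always favorable.  Non-finite BLUEs are a hard
error by default; an opt-in policy drops the offending genotypes with
a warning.  Silent imputation is deliberately unavailable — an
imputed cell would quietly shift the gain-constraint sums.

Trait polarity is configuration, never inferred from data: only the
breeder knows whether a trait improves upward or downward.

## The relationship matrix

The default construction z-scores each marker column (sample SD) into
W and returns G = WWᵀ/p.  Under this scaling trace(G) = n−1, every
row sums to zero, and G is a Gram matrix, hence positive
semidefinite.  Monomorphic markers are an error by default (dropping
them silently would change p and the scale of G); an opt-in flag
drops them with a warning.  VanRaden's allele-frequency scaling
(center by 2p̂_j, divide by 2Σp̂_j(1−p̂_j)) is available behind a flag
for compatibility with pipelines that use dosage frequencies; it
requires 0/1/2 coding, whereas the default accepts any additive
numeric coding because centering removes the offset.  Precomputed
matrices are validated: asymmetry up to 1e−6 is averaged away, larger
asymmetry is an error; a smallest eigenvalue in [−1e−4, −1e−8) warns,
below that errors.

## Exact optimization

Both indices are solved with HiGHS through `scipy.optimize.milp`.
The binary quadratic objective is reduced to a mixed-integer linear
program by Glover's compact linearization: one continuous auxiliary
w_i per genotype represents x_i(Gx)_i through

    w_i ≥ (Gx)_i − U_i(1 − x_i),     w_i ≥ L_i x_i,

with U_i the largest achievable (Gx)_i over s-subsets *excluding* i
and L_i the smallest over subsets *including* i (the conditioning
tightens the LP relaxation).  Since the penalty enters the
maximization with a negative sign, every w_i sits on its lower
envelope at the optimum, which equals x_i(Gx)_i exactly for binary x
— the reformulation is exact, not a relaxation.  The classical
pairwise (McCormick) product linearization is retained as
`method="exact_milp_mccormick"`; it is equally exact but carries
O(n²) auxiliaries and solves roughly an order of magnitude slower on
dense family-structured G, which is why the compact form is the
default.  An exhaustive enumeration oracle (`brute_force_select`)
and a swap-based local search round out the solver set; the test
suite checks both exact formulations against enumeration on hundreds
of random instances.

Numerical conventions: gain-constraint feasibility tolerance 1e−6;
objective-tie tolerance 1e−9; enumeration visits subsets in
lexicographic order and replaces the incumbent only on strict
improvement, so ties resolve to the lexicographically smallest index
set.  The MILP path is deterministic (fixed HiGHS options) but its
choice among exactly tied optima is solver-defined; cross-solver
assertions therefore compare objectives, not index sets.  The
brute-force subset cap defaults to 2×10⁶ evaluated subsets.

Infeasibility — no s-subset meeting every gain constraint — is a
first-class result carried in `SelectionResult.status`, with a
diagnostic that checks each trait's constraint against that trait's
own top-s sum: if even the best-case sum falls short, the culprit
trait is named; otherwise the infeasibility is a joint conflict and
the report recommends lowering R or k or falling back to the linear
index.  The seed argument affects only the local-search path.

## Evaluation metrics

M = (Σ selected y)/(s·p₀); V = xᵀGx/s²; MV = M/√V (undefined when
V = 0, flagged rather than crashed); MR = mean strictly-upper
triangle of the selected submatrix (undefined at s = 1).  Relative
efficiency compares methods on one metric: best = max for M and MV,
best = min for V and MR, with RE = (best/q − 1)·100 for M/MV and
(q/best − 1)·100 for V/MR.  The ratio form is ill-behaved when values
straddle zero — common for MR under strong penalization, which drives
mean pairwise relatedness negative.  The formula is computed verbatim
and the entry is flagged `unreliable: sign change`; redefining the
statistic would silently disagree with how the published comparison
tables were built.  A bundled benchmark table
(`qpmsi.benchmarks`) carries the published five-crop metric values;
regression tests verify the recomputed percentages against the
published ones *at the precision the three-decimal inputs support*
(interval arithmetic with half-ulp slack), and percentages that are
not arithmetically recoverable from the rounded table are omitted
from the fixture rather than force-fitted.

## Synthetic data

The generator emulates the two features of real candidate panels that
the indices actually exercise: block-structured relatedness and
inter-trait genetic correlation.

Markers: each family gets two founder parents drawn
Binomial(2, q_m) per locus, with q_m uniform in a configurable window
(default 0.1–0.9, kept off the boundaries so realized monomorphism is
rare; chance monomorphic loci are redrawn with a logged note).
Offspring receive one gamete per parent with transmission probability
dosage/2 — full sibs share half their genome in expectation, so the
derived GRM shows elevated within-family blocks.  Loci are unlinked.

Traits: marker-effect rows are drawn jointly normal with covariance
equal to the target correlation matrix, so genetic values
g = W_scaled·B inherit the inter-trait correlation; each trait mixes
its unit-scaled genetic value with independent noise as
√h2·g + √(1−h2)·e and is mapped to an arbitrary raw scale (distinct
means and SDs per trait, inverted polarity for `lower_is_better`
traits) so standardization is genuinely exercised.

Default study conditions, and why: 5 families × 10 sibs (n = 50,
s = 10) for end-to-end comparisons — a desk-scale panel with strong
family structure where penalized and unpenalized selection visibly
diverge; four traits with common correlation 0.5 and h2 = 0.5 —
mid-range values inside the spread observed in real multi-trait BLUE
panels (|r| from near 0 to above 0.9); 300 markers for selection
experiments (G is already well-resolved at n = 50), but 1,500 markers
for correlation-recovery checks, because the realized inter-trait
effect correlation fluctuates with SD ≈ √((1−ρ²)/p) and real panels
carry thousands of markers — at p = 300 that sampling noise (±0.06)
is a simulator artifact, not a property of the populations being
emulated.  All randomness flows from one master seed through
deterministically spawned per-stage substreams.

What the simulator does *not* model — linkage disequilibrium,
multi-generation recombination, selection history, genotyping error,
non-Gaussian trait architectures — bounds what passing tests show:
they validate the optimization and evaluation machinery and the
direction of the gain/relatedness trade-off under clean family
structure, not performance on any particular real breeding panel.

## Known limitations

* MILP solve time grows steeply with n for dense G; n in the low
  hundreds is comfortable, beyond that the local-search path or a
  sparsified G is advisable.
* The per-trait R_j system expresses importance through constraint
  floors, not through economic weights in the objective; a trait can
  only be emphasized, not traded off continuously.
* Relative efficiencies involving near-zero or sign-changing metric
  values (V and MR under strong penalization) are reported but
  flagged; they are arithmetically fragile and should not be read as
  effect sizes.
* `run_compare` solves each k independently; no warm-starting across
  the grid.
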