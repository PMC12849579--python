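# qpmsi — coancestry-penalized multi-trait selection indices

Intensive genomic selection raises genetic merit fast but, left
unchecked, concentrates the selected set in a few closely related
families — eroding the diversity future breeding cycles depend on.
`qpmsi` implements two selection indices for choosing exactly *s*
candidates out of *n* from multi-trait breeding values (BLUEs) and a
genomic relationship matrix (GRM):

* **QPMSI** (quadratic-programming multi-trait selection index):
  with binary decisions *xᵢ* ∈ {0, 1}, maximize

  &nbsp;&nbsp;&nbsp;&nbsp;Z = Σᵢ Σⱼ y<sub>ji</sub> xᵢ − k · xᵀGx

  subject to Σᵢ xᵢ = s and, per trait *j*, the minimum-gain constraint
  Σᵢ y<sub>ji</sub> xᵢ ≥ l<sub>j</sub> with l<sub>j</sub> = R<sub>j</sub>·s/100.
  Here y<sub>ji</sub> are standardized, direction-adjusted trait scores, G
  is the GRM and k ≥ 0 weights the relatedness penalty (k = 1 weights
  gain and relatedness equally).

* **LPMSI** (linear-programming multi-trait selection index): the same
  constraints with the merit-only objective Z = Σᵢ Σⱼ y<sub>ji</sub> xᵢ —
  the classical truncation-style baseline the quadratic index
  generalizes.

Both are solved to proven optimality as mixed-integer linear programs
(HiGHS via `scipy.optimize.milp`; the quadratic objective is
linearized exactly for binary variables).  Selections are evaluated
with four metrics: mean gain **M** = Σ y<sub>ji</sub> xᵢ / (s·p₀), variance of
the mean **V** = xᵀGx/s², gain-to-relatedness ratio **MV** = M/√V, and
mean pairwise relatedness **MR** (mean of the strictly-upper-triangle
entries of the selected G submatrix), plus relative-efficiency
percentages across methods.  When a gain demand makes the problem
infeasible, that is reported as a result (with a diagnostic naming the
unsatisfiable trait), not an error.

The package also ships a sib-family simulator (Mendelian dosage
sampling from founder parents, correlated marker effects) so the whole
pipeline is testable without any external dataset, and a GRM builder
(`G = WWᵀ/p` from column-scaled markers, or VanRaden's
allele-frequency scaling).

## Worked example

Simulate 5 full-sib families × 10 sibs with four correlated traits,
then select 10 of the 50 candidates with both indices:

```bash
qpmsi simulate --out-dir data --n-families 5 --family-size 10 \
    --p-markers 300 --n-traits 4 --trait-corr 0.5 --h2 0.5 --seed 1

cat > run.yaml <<EOF
traits: data/traits.csv
markers: data/markers.csv
s: 10
k_grid: [0.5, 1.0, 1.5]
out_dir: out
EOF

qpmsi compare --config run.yaml
```

which prints

```
Method     k  status     M     V    MV     MR
 LPMSI   NaN optimal 0.721 0.109 2.183  0.011
 QPMSI 0.500 optimal 0.696 0.047 3.217 -0.056
 QPMSI 1.000 optimal 0.696 0.047 3.217 -0.056
 QPMSI 1.500 optimal 0.696 0.047 3.217 -0.056
```

The merit-only LPMSI reaches the higher mean gain (M = 0.721 vs
0.696) but picks a more related set (MR = 0.011 vs −0.056, V = 0.109
vs 0.047); the penalized index trades ~3 % of mean gain for less than
half the variance-of-mean, a 47 % higher gain-to-relatedness ratio
(MV 3.217 vs 2.183, written with the full relative-efficiency tables
to `out/report.json`).  On this instance the selected set is stable
across the k grid; on larger or more constrained problems the k values
trace out the gain–relatedness frontier.

The same objects are available as a library
(`build_problem`, `solve_qpmsi`, `solve_lpmsi`, `compute_metrics`,
`relative_efficiency`, `simulate_dataset`, ...), and `qpmsi grm` /
`qpmsi select` expose the individual steps.

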