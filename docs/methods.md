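# Methods

## The model

`diffcoex` detects *differential coexpression*: changes, between two or
more sample groups, in the correlation structure among genes. Two
archetypes motivate the design:

* **(i) within-module decorrelation** — a group of genes is tightly
  coexpressed in one condition and loses that coordination in another
  (e.g. a common regulator becomes inactive);
* **(ii) module-to-module rewiring** — two groups keep their internal
  coexpression in both conditions, but the correlation *between* the
  groups changes (e.g. a hub coupling two pathways disappears).

The pipeline applies the weighted-coexpression-network toolkit to the
network of correlation **changes** rather than to the correlations
themselves:

1. **Per-condition correlation.** Within each condition *k* compute the
   gene × gene correlation matrix C[k] (Spearman by default to limit
   outlier influence; Pearson selectable). Each matrix uses only that
   condition's samples.
2. **Difference adjacency.** Changes are measured on the signed-r²
   scale s = sign(c)·c², so changes equal in explained variance get equal
   weight, and soft-thresholded with a positive integer β:

       d_ij = ( ½ |s_ij[1] − s_ij[2]| )^β

   For n ≥ 2 conditions, with consensus c⁰ = mean_k s[k]:

       d_ij = ( √( 1/(2(n−1)) Σ_k (s_ij[k] − c⁰_ij)² ) )^β

   which reduces exactly to the two-condition formula at n = 2 (this
   reduction is asserted at 1e−12 in the test suite). A *strict* variant
   thresholds before differencing, d = ½|sign(c[1])|c[1]|^β −
   sign(c[2])|c[2]|^β|, and is deliberately insensitive to subtle changes;
   at β = 2 it coincides with the standard form at β = 1.
3. **Dissimilarity.** The topological-overlap measure of the change
   network,

       t_ij = 1 − (Σ_{k∉{i,j}} d_ik d_kj + d_ij) / (min(k_i, k_j) + 1 − d_ij),

   with connectivities k_i = Σ_{k≠i} d_ik, makes two genes similar when
   their correlation changes involve the *same neighbor genes*. This is
   what gives sensitivity to archetype (ii): genes of block A never change
   correlation with each other, but they all change correlation with block
   B, so they share neighbors in the change network. Index ranges follow
   the established topological-overlap convention (numerator sum excludes
   i and j; connectivity excludes the self term; the diagonal of D is fixed
   at 0 beforehand), which guarantees t ∈ [0, 1]. The `no_tom` variant
   T = 1 − D skips this step and consequently sees only direct pairwise
   change (archetype (i)).
4. **Clustering.** Average-linkage hierarchical clustering on T, followed
   by either a fixed-height cut or the adaptive branch decomposition
   described below; PAM (k-medoids) is available as an alternative.
   Clusters smaller than `min_module_size` are relabeled `grey`
   (unassigned). Modules are named by a deterministic color sequence in
   order of decreasing size.
5. **Significance.** Because β and the cut settings are user choices,
   every detected module (and module pair) is re-tested with the
   dispersion permutation test described below.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `correlation` | `spearman` | within-condition correlation measure |
| `beta` | 6 | soft threshold; *stringency* knob. Large β suppresses small correlation changes; smaller values are appropriate for larger sample sizes and for subtle signals (module-to-module rewiring in particular). The default is a convention, not an estimate — try several values and rely on step 5 |
| `dissimilarity` | `tom` | `no_tom` is cheaper but blind to archetype (ii) |
| `min_module_size` | 20 | smallest reportable module |
| `min_gap` | 0.1 | adaptive cut: required branch separation, in robust height-range units |
| `n_perm` | 1000 | permutations for the dispersion test |

## Adaptive tree cut

Soft-thresholded change networks produce dendrograms whose informative
branches occupy a tiny sliver of the height range just below a dense mass
of background merges, so no fixed cut height works across datasets. The
cutter used here walks the average-linkage tree top-down and accepts a
branch as a module when (a) it has at least `min_module_size` leaves and
(b) the gap between its own top merge and the height at which it joins the
rest of the tree is at least `min_gap`, measured in units of the 5th–95th
percentile range of all merge heights (falling back to the full range when
that is degenerate) — unless both of its children satisfy the same
criteria, in which case the walk recurses and splits them. The root is
never accepted whole. The procedure is deterministic; ties in the linkage
are resolved by scipy's ordering. On data with no differential structure
all gaps are small on the robust scale and no module is reported, which is
the desired null behavior. PAM uses the classic deterministic BUILD
initialization followed by SWAP, so repeated runs agree exactly.

## Dispersion statistic and permutation test

For a gene set G with pair set P (cross pairs A × B for the
module-to-module version):

    dispersion(G) = √( 1/|P| Σ_{(i,j)∈P} (c_ij[1] − c_ij[2])² / 2 )

i.e. the root-mean-square correlation change; zero iff no pair changes,
maximal (√2) for a single pair flipping from +1 to −1. For n > 2
conditions the squared half-difference generalizes to
1/(n−1) Σ_k (c[k] − c̄)², reducing exactly at n = 2; the multi-condition
dispersion should be considered experimental, as only the two-condition
form is exercised by the planted-scenario benchmarks. The exact
normalization is a convention: permutation p-values are invariant to any
positive rescaling of the statistic, since observed and null values scale
together.

The null distribution is built by (1) standardizing each gene to zero
mean/unit variance *within* each condition — correlations are unaffected,
but after relabeling, group differences in mean or variance can no longer
masquerade as correlation change — then (2) reassigning samples to
conditions uniformly at random with the original group sizes, and (3)
recomputing every dispersion on each of the `n_perm` permuted datasets.
The p-value is `n_exceed / n_perm` with a ≥ comparison; zero exceedances
are reported as "< 1/n_perm", never as 0. Raw p-values are reported per
target with no multiplicity correction by default; `results_to_frame(...,
bh_column=True)` adds a Benjamini–Hochberg column.

**Selection caveat.** These p-values are calibrated for gene sets fixed
in advance. Modules *selected* by the clustering are by construction the
most differentially coexpressed sets in the data, so their p-values are
anti-conservative under the null (demonstrated in the test suite on a
null simulation). Treat them as a sanity filter on the user-chosen
parameters, not as well-calibrated hypothesis tests.

## The simulator

`diffcoex.simulate` realizes the two archetypes with a latent-factor
model: block b in condition k has one factor f_b, member genes are
x = √ρ_bk·f_b + √(1−ρ_bk)·ε, and couplings prescribe the factor–factor
correlation r_k, giving gene-level cross-block correlation √(ρ_a ρ_b)·r_k.
Target correlations therefore hold *in expectation*; all cross pairs share
the same factor realizations, so empirical block means fluctuate by
roughly ρ/√m around the target for m samples. The per-condition factor
correlation matrix is validated to be positive semi-definite, so
impossible scenarios fail at construction. The factor construction (rather
than a Cholesky factor of the full gene × gene correlation matrix) lets
scenarios scale to thousands of genes cheaply.

Canonical scenarios, used by the end-to-end tests and the acceptance
script, both with 1,900 background genes and 50 samples per condition
(roughly the sample scale of a moderate two-group microarray study):

* `scenario_a`: one 100-gene block, within-correlation 0.8 → 0.0;
* `scenario_b`: two 50-gene blocks, within-correlation 0.7 conserved,
  factor cross-correlation 0.6 → 0.0 (gene-level cross correlation
  0.42 → 0).

What the simulator does **not** emulate: time-course autocorrelation,
batch effects, probe-level/microarray noise, heavy-tailed expression,
mean–variance coupling, or partially overlapping modules. Passing the
planted-recovery tests shows the machinery behaves as designed under the
factor model; it does not certify performance on real arrays.

## Analysis choices in the benchmarks

Scenario A is run with all defaults (β = 6). Scenario B's rewiring signal
(|Δsigned-r²| ≈ 0.16 per cross pair) is comparable to the sampling noise
of within-block correlations at 50 + 50 samples, so high stringency
extinguishes it; following the rule that smaller soft thresholds suit
smaller effects and larger samples, the benchmark runs it at β = 1 and
recovers stringency through the permutation test — the recommended
workflow on real data as well. At these settings the topological-overlap
pipeline groups both planted blocks into differential modules while the
`no_tom` variant finds nothing on the same data, which is precisely the
sensitivity difference the topological overlap exists to provide. Because
the two blocks rewire *towards each other*, they typically emerge as one
merged differential module; the module-to-module dispersion is therefore
evaluated on the planted block pair.

Problem sizes used by the test suite and `scripts/acceptance.py`: 2,000
genes per scenario; 200 permutations for scenario-level tests; the type-I
study uses 100 replicates of a 45-gene dataset (a conserved 30-gene block
plus background) with a pre-fixed random 30-gene set and 200 permutations
each. With 200 permutations the discrete null gives
P(p ≤ 0.05) = 11/201 ≈ 0.055 under exchangeability, which is the value
the rejection-rate check brackets.

## Numerical notes and limitations

* All matrix work is double precision; correlation and adjacency matrices
  are symmetrized by construction (`(M + Mᵀ)/2`) and clipped to their
  theoretical ranges before use; diagonals are set exactly (1 for C, 0 for
  D and T).
* A gene with zero variance within any condition has undefined
  correlations: hard error by default (naming the genes),
  `drop_zero_variance=True` drops them with a warning.
* Missing values are rejected outright; there is no pairwise-complete
  mode.
* Memory is O(p²) per matrix (a 15,000-gene analysis needs on the order
  of 10 GB); the CLI offers an optional overall-variance prefilter
  (`--min-variance-quantile`), off by default.
* Sample permutation ignores any pairing or time-course structure in the
  design; with strong within-group structure (e.g. matched time points)
  the exchangeability assumption is only approximate.
* PAM forces every gene into a cluster (no `grey`), so its output should
  always be filtered by the dispersion test.
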