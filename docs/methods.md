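# Methods

## Setting

`coopbalance` analyses associations between a microbial count table
(samples × taxa, typically genus level from 16S amplicon profiling) and
external factors — a categorical study-group label and panels of
continuous clinical parameters. All statistics operate in Aitchison
geometry: counts are pseudocounted, closed to proportions, and
centred-log-ratio (clr) transformed, after which Euclidean machinery is
valid and subcomposition-coherent effect descriptions are possible.

Effects on the community are expressed as **balances**: normalized
log-contrasts between a numerator set P and denominator set Q of taxa.
The coefficient vector carries +√(q/(p(p+q))) on P and −√(p/(q(p+q))) on
Q (p=|P|, q=|Q|), making it unit-norm and sum-zero; the per-sample
balance value is its inner product with the clr row, equivalently
√(pq/(p+q)) times the difference of mean log-abundances between the
sides.

## Pipeline stages

1. **Sample intersection.** Counts and metadata are restricted to shared
   samples, sorted by id, so results are independent of input row order.
   Samples present in only one input are dropped (logged); missing
   parameter values are handled per factor by complete-case analysis —
   never imputed — so each test reports its own n.
2. **Rarefaction.** Each sample is subsampled without replacement
   (multivariate hypergeometric) to the minimum sample depth (or a fixed
   depth). Draws are keyed to (seed, sample id), so the result does not
   depend on sample order.
3. **Diversity.** Shannon index (base 2 by default — the common amplicon
   convention; the base is configurable and only rescales values) and
   bias-corrected Chao1, S_obs + F₁(F₁−1)/(2(F₂+1)), per sample, via
   scikit-bio. Beta diversity is the Aitchison distance (Euclidean on clr
   rows); ordination is classical PCoA with taxon biplot arrows given by
   the covariance of each clr taxon with each retained axis.
4. **clr transform.** Zeros are replaced by a pseudocount of 0.5 applied
   to the *counts* before closure (so the replacement is half of the
   smallest observable count), rows closed and logged, row geometric mean
   subtracted. An all-zero sample is an error.
5. **Genus filter.** Only genera with count > 20 reads in > 10 samples
   (strict inequalities) enter the network and balance analyses.
6. **Co-abundance network.** Meinshausen–Bühlmann neighborhood selection
   on clr columns: each genus is lasso-regressed on all others
   (scikit-learn coordinate descent) along a geometric path of 10 lambdas
   from λ_max (largest absolute pairwise correlation of the standardized
   columns — the smallest penalty giving an empty model) down to
   0.2·λ_max; edges are combined with the OR rule. The fit is repeated on
   10 random 80% subsamples; the penalty is chosen StARS-style and edges
   kept only if selected in ≥ 80% of subsamples at the chosen lambda
   (edge weight = selection frequency).
7. **Cooperatives.** Louvain communities of the stability-weighted graph
   (networkx), 10 seeded restarts keeping the best-modularity partition.
   Communities of size 1 are reported as singletons, not coops. Coops are
   named after their most abundant member genus ("X-coop").
8. **Parameter de-duplication.** Within each parameter group, parameters
   with |Spearman ρ| > 0.8 (pairwise-complete) are linked; connected
   components form clusters; one representative per cluster (fewest
   missing values, ties lexicographic) is retained.
9. **Association screens.** Per retained factor: linear model on each
   alpha metric; a permutation pseudo-F test on the distance matrix
   (PERMANOVA for categorical, dbRDA for continuous factors — one engine,
   see below); a standardized linear model of each coop balance (the
   coefficient is the Pearson correlation between factor and balance
   value, a unitless quantity comparable across factors); and per-taxon
   clr linear models at every available taxonomic rank. Benjamini–
   Hochberg FDR is applied within each parameter group × feature family.
10. **Nearest balance.** For factors associated with beta diversity at
    FDR < 0.05 (or named explicitly), the cross-validated nearest balance
    is computed and exported as a membership table (taxon, side,
    reproducibility, coefficient).

## The permutation engine

PERMANOVA and dbRDA share one implementation. The factor is coded into a
model matrix X (dummy coding for categorical levels, centred values for a
continuous factor; the Gower centring absorbs the intercept). With
G = −½·C D² C the Gower-centred squared-distance matrix and H the hat
matrix of X, SS_model = tr(HGH), R² = SS_model/tr(G), and
pseudo-F = (SS_model/df_m)/(SS_res/df_r). The p-value is
(1 + #{F_perm ≥ F_obs})/(1 + n_perm) over random sample relabelings, so it
is never exactly zero. Permutations are vectorized as row permutations of
the orthonormalized model matrix. A two-level categorical factor and its
0/1 coding give identical F and p under the same permutation seed (tested),
and the categorical statistic matches scikit-bio's `permanova` and R
vegan's `adonis2` (tested against both).

## Nearest balance

Given a factor, the **association direction** v is the vector of
covariances between each clr column and the standardized factor (for a
two-level categorical factor, the difference of group mean clr vectors).
v sums to zero automatically because clr rows do. Any proportional
rescaling of v gives the same result: the search maximizes cosine
similarity, which is scale-free.

The **nearest balance** maximizes the cosine between the balance
coefficient vector and v. Because balance coefficients are constant
within each side, for fixed side sizes (p, q) the best choice is the top
p and bottom q components of v sorted descending; the search therefore
scans all (p, q) pairs in O(n²) after sorting. This restriction is exact:
an exhaustive oracle over all 3ⁿ assignments of taxa to
{numerator, denominator, excluded} agrees with the fast search on every
random trial (property-tested for n ≤ 8). Exact ties in v are broken by
taxon id, identically in both implementations.

**Cross-validated reproducibility.** 100 half-samples (⌊n/2⌋ without
replacement, complete cases only) each yield a nearest balance; taxa
assigned to one side in > 90 iterations form the final reproducible
balance, with display coefficients taken from the full-data direction.
A taxon is tallied only when its own clr–factor correlation is nominally
significant (two-sided p < 0.05) in that iteration. This gate is the
package's resolution of a genuine design gap: half-samples overlap, so
the extreme components of the full-sample *noise* direction land on the
same side in nearly every iteration, and without the gate a pure-noise
factor still produces a non-empty "reproducible" balance in most runs.
With the gate, null factors return an empty balance in ≈100% of simulated
cohorts while a planted balance (β = 2) is still recovered exactly —
genuinely associated taxa pass the per-iteration test almost surely, so
the gate costs essentially no power at this effect size. When no taxon
passes on both sides the result is flagged empty, not an error.

## Choice of the network sparsity penalty

The paper-fixed path (10 lambdas down to 0.2·λ_max) does not determine
the operating point, so the penalty is chosen by stability: the edge-wise
instability 2θ(1−θ) (θ = selection frequency over subsamples), averaged
over all candidate pairs and monotonized along decreasing lambda; the
smallest lambda with average instability ≤ `stars_beta` is used. The
default bound is **0.01**, deliberately tighter than the 0.05 often
quoted for StARS: the average is diluted by the ~d²/2 never-selected
pairs (d ≈ 100 filtered genera here), and at 0.05 the rule runs into the
dense end of the path where ~1% of pairs are spurious-but-stable noise
correlations of the fixed cohort. Those few edges barely affect global
network statistics but fragment community recovery (planted-block ARI
drops from >0.9 to ~0.5–0.7). At 0.01 the chosen graph sits at the sparse
knee of the instability curve, retaining ~70% of within-block edges and
essentially no spurious ones.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with exportable ground truth:

- **Design.** Three groups A/N/S of 48/46/86 samples (n = 180), 120
  genera, per-sample sequencing depth uniform in [10 459, 40 000] reads.
- **Latent abundances.** log-abundances are multivariate normal. Baseline
  means are N(0, 2²), giving one dominant genus at ~10–25% mean relative
  abundance and a long tail, as in stool communities. Genera carrying
  planted structure draw their baseline from N(1.5, 0.75²) — the abundant
  "core" — so that planted signal is observable above the 20-read filter
  rather than hidden in unsequenced tail taxa.
- **Coops.** Four disjoint blocks of 10/8/12/6 genera with within-block
  latent correlation 0.7.
- **Planted effects.** A factor (standard normal) adds β·(factor)·b to
  the latent log-abundances, where b is the planted balance's unit
  coefficient vector — a pure clr-space shift of β clr units per SD of
  the factor, since b sums to zero. The default scenario plants one 7+7
  balance at β = 2 on an immune-panel factor.
- **Counts.** Multinomial draws of the softmax-closed latent vector at
  the sample's depth.
- **Clinical panel.** Four parameter groups (immune 18, cardiovascular
  21, endothelial 5, metabolites 21) containing clusters of monotone
  transforms of a shared latent variable plus N(0, 0.25²) noise
  (empirical pairwise Spearman ρ > 0.8) and independent standard-normal
  null parameters.

What the generator does **not** model: Dirichlet-multinomial
overdispersion, taxonomic misclassification, group-dependent community
shifts (the groups are deliberately null, mirroring the motivating
cohort), zero-inflation beyond multinomial sampling, and real-data
phenomena such as batch effects. Passing recovery tests therefore shows
the procedures behave correctly under the model's own assumptions — not
that real cohorts satisfy those assumptions.

## Numerical conventions

- clr rows are validated to sum to zero within 1e-9; the dot-product and
  mean-log balance formulas agree within 1e-9 (both implemented, tested
  against each other).
- PCoA eigenvalues are clipped at 0 for variance proportions; negative
  eigenvalues exceeding retained positive ones (impossible for Aitchison
  distances, possible for user-supplied matrices) raise an error. Axis
  signs are fixed by making the largest-magnitude coordinate positive.
- All randomness derives from one config seed; stage-local generators are
  keyed by (seed, stage name, object id) via CRC32, so identical
  config + inputs give byte-identical outputs regardless of sample order,
  and different stages never share a stream.
- Output TSVs print floats with 6 significant digits.
- Reported problem sizes: property tests and the acceptance script use
  the default cohort (n = 180, 120 genera), 10 seeds for recovery
  checks, 20 seeds for null empty-balance rates, 200 null factors with
  199 permutations each for calibration checks, and 999 permutations for
  single headline tests.

## Known limitations

- The network step assumes the filtered clr matrix has no constant
  columns within a subsample (guaranteed in practice by the abundance
  filter).
- `brute_force_nearest_balance` is a test oracle, exponential in the
  taxon count (capped at n = 12).
- The association screens are univariate by design; covariate-adjusted
  or mixed models, longitudinal structure and phylogeny-aware distances
  are out of scope.
- dbRDA here is the single-predictor special case (the pseudo-F engine
  accepts any model matrix, but the pipeline fits one factor at a time).
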