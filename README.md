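# coopbalance

Compositional analysis of microbiome–phenotype associations: nearest
balances with cross-validated reproducibility, co-abundance cooperatives
(coops) tested as balances, Aitchison-geometry ordination, and
permutation tests — organized as a reusable library (`src/coopbalance`)
plus a worked analysis on synthetic cohorts with planted ground truth
(`analysis/`).

## The problem

Microbiome count tables are compositional: only relative information
survives sequencing, so ordinary correlations and per-taxon tests are
coherent only after a log-ratio transform. This package analyses a
genus-level count table against clinical factors entirely in Aitchison
geometry. Counts are pseudocounted (zeros → 0.5), closed and
centred-log-ratio (clr) transformed; community-level tests use the
Aitchison distance; taxon-level effects are expressed as **balances** —
normalized log-contrasts between a numerator set P and a denominator set
Q, with coefficient vector

    b_j = +sqrt(q/(p(p+q)))  for j in P,
    b_j = -sqrt(p/(q(p+q)))  for j in Q,      (p = |P|, q = |Q|)

so the per-sample balance value is `b · clr(x)` =
`sqrt(pq/(p+q)) · (mean log over P − mean log over Q)`.

Two complementary devices summarize factor–microbiome links:

- **Nearest balance.** For a factor with clr-association direction v
  (per-taxon covariance with the standardized factor), the balance whose
  coefficient vector has maximal cosine similarity with v. The search
  sorts v and scans all (p, q) top/bottom splits — provably exact, and
  verified against exhaustive enumeration of all 3^n side assignments.
  Reproducibility is assessed on 100 random half-samples: taxa assigned
  to one side in >90 iterations form the final balance.
- **Cooperatives (coops).** Louvain communities of a sparse genus
  co-abundance graph (Meinshausen–Bühlmann neighborhood selection on clr
  columns, 10 subsamples × 10 lambdas, stability-selected edges). Each
  coop is tested as the balance of its genera against all other filtered
  genera, with a standardized linear model per clinical factor.

Screens for many parameters are de-duplicated (|Spearman ρ| > 0.8
clusters collapse to one representative) and BH-FDR corrected within
each parameter group × feature family.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (180 samples in groups A/N/S = 48/46/86, 120 genera, four planted
co-abundance blocks, one planted 7+7 balance at β = 2 on the immune
factor `lymphocytes_pct`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_diversity_ordination.py
python analysis/03_coop_network.py
python analysis/04_association_screens.py
python analysis/05_nearest_balance.py
```

Output (seed 1, abridged):

```
rarefaction depth: 10537 reads/sample
mean Shannon 5.09 bits, mean Chao1 115.3 genera
group PERMANOVA: pseudo-F=0.972 R2=0.0109 p=0.54 (no group signal, as planted)

98 genera pass the abundance filter
network: 124 stable edges at lambda=0.255 (instability 0.0095)
coops: 5 communities, 50 singletons
adjusted Rand index vs planted blocks: 0.817

beta-diversity screen: 2 parameter(s) at FDR < 0.05: lymphocytes_pct, ...
  top: lymphocytes_pct pseudo-F=6.86 R2=0.0371 p=0.001 FDR=0.016 (n=180)

reproducible balance for lymphocytes_pct: 7 numerator + 7 denominator genera
planted members recovered: 7/7 numerator, 7/7 denominator; spurious: 0
balance value vs factor: Pearson r = 0.885
```

Reading this: the study groups carry no planted microbiome effect and
the PERMANOVA is duly null; the planted factor is the top beta-diversity
hit (R² ≈ 0.04 at n = 180), which triggers the nearest-balance analysis;
cross-validation recovers exactly the planted 14 genera on the correct
sides. The coop step recovers the four planted covariance blocks (ARI
0.82 here; the planted factor's own 7+7 genera form a fifth, genuine
co-abundance module that the block-only ground truth counts against).
Result tables land in `results/` (larger intermediates in `scratch/`,
which is disposable).

The same pipeline runs on real data from the shell:

```sh
coopbalance run --counts counts.tsv --metadata meta.tsv --out results/
coopbalance nb --counts counts.tsv --metadata meta.tsv --factor lymphocytes_pct
coopbalance simulate --scenario planted --seed 1 --out cohort/
```

## Layout

```
src/coopbalance/   library: io, composition, nb, coop_network,
                   associations, simulate, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, end-to-end)
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
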