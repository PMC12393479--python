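# Methods

## Communication scoring model

Let `x_{i,g}` be the (preprocessed) expression of sensor gene *g* in cell
*i*. Within each group, cells are stratified by cell type *k* and the model
works entirely on per-type mean expression:

- `mu_{g,k} = (1/n_k) Σ_{i∈C_k} x_{i,g}`
- `Z_{g,k} = (mu_{g,k} − mean_k mu_g) / sd_k mu_g`, sample sd (ddof = 1)
  because the number of cell types K is small; genes whose mean is constant
  across cell types have no defined z-score and are dropped with a warning.
- `Score_{g,m,k} = Z_{g,k} · A_{g,m}` for each metabolite–sensor pair
  (m, g).

The score asks a *pattern* question — is the sensor specifically elevated
in this cell type relative to the others — scaled by how strongly the
metabolite engages it. Because Z is standardized, |Z| is bounded by
`(K−1)/√K`; the score carries no information about absolute expression
level beyond the low-expression mask. Metabolite concentrations are
treated as saturating (a pair's strength depends only on the curated
binding activity, not on metabolite abundance).

Preprocessing: cells expressing fewer than `min_genes` genes (default 200)
and genes expressed in fewer than `min_cells` cells (default 10) are
removed once, in that order; surviving cells are scaled to 10,000 total
counts (CP10K) and log1p-transformed. The defaults suit genome-wide
matrices; studies on simulated panels of a few hundred genes pass a
panel-scaled `min_genes` (20–50), since a 250-gene panel cannot express
200 genes.

Low-expression mask: within each (cell type, group) stratum, sensor genes
whose mean falls below the stratum's 25th percentile (linear-interpolation
quantile) of the sensor-gene mean distribution are excluded from scoring.
The mask is part of the scored chain, so the permutation null recomputes
it per shuffle.

## Permutation null

Cell-type labels are shuffled within each group (groups are never mixed:
scores are per-group quantities), and the full chain mu → mask → Z is
recomputed per shuffle. The default p-value is two-sided on |Score|,

```
p = #{ shuffles: |Score_shuffle| ≥ |Score_obs|, entry scored } / #{ shuffles: entry scored }
```

with three deliberate choices:

- **Ties count as extreme**, with a 1e−9 tolerance so tie-breaking does not
  depend on float summation order; this is conservative.
- **Masked shuffles are excluded from both numerator and denominator.**
  An entry masked in a given shuffle has no score in that replicate;
  counting it as "not extreme" would deflate p by roughly the masking rate
  and inflate the type-I error correspondingly, while counting it as
  extreme would be heavily conservative. The conditional proportion keeps
  the null calibrated (verified empirically: type-I error 0.048–0.058 at
  nominal 0.05 across development seeds).
- A **one-sided option** (`two_sided=False`, `--one-sided`) reproduces the
  plain `Score_shuffle ≥ Score_obs` rule; it cannot flag depleted
  (negative-score) pairs, which is why two-sided is the default.

When the number of distinct within-group label assignments does not exceed
`n_permutations`, the null is enumerated exhaustively (identity included)
instead of sampled; `method='exhaustive'` forces this. P-values are raw
proportions; a pseudocount option in the pathway scorer provides
`(1+x)/(1+N)` for users who want strictly positive p.

BH adjustment runs across all (pair, cell type) entries within each group.
Differential calls between two groups require q < 0.05 in at least one
group and |Score_A − Score_B| > 0.5; |difference| > 10 is annotated as
highly selective.

## Knowledgebase curation

Raw records carry one measurement (Kd, Ki, IC50, EC50, AC50 or potency)
with a molar unit. The chain, in order: standardize to nM; drop
PAINS-flagged rows (substructure detection is delegated — the reader
consumes a precomputed boolean column); drop rows at or above 1 mM
(10^6 nM); collapse exact duplicates (same pair, assay type and value);
then, within each pair whose max/min ratio exceeds 10, drop measurements
above 10× the pair minimum — removing the offending records rather than
the pair keeps the strongest evidence. Aggregation is the geometric mean
on the nM scale (affinities are log-distributed), and the interaction
strength is the fixed affine map `A = clip((pActivity − 3)/9, 0, 1)`
anchored at 1 mM (A = 0) and 1 pM (A = 1) — not a dataset-dependent
min-max, so strengths are comparable across knowledgebases. Assay types
are pooled; nothing in the inputs supports weighting functional versus
binding assays differently.

## Signaling entropy rate

A cell's expression vector x (CP10K + 1.0 pseudocount; strictly positive)
drives a random walk on an undirected gene network with
`P_ij = A_ij x_j / Σ_k A_ik x_k`. This walk is reversible with stationary
distribution `u_i ∝ x_i (Ax)_i`, which the implementation uses in closed
form (and tests against the numeric leading left eigenvector of P). The
entropy rate `Σ_i u_i S_i`, with local entropies
`S_i = −Σ_j P_ij log P_ij`, is divided by log ρ — the maximum entropy rate
attainable on the network, with ρ the adjacency spectral radius — giving
SR ∈ [0, 1]; division (not multiplication) by log ρ is what makes the
0–1 range hold, and SR = 1 exactly for regular graphs under uniform
expression. Natural logs throughout (the ratio is base-invariant), and SR
is invariant to global rescaling of x, so the normalization choice only
fixes the pseudocount's relative size. The network is restricted to its
largest connected component after intersection with measured genes
(dropped genes are logged); fewer than 3 surviving genes is an error, and
a network whose log ρ ≤ 0 (no cycle structure to explore) is rejected as
degenerate. SR is computed per cell (not on pseudobulk), matching the
single-cell resolution of the rest of the pipeline.

Group summaries use a two-sided rank-sum test per cell type — exact by
enumeration with midranks when C(n, n1) ≤ 20,000, so identical
distributions give p = 1 exactly, otherwise the tie-corrected normal
approximation — BH-adjusted across cell types.

## Pathway activity

Relative expression `r_{g,k,group}` is the stratum mean divided by the
global mean over *all* cells, both groups pooled, so the two groups share
one baseline (a per-group baseline is available behind a flag). Gene
weights are `w_g = 1 / #pathways containing g`, computed over the supplied
collection. Outlier exclusion is gene-level: quartiles are taken over the
pathway's full r matrix (genes × cell types, Hyndman–Fan type-7 linear
interpolation, the numpy default), and a gene with any value above 3×Q3 or
below Q1/3 is removed from the pathway in every cell type, keeping scores
comparable across cell types. The score is the weighted mean of the
surviving genes' r values; 1 is the neutral baseline and score > 1 flags
enrichment. The permutation null shuffles cell-type labels within each
group and recomputes the full chain including outlier exclusion; p is
two-sided on |score − 1|. Between groups, a (pathway, cell type) is
*changed* when |Δscore| > 0.1 and the pathway is significant (q < 0.05) in
at least one group (requiring significance in both is stricter than the
stated decision rule and is not imposed).

## Synthetic data

The generator emulates sparse UMI count data: gene baseline means drawn
log-normally (sd 0.5 in log space) around a global baseline of 2, gamma–
Poisson (negative binomial) sampling with dispersion 0.5, log-normal
library-size factors with sd 0.3, and multiplicative fold changes planted
on chosen (sensor, cell type, group) tuples. All draws come from one
seeded generator; the same seed gives byte-identical matrices. An optional
`celltype_signature_sd` adds shared cross-group cell-type signatures for
studies needing baseline structure; the default of 0 keeps the model
minimal and fully exchangeable, which is the correct null for
label-permutation calibration.

The activity generator pairs each sensor with one metabolite, draws
pActivity uniformly in [5, 9] (log-uniform strength), jitters per-pair
records so the geometric mean is hit exactly with a within-pair ratio well
under 10, and injects exact numbers of QC violations — duplicate rows,
PAINS-flagged rows, 2 mM rows, 50×-minimum outliers — so curation tests
can assert survivor counts by hand. Sensors carrying planted expression
effects are guaranteed an aggregated strength of at least 0.5
(pActivity ≥ 7.5, i.e. ≤ ~30 nM, a typical high-affinity regime).

What the simulation does not model: doublets, ambient RNA, batch and donor
effects, zero inflation beyond NB sparsity, and correlated gene programs.
Passing recovery tests therefore demonstrate the statistical machinery —
calibration of the null, power against planted signals, exactness of the
decision rules — not robustness to those artifacts on real tissue.

## Frozen evaluation studies

- **Planted recovery**: 12 cell types (an intermediate-resolution brain
  taxonomy), 200 cells per type per group, two groups, 200 genes of which
  60 sensors, 30 tuples planted at fold change 4 in the AD group, 1000
  permutations. Effects are planted on sensors *expressed* in the target
  cell type (expected mean clear of the low-expression mask, computed from
  the seed before sampling) and at a mid-ranked cell type of the sensor's
  profile, since the z-score method can only flag changes that dominate a
  gene's cross-type profile: detection requires Z near its saturation
  bound, so a change hidden under a strong pre-existing signature, or in a
  masked stratum, is undetectable by construction. This is a property of
  the method, not of the simulation, and is the main known limitation.
- **Null calibration**: 4 cell types × 100 cells × 2 groups, 84 pairs
  (~504 scored tests after masking), 200 permutations, no planted effects.
  The ±2·SE acceptance band around 0.05 is, by construction, exceeded by
  roughly one random seed in twenty.
- **Pathway detection**: 3 cell types × 200 cells, a 4-gene pathway at
  3-fold in one cell type, Poisson(10) baseline, 1000 permutations.

## Numerical notes

- Quantiles everywhere are numpy's default linear interpolation (type 7);
  the outlier and low-expression rules depend on this choice.
- Strict inequalities are used exactly as stated in the decision rules:
  ratio > 10, activity < 1 mM, q < 0.05, |Δscore| > 0.5 (pairs) and > 0.1
  (pathways), enrichment at score > 1; boundary values fall on the
  non-triggering side and are tested on both sides.
- With two cell types, |Z| is constant (±1/√2), so every two-sided
  permutation comparison is a tie and p ≡ 1: the communication test is
  uninformative at K = 2 by design of the statistic; use K ≥ 3.
- Writers emit deterministic TSVs (stable sort order, 6 significant
  digits); every CLI run can record a JSON manifest with parameters, seed,
  input SHA-256 digests and filter attrition, sufficient to reproduce the
  run.
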