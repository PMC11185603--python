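# Methods

## Scope and model

immunorank ranks genes as candidate immunotherapy surface targets by a
weighted average of transformed evidence features and learns the
feature parameters by maximizing mean average precision (MAP) against
known-positive/known-negative targets. This note records the modelling
assumptions, the tunable parameters and their defaults, the numerical
choices, what the synthetic benchmark does and does not emulate, and known
limitations.

## Expression summaries

The tumor matrix (genes × samples, non-negative, missing allowed) yields
five per-gene features: mean and maximum over non-missing samples, the
count of samples with any expression (> 0), and the counts of samples
strictly above a high threshold / strictly below a low threshold. The
thresholds are *global* percentiles of all non-missing values in the matrix
(defaults: 20th and 80th), computed with the linear-interpolation
percentile rule; per-gene percentiles would make the counts constant across
genes and carry no information. Ties at a threshold are not counted —
"below" and "above" are strict. Duplicate gene symbols are collapsed by the
per-sample maximum (detection evidence wins); gene symbols are uppercased
and trimmed, with no alias resolution.

Mean and maximum were chosen as the two location/scale summaries
accompanying the three count features: they are the minimal pair that
captures both typical and peak expression, the quantities antibody
engineers ask about first.

## Enrichment features

* **Normal tissue** (per database, ten features): tissue-level value =
  median of the tissue's samples; features are the maximum tissue value,
  maximum sample value, counts of tissues/samples strictly above the
  high-expression threshold, and a normalized maximum — max over tissues of
  tissue value × (tissue sample count / total sample count), a peak that
  discounts tissues represented by few samples. Each is computed with all
  tissues and with brain tissues excluded (blood-brain-barrier-excluded
  therapies tolerate brain expression). The threshold defaults to 10
  TPM/RPKM for RNA snapshots and to the 90th percentile of all snapshot
  values for proteomic intensities.
* **Localization**: pass-through of two surface-confidence scores
  (validated ranges 0–4 and 0–5) and extracellular-domain length in
  residues.
* **Dependency**: probability that the gene is a viability dependency,
  aggregated over the cell lines annotated to the queried phenotype by mean
  (default) or max.
* **Gene sets**: binary membership per selected set.
* **Therapy records**: per gene, the signed development-phase score of the
  best (maximum-score) record matching the disease after optional
  mode-of-action filtering. Default phase map: approved 1.0, phase3 0.8,
  phase2 0.6, phase1 0.4, preclinical 0.2, discontinued −0.5 (fully
  configurable). Genes whose best score is positive are known-positives;
  negative, known-negatives. Disease matching is exact on a normalized
  string; no ontology expansion.

Genes absent from a snapshot get missing values, resolved later by
imputation; a gene absent from the normal-tissue snapshot counts as
normal-tissue *restricted* in the restriction view (no detected normal
expression), with a logged caveat.

## Transform stack

Fixed order, applied at most once: rescale → impute → curve → weight.

* Rescale (default `percentile`): average-rank / n, mapping into (0, 1] and
  invariant under strictly monotone transforms of the raw column; `minmax`
  and `none` available (constant columns map to 0.5 under minmax).
* Impute (default `min`): absent evidence is treated as the weakest
  observed support — the conservative choice for nominating targets;
  `mean`, `median`, `zero` available.
* Curve: the rational family f(x;c) = (1+c)x/(1+cx) for c ≥ 0, x/(1+|c|(1−x))
  for c < 0. It fixes both endpoints, is strictly monotone, is the identity
  at c = 0, and f(·;−c) inverts f(·;c); c ∈ [−5, 5] by default.
* Weight: signed multiplier, w ∈ [−1, 1] by default; negative weights
  penalize (e.g. normal-tissue expression).

The score is S_g = Σ_f w_f·f(r_gf;c_f) / Σ_f |w_f|. Absolute-value
normalization keeps the scale stable under negative weights and differs
from the plain product-sum only by a positive constant, so rankings — and
every ranking-based quantity — are identical. Ties are broken by ascending
gene symbol for bit-reproducibility. The rank percentile is
100·(n−rank)/(n−1) (100 for the top gene), and the top-k% view keeps genes
with percentile ≥ 100−k inclusive, so it is never empty.

## Evaluation

AP = (1/|P|) Σ_i i/r_i over the positives' ranks. Two modes: `labeled_only`
(default whenever negatives are present) first restricts the ranking to
labeled genes so each negative ranked above a positive directly lowers
precision; `full_list` ranks positives against the entire list and serves
phenotypes without negatives. MAP is the arithmetic mean of AP over
phenotypes.

GSEA enrichment: genes sorted by descending score (ties by symbol); the
running sum gains |score|^p / Σ_set |score|^p at set members (p = 1 default,
p = 0 rank-only) and loses 1/(N−N_hit) elsewhere; ES is the extremum of
largest magnitude. The permutation null draws size-matched gene sets
without replacement; p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1), never
exactly zero. When the number of distinct size-k subsets is at most n_perm
the null is enumerated exactly instead (p = fraction of all subsets at
least as extreme, the observed set included).

## Optimization

Objective: mean AP over the projects (multi-cancer) or the project's own AP
(phenotype-specific), computed from the rescaled+imputed matrix with the
candidate (w, c) applied on the fly. When negatives exist only the labeled
genes can affect the AP, so the objective is evaluated on that submatrix.

* **SFS + Brent.** Candidates in alphabetical order; each enters at the
  neutral (w = 1, c = 0) and its weight, then curve, is line-searched while
  the rest stay fixed. Because the AP objective is piecewise constant in
  any single parameter, the line search is a 21-point grid scan followed by
  bounded Brent refinement in the bracketing sub-interval, never worse than
  the neutral start and never outside the bounds. After a tentative
  inclusion, a coordinate-wise Brent polish over all selected weights and
  curves performs the local-maximum search; candidates tying the round's
  best within the gain threshold are polished before acceptance is judged.
  The round's best polished configuration is accepted only if it improves
  the objective by ≥ 0.1 % relative (absolute floor 1e−6 when the objective
  is 0); otherwise selection stops.
* **GA + Nelder-Mead.** Real-coded GA over the concatenated (w, c) vector
  of the selected features: population 50 (first individual = the SFS
  solution, the rest Gaussian perturbations), 40 generations, tournament
  selection (k = 3), one-point crossover, per-coordinate Gaussian mutation
  (rate 0.3, sd 5 % of the parameter range), 10 % elitism. Each generation
  the top 2 individuals are polished with bounded Nelder-Mead (maxfev 80).
  The incumbent starts at the SFS solution and is replaced only by a
  candidate exceeding it by the same 0.1 % rule, so refinement can never
  lower the result; a terminal coordinate-wise Brent polish (keeping any
  strict improvement, as after an SFS inclusion) closes the run. All GA
  hyperparameters are configurable; the seed is mandatory and every run is
  bit-reproducible.

Multi-cancer mode requires ≥ 2 projects and returns one shared parameter
set; phenotype-specific mode returns one per project. Projects without
known positives are excluded with a warning (fatal if none remain).

A known behaviour of greedy forward selection with the 0.1 % inclusion
rule: on a phenotype whose labeled sample gives every additional feature a
sub-threshold *marginal* gain, selection stops early even when a larger
feature set would do better jointly. A parameter set trained across many
phenotypes can therefore occasionally outrank the phenotype's own
greedy-selected set on that phenotype. On the planted benchmark this
affects roughly 1 % of phenotype×seed combinations; the corresponding
strict ordering test documents it by failing on those cases.

## Synthetic benchmark

Defaults (the study conditions): 12 phenotypes, 500 genes, 8 tumor samples
per phenotype, 5–15 known positives (uniform per phenotype) drawn from a
100-gene target-like pool, 40 known negatives per phenotype from a 120-gene
failed-target pool, 40 features of which 9 are informative (the four
label-associated expression summaries, three localization fields,
dependency, gene-set membership).

Planted structure: positives are elevated in tumor expression (log2FC 2)
and carry high localization confidence (penetrance 0.9), high dependency
probability in their phenotype's cell lines (penetrance 0.85, consistent
across the lines), and gene-set membership (0.85). Negatives share a weaker
tumor-expression elevation (log2FC 1.2) — discontinued-drug targets were
genuinely expressed proteins — but none of the other merit, so default
equal weights barely separate the labels and an optimizer must discover
the discriminating channels. The three normal-tissue snapshots are
label-independent nuisance whose 30 feature columns are strongly correlated
through a shared per-gene latent expression level plus gene-by-tissue
effects, mirroring how real normal-tissue resources measure the same
underlying biology. Expression noise is lognormal with 5 %
missing-completely-at-random dropout; snapshots have partial gene coverage
(85–90 %) to exercise imputation.

What passing tests on this benchmark do **not** show: robustness to real
mass-spectrometry intensity distributions, tissue-correlation structure,
gene-symbol aliasing, ontology-level disease matching, or label noise in
therapy databases — none of which the generator attempts to emulate.

## Degenerate inputs and numerical conventions

All-missing matrices/columns are fatal with the offending column named;
constant columns are legal everywhere (minmax → 0.5; strict threshold
comparisons count zero). Percentiles use linear interpolation throughout.
Curve inputs are validated to [0, 1] within 1e−9 (skipped for c = 0, the
identity). Manifest files hash inputs and record outputs relative to the
run directory, so reruns into different directories are byte-comparable;
no output embeds timestamps.

## Limitations

Greedy selection is order-dependent and myopic (see above); the GA cannot
re-activate features the selection stage rejected. Disease and gene
matching are string-exact. No cross-validation: optimized parameters are
in-sample for the projects supplied, and the multi-cancer/phenotype-specific
comparison on fresh phenotypes is the user's responsibility. Scores carry
no uncertainty estimates.
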