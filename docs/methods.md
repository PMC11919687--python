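# Methods

## Data model

Expression lives in a genes × cells container (`CellMatrix`): integer UMI
counts (MatrixMarket triplet on disk) plus a log-normalized layer
`log10(1 + s·c_gc / Σ_g c_gc)` with scale factor `s = 10,000` (the 10x
community convention; the source protocol does not pin the constant, so it
is exposed as a parameter). Base-10 logarithms are used throughout because
the downstream models are defined on log₁₀-normalized UMI counts.
Clonotypes are rows of a validated table keyed by `(clone_id, patient)`
with CDR3α/β amino-acid sequences (20-letter alphabet), clone size, a label
in {tumor_reactive, non_tumor_reactive, unknown}, an avidity call in
{high, low, unknown}, and an in-repertoire frequency. Cells without TCR
information stay in the matrix but are excluded from clone-level
operations.

Pseudo-bulk profiles are the arithmetic means of the log-normalized layer
over each clone's cells; weighting clone profiles by clone size exactly
reconstructs the grand mean (a conservation check in the test suite).

## Differential expression

Three engines are implemented; further engines can be registered through a
plugin hook (`register_de_method`) so the registry can host the full set of
pseudo-bulk and single-cell methods a study might compare.

* **Wilcoxon (single-cell).** Two-sided Mann–Whitney per gene on
  log-normalized cell values, no pre-filtering of genes. Exact null when
  the smaller group has ≤ 8 cells and the gene has no ties; otherwise the
  normal approximation with tie correction. An all-tied gene is defined to
  have P = 1.
* **Quasi-likelihood F (pseudo-bulk).** Because the input is clone-average
  log-normalized expression — already variance-stabilized, not raw counts —
  the working model is a two-group Gaussian linear model per gene with a
  *quasi-dispersion*: the residual variance (df = n−2) is shrunk toward a
  lowess mean–variance trend with empirical-Bayes weights. The prior
  degrees of freedom d₀ are estimated by matching the spread of
  log-variances around the trend to the theoretical scaled-F spread
  (trigamma moment equation solved by Newton); the posterior variance is
  (d₀s₀² + d·s²)/(d₀+d) and the group effect is tested with
  F = n̄(m₁−m₀)²/s̃² on (1, d+d₀) df (χ² limit when d₀ = ∞). Simulated
  Gaussian nulls give a type-I error within [0.03, 0.07] at α = 0.05
  (asserted in the tests at 2,000 genes).
* **Moderated t (pseudo-bulk).** The same trend-shrinkage machinery
  reported as a t statistic with augmented df; with the prior weight forced
  to zero it reduces exactly to the ordinary pooled two-sample t.

logFC is reported as `(mean₁ − mean₀)/log10(2)` on the log₁₀ analysis
scale, i.e. the log₂ fold change of geometric means of (1 + normalized
counts). P-values are Benjamini–Hochberg adjusted by default; Bonferroni is
available per call site (it is the convention used by the LR feature
filter).

**Signature derivation.** Genes are ordered by ascending p-value or
descending |logFC|; ties break by |logFC| then lexicographic gene id (a
total, documented order so results are reproducible). `side="up"` keeps
positive-fold genes; `side="both"` splits the length budget between up and
down genes proportionally to availability (the split rule is not specified
by the protocol; proportional allocation is this package's choice). A
too-short gene pool truncates with a warning rather than erroring.

## Scoring, scaling, thresholding

All four cell-scoring schemes are documented generic analogues of the
common signature-scoring families (exact third-party formulas are not
re-implemented; the method tag records which analogue produced a score):

* `average` — mean z-scaled (per-gene, training statistics) expression over
  up genes minus the down-gene mean.
* `rank_auc` — expression ranks (descending, average ties) capped at
  ⌈top_frac·G⌉+1; score is the Mann–Whitney AUC between signature and
  background genes on the capped ranks. Perfect top-enrichment scores 1; a
  random gene set has expectation exactly 0.5 for any `top_frac`
  (this cap-AUC form was chosen over a truncated recovery-curve integral
  precisely to get a top_frac-independent chance level). Default
  `top_frac = 0.05`.
* `u_score` — ranks capped at `rank_cap` (default 1,500); the capped U
  statistic mapped to [0, 1] with U_max = S(cap − (S+1)/2), so the best
  case is exactly 1 and the all-at-cap worst case exactly 0. Monotone in
  every signature gene's rank.
* `rank_mean` — mean ascending rank of the up genes, centered:
  (mean rank − (G+1)/2)/G ∈ (−0.5, 0.5); antisymmetric under ranking
  reversal.

Down genes are always scored on the reversed ranking (or subtracted z-mean)
and subtracted. Scores are scaled as (x − μ_t)/σ_t with μ_t, σ_t estimated
on **training cells only**; clone scores are the maximum over member
cells; the decision threshold τ is the training-accuracy-maximizing
midpoint between adjacent distinct sorted scores (ties toward the smallest
τ; all-equal scores fall back to that value), with `score ≥ τ → reactive`.
By default τ is fit on clone-level scores against clone labels; a
`threshold_level="cell"` switch fits it on cell scores against broadcast
labels instead — the text of the underlying protocol is ambiguous between
the two orders, so both are provided with the clone-level fit as default.

## Elastic-net family

Cells inherit their clone's label. RNA space: per-gene z-scaling, then
greedy correlation pruning visiting genes in variance-descending order and
keeping a gene only if |r| ≤ 0.8 with every gene already kept (the pruning
order is unspecified upstream; variance-descending keep-first is fixed here
for determinism), then an optional filter: rank-sum association p < 0.01,
or DE with Bonferroni-adjusted p < 0.05. PCA space: components of the
z-scaled training matrix, kept by explained-variance ratio > 10⁻⁴ or the
association filter. The solver is scikit-learn's saga with the objective
(1/n)Σ loss + λ(α|w|₁ + (1−α)|w|₂²/2); the unpenalized intercept is
profiled out exactly after the fit (1-D Newton), which is a no-op at the
joint optimum and removes solver bias in the heavy-penalty limit, so
λ → ∞ yields zero coefficients and an intercept equal to the logit class
prevalence. Default grids: α ∈ {0, 0.25, 0.5, 0.75, 1},
λ ∈ 10^{−4..1} (6 log-spaced values); no class weights.

The default registry exposes one signature model per DE engine and the
LR grid {no filter, association filter, DE-Bonferroni × engine} in RNA
space plus the two PCA recipes — with eight registered DE engines this is
exactly ten RNA- and two PCA-based LR models.

## Evaluation

LOPO folds hold out one whole patient each; nested CV tunes
hyperparameters in an inner LOPO over the outer-training patients by mean
inner MCC (ties keep grid order), evaluates clone-wise on the outer fold,
and averages outer MCC **unweighted across folds** (each patient counts
equally; pooled confusion counts are also recorded since the alternative
pooling convention is defensible). The winner is refit on all data after a
final LOPO tuning pass. MCC uses the zero-denominator → 0 convention
("reliable" MCC). ROC AUC is the rank formulation with tie correction.
One-class inner folds are skipped with a warning and recorded.

Y-randomization permutes the clone labels uniformly (multiset preserved)
before each complete LOPO rerun and summarizes the per-repetition
fold-averaged MCC and accuracy over 100 repetitions.

## TCR features, avidity and clustering

CDR3 loops are summarized by per-descriptor means of the five Atchley
factors over the central residues — the default mask drops 3 N-terminal
and 2 C-terminal residues as buried framework-proximal positions —
concatenated with the retained length. Sequences shorter than the mask
fall back to the full sequence with a warning. The property table and mask
are configurable (alternative tables load from TSV), since the exact
solvent-exposure definitions of the published avidity and TCR-distance
tools are not redistributable; both components here are clearly labeled
trainable/configurable analogues, not re-implementations.

* **Avidity analogue**: standardized pooled CDR3β descriptors → regularized
  logistic regression → high/low call at probability ≥ 0.5 (boundary =
  high). Clones without a CDR3β are called `unknown` and excluded
  downstream.
* **TCR distance**: chain-weighted root-mean of per-chain Euclidean
  distances between descriptor vectors; a missing α chain in either TCR
  renormalizes to β-only. The metric is Euclidean per chain, hence
  symmetric, zero on identity, and triangle-inequality-respecting (property
  tested). Both chains are used when present.
* **UPGMA**: average linkage on the distance matrix (scipy linkage behind
  the package surface; an independent brute-force average-linkage oracle
  backs the tests). Cluster cuts remove the k−1 highest merges by walking
  the merge list, which always yields exactly k clusters — even for
  degenerate all-equal distance matrices, where ties break by merge order.
  Dendrograms export to Newick.

## Candidate-selection pipeline

Filter to `avidity_call == high`, then to `trt_call == true`; rank by
`trt_score` (ties: larger clone, then clone id — every ranking step has a
total order, so the pipeline is deterministic); keep the top 20; cluster
and cut at k = 5; select the argmax-score clone per cluster. `top_n` and
`k` are flags: 5 clusters matches the validated reference run but is
explicitly adaptable to the clinical context, and the pipeline errors with
that advice when fewer than k clones survive. Output embeds provenance
(model id, config hash, parameters).

## Synthetic cohorts

The generator emulates the structure the predictor assumes. Defaults (the
reference conditions, chosen once): 10 patients × 40 clones; clone sizes
geometric with mean 4 cells; 1,000 genes with log-normal baseline means
(meanlog log 0.2, sdlog 1.2 — sparse T-cell-like UMI depth over a
variable-gene-scale panel); negative-binomial counts with dispersion
φ = 0.3 (Var = μ + φμ²), matching the mean–dispersion family the
pseudo-bulk tests assume; 50 up / 25 down signal genes shifted by
e^{±effect} in cells of reactive clones with effect_size = 1.0 (moderate);
reactive fraction 0.5, mirroring the near-balanced annotated cohorts such
predictors are trained on; labels assigned clone-wise and broadcast to
cells. CDR3s (lengths 10–18, canonical alphabet) come in 5 mutational
families with ≤ 2 substitutions per member; ground-truth avidity follows a
threshold on the first Atchley factor of the masked CDR3β with 5% label
flips, so the avidity analogue has a learnable planted rule.

What the generator does **not** emulate: doublets, ambient RNA, batch and
patient covariate shifts, UMI saturation, dropout beyond NB zeros,
V(D)J-realistic CDR3 grammar, or any dependence between transcriptional
state and TCR sequence. Passing tests therefore demonstrate correctness of
the statistical machinery under its stated assumptions, not performance on
real tumors.

## Numerical and design choices

* Problem sizes in the test and acceptance runs (300–1,000 genes, 6–10
  patients, 100 permutation repetitions) are the package's reference
  desk-scale conditions; all are parameters.
* Lowess trend fraction 0.5; variance floor 10⁻¹² before logs; trigamma
  inverse by 75-step Newton with analytic derivative.
* Exact-vs-asymptotic switch for the rank-sum test at group size 8.
* Threshold candidates are restricted to adjacent-distinct midpoints by
  construction, so train accuracy is exactly reproducible by exhaustive
  search (asserted to 10⁻⁹).
* Seeds: every stochastic component takes an explicit seed; derived seeds
  stay below 2³¹.

## Known limitations

The pseudo-bulk engines are Gaussian working-model analogues, not
numerical clones of the corresponding count-based bulk packages; their
agreement is in calibration and ranking behavior, not digit-for-digit
statistics. The avidity model and TCR distance are physicochemical
stand-ins with configurable tables. Cross-dataset transfer (training on
one cohort, applying to another sequencing chemistry) is out of scope, as
is any wet-lab validation logic.
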