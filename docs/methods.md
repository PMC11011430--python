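# Methods

## Problem setting

Prostate adenocarcinoma differentiation is graded histologically by the
Gleason system: the two most prevalent growth patterns (each 3–5) sum to the
Gleason score, regrouped into ISUP grade groups 1–5 (1: GS ≤ 6; 2: 3+4;
3: 4+3; 4: GS 8; 5: GS 9–10). The package treats grade group as an ordinal
covariate of bulk gene expression (FPKM_UQ units) and asks two questions:
which genes track differentiation, and how small a gene panel suffices to
classify a tissue sample as normal, low-Gleason (groups 1–3) or
high-Gleason (groups 4–5).

## Statistical components

**Differential expression.** Per gene, an unpaired Welch *t* test of tumor
vs. normal samples (a pooled-variance flag exists; Welch is the default
because FPKM variance is strongly expression-dependent). Fold change is
computed on raw group means with pseudocount ε = 10⁻³,
`log2FC = log2((m_T+ε)/(m_N+ε))`; ε only matters for all-zero genes. Genes
with zero variance in both groups are kept with p = 1 and a degeneracy flag
so denominators of downstream counts are stable. All p-values are adjusted
by Benjamini–Hochberg step-up over the full gene list.

**Grade correlation.** Per-gene Pearson *r* against the integer grade
score, by default over tumor samples only (normals carry no grade group; an
option codes them as 0, consistent with the observed
normal→low→high expression trajectory). Correlation is computed on the raw
FPKM_UQ scale to mirror the conventional protocol; a `log2p1` option is
less tail-sensitive. Two-sided p-values come from the exact t
transformation of *r*; constant genes get r = 0, p = 1, flagged. Genes are
ranked by |r| (strong negative correlates are as informative as positive
ones); a signed ranking is exposed for users who want directional lists.

**kNN protocol.** All classification uses the same protocol: a random
50:50 train/validation split (stratified by class by default, so every
class is present in both halves; an unstratified mode reproduces a literal
"random split"), features log2(x+1)-transformed and z-scored per gene with
location/scale fit on the training half only (raw-scale Euclidean distance
would be dominated by high-abundance genes; a `raw` mode exists), k = 10
neighbors by Euclidean distance, class probability = neighbor vote
fraction. Prediction tie rule, which matters at k = 10 with 3 classes: a
vote tie goes to the tied class with the smaller summed neighbor distance,
any residual tie to the fixed order normal < low < high. Global accuracy is
the fraction of validation samples classed correctly.

**Decorrelation network.** Candidate genes are linked when their pairwise
|Pearson r| (log2(x+1) scale, all analysis samples) is *below* the 0.2
threshold; "degree" is plain undirected degree (correlation is symmetric,
so no direction exists), and candidates are nodes with degree > 10, i.e.
genes weakly correlated with many others — carriers of non-redundant
information. The number of survivors is whatever passes the cut, sorted by
degree then gene ID; `max_selected` caps the pool, which is needed at small
simulated scale where most noise genes pass. A signed-threshold option
(r < 0.2 rather than |r| < 0.2) is available.

**Signature search.** Exhaustive enumeration (no greedy shortcuts — the
search spaces, ≈6×10⁴ per route, are tractable): route A enumerates sizes
3–6 over the top-20 correlated genes; route B does the same over the
network-filtered candidates from the top 200. Per route, genes are ranked
by *marginal accuracy* (mean accuracy of all evaluated combinations
containing the gene) and the top 8 kept. The pooled 16 are searched at
sizes 3–8 (the final round must be able to produce an 8-gene signature,
which sizes ≤ 6 cannot; a strict 3–6 mode is configurable). The signature
is the best-accuracy combination; ties break toward the smaller set, then
the higher mean per-class AUROC, then lexicographic gene order. All
combination evaluations within a run share one split/seed so accuracies are
comparable. Implementation note: per-candidate-gene squared-difference
matrices between the validation and training halves are precomputed once,
so each combination costs a few matrix additions and one k-selection.

**Evaluation.** One-vs-rest ROC per class on the kNN probability, AUROC by
trapezoid over the ROC curve — with midrank tie handling this equals the
normalized Mann–Whitney U, which the tests verify against a brute-force
pairwise count. AUROCs are computed on the validation half, consistent with
the train/validate protocol (a full-cohort mode would inflate them).
Gene-set comparisons reuse one split across sets. Class separation of a
gene subset is summarized as the silhouette score of the three classes on
the first two principal components of the transformed subset — a
deterministic measurement chosen in preference to t-SNE projections, which
are visualization, not measurement.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
not the full covariance of real TCGA data. Log2 expression is

    log2 x_gs = b + e_g·G_s + ρ·f_{B(g),s} + ε_gs,  ε ~ N(0, σ)

with baseline b = 5 (a typical log2 FPKM_UQ magnitude), grade covariate
G_s ∈ {1..5} for tumors and 0 for normals (one latent axis from normal
through high grade), planted genes carrying e_g = ±effect_size (alternating
signs, default 0.35 per grade step — strong enough to rank reliably at
cohort scale without being trivial), block genes sharing a standard-normal
latent factor with loading ρ = 0.8 and *no* grade effect (so the
redundancy the network filter removes is separable from signal), and noise
σ = 1.0 log2 units, a typical bulk-RNA dispersion. Group sizes default to
the published cohort (52 normals; 45/146/101/64/141 tumors in groups 1–5).
Clinical covariates are drawn per grade group from the published empirical
frequencies (age normal with the published mean/sd; ethnicity, pathologic
T/N, clinical M multinomial conditional on being observed — the generator
emits no missing clinical values). Gleason patterns are drawn consistently
with the grade group. Everything is reproducible bit-for-bit from one seed.

What the simulator does **not** model: library-size artifacts, count noise
at low expression, realistic gene–gene covariance beyond single-factor
blocks, or confounding between clinical covariates and expression. Passing
tests on synthetic cohorts therefore demonstrate correctness of the
machinery and recoverability of planted structure — not clinical
performance on real cohorts, which must be established on real data.

## Canned studies

`gleason_sig.experiments` fixes two reduced-scale study designs, sized so a
ten-replicate study runs in minutes on one CPU (the planted structure is
what the method consumes, so recovery behaviour is informative at this
scale):

- **Planted recovery** — cohorts of ~600 samples (published group
  proportions) × 500 genes with 8 planted genes at effect 0.5, σ = 1;
  candidate pools capped at 12 (direct route) and 40→12 (network route).
  The study reports, per replicate, how many planted genes the final
  signature contains and its accuracy/AUROCs on an independently simulated
  held-out cohort.
- **Null calibration** — the same cohort shape with no planted effects
  (blocks kept): the fraction of genes at q < 0.05 in the correlation
  ranking, and kNN accuracy under randomly permuted balanced labels, which
  should sit at the 1/3 chance level.

## Numerical conventions and edge cases

- BH adjustment via `statsmodels.multipletests("fdr_bh")`; verified against
  a literal step-up implementation to < 10⁻¹².
- Chi-squared without continuity correction (standard for tables larger
  than 2×2); zero-margin rows/columns dropped with a warning; per-variable
  missing values excluded, which reproduces published percentages whose
  denominators differ across variables.
- Duplicate Ensembl IDs after version stripping: the row with the highest
  mean expression wins, deterministically, with a warning.
- Multiple tumor aliquots per patient: one kept (lexicographically smallest
  sample ID); all matched normals kept. The published cohort counts imply
  one tumor record per patient but do not document the collapse rule; this
  is a deterministic choice.
- Protein-coding restriction is delegated to an optional gene-ID allowlist
  rather than bundling an annotation database.
- Exact distance ties in neighbor selection are resolved by a canonical
  (input-order-independent) training ordering in `knn_predict_proba`;
  within the selection pipeline the training order is fixed by the split,
  so runs are deterministic.
- Advanced-T-stage summaries report the percentage both including and
  excluding T4 in the numerator, because published "T3a or higher"
  percentages are ambiguous about T4.

## Known limitations

- Raw-scale Pearson ranking is sensitive to extreme FPKM values; the
  `log2p1` option is recommended when tails are heavy.
- Marginal-accuracy pooling can admit a hitchhiker gene that co-occurs with
  strong genes; the final exhaustive round usually, but not always, removes
  it.
- With very strong effects the validation accuracy saturates and many
  combinations tie at 1.0; the smaller-size tie rule then returns a compact
  subset of the informative genes rather than all of them. This is the
  intended reading of "best" but means signature size is not a stable
  output near saturation.
- AUROC on a 50% validation half of a small cohort has substantial seed
  variance; `n_repeats` averages over repeated splits when stability
  matters.
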