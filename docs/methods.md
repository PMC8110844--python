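# Methods

This note records the models, parameter choices and numerical conventions
behind `emtdecouple`, and what the synthetic benchmarks do and do not show.

## Expression scales

Single-cell expression is transcripts-per-million (TPM) converted to
`log2(TPM/10 + 1)`; the division by 10 reflects an upper-bound estimate of
~100,000 transcripts per single-cell library. Bulk values are on the same
log2 scale. "Genes detected" means strictly positive entries. Cells with
fewer than a configurable number of detected genes (1000 for real data; 600
for the 1200-gene synthetic universe) are removed before any analysis.

## Synthetic data model

The generator is the package's study design: its defaults define the
conditions under which recovery is demonstrated.

* **Genes.** 1200 genes on 6 chromosomes. Planted programs: 70 pEMT genes
  (containing SNAI2), 100 CAF genes (containing VIM, SNAI1, TWIST1, ZEB1,
  ZEB2 — the classical markers are CAF-biased, as observed in tumours),
  80 shared genes expressed by both compartments, 20 epithelial markers
  (CDH1, EPCAM, SFN, keratins), and 25 marker genes for each of endothelial
  cells, macrophages and T cells. Baseline TPM is log-normal
  (log2 mean 3.5, sd 1.5), scaled to ~1e6 per cell.
* **Programs as log2 mean shifts.** CAF program +3 in CAFs; pEMT program
  +1.5 in pEMT-state cancer cells — half the CAF shift, so cancer-cell
  expression of the partial program stays weak and comparatively uniform;
  shared genes +2.5 in CAFs and +1.25 in pEMT cells; cell-type markers +3;
  epithelial genes +2 in cancer cells. These magnitudes are the package's
  own calibration: they produce the qualitative contrast (CAFs expressing
  ESGs broadly and strongly, cancer cells a weak subset) without claiming to
  match any real effect size.
* **Noise.** Log-normal dispersion (σ = 0.4 natural log) and
  expression-dependent dropout: gene *g* in cell *c* is detected with
  probability `1 − exp(−TPM·capture_c / 100)` with per-cell capture
  efficiency uniform on [0.08, 1]. This gives a ≥ 2-fold span in genes
  detected while leaving highly expressed genes stable — the behaviour real
  scRNA-seq shows. A uniform (expression-independent) dropout was rejected
  because it floods windowed CNA estimates with variance from high-expressed
  genes, which real data does not do.
* **CNAs.** Cancer cells carry a +1 log2 block of 150 contiguous genes on
  chromosome 2 and a −0.7 block of 80 genes on chromosome 5. Block intervals
  are laid out over background genes only, keeping copy-number structure
  orthogonal to the expression programs.
* **Bulk cohorts.** 300 tumours; each sample is a convex mixture of
  noise-free cell-type archetype profiles (cancer split into pEMT and
  non-pEMT states) with log-normal noise (σ = 0.1). The CAF fraction is
  `0.05 + 0.5·Beta(2,5)`, the pEMT fraction (share of cancer cells in the
  pEMT state) `Beta(2,4)`; a Gaussian copula ties them at rank correlation
  0.1, under a configured cap of 0.2 — the "limited correlation" assumption
  the deconvolution relies on. Purity is the cancer fraction. With noise off
  the linear-scale bulk equals the weighted archetype sum exactly.
* **Clinical tables.** Raw Firehose-like vocabularies (integer node counts,
  "n2"/"g3" strings, days-to-death, follow-up outcomes) so binarization is
  exercised end to end. One association is planted: the worse-prognosis
  group of one feature (default grade) has its pEMT exposure
  (cancer fraction × pEMT fraction) shifted by 0.5 standard deviations of
  that exposure. Everything else is null.
* **Cell lines.** Mixtures of the two cancer archetypes (pEMT admixture
  uniform on [0, 0.3]) with log-normal noise — cancer-only by construction,
  so CAF genes are depleted relative to bulk.
* A `stroma_pemt_confound` option rank-correlates the macrophage fraction
  with the pEMT fraction, planting exactly the residual confounding that
  robustness QC is designed to catch.

What the synthetic data does **not** emulate: UMI count statistics, doublets,
batch effects, patient-specific program variants, cell-type capture biases
and the long-tailed sizes of real gene families. Passing tests therefore
demonstrate that the implementation recovers planted structure under the
stated assumptions — not that those assumptions hold in any real cohort.

## Signature scoring

Genes passing the minimum-expression criterion are ordered by mean expression
and split into *m* = 25 bins; each signature gene is compared against
*n* = 100 control genes sampled from its bin with replacement (signature
genes are not excluded from control pools). The cell score is the mean over
signature genes of gene minus control-mean. With a grouping key (e.g.
tumour), binning, sampling and scoring run independently per group, each with
a seed derived from (seed, group index). The same routine scores bulk
tumours in place of cells for the clinical analysis.

## CNA inference and malignant calling

Relative expression (per-gene centring across cells, then per-cell centring
across genes — the second step removes library-size offsets that would
otherwise read as genome-wide copy-number shifts) is averaged over a centred
100-gene window per chromosome, truncated at chromosome ends (windows shrink;
a chromosome shorter than the window uses its full length), then recentred on
the average profile of reference cells (immune + endothelial; CAFs are never
referenced, to avoid biasing the later cancer-vs-CAF comparison). Per cell:
CNA signal = mean of squared CNA values; CNA correlation = Pearson with the
mean profile of the malignant seed, or the best-matching subclone profile
when a subclone partition is supplied (the maximum across subclones — the
choice of how to collapse per-subclone values to one number is ours).
Classification uses four thresholds: below both lows → non-malignant, above
both highs → malignant, anything else → excluded as intermediate.
Thresholds are inputs; the defaults `(0.10, 0.13, 0.5, 0.75)` were chosen by
inspecting the synthetic signal/correlation distributions, mirroring the
manual per-tumour choice the procedure requires on real data, and are
meaningful for the synthetic fixture only. Accuracy is quoted over
definitive calls; intermediates are abstentions by design (~9% at defaults).

## Pseudobulk simulation

The composition sweep draws the focal type's count from
`Normal(µ·q/max(Q), 0.2·µ·q/max(Q))` (truncated below at one cell, rounded),
draws `Uniform(0, µ)` values for every other type (including the merged
"rare cell types" category, which is never itself focal) and scales them by
the closed-form `λ = N_focal(1−q)/(q·ΣN_unif)` before rounding; cells are
sampled with replacement throughout. µ defaults to 100. The deconvolution
cohort uses cancer as the focal type over 40 proportions equally spaced in
[0.1, 0.9] with 25 repetitions, bulk value `log2(Σ_m TPM_{l,m}/10 + 1)` over
sampled cells *m*, purity = realised cancer fraction. ESG contributions are
computed on the TPM scale and always sum to one per tumour.

## Seriation

Distance is `1 − r`. The side-to-side weight vector is the centred linear
ramp `w_i = (n−1)/2 − i`. One iteration scores each item by the dot product
of its distance row with the positional weights and re-sorts ascending
(stable sort, index tie-break); a sort step is accepted only when it strictly
lowers the ramp energy `Σ_ij w_i w_j D_{π(i)π(j)}`. When sorting cannot
improve — including the perfectly alternating fixed points that exactly
symmetric block matrices admit — the algorithm applies the single pair swap
with the most negative closed-form energy change, and stops when neither move
helps (or at 100 iterations). Energy is therefore strictly decreasing across
accepted steps and the terminal state is a local optimum under both moves;
on ≤ 8 items this is verified against exhaustive enumeration. A seed
requests a random starting permutation; the default start is the input order,
making the full pipeline deterministic without a seed.

## Refinement, annotation and QC conventions

* A gene inside the top/bottom 20 excludes its own self-correlation from its
  σ average (a unit self-correlation would bias it).
* σ exactly 0 counts as "same sign" and is removed unless the gene is a
  classical marker.
* All orderings use stable descending sorts with gene-id tie-breaks.
* Running averages are centred windows of 30 truncated at the ends.
* Cell-line track: robust local linear regression (tricube weights, span
  0.25, 4 robustifying iterations — statsmodels lowess) of tumour means on
  cell-line means over all shared genes; the score is observed minus
  predicted, so positive = tumour-enriched (stromal side). The track is
  centred and divided by the maximum absolute running average, bounding it
  in [−1, 1].
* End labels follow the majority of available tracks with single-cell
  evidence — the only direct measurement of cancer-cell vs CAF expression —
  breaking ties and overriding an opposing purity pattern (flagged); a
  purity track opposing the cell-line track with no single-cell data marks
  the dataset excluded. This codifies a judgement call; the annotation
  output flags every disagreement so the rule's verdict is auditable.
* Robustness QC regresses each cell type's marker correlations ρ on ordering
  position scaled to [0, 1] *from the annotated pEMT end*; minimum slope
  ≤ −0.1 excludes the dataset. Separation strength is the mean pairwise
  correlation among the top 30 genes per end (self-pairs excluded) versus
  the mean cross-correlation of the two top-30 sets.

## Cross-cancer scores and clustering

Per type, the score of gene *g* is its mean residual-space correlation with
the type's top-20 pEMT genes minus that with the top-20 CAF genes, divided by
3 × the standard deviation across scored genes (computed over non-missing
values) and clipped to [−1, 1]. Significance is a two-sided one-sample
t-test against zero (all-zero scores give p = 1 by convention; non-zero
constant scores report a missing p). Commonness ranks use position/length
with absent genes at 0.5; percentiles use linear interpolation. With the
pEMT end at position 1, the most common pEMT genes have the *lowest* 25th
percentile — the orientation is fixed by an explicit check against the end
annotation. Types cluster by average linkage on `1 − correlation` over the
100 most common pEMT genes; silhouette ≤ 0.2 flags intermediates, removed
from the final three clusters. Missing scores are excluded pairwise.

## Clinical statistics

Binarization rules: ≥ 2 metastatic lymph nodes vs none (exactly one node
unassigned — "at least 2 versus none" leaves singletons out); N stage 2–3
vs 0–1; lymphovascular invasion present vs absent; grade 3–4/"high grade"
vs borderline/1–2/"low grade"; T stage 3–4 vs 0–2; days-to-death below the
40th percentile vs above the 60th; recurrence vs complete remission after
follow-up treatment. Vocabularies are matched case-insensitively; unknown
values stay unassigned and are logged. M stage is parsed but excluded from
default runs. The rank-sum test uses the exact null distribution for
tie-free samples with n₁+n₂ ≤ 12 (so small-sample p-values equal exhaustive
enumeration) and the normal approximation with tie and continuity correction
otherwise. Features with fewer than 10 assigned samples are skipped.
BH-FDR runs per feature or globally; the realized threshold (largest
accepted p) is reported per scope. Positive effect = higher score in the
worse-prognosis group, uniformly.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical claims are stable:
1200 genes; 600–1500 cells; 150–300 bulk samples; 10–20 generator seeds for
recovery rates; 100 random seriation starts; 1000 null simulations and 50
planted-effect replicates for the clinical calibration. The full test suite
runs in about a minute; the acceptance script in about 20 seconds.

## Known limitations

The method infers cohort-level gene clusters, not per-sample decompositions
of ESG expression into cell-type amounts. Heterogeneity within CAFs (or
cancer cells) is ignored; contributions of other TME types are filtered
against, not modelled. The annotation priority rule reproduces the narrative
decisions it formalizes but remains an interpretation; its verdicts are
flagged in output metadata. Reported real-data list sizes (e.g. ESG counts
per cancer type) depend on the original cohorts and are not reproduced
synthetically.
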