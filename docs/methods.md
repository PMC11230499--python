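# Methods

## Scope

`lactsig` re-implements, as a tested library, the computational analysis
used to find a rare "PPBC-like" cell subpopulation in mouse mammary
single-cell RNA-seq, together with the set algebra applied to bulk
RNA-seq time-course DE tables. The study design it targets compares two
conplastic mouse strains — identical nuclear genome, different
mitochondrial haplotype (BL/6^C57 vs BL/6^NZB) — in non-lactating females
and at lactation day 21, three mice per condition. Because the underlying
sequencing data are not publicly deposited, the package ships a
planted-truth simulator so every stage can be validated against known
labels.

## Signature scoring and the PPBC-like call

A signature score is a per-cell log2 feature sum

    score(c) = log2(pc + sum_{g in S} x_norm(c, g)),

with pseudocount `pc = 1` by default. Three design points deserve
explanation, since the browser-based analysis being reproduced does not
fully specify them:

* **Pseudocount.** Raw feature sums can be zero, so the log2 transform
  needs an offset. `pc` is a recorded parameter of every score vector,
  not a hidden constant.
* **Depth normalization.** By default the feature sum is computed on
  median-depth-normalized counts: each cell is scaled so its total
  equals the median per-cell total, which stops sequencing depth from
  masquerading as signature activity. Before that scaling, counts are
  divided by the matrix's *count quantum* (its minimum nonzero entry).
  For any genuine UMI matrix the quantum is 1 and the step is a no-op;
  its purpose is to make the normalized matrix — and therefore every
  score, threshold and call — exactly invariant under a global rescaling
  of the counts, which median scaling alone does not give (it maps `7X`
  to `7 * normalized(X)`, and the log2-with-pseudocount score is not
  invariant under that). Raw-count scoring is available via
  `normalization="none"`.
* **Thresholding.** A cell is positive for a list when its score is at
  least half the maximum score, the maximum taken over all barcodes of
  the experiment pooled (one cutoff per list, recorded in the output).
  Positivity additionally requires a strictly positive score, so an
  all-zero score vector produces no positives instead of all positives.
  Per-sample thresholds are available behind a parameter but are
  deliberately not the default: the rule being reproduced pools every
  barcode of the experiment.

A *PPBC-like* cell is positive for **both** the 6-gene proliferation
list (Cenpe, Ccna2, Ccnb2, Mcm6, Ccnf, Bud1) and the 14-transcription-
factor regulon (Bclaf1, Cux1, E2f1, E2f4, Esr1, Foxm1, Gtf2b, Max, Myc,
Nfya, Nr4a1, Nrf1, Smarca4, Taf1). The lists ship verbatim; "Bud1" is
plausibly a typo for Bub1 but is kept as printed, and any signature gene
missing from a matrix is reported rather than silently dropped. Note the
half-max rule lives in log space: on the linear scale the cutoff is
roughly the geometric mean of the pseudocount and the maximum feature
sum, i.e. it grows like the square root of the top signal. This makes
the separation between background and an 8-fold-activated subpopulation
inherently modest, which drives several simulator choices below.

p53 positivity is a detection call: a luminal-HS cell is p53-positive
when its raw Trp53 count exceeds zero. No normalized cutoff is involved.

## Cell-type annotation

Each cell is labeled luminal alveolar (AV: Mfge8, Trf, Csn3, Wfdc18,
Ltf), luminal hormone-sensing (HS: Prlr, Pgr, Esr1, Cited1, Prom1),
myoepithelial (ME: Krt17, Krt14, Krt5) or `unassigned`. Marker lists are
scored as above, each score vector is z-standardized across cells
(marker lists differ in length and baseline, so a raw-score argmax would
favor long lists), and the cell takes the argmax label provided the best
z is positive; otherwise it is unassigned. Ties break AV < HS < ME. This
per-cell rule replaces graph clustering plus cluster labeling: it is
deterministic, dependency-light and exactly testable, at the cost of
ignoring neighborhood structure; ambiguous cells near cluster borders
may be labeled differently than a cluster-level tool would.

## Bulk DE set logic

`de_filter` keeps genes with BH-adjusted p strictly below alpha (default
0.05, boundary excluded) and a strictly signed log2 fold change; genes
at log2fc = 0 count in neither direction. `venn_partition` computes the
exact inclusion/exclusion partition of 2-3 named gene sets (all
2^k - 1 regions, possibly empty); "exclusive to day d" and "common to
all" are views of that partition. `cross_genotype_unique` splits two
common-up sets into shared/unique parts. DE tables are accepted as
inputs — the upstream contrasts were produced by a vendor platform and
are out of scope; `welch_de_log2cpm` exists only as a convenience for
exercising the set logic on synthetic bulk counts and is documented as
not the published method.

## Replicate statistics

Group comparisons of per-mouse summaries use a two-tailed Welch t-test
(Welch-Satterthwaite df). Welch rather than pooled Student's t is the
default because groups of three mice give no power to verify equal
variances; `equal_var=True` restores the pooled test. Sample variances
are floored at a machine-epsilon-scaled value so degenerate replicate
summaries (all values equal) return finite statistics: identical groups
give (t=0, p=1), complete separation gives a huge finite t. Multiple
testing uses Benjamini-Hochberg step-up everywhere "adjusted p" appears.
Per-gene DE between two cell groups is a two-sided rank-sum test on
log2(1 + normalized counts) with the log2 fold change defined as the
difference of group means on that scale (the test behind the browser's
per-sample DE is not documented; rank-sum is robust for sparse counts
and is recorded in output metadata). Top-gene selection keeps genes with
raw p below 2e-4, ordered by ascending p, then descending |log2fc|, then
symbol — fully deterministic under ties. Heatmap ordering is
average-linkage agglomeration on 1 - Pearson correlation; zero-variance
rows take correlation 0 (distance 1) by convention, and leaf order is
the deterministic dendrogram order. Tumor volume uses the modified
ellipsoidal formula 0.5 x length x width^2, warning (but computing) when
the transverse caliper exceeds the longitudinal one.

## The simulator

`simulate_cells` draws gene-wise negative binomial counts
(mean/dispersion parameterization, variance mu + mu^2/size) with
per-cell log-normal depth factors applied to the mean, so fold changes
act on mu and the NB family is preserved (depth is not applied by
post-hoc thinning for the same reason). Structure planted on top of the
baseline:

* cell types drawn per cell from state-specific fractions — NL: AV/HS/ME
  = 0.40/0.35/0.25; LacD21: 0.70/0.18/0.12, encoding alveolar expansion
  during lactation;
* each type's markers elevated `marker_fold` = 8x in their own type;
* PPBC-like cells drawn per condition (default 0.5% everywhere, 5% in
  NZB-LacD21 only), with every proliferation-list and regulon-list gene
  elevated `ppbc_fold` = 8x; planted cells are HS with probability 0.61
  (the published HS share of PPBC-like cells), the remainder split
  between AV and ME proportionally;
* Trp53 forced to a structural zero with probability 0.8 in NZB-LacD21
  luminal-HS cells only. Structural zeros rather than a reduced mean
  give exact ground truth for the detection-based p53 call.

Default sizes are 12 samples x 2000 cells x 1000 genes. The gene
universe is the union of all signature genes plus Trp53 plus anonymous
fillers.

Baseline expression parameters (defaults: per-gene mean scale 0.40,
log-normal spread sigma = 0.1, NB size 10, depth sd 0.3, and relative
abundance factors: markers 4x, proliferation genes 0.55x, regulon genes
0.25x, Trp53 4x) were chosen for test power under the half-max rule,
with loosely biological motivation: lineage markers (milk proteins,
keratins, hormone receptors) are abundant transcripts, while cell-cycle
and proliferation-regulon transcripts are depleted in largely
postmitotic secretory tissue, and Trp53 is well detected. Two details
matter:

* the proliferation list has only six genes, so its baseline cannot be
  too low or planted cells drop below the square-root-like half-max
  cutoff (recall loss);
* Esr1 belongs to both the HS marker list and the regulon, so baseline
  HS cells carry an 8x-elevated regulon gene; the regulon baseline is
  damped so this leak does not flood the co-expression call with HS
  false positives. The marker abundance factor is likewise not applied
  to Esr1, keeping the planted scoring structure controlled by
  `ppbc_fold` alone.

`simulate_bulk_de` builds per-day DE tables with exactly known Venn
structure: genes are shuffled once from the seed and consecutive blocks
are assigned to a shared significant core and day-exclusive sets, with
`round(fraction x n_genes)` members each; significant genes get padj <
0.05 and signed fold changes at the configured effect size, everything
else is null. Region counts are therefore exact, not approximate.

What the simulator does **not** emulate: doublets, ambient RNA, batch
effects beyond per-cell depth, realistic library sizes or gene counts,
gene-gene correlation beyond the planted structure, and cluster geometry
(cells of a type are exchangeable). Passing recovery tests therefore
shows the scoring/annotation logic is correct and well-calibrated under
the declared generative model — not that the thresholding rule is robust
on real tissue.

## Pipeline and reproducibility

`run_pipeline` composes simulate/load, annotate, score, classify,
per-sample counting, Welch testing, the lactating C57-vs-NZB luminal-HS
DE contrast with its top-40 list, and optional bulk Venn counting. All
thresholds (alpha 0.05, DE p cutoff 2e-4, half-max factor 0.5, top-N 40)
are configuration with those values as defaults, and the manifest
records every parameter, threshold and derived stage seed, so each
number in a report bundle is reproducible from manifest plus inputs. The
single global seed fans out per stage through a named substream (stage
name -> CRC32 -> `numpy` SeedSequence child), keeping stages locally
reproducible without coupling. Output CSVs are written with fixed float
formatting, so identical runs are byte-identical.

Problem sizes used by the shipped checks: planted-recovery runs use the
full default design (24,000 cells); invariance and ranking checks use
500 cells per sample and 300 genes over 20 seeds; calibration uses 2000
null Welch replicates and 500 random p-vectors. These sizes give stable
estimates while keeping a complete run in tens of seconds on one CPU.

## Known limitations

* The half-max cutoff depends on the single highest-scoring barcode; one
  outlier cell moves the threshold for the whole experiment. The rule is
  implemented as published; users with noisy data may prefer to inspect
  the recorded thresholds.
* The per-cell marker argmax does not use neighborhood information and
  will differ from cluster-level labeling near boundaries.
* The rank-sum DE treats cells as independent replicates (no pseudobulk
  aggregation); p-values on real data with mouse-level correlation will
  be anti-conservative.
* `welch_de_log2cpm` is a convenience for synthetic bulk counts only.
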