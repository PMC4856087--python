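# Methods

## The problem and the procedure

Single-embryo RNA-seq of cloned (SCNT) and fertilization-derived (IVF)
blastocysts gives a genes × samples count matrix with a handful of embryos
per group. The question `degscan` answers is spatial: are the genes that
are mis-expressed in cloned embryos *clustered* along the genome, as
expected when a contiguous chromatin domain resists reprogramming, rather
than scattered? The pipeline has four stages.

**Normalization.** Median-of-ratios size factors: for sample *s*,
`f_s = median_g(count_gs / geomean_g)` over genes with positive counts in
every sample. Restricting the geometric mean to all-positive genes keeps
the estimate stable for sparse single-embryo libraries. All downstream
quantities use `count_gs / f_s`.

**Differential expression.** Counts follow a negative binomial with mean μ
and variance μ + αμ². Per-gene dispersion is a pooled method-of-moments
estimate on the normalized scale, `α̂_g = max(floor, (s² − μ̂)/μ̂²)`, with
within-group residual variance pooled over the two contrasted groups
(floor 0.01). Gene-wise estimates at 2–3 replicates have very few residual
degrees of freedom; when they undershoot, the Wald statistic blows up, so
by default each gene's dispersion is the **maximum** of its gene-wise
estimate and a least-squares fit of the classical trend
`α(μ) = a₀ + a₁/μ` across genes — the conservative sharing rule
established for small-replicate RNA-seq. (Set `sharing="gene"` for raw
gene-wise estimates.)

The test statistic is `log2fc / SE` where
`log2fc = log2((m̄_con + c)/(m̄_ref + c))` with pseudocount c = 1 on
normalized group means (finite even with zeros), and the SE comes from the
delta method with per-group variance `(μ·mean(1/f_s) + αμ²)/n`. The
reference distribution depends on how the dispersions were obtained:

* dispersions **estimated from the data** → Student t with the residual
  degrees of freedom of the dispersion estimate (n₁ + n₂ − 2). This
  accounts for variance-estimation noise and makes the test conservative
  at n = 3 per group (empirical type-I error ≈ 0.006 at nominal 0.05 in
  the package's own null simulations), matching the conservative
  small-sample behavior of the classical NB exact-test pipelines. The
  sensitivity cost is deliberate: the genome scan multiplies per-gene
  false positives by the gene count of a window, and a dense cluster
  window (~80 genes) would otherwise be flagged by chance far too often.
* dispersions **supplied externally** (treated as known) → standard
  normal, which is calibrated at nominal level.

Genes below a minimum total count (default 1) are excluded from testing
and from the Benjamini–Hochberg denominator; all-zero genes report
p = 1, log2fc = 0. A DEG is `p < α` (default raw p, α = 0.05; BH-adjusted
mode behind `use_padj`), optionally with `|log2fc|` above a threshold.
Raw p is the default because the discovery procedure this package
re-implements defined DEGs that way; the adjusted mode is the defensible
alternative and the report records which was used.

**Window scan.** Windows of `window_size` (default 2 Mb) at `step`
(default 1 Mb — the scan is described as sliding; the step itself is a
package choice and fully configurable) tile each chromosome from 0 to the
declared chromosome length, the final window truncated. A gene belongs to
every window containing its anchor — the gene start, strand-blind,
half-open membership, so a boundary anchor joins only the later window.
A window is flagged for a contrast when it holds ≥ `min_degs` DEGs
(default 6; 5 mirrors a common display threshold) regardless of direction;
the coordination score (majority-direction fraction of the window's DEGs)
is reported, not filtered on. Flagged windows are intersected across
contrasts on identical grids, then overlapping or ≤ `max_gap`-separated
windows merge into refractory regions. A region's dominant direction is
up/down when ≥ 75 % of its distinct DEGs agree, else mixed.

Under a null in which DEG labels land uniformly at random at rate q, the
flagged-window count follows the binomial tail `P(Binom(n_genes, q) ≥
min_degs)` per window; the suite checks the scanner against both this
expectation and an exact brute-force recount. "Refractory" therefore means
enrichment far beyond that tail, replicated across donor contrasts.

**Locus follow-up.** Relative expression is
`(norm + c)/(mean_ref(norm) + c)` with c = 1 by default (the reference
mean of the output is exactly 1 at c = 0, an identity the tests exploit).
Subset comparison takes, per gene, the mean log₂ relative expression over
the contrast group's samples and applies two-sided Welch t-tests between
subsets — genes, not embryos, are the replication unit, matching
gene-level box plots; the unequal-variance form is the safe default.
Subsets are the cluster's histone genes, its nonhistone genes, the nearest
47 genes upstream and 57 downstream (gene counts, not bp; the flank sizes
are parameters because the source material is internally inconsistent
about side assignment), and histone genes outside the cluster. The
fraction report divides the group-mean sum of normalized counts over
cluster histone genes by the sum over all histone genes; conservation
(cluster + noncluster = total) is exact by construction. Group correlation
is Pearson r on `log2(norm + 1)` group-mean profiles (sample-level mode
for diagnostics); constant profiles yield flagged NaN rather than an
arbitrary value.

Relative expression and fractions use normalized counts, not FPKM — gene
length never enters, which is the right unit for comparing the *same* gene
across groups.

## The synthetic study

The generator emulates the statistical skeleton of a single-blastocyst
RNA-seq comparison at desk scale, not its read-level detail:

| parameter | default | meaning |
|---|---|---|
| `n_chroms`, `genes_per_chrom`, `chrom_length` | 5, 400, 50 Mb | ~8 genes/Mb background density, as in a mammalian genome |
| cluster | 47 histone + 26 nonhistone genes in 1.5 Mb at 30.5 Mb of chr1 | the HIST1-like locus, classes shuffled so they interleave |
| `n_noncluster_histone` | 100 | histone genes scattered on other chromosomes |
| `samples_per_group` | 3 each of IVF, cSCNT, fSCNT, IVF+TSA, fSCNT+TSA | single-blastocyst replicates (n ≈ 3–6 in such designs; 3 is the stringent default) |
| `library_size`, `library_size_cv` | 2×10⁵, 0.3 | gene-assigned counts per library; a desk-scale stand-in for ~10⁷-read libraries |
| `baseline_log_sd`, `histone_boost` | 1.2, 20 | log-normal abundance spread; replication-dependent histones are among the most abundant transcripts, and the boost puts the cluster at ~24 % of total histone output |
| `dispersion` | 0.3 | biological overdispersion between individual embryos |
| `cluster_effect_log2fc` | −2 | coordinated knockdown of cluster histone genes in SCNT groups |
| `tsa_rescue` | 1.0 | fraction of every SCNT effect removed in TSA-treated clones |
| `background_deg_rate` | 0.03 | per-lineage reprogramming-error DEGs (lfc uniform 1–3, random sign), never inside the cluster |
| `tsa_response_rate` | 0.10 | shared TSA transcriptional response, 75 % upregulated, identical in all TSA-treated groups |

Counts are `NB(L_s · p_g · 2^β, α)` where p are baseline abundance
proportions and β the group effect. Two structural choices matter for
interpretation. First, reprogramming-error background is drawn **per donor
lineage** and inherited (scaled by `1 − tsa_rescue`) by that lineage's
TSA-treated group — TSA relieves reprogramming errors globally, which is
what makes the treated pair correlate better than the untreated pair.
Second, the TSA response is a **shared** signature applied identically to
all treated groups, so it cancels in the treated-vs-treated contrast while
producing realistic treated-vs-untreated DEG counts. Background never
falls inside the cluster span, keeping planted truth unambiguous.

What the generator does *not* emulate: read-level artifacts (alignment,
positional bias, gene length), donor-cell expression memory beyond the
planted effects, correlated gene–gene noise within the cluster (each gene
draws independently given its mean), DNA methylation, or chromosome-scale
expression territory effects. Passing tests therefore show that the
*procedure* recovers a planted coordinated cluster at realistic depth,
dispersion and replication — not that any particular biological locus
behaves this way.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; GTF/GFF3 converts at the
  I/O boundary. Strand is stored, never used for windowing.
* Windows tile the full declared chromosome length; trailing gene-free
  windows are harmless because they can never be flagged.
* Dispersion floor 0.01; pseudocount 1 on normalized means for fold
  changes and relative expression.
* Coordination of a DEG-free window is 0 by convention.
* Ties/degenerates: all-zero genes get p = 1; constant profiles give
  flagged NaN correlations; subset pairs with < 2 genes give flagged NaN
  tests; an all-zero sample is a hard error naming the sample.
* BED scores cap at 1000 (format limit); region names carry the
  supporting contrast labels.
* Simulation determinism: one integer seed drives gene placement and
  count draws on separate streams (seed, seed + 1); fixtures are
  byte-identical across runs.

## Problem sizes used by the checks

The acceptance checks run the full pipeline on the default study
(2173 genes × 15 samples) across 20 seeds, the scanner–oracle comparison
on 200 random annotations of ≤ 500 genes, and the calibration null on
2000 genes × 3 + 3 samples; the whole suite completes in well under a
minute on one core. These sizes were chosen as the smallest at which the
binomial pass criteria (≥ 18/20 seeds) are meaningful.

## Known limitations

* The Wald-with-t small-sample correction is conservative; at n = 3 its
  effective level is far below nominal, and weak effects (|log2fc| ≲ 1)
  on low-count genes will be missed. This is the intended trade-off for
  window-level specificity.
* No empirical-Bayes dispersion shrinkage, GLM offsets, or multi-factor
  designs; contrasts are strictly two-group.
* The scan reports enrichment, not per-window permutation p-values; the
  binomial null diagnostic is a guide, not a formal test.
* Flank subsets are defined by gene count, so their genomic extent varies
  with local gene density.
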