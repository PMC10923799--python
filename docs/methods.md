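# Methods

This note documents the models, estimators and numerical choices behind
`diapop`, and what the synthetic-data tests do and do not establish.

## Study design and contrasts

The sampling design is two developmental trajectories of pupae: diapause,
sampled at days 0, 3, 6, 24, 114, 144 and 155 after pupation, and direct
development, sampled at days 0, 3 and 6.  `enumerate_comparisons` builds
(i) the cross-trajectory day-0 contrast, (ii) day 0 versus each later day
within each trajectory ("reference"), and (iii) each adjacent-day pair
("stepwise"), de-duplicating the day-0-vs-first-later pair, which appears
in both schemes — 15 contrasts for the full design.  Classification into
Diap / Both / Dir / None uses only the within-trajectory contrasts: the
cross-trajectory day-0 contrast measures a baseline difference, not change
*through* a trajectory, so it is computed and reported but excluded from
the category definition.

## Differential tests

All three tests are two-group tests applied per contrast, with BH
adjustment within the contrast and significance at adjusted p < 0.01.

**Normalization.**  TMM (trimmed mean of M-values): the reference sample
is the one whose 75th-percentile CPM is closest to the across-sample mean;
per-sample factors are the double-trimmed (30% on M, 5% on A),
precision-weighted mean of log2 ratios against the reference, rescaled to
geometric mean 1.  The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ≤ 1e-6 on a frozen fixture.  Log CPM
uses natural logs with a +0.5 count and +1 library offset so zero counts
stay finite.

**Exon usage.**  Exons are filtered by the usual count rule (CPM ≥
10/median-library-in-millions in at least k samples, k the smallest
trajectory×day group size, and total ≥ 15, both inclusive).  Per exon, a
G-test (1 df) on the 2×2 table of group-summed exon vs. rest-of-gene
counts asks whether the exon's within-gene share differs between groups.
Per gene, exon p-values combine via Simes: p_gene = min_i m·p_(i)/i.
Genes with fewer than two tested exons get no call.  Summing counts within
groups means the test sees multinomial noise only; it is calibrated on the
generator (which plants group-constant exon shares) and conservative, and
is not claimed numerically equivalent to quasi-likelihood exon models.

**Event PSI.**  PSI = (inc/ℓ_inc)/((inc/ℓ_inc) + (skip/ℓ_skip)); missing
when no junction reads.  Events need, per group, ≥ 3 samples with
inclusion ≥ 5 or skip ≥ 5 reads (an alternative group-wise reading of the
support rule is available behind `mode="group_wise"`).  The test is a
binomial likelihood ratio on pooled (inclusion, skip) counts, with the
null allowing the two proportions to differ by up to 0.001 — an
effect-size floor that keeps negligible differences non-significant at any
depth.  Significance additionally requires |ΔPSI| > 0.05 on the
length-normalized scale.

**Whole-gene expression.**  Group mean rates λ̂_g = Σy/Σ(lib·TMM factor);
per-gene dispersion by method of moments with an n/(n−2) degrees-of-freedom
factor, shrunk halfway toward a lowess trend on log mean (shrinkage
stabilizes the 3-vs-3 case); Wald z on log λ̂₁ − log λ̂₂ with a
half-count pseudo-rate to guard zeros.  Under the generator's null the
test is slightly conservative; with many true effects its false positives
rise toward the BH-threshold as expected for moderately miscalibrated
tails at n = 3.

## Pool-seq estimators

Sites enter the pipeline after base-quality filtering (Phred ≥ 20), indel
masking (every position within ±5 bp of an indel-bearing position,
inclusive), and coverage handling: sites under 4 or over 100 reads are
dropped, sites between 4 and 19 reads kept at native depth, deeper sites
subsampled without replacement (multivariate hypergeometric) to M = 20.
Keeping below-target sites preserves the stated 4-read minimum; their
per-site statistics use their own M.

- **π** per site: (M/(M−1))(1 − Σₐ(c_a/M)²), the mean pairwise difference
  over all C(M,2) read pairs (tested as an exact identity).  Gene π is
  the sum over SNP sites divided by covered sites.
- **SNP call**: ≥ 2 alleles with count ≥ `min_allele_count` (default 2;
  the generator has no sequencing error, so generator-based recovery runs
  use 1).
- **θ_W** = S/(a₁L); **Tajima's D** with the 1989 constants at n = M
  (modal site depth when depths vary).  D is undefined at S = 0.
- **π_N/π_S**: Nei–Gojobori site counting — per CDS position, the fraction
  of the three single-base changes preserving the amino acid (stop-gaining
  changes count as nonsynonymous); observed SNPs are classified by whether
  the top non-reference allele preserves the amino acid; denominators are
  the expected site counts restricted to covered positions.  Minus-strand
  CDS are reverse-complemented first.
- **F_ST**: Hudson-type ratio of averages per 100-SNP window,
  1 − mean(h̄_w)/mean(h_b), with the within-pool heterozygosity carrying
  the finite-depth M/(M−1) correction.  "Sliding" windows are implemented
  as consecutive non-overlapping windows (step = window, configurable);
  the trailing remainder window is flagged partial.  Sites must sit inside
  the 10th–90th depth percentile band (linear interpolation, inclusive) in
  every pool.

Genes on the Z chromosome and single-exon genes are excluded from all
category comparisons (unknown sex composition of one pool; comparability
of spliced and expressed gene sets and TE-misannotation risk).

Treating M subsampled reads as M sequences omits any pool-size correction:
reads sample the 2n pool chromosomes *with replacement*, so the effective
number of distinct chromosomes behind M = 20 reads from 2n = 60 is ≈ 17,
which biases Tajima's D slightly positive (≈ +0.2 on generator data, well
inside the ±0.3 acceptance band) and π down by (1 − 1/2n)² ≈ 3%.  This is
a documented property of the estimator under the generator's sampling
model, not corrected post hoc.

## Comparison with matched null sets

Kruskal–Wallis H uses midranks with tie correction (H ≡ 0 when all values
are equal); η² = (H − k + 1)/(n − k).  Dunn's z uses mean-rank differences
with the tie-corrected standard error, two-sided p, and BH over exactly
the six category pairs of each (statistic, pool) set.

Matching is explicit stratified sampling rather than propensity machinery:
genes are binned by length decile × folded-relative-position quintile
(quantiles computed on focal ∪ pool), and the None pool is sampled without
replacement to the focal stratum counts; short strata borrow from
neighboring strata in increasing Chebyshev distance on the bin grid (ties
in (length bin, position bin) order), logged.  Relative position is folded
(|midpoint/length − 0.5|) because the recombination-rate proxy is
symmetric about the chromosome midpoint.  When the combined focal sets
exceed the None pool, each replicate first subsamples 50% of each focal
category (per replicate by default; once-per-run behind a flag).
Replicate r uses seed + r for auditability.  Summaries are arithmetic
means over replicates of H, η² and each Dunn z and adjusted p, with
medians reported alongside as a robustness column.

## Clustering

Rows (features) are standardized to mean 0, sample sd 1 (n−1 denominator);
zero-variance rows are dropped.  Fuzzy c-means uses fuzzifier m = 2
(configurable; no data-driven m heuristic), random data points as initial
centers, membership^m-weighted center updates, inverse-distance^{2/(m−1)}
membership updates, and convergence when the largest center shift is
< 1e-6.  The number of clusters is selected from the minimum pairwise
centroid distance over k = 2–20: the chosen k maximizes the forward second
difference Dmin(k) − 2·Dmin(k+1) + Dmin(k+2), i.e. it sits just before the
sharpest drop of the curve; a flat curve falls back to the smallest k with
a warning, and the curve is always written out so a manual override can be
configured.

## The generator and what the tests show

The generator emulates: log-normal gene baselines (σ = 1) with
negative-binomial counts (dispersion 0.1, Var = μ + 0.1μ²) scaled to
log-normal library sizes; exon counts multinomial within gene with the
first exon's weight shifted by a planted log-fold change in affected
samples; one skipped-exon event per multi-exon gene with binomial
inclusion counts around a planted ΔPSI; and pooled sites that segregate
independently at per-site probability θ·a₁(2n), with minor-allele
frequencies from the folded neutral SFS (weight ∝ 1/i + 1/(2n−i), halved
at i = n), pool counts Binomial(2n, f) and read counts Binomial(Poisson
depth, pool frequency).  Planted effects act in all post-day-0 samples of
the designated trajectory.  Pool sizes default to 24 and 30 diploid
individuals, matching the two study populations.

The dispersion and σ values are field-typical placeholders, not estimates
of the real data.  The generator omits coalescent linkage, recombination,
demography, GC/mappability structure, biological exon-share variability
between replicates, and sequencing error; passing tests therefore
establish internal correctness and statistical calibration under these
conditions, not performance on the original sequencing data, whose
headline values depend on the deposited accessions.

Problem sizes in tests and the acceptance run are chosen to keep
Monte-Carlo error well inside the asserted bands: θ recovery uses ~5×10⁵
sites; the π_N/π_S recovery run uses CDS-rich genes (5–9 exons of ~400 bp,
θ = 0.02) because the per-gene ratio is a small-sample-biased estimator —
with few synonymous SNPs the mean of ratios overshoots the true ratio even
when the ratio of means is exact; constraint detection uses 20 datasets of
400 genes with 20 matched replicates each.

## Formats and conventions

Internal coordinates are 0-based half-open; GFF3, mpileup and sync convert
at the parser boundary (both formats are 1-based).  Pileup deletion
characters (`*`) count toward the del slot and toward depth, matching the
sync del column; N never counts as an allele.  Sync columns are
A:T:C:G:N:del.  Longest-isoform selection maximizes pre-mRNA span with
first-listed winning ties.  Pools in a joint pileup are treated
independently by the parsers.  All tables are tab-separated UTF-8 with a
single header row and floats at six significant digits; every CLI run
writes a provenance file (config hash, seed, version).

## Known limitations

- No BAM/CRAM or FASTQ handling; the pipeline starts from count tables,
  event tables and pileup/sync text.
- π/D make no pool-size correction beyond uniform subsampling (above);
  numeric equivalence to PoPoolation's corrected estimators is not
  claimed.
- The exon and event tests are intentionally simpler than quasi-likelihood
  or paired-model alternatives; they are validated by calibration and
  planted-effect recovery only.
- π_N/π_S from pileup input reconstructs CDS codons from the pileup
  reference column, so codons with uncovered positions are skipped.
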