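# diapop

Transcriptional plasticity and genetic constraint in facultative diapause.

Many temperate insects overwinter in diapause, a pre-programmed arrest of
development; in facultatively diapausing butterflies the same genotype can
instead develop directly, depending on photoperiod cues.  If purifying
selection maintains the regulatory machinery of this seasonal plasticity,
genes whose splicing or expression changes specifically through diapause
should carry *less* standing genetic variation than comparable genes.
`diapop` implements the full analysis needed to test that prediction:

1. **Transcriptional plasticity.**  Genes are classified from RNA-seq count
   tables at three levels — exon usage, splice-event percent-spliced-in
   (PSI), and whole-gene expression — across a contrast design mirroring
   the study: diapause pupae sampled at days 0, 3, 6, 24, 114, 144 and 155
   after pupation and direct-developing pupae at days 0, 3 and 6 (15
   contrasts in total).  A gene is *Diap* if it changes only within the
   diapause trajectory, *Dir* if only within direct development, *Both* if
   in each, otherwise *None*.
2. **Pool-seq population genetics.**  From mpileup/sync files, per-gene
   nucleotide diversity π = Σ(M/(M−1))(1 − Σₐ p̂ₐ²)/L, Watterson's
   θ_W = S/(a₁L) with a₁ = Σᵢ₌₁^{M−1} 1/i, Tajima's D, Nei–Gojobori
   π_N/π_S over the CDS of the longest isoform, and a Hudson-type F_ST in
   consecutive 100-SNP windows — after indel masking (±5 bp), base-quality
   filtering (Phred ≥ 20) and uniform subsampling of coverage to 20 reads
   (sites outside 4–100 reads dropped).
3. **Constraint comparison.**  π, D and π_N/π_S are compared across the
   four plasticity categories with Kruskal–Wallis tests (effect size
   η² = (H − k + 1)/(n − k)) and Dunn's post-hoc tests (BH correction over
   the six category pairs), both on the full data and against null sets
   repeatedly resampled from the *None* pool to match the focal genes'
   length and folded relative chromosomal position (a recombination-rate
   proxy).
4. **Profile clustering.**  Fuzzy c-means over standardized profiles, with
   the cluster number chosen from the minimum-centroid-distance curve over
   k = 2–20.

A synthetic-data generator (`diapop.simulate`) produces an annotated
genome, count/event tables and pooled reads with *known planted truth*
(negative-binomial counts with planted ΔPSI/fold-change effects per
category; segregating sites from a folded neutral SFS with per-category θ
and a nonsynonymous constraint multiplier), so every stage of the pipeline
is verifiable without the original sequencing data.

## Worked example

Simulate 300 genes where the Diap category carries a planted 30% diversity
deficit (θ = 0.007 vs. 0.01), run the pool-seq pipeline, and test the
deficit against covariate-matched null sets:

```python
from diapop.simulate import (SimulationConfig, simulate_annotation,
                             simulate_pooled_reads)
from diapop.pipeline import pooled_gene_diversity
from diapop.compare import matched_comparison, match_covariates
from diapop.popgen import filter_gene_universe

cfg = SimulationConfig(
    seed=1, n_genes=300, pool_sizes={"lulea": 30},
    theta_by_category={"Diap": 0.007, "Both": 0.01, "Dir": 0.01, "None": 0.01},
    category_fractions={"Diap": 0.15, "Both": 0.1, "Dir": 0.1},
)
sim = simulate_annotation(cfg)
pooled = simulate_pooled_reads(cfg, sim)
stats = pooled_gene_diversity(pooled, sim, "lulea", seed=2, min_allele_count=1)
stats = stats[stats.index.isin(filter_gene_universe(sim.annotation))]
print(stats[["pi", "tajimas_d", "pn_ps"]]
      .groupby(sim.truth["category"]).median().round(4))

res = matched_comparison(stats, sim.truth["category"],
                         match_covariates(sim.annotation),
                         statistics=("pi",), n_reps=100, seed=3)
s = res.summary
print(s[(s.group_a == "Diap") & (s.group_b == "None")]
      [["mean_z", "mean_adjusted_p", "mean_sign"]].round(4).to_string(index=False))
```

prints

```
              pi  tajimas_d   pn_ps
category
Both      0.0096     0.3846  0.8581
Diap      0.0064     0.0979  1.3291
Dir       0.0095     0.2371  0.7443
None      0.0093     0.2071  1.0488

 mean_z  mean_adjusted_p  mean_sign
-6.2483              0.0       -1.0
```

The Diap median π (0.0064) sits well below the other categories, and over
100 matched null replicates the Diap-vs-None Dunn test is strongly
significant (mean BH-adjusted p ≈ 0) with the Diap median consistently
lower (`mean_sign = −1`) — the planted constraint is recovered.

The same stages are exposed as a CLI (`diapop simulate | splice | popgen |
compare | cluster`), each taking `--config` (YAML), `--seed`, `--out-dir`
and `--log-level` and writing a provenance file.

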