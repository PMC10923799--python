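"""End-to-end pipeline stages composing the lower-level modules.

These functions connect the generator / parsers to the statistics: pooled
site counts -> per-gene diversity tables, pileup files -> the same tables,
count/event tables -> per-contrast calls and gene categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, select_longest_isoform
from .pileio import parse_pileup
from .popgen import (
    codon_site_classes,
    diversity_from_counts,
    gene_pin_pis,
    tajima_constants,
)
from .splice import (
    Contrast,
    classify_genes,
    diff_event_usage,
    diff_exon_usage,
    diff_gene_expression,
    enumerate_comparisons,
    filter_events,
    filter_low_expression,
    tmm_normalize,
)
from .tables import CountTable

log = logging.getLogger(__name__)

__all__ = [
    "subsample_counts_matrix",
    "pooled_gene_diversity",
    "stats_from_pileup",
    "SpliceResults",
    "run_splice_analysis",
]

# ACGT index complement (A<->T, C<->G): reversing the count vector
_REVCOMP_SLICE = slice(None, None, -1)


def subsample_counts_matrix(
    counts: np.ndarray,
    rng: np.random.Generator,
    target: int = 20,
    min_cov: int = 4,
    max_cov: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the coverage filter + without-replacement subsampling to a
    sites x 4 count matrix.

    Returns ``(kept_row_indices, subsampled_counts)``.  Biallelic rows use
    a vectorized hypergeometric draw; rows with more alleles fall back to
    the multivariate form.
    """
    counts = np.asarray(counts, dtype=np.int64)
    cov = counts.sum(axis=1)
    keep = (cov >= min_cov) & (cov <= max_cov)
    idx = np.where(keep)[0]
    sub = counts[idx].copy()
    cov = cov[idx]
    need = cov > target
    if need.any():
        rows = np.where(need)[0]
        nz_counts = sub[rows] > 0
        n_alleles = nz_counts.sum(axis=1)
        # biallelic (or mono) rows: one vectorized hypergeometric draw
        easy = n_alleles <= 2
        if easy.any():
            er = rows[easy]
            order = np.argsort(sub[er], axis=1)
            top = order[:, -1]
            second = order[:, -2]
            n_top = sub[er, top]
            n_second = sub[er, second]
            drawn_second = rng.hypergeometric(n_second, n_top, target)
            new = np.zeros((len(er), 4), dtype=np.int64)
            new[np.arange(len(er)), second] = drawn_second
            new[np.arange(len(er)), top] = target - drawn_second
            sub[er] = new
        hard = rows[~easy]
        for r in hard:
            sub[r] = rng.multivariate_hypergeometric(sub[r], target)
    return idx, sub


def _indel_mask_rows(positions: np.ndarray, indel_flags: np.ndarray, window: int = 5) -> np.ndarray:
    """Boolean mask of rows within +-window of an indel-bearing position."""
    if not indel_flags.any():
        return np.zeros(len(positions), dtype=bool)
    indel_pos = positions[indel_flags]
    masked = np.zeros(len(positions), dtype=bool)
    for p in indel_pos:
        masked |= np.abs(positions - p) <= window
    return masked


def pooled_gene_diversity(
    sim,
    sim_ann,
    pool: str,
    seed: int,
    target: int = 20,
    min_cov: int = 4,
    max_cov: int = 100,
    min_allele_count: int = 2,
    indel_window: int = 5,
    with_pin_pis: bool = True,
    sample_size: int | None = None,
) -> pd.DataFrame:
    """Per-gene diversity statistics from simulated pooled counts.

    Runs the full site pipeline — indel masking, coverage filter, uniform
    subsampling to the target depth — then pi / thetaW / Tajima's D over
    gene-body sites and Nei-Gojobori piN/piS over covered CDS sites.
    Returns one row per gene.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * sim.pool_sizes[pool]
    if target > two_n:
        log.warning("target coverage %d exceeds pool chromosome count %d", target, two_n)
    rows = []
    for gid, g in sim.genes.items():
        counts = sim.counts_acgt(gid, pool)
        masked = _indel_mask_rows(g.positions, g.has_indel, indel_window)
        counts = counts[~masked]
        positions = g.positions[~masked]
        kept, sub = subsample_counts_matrix(counts, rng, target, min_cov, max_cov)
        if len(kept) == 0:
            log.info("gene %s has no covered sites in pool %s", gid, pool)
            continue
        positions = positions[kept]
        pi, theta_w, d, covered, s = diversity_from_counts(
            sub, min_allele_count=min_allele_count, sample_size=sample_size or target
        )
        pi_n = pi_s = ratio = np.nan
        if with_pin_pis and gid in sim_ann.cds_seq:
            gene = sim_ann.annotation.genes[gid]
            cds_pos = sim_ann.cds_positions[gid]
            classes = codon_site_classes(sim_ann.cds_seq[gid], "+")
            pos_to_row = {int(p): i for i, p in enumerate(positions)}
            covered_sites = {}
            n_cds = len(cds_pos)
            for j, gp in enumerate(cds_pos):
                row = pos_to_row.get(int(gp))
                if row is None:
                    continue
                cds_i = j if gene.strand == "+" else n_cds - 1 - j
                c = sub[row]
                covered_sites[cds_i] = c if gene.strand == "+" else c[_REVCOMP_SLICE]
            if covered_sites:
                pi_n, pi_s, ratio = gene_pin_pis(
                    sim_ann.cds_seq[gid], classes, covered_sites, min_allele_count
                )
        rows.append(
            {
                "gene_id": gid,
                "pool_id": pool,
                "pi": pi,
                "theta_w": theta_w,
                "tajimas_d": d,
                "pi_n": pi_n,
                "pi_s": pi_s,
                "pn_ps": ratio,
                "covered_sites": covered,
                "segregating_sites": s,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def stats_from_pileup(
    path: str,
    annotation: GenomeAnnotation,
    seed: int,
    pool_id: str = "pool",
    min_base_quality: int = 20,
    target: int = 20,
    min_cov: int = 4,
    max_cov: int = 100,
    min_allele_count: int = 2,
    indel_window: int = 5,
) -> pd.DataFrame:
    """Per-gene pi / thetaW / Tajima's D (and piN/piS where the CDS is
    covered) from an mpileup file.

    Sites are assigned to genes by the pre-mRNA span of the longest
    isoform; indel-adjacent positions are masked; coverage is filtered and
    subsampled as in :func:`pooled_gene_diversity`.  CDS reference codons
    are reconstructed from the pileup reference column, so codons with
    uncovered positions are skipped in the piN/piS denominators.
    """
    rng = np.random.default_rng(seed)
    longest = select_longest_isoform(annotation)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    # collect per-chromosome sites
    sites: dict[str, list] = {}
    for site in parse_pileup(path, min_base_quality):
        sites.setdefault(site.chromosome, []).append(site)
    rows = []
    for gid, gene in annotation.genes.items():
        tx = longest[gid]
        span = tx.span
        chrom_sites = sites.get(gene.chromosome, [])
        in_gene = [s for s in chrom_sites if span.start < s.position <= span.end]
        if not in_gene:
            continue
        positions = np.array([s.position for s in in_gene])
        indels = np.array([s.has_indel for s in in_gene])
        counts = np.array(
            [[s.base_counts.get(b, 0) for b in ("A", "C", "G", "T")] for s in in_gene],
            dtype=np.int64,
        )
        refs = np.array([s.ref_base for s in in_gene])
        masked = _indel_mask_rows(positions, indels, indel_window)
        counts, positions, refs = counts[~masked], positions[~masked], refs[~masked]
        if len(counts) == 0:
            continue
        kept, sub = subsample_counts_matrix(counts, rng, target, min_cov, max_cov)
        if len(kept) == 0:
            continue
        positions, refs = positions[kept], refs[kept]
        pi, theta_w, d, covered, s = diversity_from_counts(
            sub, min_allele_count=min_allele_count, sample_size=target
        )

        pi_n = pi_s = ratio = np.nan
        if tx.cds:
            cds_pos = np.concatenate(
                [np.arange(c.start, c.end) for c in tx.cds]
            )  # 0-based ascending
            pos_to_row = {int(p): i for i, p in enumerate(positions)}  # 1-based
            n_cds = len(cds_pos)
            # reconstruct CDS reference sequence from pileup ref column
            cds_ref = np.full(n_cds, "N", dtype="<U1")
            covered_sites = {}
            for j, gp in enumerate(cds_pos):
                row = pos_to_row.get(int(gp) + 1)
                cds_i = j if tx.strand == "+" else n_cds - 1 - j
                if row is None:
                    continue
                base = refs[row]
                if tx.strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
                cds_ref[cds_i] = base
                c = sub[row]
                covered_sites[cds_i] = c if tx.strand == "+" else c[::-1]
            if covered_sites:
                seq = "".join(cds_ref)
                try:
                    classes = codon_site_classes(seq, "+")
                    pi_n, pi_s, ratio = gene_pin_pis(seq, classes, covered_sites, min_allele_count)
                except ValueError as exc:
                    log.info("piN/piS skipped for %s: %s", gid, exc)
        rows.append(
            {
                "gene_id": gid,
                "pool_id": pool_id,
                "pi": pi,
                "theta_w": theta_w,
                "tajimas_d": d,
                "pi_n": pi_n,
                "pi_s": pi_s,
                "pn_ps": ratio,
                "covered_sites": covered,
                "segregating_sites": s,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# Splicing/expression analysis over all contrasts


@dataclass
class SpliceResults:
    contrasts: list[Contrast]
    exon_calls: pd.DataFrame  # genes x contrast labels (bool)
    event_calls: pd.DataFrame
    gene_calls: pd.DataFrame
    categories: pd.DataFrame  # genes x level (exon, event, gene)
    details: dict = field(default_factory=dict)


def run_splice_analysis(
    exon_table: CountTable,
    gene_table: CountTable,
    events,
    design: pd.DataFrame,
    contrasts: list[Contrast] | None = None,
    alpha: float = 0.01,
    min_dpsi: float = 0.05,
    event_filter_mode: str = "per_sample_or",
) -> SpliceResults:
    """Run all three differential tests over the contrast design and
    classify genes per level into Diap / Both / Dir / None."""
    if contrasts is None:
        days = lambda traj: sorted(design.loc[design["trajectory"] == traj, "day"].unique())
        contrasts = enumerate_comparisons(days("diapause"), days("direct"))

    keep_exon = filter_low_expression(exon_table, design)
    exon_f = CountTable(
        exon_table.counts.loc[keep_exon[keep_exon].index],
        exon_table.gene_of_feature,
        "exon",
    )
    keep_gene = filter_low_expression(gene_table, design)
    gene_f = CountTable(
        gene_table.counts.loc[keep_gene[keep_gene].index],
        gene_table.gene_of_feature,
        "gene",
    )
    norm = tmm_normalize(gene_f)

    all_genes = gene_table.feature_ids
    exon_calls = pd.DataFrame(index=all_genes)
    event_calls = pd.DataFrame(index=all_genes)
    gene_calls = pd.DataFrame(index=all_genes)
    details: dict = {"exon": {}, "event": {}, "gene": {}}

    for contrast in contrasts:
        gres, _ = diff_exon_usage(exon_f, design, contrast, alpha=alpha)
        exon_calls[contrast.label] = gres["significant"].astype(bool).reindex(all_genes, fill_value=False)
        details["exon"][contrast.label] = gres

        kept_events = filter_events(events, design, contrast, mode=event_filter_mode)
        eres, ecalls = diff_event_usage(
            kept_events, design, contrast, alpha=alpha, min_dpsi=min_dpsi
        )
        event_calls[contrast.label] = ecalls.astype(bool).reindex(all_genes, fill_value=False)
        details["event"][contrast.label] = eres

        gexp = diff_gene_expression(gene_f, design, contrast, alpha=alpha, norm=norm)
        gene_calls[contrast.label] = gexp["significant"].astype(bool).reindex(all_genes, fill_value=False)
        details["gene"][contrast.label] = gexp

    categories = pd.DataFrame(
        {
            "exon": classify_genes(exon_calls, contrasts),
            "event": classify_genes(event_calls, contrasts),
            "gene": classify_genes(gene_calls, contrasts),
        }
    )
    return SpliceResults(contrasts, exon_calls, event_calls, gene_calls, categories, details)
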