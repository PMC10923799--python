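"""Pool-seq diversity statistics per gene and windowed FST.

The pipeline mirrors a PoPoolation-style workflow: indel masking (+-5 bp),
uniform subsampling of read depth to a common target (20 reads by default,
sites below 4 or above 100 reads dropped), per-site heterozygosity with the
M/(M-1) small-sample correction, Watterson's theta and Tajima's D per gene
over the pre-mRNA span of the longest isoform, Nei-Gojobori piN/piS over
the CDS, and a Hudson-type FST in consecutive 100-SNP windows with a
finite-depth correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "mask_indels",
    "subsample_coverage",
    "site_pi",
    "is_snp",
    "tajima_constants",
    "tajimas_d",
    "GeneDiversityStats",
    "diversity_from_counts",
    "gene_diversity",
    "codon_site_classes",
    "classify_snp",
    "gene_pin_pis",
    "WindowFst",
    "fst_windows",
    "depth_percentile_filter",
    "filter_gene_universe",
]

BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Site-level filters


def mask_indels(sites, window_bp: int = 5) -> set[tuple[str, int]]:
    """Positions within +-``window_bp`` (inclusive) of an indel-bearing site."""
    masked: set[tuple[str, int]] = set()
    for s in sites:
        if s.has_indel:
            for pos in range(max(1, s.position - window_bp), s.position + window_bp + 1):
                masked.add((s.chromosome, pos))
    return masked


def subsample_coverage(
    counts: np.ndarray,
    rng: np.random.Generator,
    target: int = 20,
    min_cov: int = 4,
    max_cov: int = 100,
) -> np.ndarray | None:
    """Subsample ACGT read counts without replacement to a common depth.

    Sites below ``min_cov`` or above ``max_cov`` are dropped (None); sites
    between ``min_cov`` and ``target`` are retained at native coverage;
    otherwise ``target`` reads are drawn multivariate-hypergeometrically.
    """
    counts = np.asarray(counts, dtype=np.int64)
    cov = int(counts.sum())
    if cov < min_cov or cov > max_cov:
        return None
    if cov <= target:
        return counts
    return rng.multivariate_hypergeometric(counts, target)


def depth_percentile_filter(
    depths: np.ndarray, low: float = 10.0, high: float = 90.0
) -> np.ndarray:
    """Mask of sites whose depth is within the [low, high] percentile band
    (linear-interpolation percentiles, inclusive) in EVERY pool.

    ``depths`` is sites x pools.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.ndim == 1:
        depths = depths[:, None]
    keep = np.ones(depths.shape[0], dtype=bool)
    for j in range(depths.shape[1]):
        lo, hi = np.percentile(depths[:, j], [low, high])
        keep &= (depths[:, j] >= lo) & (depths[:, j] <= hi)
    return keep


# ---------------------------------------------------------------------------
# Diversity estimators


def site_pi(counts: np.ndarray) -> float:
    """Per-site heterozygosity with the small-sample correction.

    ``pi = (M/(M-1)) * (1 - sum((c/M)^2))`` for allele counts summing to M;
    equals the mean pairwise difference over all C(M, 2) read pairs.
    """
    counts = np.asarray(counts, dtype=float)
    m = counts.sum()
    if m < 2:
        raise ValueError("site_pi needs at least 2 reads")
    return float(m / (m - 1.0) * (1.0 - np.sum((counts / m) ** 2)))


def is_snp(counts: np.ndarray, min_allele_count: int = 2) -> bool:
    """A site is a SNP iff >=2 alleles have count >= ``min_allele_count``."""
    counts = np.asarray(counts)
    return int((counts >= min_allele_count).sum()) >= 2


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for sample size ``n``."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_total: float, s: int, n: int) -> float:
    """Tajima's D from total pairwise diversity, segregating sites and n."""
    if s == 0:
        return np.nan
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    return float((pi_total - s / k["a1"]) / np.sqrt(var))


@dataclass
class GeneDiversityStats:
    gene_id: str
    pool_id: str
    pi: float
    theta_w: float
    tajimas_d: float
    pi_n: float
    pi_s: float
    pn_ps: float
    covered_sites: int
    segregating_sites: int


def diversity_from_counts(
    counts: np.ndarray,
    min_allele_count: int = 2,
    sample_size: int | None = None,
) -> tuple[float, float, float, int, int]:
    """Vectorized per-gene pi, Watterson's theta and Tajima's D.

    ``counts`` is sites x 4 (ACGT) over the covered gene-body sites.
    Sites not called as SNPs (fewer than two alleles at
    ``min_allele_count``) contribute zero heterozygosity; ``sample_size``
    (n for the Tajima constants) defaults to the modal site depth.

    Returns ``(pi, theta_w, D, covered_sites, segregating_sites)``; D is
    NaN when no site segregates.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("gene has no covered sites")
    covered = counts.shape[0]
    m = counts.sum(axis=1)
    ok = m >= 2
    if not ok.any():
        raise ValueError("no site with >=2 reads")
    snp = (counts >= min_allele_count).sum(axis=1) >= 2
    use = ok & snp
    s = int(use.sum())
    if s:
        mu = m[use].astype(float)
        freqs = counts[use] / mu[:, None]
        pi_sites = mu / (mu - 1.0) * (1.0 - (freqs**2).sum(axis=1))
        pi_total = float(pi_sites.sum())
    else:
        pi_total = 0.0
    if sample_size is None:
        vals, freq = np.unique(m[ok], return_counts=True)
        sample_size = int(vals[np.argmax(freq)])
    k = tajima_constants(int(sample_size))
    pi = pi_total / covered
    theta_w = s / (k["a1"] * covered)
    d = tajimas_d(pi_total, s, int(sample_size))
    return pi, theta_w, d, covered, s


def gene_diversity(
    site_counts: list[np.ndarray],
    min_allele_count: int = 2,
    sample_size: int | None = None,
) -> tuple[float, float, float, int, int]:
    """Per-gene diversity from a list of per-site ACGT count vectors.

    Convenience wrapper over :func:`diversity_from_counts`.
    """
    if len(site_counts) == 0:
        raise ValueError("gene has no covered sites")
    return diversity_from_counts(
        np.vstack([np.asarray(c, dtype=np.int64) for c in site_counts]),
        min_allele_count=min_allele_count,
        sample_size=sample_size,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori synonymous/nonsynonymous sites

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon; None for stops."""
    return _CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def _codon_syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous fraction of a sense codon (Nei-Gojobori).

    For each of the three positions, the fraction of the 3 possible
    single-base changes that preserve the amino acid; changes to stop
    codons count as nonsynonymous.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site classes")
    aa0 = _aa(codon)
    if aa0 is None:
        raise ValueError(f"invalid codon {codon!r}")
    fractions = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mutant) == aa0:  # stops give None -> nonsynonymous
                syn += 1
        fractions.append(syn / 3.0)
    return tuple(fractions)


def codon_site_classes(cds_seq: str, strand: str = "+") -> np.ndarray:
    """Per-CDS-position fractional synonymous site counts.

    Reverse-strand CDS are reverse-complemented before classification; the
    returned array is in mRNA (5'->3') order.  Codons with ambiguous bases
    are skipped (NaN); an internal stop codon is an error.
    """
    seq = str(cds_seq).upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    out = np.full(len(seq), np.nan)
    n_codons = len(seq) // 3
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        if any(b not in "ACGT" for b in codon):
            log.info("codon %d (%s) ambiguous; skipped", ci, codon)
            continue
        if codon in _STOPS:
            if ci == n_codons - 1:
                continue  # terminal stop carries no site classes
            raise ValueError(f"internal stop codon {codon} at codon {ci}")
        out[3 * ci : 3 * ci + 3] = _codon_syn_fractions(codon)
    return out


def classify_snp(cds_seq: str, cds_pos: int, alt_base: str) -> bool:
    """True if substituting ``alt_base`` at ``cds_pos`` is synonymous.

    ``cds_seq`` must already be in mRNA orientation.  Changes to stop
    codons are nonsynonymous.
    """
    seq = str(cds_seq).upper()
    ci, within = divmod(cds_pos, 3)
    codon = seq[3 * ci : 3 * ci + 3]
    mutant = codon[:within] + alt_base.upper() + codon[within + 1 :]
    return _aa(codon) is not None and _aa(mutant) == _aa(codon)


def gene_pin_pis(
    cds_seq: str,
    site_classes: np.ndarray,
    covered_sites: dict[int, np.ndarray],
    min_allele_count: int = 2,
) -> tuple[float, float, float]:
    """piN, piS and their ratio over covered CDS positions.

    ``covered_sites`` maps CDS position (mRNA orientation, 0-based) to ACGT
    read counts.  Each SNP is classified by whether its observed alternate
    allele (top non-reference allele) preserves the amino acid; piN sums
    heterozygosity over nonsynonymous SNPs divided by the Nei-Gojobori
    nonsynonymous site count restricted to covered positions, piS
    analogously.  The ratio is NaN when piS = 0.
    """
    seq = str(cds_seq).upper()
    syn_sites = 0.0
    nonsyn_sites = 0.0
    pi_syn = 0.0
    pi_nonsyn = 0.0
    for pos, counts in covered_sites.items():
        frac = site_classes[pos]
        if np.isnan(frac):
            continue
        syn_sites += frac
        nonsyn_sites += 1.0 - frac
        counts = np.asarray(counts, dtype=np.int64)
        if not is_snp(counts, min_allele_count):
            continue
        ref = seq[pos]
        order = np.argsort(counts)[::-1]
        alt = None
        for idx in order:
            if BASES[idx] != ref and counts[idx] > 0:
                alt = BASES[idx]
                break
        if alt is None:
            continue
        if classify_snp(seq, pos, alt):
            pi_syn += site_pi(counts)
        else:
            pi_nonsyn += site_pi(counts)
    if syn_sites == 0:
        return np.nan, np.nan, np.nan
    pi_s = pi_syn / syn_sites
    pi_n = pi_nonsyn / nonsyn_sites if nonsyn_sites > 0 else np.nan
    ratio = pi_n / pi_s if pi_s > 0 else np.nan
    return pi_n, pi_s, ratio


# ---------------------------------------------------------------------------
# FST in 100-SNP windows


@dataclass
class WindowFst:
    chromosome: str
    window_index: int
    first_pos: int
    last_pos: int
    n_snps: int
    fst: float
    partial: bool = False


def _sync_acgt(pool_counts) -> np.ndarray:
    """ACGT counts from a sync sextuple (A:T:C:G:N:del); N/del excluded."""
    a, t, c, g, _n, _d = pool_counts
    return np.array([a, c, g, t], dtype=np.int64)


def fst_windows(
    sync_sites,
    window: int = 100,
    min_allele_count: int = 2,
    step: int | None = None,
    depth_percentiles: tuple[float, float] | None = (10.0, 90.0),
) -> list[WindowFst]:
    """Hudson-type FST between two pools in consecutive SNP windows.

    Sites are filtered to the per-pool depth percentile band, called
    biallelic on pooled counts (second allele at ``min_allele_count``
    jointly), and each window's FST is a ratio of averages:
    ``1 - mean(hw) / mean(hb)`` where ``hw`` is the mean within-pool
    heterozygosity with the finite-depth M/(M-1) correction and ``hb`` the
    between-pool heterozygosity.  ``step`` defaults to ``window``
    (non-overlapping); a trailing remainder window is flagged partial.
    """
    sites = list(sync_sites)
    if step is None:
        step = window
    records = []
    for s in sites:
        if len(s.counts) != 2:
            raise ValueError("fst_windows needs exactly 2 pools")
        c1, c2 = _sync_acgt(s.counts[0]), _sync_acgt(s.counts[1])
        records.append((s.chromosome, s.position, c1, c2))
    if not records:
        return []
    depths = np.array([[r[2].sum(), r[3].sum()] for r in records], dtype=float)
    if depth_percentiles is not None and len(records) > 1:
        keep = depth_percentile_filter(depths, *depth_percentiles)
    else:
        keep = np.ones(len(records), dtype=bool)

    per_chrom: dict[str, list[tuple[int, float, float]]] = {}
    for (chrom, pos, c1, c2), ok in zip(records, keep):
        if not ok:
            continue
        m1, m2 = c1.sum(), c2.sum()
        if m1 < 2 or m2 < 2:
            continue
        total = c1 + c2
        order = np.argsort(total)[::-1]
        major, minor = order[0], order[1]
        if total[minor] < min_allele_count or int((total >= min_allele_count).sum()) < 2:
            continue
        p1 = c1[major] / m1
        p2 = c2[major] / m2
        h1 = m1 / (m1 - 1.0) * 2.0 * p1 * (1.0 - p1)
        h2 = m2 / (m2 - 1.0) * 2.0 * p2 * (1.0 - p2)
        hw = 0.5 * (h1 + h2)
        hb = p1 * (1.0 - p2) + p2 * (1.0 - p1)
        per_chrom.setdefault(chrom, []).append((pos, hw, hb))

    out: list[WindowFst] = []
    for chrom in sorted(per_chrom):
        snps = per_chrom[chrom]
        widx = 0
        for start in range(0, len(snps), step):
            chunk = snps[start : start + window]
            if not chunk:
                break
            mean_hw = float(np.mean([c[1] for c in chunk]))
            mean_hb = float(np.mean([c[2] for c in chunk]))
            fst = 1.0 - mean_hw / mean_hb if mean_hb > 0 else np.nan
            out.append(
                WindowFst(
                    chromosome=chrom,
                    window_index=widx,
                    first_pos=chunk[0][0],
                    last_pos=chunk[-1][0],
                    n_snps=len(chunk),
                    fst=fst,
                    partial=len(chunk) < window,
                )
            )
            widx += 1
    return out


# ---------------------------------------------------------------------------
# Gene universe


def filter_gene_universe(annotation, z_chromosome: str = "Z") -> set[str]:
    """Analysis gene set: exclude Z-linked genes and single-exon genes.

    The Z exclusion reflects unknown sex composition in one pool; the
    single-exon exclusion keeps spliced and expressed gene sets comparable
    and avoids mis-annotated transposable elements.
    """
    keep = set()
    for gid, gene in annotation.genes.items():
        if gene.chromosome == z_chromosome:
            continue
        if gene.n_exons <= 1:
            continue
        keep.add(gid)
    return keep
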