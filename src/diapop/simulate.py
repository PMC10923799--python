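"""Synthetic annotation, RNA-seq count/event tables and pooled reads.

The generator emulates the study conditions with known planted truth so
every pipeline stage is verifiable without external data:

* an annotated genome (two autosomes plus a Z chromosome, multi- and
  single-exon genes, in-frame CDS of random sense codons, some genes with
  a shorter second isoform);
* exon/gene count tables (negative-binomial counts over a log-normal
  baseline, exon shares multinomial within gene) and skipped-exon splice
  events (binomial inclusion counts) for a design of diapause pupae
  sampled at days 0/3/6/24/114/144/155 and direct-developing pupae at days
  0/3/6, with effects planted per gene category (Diap / Both / Dir /
  None) in the designated trajectory's post-day-0 samples;
* pooled sequencing over gene bodies: sites segregate independently at
  per-site rate theta * a1(2n), minor-allele frequencies follow the folded
  neutral SFS (weight 1/i + 1/(2n-i)), nonsynonymous CDS positions
  segregate at a rate scaled by a constraint multiplier, pool allele
  counts are Binomial(2n, f)/2n and read counts Binomial(Poisson depth,
  pool frequency).  Occasional indel tags are emitted on monomorphic
  sites so masking is testable in isolation.

Everything is byte-identically reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
import pandas as pd

from .annotation import CdsSegment, Gene, GenomeAnnotation, Interval, Transcript
from .pileio import SyncSite
from .popgen import BASES, codon_site_classes, tajima_constants
from .splice import CATEGORIES
from .tables import CountTable, EventRecord, make_design

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedAnnotation",
    "PooledSim",
    "simulate_annotation",
    "simulate_splice_experiment",
    "simulate_pooled_reads",
]

_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# the 61 sense codons of the standard code
_SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the study design where one is stated (sampling days,
    pool sizes of 24 and 30 diploid individuals, target coverage regime);
    remaining values are field-typical choices documented in the methods
    note.
    """

    seed: int = 0
    # genome / annotation
    n_genes: int = 300
    chromosomes: tuple[str, ...] = ("chr1", "chr2", "Z")
    z_chromosome: str = "Z"
    chromosome_lengths: dict[str, int] | None = None
    exons_per_gene: tuple[int, int] = (2, 8)
    single_exon_fraction: float = 0.1
    second_isoform_fraction: float = 0.3
    exon_length: int = 200
    intron_length: int = 100
    gene_spacing: int = 300
    # RNA experiment
    diapause_days: tuple[int, ...] = (0, 3, 6, 24, 114, 144, 155)
    direct_days: tuple[int, ...] = (0, 3, 6)
    replicates: int = 5
    tissue: str = "head"
    mean_library_size: float = 1.5e6
    library_size_cv: float = 0.2
    nb_dispersion: float = 0.1
    log_mean: float = float(np.log(150.0))
    log_sigma: float = 1.0
    category_fractions: dict[str, float] = field(
        default_factory=lambda: {"Diap": 0.10, "Both": 0.05, "Dir": 0.05}
    )
    exon_lfc: float = 1.5  # natural-log shift of the planted exon's weight
    delta_psi: float = 0.3
    gene_lfc: float = 1.5  # natural-log fold change of gene expression
    event_mean_reads: float = 60.0
    # pooled sequencing
    theta_by_category: dict[str, float] = field(
        default_factory=lambda: {c: 0.01 for c in CATEGORIES}
    )
    theta_scale_nonsyn: float = 1.0
    pool_sizes: dict[str, int] = field(
        default_factory=lambda: {"kullaberg": 24, "lulea": 30}
    )
    mean_coverage: float = 50.0
    indel_rate: float = 5e-4
    sfs_sample_size: int | None = None  # 2n for the site-frequency model

    def validate(self) -> None:
        if sum(self.category_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("planted category fractions must sum to <= 1")
        for cat, theta in self.theta_by_category.items():
            if not (0.0 <= theta < 0.5):
                raise ValueError(f"theta for {cat} must be in [0, 0.5)")
        if any(n < 2 for n in self.pool_sizes.values()):
            raise ValueError("pool sizes must be >= 2 individuals")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def sfs_m(self) -> int:
        """Chromosome count 2n used by the site-frequency model."""
        if self.sfs_sample_size is not None:
            return int(self.sfs_sample_size)
        return 2 * max(self.pool_sizes.values())


@dataclass
class SimulatedAnnotation:
    annotation: GenomeAnnotation
    truth: pd.DataFrame  # indexed by gene_id
    genome: dict[str, np.ndarray]  # chromosome -> array of base characters
    cds_positions: dict[str, np.ndarray]  # gene -> genomic 0-based, ascending
    cds_seq: dict[str, str]  # gene -> CDS in mRNA orientation


def _draw_categories(rng: np.random.Generator, n: int, fractions: dict[str, float]) -> np.ndarray:
    cats = list(fractions) + ["None"]
    probs = list(fractions.values())
    probs.append(1.0 - sum(probs))
    return rng.choice(cats, size=n, p=probs)


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Generate an annotated genome with planted per-gene truth.

    Genes are laid out left to right without overlap, balanced across
    chromosomes; a configurable fraction is single-exon; one chromosome is
    labeled Z.  CDS are built from random sense codons written into the
    genome (reverse-complemented on the minus strand), so CDS lengths are
    whole numbers of codons by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    single = rng.random(n) < config.single_exon_fraction
    lo, hi = config.exons_per_gene
    n_exons = np.where(single, 1, rng.integers(lo, hi + 1, size=n))
    strands = rng.choice(["+", "-"], size=n)
    categories = _draw_categories(rng, n, config.category_fractions)

    # per-gene exon length lists
    exon_lengths: list[np.ndarray] = []
    for g in range(n):
        lens = rng.integers(
            max(30, config.exon_length // 2), config.exon_length * 3 // 2 + 1, size=n_exons[g]
        )
        exon_lengths.append(lens)
    spans = np.array(
        [lens.sum() + (len(lens) - 1) * config.intron_length for lens in exon_lengths]
    )

    chroms = list(config.chromosomes)
    if config.z_chromosome not in chroms:
        raise ValueError("chromosome list must include the Z chromosome label")
    if config.chromosome_lengths is None:
        needed = int(spans.sum() + config.gene_spacing * (n + len(chroms)))
        per_chrom = int(np.ceil(needed / len(chroms) * 1.25))
        chrom_lengths = {c: per_chrom for c in chroms}
    else:
        chrom_lengths = dict(config.chromosome_lengths)

    cursors = {c: config.gene_spacing for c in chroms}
    genes: dict[str, Gene] = {}
    rows = []
    cds_positions: dict[str, np.ndarray] = {}
    cds_seqs: dict[str, str] = {}
    genome = {
        c: rng.choice(np.array(list("ACGT")), size=chrom_lengths[c]) for c in chroms
    }

    for g in range(n):
        gid = f"gene{g + 1:05d}"
        # balance: put the gene on the emptiest chromosome it fits on
        order = sorted(chroms, key=lambda c: cursors[c] / chrom_lengths[c])
        placed = None
        for c in order:
            if cursors[c] + spans[g] + config.gene_spacing <= chrom_lengths[c]:
                placed = c
                break
        if placed is None:
            raise ValueError(
                "genes cannot be placed without overlap at the requested density; "
                "increase chromosome_lengths or reduce n_genes"
            )
        start = cursors[placed]
        cursors[placed] = start + int(spans[g]) + config.gene_spacing

        exons = []
        pos = start
        for elen in exon_lengths[g]:
            exons.append(Interval(pos, pos + int(elen)))
            pos += int(elen) + config.intron_length
        end = exons[-1].end
        strand = strands[g]

        tx1 = Transcript(f"{gid}.t1", gid, strand, exons=list(exons))
        transcripts = [tx1]
        if len(exons) >= 3 and rng.random() < config.second_isoform_fraction:
            transcripts.append(
                Transcript(f"{gid}.t2", gid, strand, exons=list(exons[:-1]))
            )

        # CDS over the longest isoform's exonic positions, in frame
        exonic = np.concatenate([np.arange(e.start, e.end) for e in exons])
        usable = len(exonic) - 20
        n_codons = max(10, usable // 3) if usable >= 30 else 0
        if n_codons:
            cds_len = 3 * min(n_codons, (len(exonic) - 10) // 3)
            offset = 5
            pos_idx = exonic[offset : offset + cds_len]
            codons = rng.choice(_SENSE_CODONS, size=cds_len // 3)
            cds = "".join(codons)
            if strand == "+":
                genome[placed][pos_idx] = np.array(list(cds))
            else:
                rc = "".join(_COMPLEMENT[b] for b in reversed(cds))
                genome[placed][pos_idx] = np.array(list(rc))
            cds_positions[gid] = pos_idx
            cds_seqs[gid] = cds
            tx1.cds = _cds_segments(pos_idx, strand)

        gene = Gene(gid, placed, strand, start, end, transcripts)
        genes[gid] = gene
        rows.append(
            {
                "gene_id": gid,
                "chromosome": placed,
                "strand": strand,
                "start": start,
                "end": end,
                "length": end - start,
                "n_exons": int(len(exons)),
                "single_exon": bool(single[g]),
                "z_linked": placed == config.z_chromosome,
                "category": categories[g],
                "theta": config.theta_by_category.get(categories[g], 0.0),
                "has_cds": gid in cds_seqs,
            }
        )

    truth = pd.DataFrame(rows).set_index("gene_id")
    ann = GenomeAnnotation(genes, chrom_lengths)
    ann.validate()
    return SimulatedAnnotation(ann, truth, genome, cds_positions, cds_seqs)


def _cds_segments(pos_idx: np.ndarray, strand: str) -> list[CdsSegment]:
    """Contiguous genomic runs of CDS positions, with translation phases."""
    breaks = np.where(np.diff(pos_idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(pos_idx)]])
    runs = [(int(pos_idx[s]), int(pos_idx[e - 1]) + 1) for s, e in zip(starts, ends)]
    order = runs if strand == "+" else runs[::-1]
    segments = {}
    cum = 0
    for s, e in order:
        segments[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    return [CdsSegment(s, e, segments[(s, e)]) for s, e in runs]


# ---------------------------------------------------------------------------
# RNA-seq experiment


def _affected_mask(design: pd.DataFrame, category: str) -> np.ndarray:
    """Samples in which a planted effect of this category is expressed:
    post-day-0 samples of the designated trajectory (both for Both)."""
    day = design["day"].to_numpy()
    traj = design["trajectory"].to_numpy()
    if category == "Diap":
        return (traj == "diapause") & (day > 0)
    if category == "Dir":
        return (traj == "direct") & (day > 0)
    if category == "Both":
        return day > 0
    return np.zeros(len(design), dtype=bool)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_splice_experiment(
    config: SimulationConfig, sim_ann: SimulatedAnnotation
) -> tuple[CountTable, CountTable, list[EventRecord], pd.DataFrame]:
    """Exon/gene count tables and skipped-exon events with planted effects.

    Gene baselines are log-normal; per-sample counts negative-binomial
    scaled to library size; exon counts multinomial within gene with the
    first exon's weight shifted by ``exon_lfc`` in affected samples; event
    totals NB with inclusion counts binomial around a planted PSI shift.
    Effects of category "Both" apply in both trajectories.  Exon-level
    effects on single-exon genes are skipped and logged.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    design = make_design(config.diapause_days, config.direct_days, config.replicates, config.tissue)
    samples = design["sample_id"].tolist()
    n_samples = len(samples)
    truth = sim_ann.truth
    gene_ids = truth.index.tolist()
    n = len(gene_ids)

    lib_factor = np.exp(
        rng.normal(0.0, config.library_size_cv, size=n_samples)
    )
    base = np.exp(rng.normal(config.log_mean, config.log_sigma, size=n))

    cats = truth["category"].to_numpy()
    n_exons = truth["n_exons"].to_numpy()
    affected = np.stack([_affected_mask(design, c) for c in cats])  # genes x samples

    gene_mult = np.where(affected, np.exp(config.gene_lfc), 1.0)
    mu = base[:, None] * lib_factor[None, :] * gene_mult
    gene_counts = _nb_draw(rng, mu, config.nb_dispersion)
    gene_table = CountTable(
        pd.DataFrame(gene_counts, index=gene_ids, columns=samples),
        pd.Series(gene_ids, index=gene_ids),
        "gene",
    )

    # exon tables: totals NB (no gene-level effect so the exon signal is a
    # pure usage shift), split multinomially with planted first-exon shifts
    exon_rows = []
    exon_index = []
    exon_gene = []
    mu_exon = base[:, None] * lib_factor[None, :]
    totals = _nb_draw(rng, mu_exon, config.nb_dispersion)
    for gi, gid in enumerate(gene_ids):
        k = int(n_exons[gi])
        gene = sim_ann.annotation.genes[gid]
        lens = np.array([len(e) for e in gene.transcripts[0].exons], dtype=float)
        w0 = lens / lens.sum()
        if cats[gi] != "None" and k == 1:
            log.info("exon effect requested for single-exon gene %s; skipped", gid)
        counts = np.zeros((k, n_samples), dtype=np.int64)
        aff = affected[gi]
        if cats[gi] != "None" and k > 1:
            w1 = w0.copy()
            w1[0] *= np.exp(config.exon_lfc)
            w1 /= w1.sum()
        else:
            w1 = w0
        for s in range(n_samples):
            w = w1 if aff[s] else w0
            counts[:, s] = rng.multinomial(int(totals[gi, s]), w)
        exon_rows.append(counts)
        exon_index.extend(f"{gid}:e{j + 1}" for j in range(k))
        exon_gene.extend([gid] * k)
    exon_table = CountTable(
        pd.DataFrame(np.vstack(exon_rows), index=exon_index, columns=samples),
        pd.Series(exon_gene, index=exon_index),
        "exon",
    )

    # one skipped-exon event per multi-exon gene
    events: list[EventRecord] = []
    inc_len, skip_len = 2, 1
    for gi, gid in enumerate(gene_ids):
        if n_exons[gi] < 2:
            continue
        psi0 = rng.uniform(0.2, 0.8)
        shift = config.delta_psi if psi0 < 0.5 else -config.delta_psi
        psi = np.full(n_samples, psi0)
        if cats[gi] != "None":
            psi[affected[gi]] = np.clip(psi0 + shift, 0.02, 0.98)
        totals_ev = _nb_draw(
            rng, config.event_mean_reads * lib_factor, config.nb_dispersion
        )
        p_raw = psi * inc_len / (psi * inc_len + (1.0 - psi) * skip_len)
        inc = rng.binomial(totals_ev, p_raw)
        events.append(
            EventRecord(
                event_id=f"{gid}:SE1",
                gene_id=gid,
                event_type="SE",
                inc_len=inc_len,
                skip_len=skip_len,
                inclusion=pd.Series(inc, index=samples),
                skip=pd.Series(totals_ev - inc, index=samples),
            )
        )
    return exon_table, gene_table, events, design


# ---------------------------------------------------------------------------
# Pooled sequencing


@dataclass
class GenePoolSites:
    positions: np.ndarray  # genomic, 0-based ascending over the gene span
    ref_idx: np.ndarray  # index into ACGT
    alt_idx: np.ndarray  # -1 where monomorphic
    true_freq: np.ndarray  # population frequency of the alt allele
    site_class: np.ndarray  # 0 noncoding, 1 synonymous, 2 nonsynonymous
    depth: dict[str, np.ndarray]
    alt_reads: dict[str, np.ndarray]
    has_indel: np.ndarray


@dataclass
class PooledSim:
    pools: list[str]
    pool_sizes: dict[str, int]
    genes: dict[str, GenePoolSites]
    chromosome_of: dict[str, str]
    ref_base: dict[str, np.ndarray]  # gene -> base chars at positions

    def counts_acgt(self, gene_id: str, pool: str) -> np.ndarray:
        """Sites x 4 ACGT read counts for one gene in one pool."""
        g = self.genes[gene_id]
        depth = g.depth[pool]
        alt = g.alt_reads[pool]
        counts = np.zeros((len(g.positions), 4), dtype=np.int64)
        counts[np.arange(len(g.positions)), g.ref_idx] = depth - alt
        has_alt = g.alt_idx >= 0
        counts[np.where(has_alt)[0], g.alt_idx[has_alt]] += alt[has_alt]
        return counts

    def truth_sites(self) -> pd.DataFrame:
        rows = []
        for gid, g in self.genes.items():
            seg = g.alt_idx >= 0
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gid,
                        "position": g.positions[seg] + 1,
                        "true_freq": g.true_freq[seg],
                        "site_class": np.array(["noncoding", "syn", "nonsyn"])[g.site_class[seg]],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def write_pileup(self, pool: str, path: str | TextIO, qual_char: str = "I") -> None:
        close = False
        fh = open(path, "w") if isinstance(path, str) else path
        close = isinstance(path, str)
        try:
            for gid in self.genes:
                g = self.genes[gid]
                chrom = self.chromosome_of[gid]
                refs = self.ref_base[gid]
                depth = g.depth[pool]
                alt = g.alt_reads[pool]
                for i, pos in enumerate(g.positions):
                    d = int(depth[i])
                    if d == 0:
                        continue
                    a = int(alt[i]) if g.alt_idx[i] >= 0 else 0
                    bases = "." * (d - a)
                    if a:
                        bases += BASES[g.alt_idx[i]] * a
                    if g.has_indel[i]:
                        bases = bases[:1] + "+1A" + bases[1:] if bases else bases
                    fh.write(
                        f"{chrom}\t{pos + 1}\t{refs[i]}\t{d}\t{bases}\t{qual_char * d}\n"
                    )
        finally:
            if close:
                fh.close()

    def sync_sites(self):
        """Yield SyncSite records (A:T:C:G:N:del order) over all pools."""
        sync_order = ["A", "T", "C", "G"]
        remap = [sync_order.index(b) for b in BASES]  # ACGT idx -> sync slot
        for gid in self.genes:
            g = self.genes[gid]
            chrom = self.chromosome_of[gid]
            refs = self.ref_base[gid]
            per_pool_counts = {p: self.counts_acgt(gid, p) for p in self.pools}
            for i, pos in enumerate(g.positions):
                pools = []
                for p in self.pools:
                    row = per_pool_counts[p][i]
                    sextuple = [0] * 6
                    for acgt_idx, c in enumerate(row):
                        sextuple[remap[acgt_idx]] = int(c)
                    pools.append(tuple(sextuple))
                yield SyncSite(chrom, int(pos) + 1, str(refs[i]), tuple(pools))


def _folded_sfs_freqs(rng: np.random.Generator, m: int, size: int) -> np.ndarray:
    """Minor-allele frequencies i/m drawn from the folded neutral SFS."""
    i = np.arange(1, m // 2 + 1)
    w = (1.0 / i + 1.0 / (m - i)) / (1.0 + (i == m - i))
    w /= w.sum()
    draws = rng.choice(i, size=size, p=w)
    return draws / m


def simulate_pooled_reads(
    config: SimulationConfig, sim_ann: SimulatedAnnotation
) -> PooledSim:
    """Pooled read counts over gene bodies with known site truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    m = config.sfs_m
    a1 = tajima_constants(m)["a1"]
    scale = config.theta_scale_nonsyn
    pools = list(config.pool_sizes)
    genes: dict[str, GenePoolSites] = {}
    chromosome_of: dict[str, str] = {}
    ref_base: dict[str, np.ndarray] = {}

    for gid, gene in sim_ann.annotation.genes.items():
        theta = float(sim_ann.truth.loc[gid, "theta"])
        positions = np.arange(gene.start, gene.end)
        L = len(positions)
        refs = sim_ann.genome[gene.chromosome][positions]
        ref_idx = np.array([_BASE_TO_IDX[b] for b in refs], dtype=np.int8)

        # per-position synonymous fraction (NaN outside CDS)
        syn_frac = np.full(L, np.nan)
        cds_pos = sim_ann.cds_positions.get(gid)
        if cds_pos is not None and len(cds_pos):
            classes = codon_site_classes(sim_ann.cds_seq[gid], "+")
            if gene.strand == "-":
                classes = classes[::-1]  # genomic ascending order
            idx_in_gene = cds_pos - gene.start
            syn_frac[idx_in_gene] = classes

        seg_prob = theta * a1
        if seg_prob >= 1.0:
            raise ValueError("theta too large: per-site segregation probability >= 1")
        mult = np.ones(L)
        in_cds = ~np.isnan(syn_frac)
        mult[in_cds] = syn_frac[in_cds] + scale * (1.0 - syn_frac[in_cds])
        seg = rng.random(L) < seg_prob * mult

        alt_idx = np.full(L, -1, dtype=np.int8)
        true_freq = np.zeros(L)
        site_class = np.zeros(L, dtype=np.int8)
        seg_idx = np.where(seg)[0]
        if len(seg_idx):
            true_freq[seg_idx] = _folded_sfs_freqs(rng, m, len(seg_idx))
            for si in seg_idx:
                ref_b = BASES[ref_idx[si]]
                if in_cds[si]:
                    f_syn = syn_frac[si]
                    p_syn = f_syn / (f_syn + scale * (1.0 - f_syn)) if (f_syn + scale * (1.0 - f_syn)) > 0 else 0.0
                    syn_choice = rng.random() < p_syn
                    cds_i = _cds_index(sim_ann, gid, gene, positions[si])
                    alts = _alt_bases(sim_ann.cds_seq[gid], cds_i, syn_choice)
                    if not alts:  # no alternative of the requested class exists
                        syn_choice = not syn_choice
                        alts = _alt_bases(sim_ann.cds_seq[gid], cds_i, syn_choice)
                    alt_mrna = alts[rng.integers(len(alts))]
                    alt_b = alt_mrna if gene.strand == "+" else _COMPLEMENT[alt_mrna]
                    site_class[si] = 1 if syn_choice else 2
                else:
                    choices = [b for b in BASES if b != ref_b]
                    alt_b = choices[rng.integers(3)]
                    site_class[si] = 0
                alt_idx[si] = _BASE_TO_IDX[alt_b]

        depth = {}
        alt_reads = {}
        for pool, n_ind in config.pool_sizes.items():
            two_n = 2 * n_ind
            pool_count = rng.binomial(two_n, true_freq)
            p_pool = pool_count / two_n
            d = rng.poisson(config.mean_coverage, size=L)
            ar = rng.binomial(d, p_pool)
            depth[pool] = d
            alt_reads[pool] = ar

        mono = alt_idx < 0
        has_indel = mono & (rng.random(L) < config.indel_rate)

        genes[gid] = GenePoolSites(
            positions=positions,
            ref_idx=ref_idx,
            alt_idx=alt_idx,
            true_freq=true_freq,
            site_class=site_class,
            depth=depth,
            alt_reads=alt_reads,
            has_indel=has_indel,
        )
        chromosome_of[gid] = gene.chromosome
        ref_base[gid] = refs
    return PooledSim(pools, dict(config.pool_sizes), genes, chromosome_of, ref_base)


def _cds_index(sim_ann: SimulatedAnnotation, gid: str, gene, genomic_pos: int) -> int:
    """CDS (mRNA-orientation) index of a genomic position."""
    cds_pos = sim_ann.cds_positions[gid]
    i = int(np.searchsorted(cds_pos, genomic_pos))
    if gene.strand == "+":
        return i
    return len(cds_pos) - 1 - i


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_alt_bases(codon: str, within: int, synonymous: bool) -> tuple[str, ...]:
    from .popgen import _aa

    aa0 = _aa(codon)
    out = []
    for b in BASES:
        if b == codon[within]:
            continue
        mutant = codon[:within] + b + codon[within + 1 :]
        is_syn = _aa(mutant) is not None and _aa(mutant) == aa0
        if is_syn == synonymous:
            out.append(b)
    return tuple(out)


def _alt_bases(cds_seq: str, cds_i: int, synonymous: bool) -> tuple[str, ...]:
    """Alternative bases at a CDS position of the requested class."""
    ci, within = divmod(cds_i, 3)
    return _codon_alt_bases(cds_seq[3 * ci : 3 * ci + 3], within, synonymous)
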