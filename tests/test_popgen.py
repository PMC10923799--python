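import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diapop.pileio import PileupSite, SyncSite
from diapop.popgen import (
    BASES,
    classify_snp,
    codon_site_classes,
    depth_percentile_filter,
    diversity_from_counts,
    filter_gene_universe,
    fst_windows,
    gene_diversity,
    gene_pin_pis,
    mask_indels,
    site_pi,
    subsample_coverage,
    tajima_constants,
)


def _pileup_site(pos, has_indel=False):
    return PileupSite("chr1", pos, "A", 10, {"A": 10}, has_indel)


# ---------------------------------------------------------------------------
# masking and subsampling


def test_mask_indels_window():
    sites = [_pileup_site(100, True), _pileup_site(50)]
    masked = mask_indels(sites, window_bp=5)
    assert masked == {("chr1", p) for p in range(95, 106)}
    assert mask_indels([_pileup_site(50)]) == set()
    union = mask_indels([_pileup_site(100, True), _pileup_site(104, True)])
    assert union == {("chr1", p) for p in range(95, 110)}


def test_subsample_coverage_limits(rng):
    assert subsample_coverage(np.array([3, 0, 0, 0]), rng) is None  # below min 4
    assert subsample_coverage(np.array([150, 0, 0, 0]), rng) is None  # above max 100
    native = subsample_coverage(np.array([5, 3, 0, 0]), rng)
    assert native.tolist() == [5, 3, 0, 0]  # below target kept at native depth


def test_subsample_coverage_hypergeometric_expectation():
    draws = []
    for seed in range(300):
        rng = np.random.default_rng(seed)
        out = subsample_coverage(np.array([30, 0, 0, 10]), rng, target=20)
        assert out.sum() == 20
        draws.append(out[0])
    assert np.mean(draws) == pytest.approx(15.0, abs=0.3)


# ---------------------------------------------------------------------------
# site_pi and Tajima's D


@pytest.mark.parametrize(
    "counts, expected",
    [([20, 0, 0, 0], 0.0), ([1, 1, 0, 0], 1.0), ([10, 10, 0, 0], 20 / 19 * 0.5)],
)
def test_site_pi_values(counts, expected):
    assert site_pi(np.array(counts)) == pytest.approx(expected)


def _brute_force_pi(counts):
    reads = [b for b, c in zip("ACGT", counts) for _ in range(c)]
    pairs = list(itertools.combinations(reads, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


@given(st.lists(st.integers(0, 30), min_size=4, max_size=4).filter(lambda c: sum(c) >= 2))
def test_site_pi_equals_brute_force_pairwise_difference(counts):
    assert site_pi(np.array(counts)) == pytest.approx(_brute_force_pi(counts), abs=1e-12)


def _independent_tajima(pi_total, s, n):
    """Direct transcription of the 1989 formulas, kept separate from the
    implementation under test."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def test_tajimas_d_oracle_doubleton_and_singleton():
    mono = [np.array([4, 0, 0, 0])] * 9
    pi, theta, d, covered, s = gene_diversity(
        [np.array([2, 2, 0, 0])] + mono, min_allele_count=1
    )
    assert pi == pytest.approx((4 / 3 * 0.5) / 10)
    assert s == 1
    assert d == pytest.approx(_independent_tajima(4 / 3 * 0.5, 1, 4), abs=1e-12)
    assert d == pytest.approx(1.63, abs=0.01)
    _, _, d2, _, _ = gene_diversity([np.array([3, 1, 0, 0])] + mono, min_allele_count=1)
    assert d2 == pytest.approx(_independent_tajima(0.5, 1, 4), abs=1e-12)
    assert d2 == pytest.approx(-0.61, abs=0.01)


def test_tajimas_d_missing_when_no_segregating_sites():
    pi, theta, d, covered, s = gene_diversity([np.array([20, 0, 0, 0])] * 5)
    assert pi == 0.0 and theta == 0.0 and s == 0
    assert np.isnan(d)


def test_min_allele_count_gates_snp_calls():
    sites = [np.array([19, 1, 0, 0])] + [np.array([20, 0, 0, 0])] * 4
    _, _, _, _, s1 = diversity_from_counts(np.vstack(sites), min_allele_count=2)
    _, _, _, _, s2 = diversity_from_counts(np.vstack(sites), min_allele_count=1)
    assert (s1, s2) == (0, 1)


# ---------------------------------------------------------------------------
# Nei-Gojobori site classes


GENETIC_CODE = {}
for b1 in "TCAG":
    for b2 in "TCAG":
        for b3 in "TCAG":
            codon = b1 + b2 + b3
            GENETIC_CODE[codon] = None
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for i, codon in enumerate(GENETIC_CODE):
    GENETIC_CODE[codon] = _AA[i]


def _brute_force_syn_fraction(codon, pos):
    aa = GENETIC_CODE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == aa:
            syn += 1
    return syn / 3


def test_codon_site_classes_examples():
    assert codon_site_classes("TGG").tolist() == [0.0, 0.0, 0.0]  # Trp: nothing synonymous
    assert codon_site_classes("GGA")[2] == pytest.approx(1.0)  # 4-fold third position
    assert codon_site_classes("TTT")[2] == pytest.approx(1 / 3)  # only TTC keeps Phe


def test_codon_site_classes_match_brute_force_for_all_sense_codons():
    sense = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
    assert len(sense) == 61
    for codon in sense:
        got = codon_site_classes(codon)
        want = [_brute_force_syn_fraction(codon, p) for p in range(3)]
        np.testing.assert_allclose(got, want, atol=1e-12, err_msg=codon)


def test_codon_site_classes_strand_and_errors():
    # reverse strand: CCA on the minus strand reads TGG
    np.testing.assert_allclose(codon_site_classes("CCA", strand="-"), [0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="divisible"):
        codon_site_classes("ACGT")
    with pytest.raises(ValueError, match="stop"):
        codon_site_classes("TAAGGG")


def test_classify_snp():
    assert classify_snp("GGA", 2, "G")  # GGA -> GGG, still Gly
    assert not classify_snp("TGG", 2, "A")  # TGG -> TGA stop, nonsynonymous


def test_gene_pin_pis_cases():
    seq = "GGATTT"  # Gly (4-fold third position), Phe
    classes = codon_site_classes(seq)
    # no SNPs
    covered = {i: np.array([20, 0, 0, 0]) for i in range(6)}
    covered = {
        i: np.eye(4, dtype=int)[ {"A":0,"C":1,"G":2,"T":3}[seq[i]] ] * 20 for i in range(6)
    }
    pi_n, pi_s, ratio = gene_pin_pis(seq, classes, covered)
    assert pi_n == 0.0 and pi_s == 0.0 and np.isnan(ratio)
    # one synonymous SNP only (GGA -> GGG at position 2)
    covered[2] = np.array([10, 0, 10, 0])  # A/G split
    pi_n, pi_s, ratio = gene_pin_pis(seq, classes, covered)
    assert pi_n == 0.0 and pi_s > 0 and ratio == 0.0


# ---------------------------------------------------------------------------
# depth percentile filter


def test_depth_percentile_filter_cases():
    equal = np.full((50, 2), 30.0)
    assert depth_percentile_filter(equal).all()
    depths = np.arange(1, 101, dtype=float)[:, None]
    keep = depth_percentile_filter(depths)
    lo, hi = np.percentile(depths[:, 0], [10, 90])
    expected = (depths[:, 0] >= lo) & (depths[:, 0] <= hi)
    assert (keep == expected).all()
    assert lo == pytest.approx(10.9) and hi == pytest.approx(90.1)
    # extreme in one pool only -> dropped (EVERY-pool rule)
    two = np.column_stack([np.full(100, 50.0), np.arange(1, 101, dtype=float)])
    keep2 = depth_percentile_filter(two)
    assert keep2.sum() < 100 and not keep2[0]


# ---------------------------------------------------------------------------
# FST


def _sync(pos, c1, c2):
    def sextuple(c):
        a, cc, g, t = c
        return (a, t, cc, g, 0, 0)

    return SyncSite("chr1", pos, "A", (sextuple(c1), sextuple(c2)))


def test_fst_identical_pools_is_zero():
    sites = [_sync(i + 1, (30, 10, 0, 0), (30, 10, 0, 0)) for i in range(50)]
    wins = fst_windows(sites, window=50, depth_percentiles=None)
    assert len(wins) == 1
    # the M/(M-1) within-pool correction leaves a small negative residual
    # when counts are literally identical rather than sampled
    assert wins[0].fst == pytest.approx(0.0, abs=0.03)


def test_fst_fixed_differences_approach_one():
    sites = [_sync(i + 1, (500, 0, 0, 0), (0, 500, 0, 0)) for i in range(100)]
    wins = fst_windows(sites, window=100, depth_percentiles=None)
    assert wins[0].fst == pytest.approx(1.0, abs=2e-3)
    assert not wins[0].partial


def test_fst_pool_order_invariance_and_partial_window(rng):
    sites = []
    for i in range(130):
        a = rng.integers(5, 40)
        sites.append(_sync(i + 1, (a, 50 - a, 0, 0), (50 - a, a, 0, 0)))
    wins = fst_windows(sites, window=100, depth_percentiles=None)
    swapped = [
        SyncSite(s.chromosome, s.position, s.ref_base, (s.counts[1], s.counts[0]))
        for s in sites
    ]
    wins2 = fst_windows(swapped, window=100, depth_percentiles=None)
    assert [w.fst for w in wins] == pytest.approx([w.fst for w in wins2])
    assert wins[-1].partial and wins[-1].n_snps == 30


def test_fst_panmictic_null_near_zero(rng):
    sites = []
    for i in range(500):
        f = rng.uniform(0.1, 0.9)
        c1a = rng.binomial(60, f)
        c2a = rng.binomial(60, f)
        sites.append(_sync(i + 1, (c1a, 60 - c1a, 0, 0), (c2a, 60 - c2a, 0, 0)))
    wins = fst_windows(sites, window=100, depth_percentiles=None)
    mean_fst = np.mean([w.fst for w in wins])
    assert abs(mean_fst) < 0.02


# ---------------------------------------------------------------------------
# gene universe


def test_filter_gene_universe(small_sim):
    sim_ann = small_sim["sim_ann"]
    keep = filter_gene_universe(sim_ann.annotation)
    truth = sim_ann.truth
    for gid in truth.index:
        expected = (not truth.loc[gid, "z_linked"]) and truth.loc[gid, "n_exons"] > 1
        assert (gid in keep) == expected
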