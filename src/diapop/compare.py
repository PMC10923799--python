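"""Group comparisons of per-gene diversity statistics with matched nulls.

Genes are grouped by plasticity category (Diap / Both / Dir / None) and
their diversity statistics compared with Kruskal-Wallis tests (effect size
eta^2), Dunn's post-hoc pairwise tests with BH correction over the six
category pairs, and covariate-matched resampled null sets: the None pool
is repeatedly subsampled to match the focal sets' gene length and folded
relative chromosomal position (a recombination-rate proxy) and the
comparison repeated, summarizing means over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "KruskalResult",
    "kruskal_eta",
    "dunn_bh",
    "match_covariates",
    "match_gene_sets",
    "GroupComparison",
    "group_comparison",
    "MatchedRunSummary",
    "matched_comparison",
]


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    eta_sq: float
    n: int
    k: int


def kruskal_eta(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with eta^2 effect size.

    ``eta^2 = (H - k + 1) / (n - k)``; identical observations across all
    groups give H = 0 by convention.  Groups left empty after NaN removal
    are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    samples = []
    for g in pd.unique(groups):
        x = values[groups == g]
        if x.size == 0:
            log.warning("group %r empty after filtering; dropped", g)
            continue
        samples.append(x)
    k = len(samples)
    if k < 2:
        raise ValueError("need >=2 non-empty groups")
    n = sum(len(s) for s in samples)
    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    eta = (h - k + 1.0) / (n - k)
    return KruskalResult(float(h), float(p), float(eta), n, k)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_bh(values, groups, pairs=None) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests with BH correction.

    z from mean-rank differences with the tie-corrected standard error;
    two-sided p; BH applied over exactly the tested pairs (the six category
    pairs when four groups are present).  Returns one row per pair with the
    sign of the median difference.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    if pairs is None:
        pairs = list(combinations(labels, 2))
    n = values.size
    ranks = stats.rankdata(values)
    tie_corr = _tie_term(values) / (12.0 * (n - 1.0)) if n > 1 else 0.0
    base_var = n * (n + 1.0) / 12.0 - tie_corr
    rows = []
    for ga, gb in pairs:
        xa, xb = groups == ga, groups == gb
        na, nb = int(xa.sum()), int(xb.sum())
        if na == 0 or nb == 0:
            rows.append({"group_a": ga, "group_b": gb, "z": np.nan, "p_value": np.nan, "median_diff_sign": 0})
            continue
        ra, rb = ranks[xa].mean(), ranks[xb].mean()
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (ra - rb) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        sign = int(np.sign(np.median(values[xa]) - np.median(values[xb])))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_value": p, "median_diff_sign": sign})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["adjusted_p"] = np.nan
    if tested.any():
        out.loc[tested, "adjusted_p"] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Covariate-matched null sets


def match_covariates(annotation, chromosome_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Matching covariates per gene: pre-mRNA span length (bp) and folded
    relative chromosomal position |midpoint/length - 0.5| in [0, 0.5]."""
    lengths = chromosome_lengths or annotation.chromosome_lengths
    rows = []
    for gid, gene in annotation.genes.items():
        chrom_len = lengths[gene.chromosome]
        rel = abs(gene.midpoint / chrom_len - 0.5)
        rows.append({"gene_id": gid, "length": gene.end - gene.start, "rel_position": rel})
    return pd.DataFrame(rows).set_index("gene_id")


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return np.zeros(len(x), dtype=int)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)


def match_gene_sets(
    focal: list[str],
    pool: list[str],
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    n_length_bins: int = 10,
    n_pos_bins: int = 5,
) -> list[str]:
    """Sample a covariate-matched null set from the None pool.

    Genes are stratified by (length decile x relative-position quintile),
    bins computed on focal + pool jointly; within each stratum the pool is
    sampled without replacement to the focal stratum count.  Strata short
    of pool genes borrow from the nearest neighboring strata (increasing
    Chebyshev distance on the bin grid, ties in (length bin, position bin)
    order) with a log message.  The matched set always has the focal size.
    """
    focal = list(focal)
    pool = list(pool)
    if set(focal) & set(pool):
        raise ValueError("focal and pool sets must be disjoint")
    if len(pool) < len(focal):
        raise ValueError(
            f"pool ({len(pool)}) smaller than focal ({len(focal)}); "
            "subsample the focal sets (e.g. 50%) before matching"
        )
    all_ids = focal + pool
    cov = covariates.loc[all_ids]
    lbin = _quantile_bins(cov["length"].to_numpy(float), n_length_bins)
    pbin = _quantile_bins(cov["rel_position"].to_numpy(float), n_pos_bins)
    strata = list(zip(lbin.tolist(), pbin.tolist()))
    focal_strata = strata[: len(focal)]
    pool_strata = strata[len(focal) :]

    available: dict[tuple[int, int], list[str]] = {}
    for gid, st in zip(pool, pool_strata):
        available.setdefault(st, []).append(gid)
    for st in available:
        idx = rng.permutation(len(available[st]))
        available[st] = [available[st][i] for i in idx]

    need: dict[tuple[int, int], int] = {}
    for st in focal_strata:
        need[st] = need.get(st, 0) + 1

    matched: list[str] = []
    deficits: dict[tuple[int, int], int] = {}
    for st in sorted(need):
        take = min(need[st], len(available.get(st, [])))
        for _ in range(take):
            matched.append(available[st].pop())
        if need[st] > take:
            deficits[st] = need[st] - take

    if deficits:
        all_strata = sorted({st for st in available if available[st]})
        for st in sorted(deficits):
            short = deficits[st]
            log.info("stratum %s short by %d; borrowing from neighbors", st, short)
            neighbors = sorted(
                (max(abs(o[0] - st[0]), abs(o[1] - st[1])), o) for o in all_strata
            )
            for _dist, o in neighbors:
                while short > 0 and available.get(o):
                    matched.append(available[o].pop())
                    short -= 1
                if short == 0:
                    break
            if short > 0:
                raise RuntimeError("pool exhausted while borrowing (should be impossible)")
    assert len(matched) == len(focal)
    return matched


# ---------------------------------------------------------------------------
# Full comparison with matched resampling


@dataclass
class GroupComparison:
    statistic_name: str
    kruskal: KruskalResult
    dunn: pd.DataFrame


def group_comparison(df: pd.DataFrame, statistic: str, category_col: str = "category") -> GroupComparison:
    sub = df[[statistic, category_col]].dropna()
    kw = kruskal_eta(sub[statistic], sub[category_col])
    dunn = dunn_bh(sub[statistic], sub[category_col])
    return GroupComparison(statistic, kw, dunn)


@dataclass
class MatchedRunSummary:
    statistics: list[str]
    full: dict[str, GroupComparison]
    replicates: pd.DataFrame  # long: replicate, statistic, group_a, group_b, z, adjusted_p, ...
    replicate_kw: pd.DataFrame  # replicate, statistic, h, p, eta_sq
    summary: pd.DataFrame  # means (and medians) over replicates
    n_reps: int
    focal_subsampled: bool = False


def matched_comparison(
    stats_df: pd.DataFrame,
    categories: pd.Series,
    covariates: pd.DataFrame,
    statistics: tuple[str, ...] = ("pi", "tajimas_d", "pn_ps"),
    n_reps: int = 1000,
    focal_subsample: float = 0.5,
    seed: int = 0,
    n_length_bins: int = 10,
    n_pos_bins: int = 5,
) -> MatchedRunSummary:
    """Compare diversity statistics across categories against matched nulls.

    ``stats_df`` is indexed by gene with one column per statistic (one
    pool); ``categories`` maps gene -> Diap/Both/Dir/None.  The full-data
    comparison is computed once; then, per replicate, a None set matched on
    the covariates to the union of the focal sets replaces the None group
    and the comparison is recomputed.  When the combined focal sets exceed
    the None pool, each replicate first subsamples ``focal_subsample`` of
    each focal category.  Replicate r uses seed + r.  Summaries are
    arithmetic means over replicates (medians reported alongside).
    """
    genes = stats_df.index.intersection(categories.index)
    df = stats_df.loc[genes].copy()
    df["category"] = categories.loc[genes]
    missing_cov = set(genes) - set(covariates.index)
    if missing_cov:
        raise ValueError(f"covariates missing for {len(missing_cov)} genes")

    available = [s for s in statistics if df[s].notna().any()]
    for s in statistics:
        if s not in available:
            log.warning("statistic %s entirely missing; flagged and skipped", s)

    full = {s: group_comparison(df, s) for s in available}

    focal_by_cat = {
        c: df.index[df["category"] == c].tolist() for c in ("Diap", "Both", "Dir")
    }
    none_pool = df.index[df["category"] == "None"].tolist()
    n_focal_total = sum(len(v) for v in focal_by_cat.values())
    subsample_needed = n_focal_total > len(none_pool)

    rep_rows = []
    kw_rows = []
    if n_focal_total == 0:
        log.warning("no focal (Diap/Both/Dir) genes; matched replicates skipped")
        n_reps = 0
    for r in range(1, n_reps + 1):
        rng = np.random.default_rng(seed + r)
        if subsample_needed:
            focal_sets = {
                c: list(rng.choice(v, size=max(1, int(round(focal_subsample * len(v)))), replace=False))
                if v
                else []
                for c, v in focal_by_cat.items()
            }
        else:
            focal_sets = {c: list(v) for c, v in focal_by_cat.items()}
        focal_union = [g for v in focal_sets.values() for g in v]
        matched_none = match_gene_sets(
            focal_union, none_pool, covariates, rng, n_length_bins, n_pos_bins
        )
        rep_genes = focal_union + matched_none
        rep_df = df.loc[rep_genes]
        rep_df = rep_df.assign(
            category=["None" if g in set(matched_none) else df.loc[g, "category"] for g in rep_genes]
        )
        for s in available:
            gc = group_comparison(rep_df, s)
            kw_rows.append(
                {"replicate": r, "statistic": s, "h": gc.kruskal.h, "p": gc.kruskal.p, "eta_sq": gc.kruskal.eta_sq}
            )
            d = gc.dunn.assign(replicate=r, statistic=s)
            rep_rows.append(d)

    replicates = (
        pd.concat(rep_rows, ignore_index=True)
        if rep_rows
        else pd.DataFrame(columns=["replicate", "statistic", "group_a", "group_b", "z", "p_value", "adjusted_p"])
    )
    replicate_kw = pd.DataFrame(kw_rows)

    if len(replicates):
        pair_summary = (
            replicates.groupby(["statistic", "group_a", "group_b"])
            .agg(
                mean_z=("z", "mean"),
                mean_adjusted_p=("adjusted_p", "mean"),
                median_adjusted_p=("adjusted_p", "median"),
                mean_sign=("median_diff_sign", "mean"),
            )
            .reset_index()
        )
        kw_summary = (
            replicate_kw.groupby("statistic")
            .agg(mean_h=("h", "mean"), mean_p=("p", "mean"), mean_eta_sq=("eta_sq", "mean"))
            .reset_index()
        )
        summary = pair_summary.merge(kw_summary, on="statistic")
    else:
        summary = pd.DataFrame()

    return MatchedRunSummary(
        statistics=available,
        full=full,
        replicates=replicates,
        replicate_kw=replicate_kw,
        summary=summary,
        n_reps=n_reps,
        focal_subsampled=subsample_needed,
    )
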