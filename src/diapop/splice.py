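"""Differential splicing and expression across diapause vs. direct development.

Transcriptional plasticity is quantified at three levels:

* **exon usage** — per-exon share of within-gene counts, tested with a
  G-test on group-summed exon vs. rest-of-gene counts and aggregated to a
  gene-level p-value with the Simes rule;
* **event PSI** — percent-spliced-in of splice events from
  length-normalized inclusion/skip junction counts, tested with a binomial
  likelihood-ratio test with a small effect-size floor;
* **whole-gene expression** — a two-group negative-binomial Wald test with
  moment dispersion estimates shrunk toward a trended fit, under TMM
  offsets.

The contrast set mirrors the study design: diapause pupae sampled at days
0, 3, 6, 24, 114, 144 and 155 after pupation and direct-developing pupae at
days 0, 3 and 6, compared (i) across trajectories at day 0, (ii) against
day 0 within each trajectory and (iii) between adjacent days within each
trajectory — 15 contrasts for the full design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .tables import CountTable

log = logging.getLogger(__name__)

__all__ = [
    "Contrast",
    "enumerate_comparisons",
    "NormalizedMatrix",
    "tmm_normalize",
    "residual_exon_expression",
    "filter_low_expression",
    "simes_p",
    "diff_exon_usage",
    "compute_psi",
    "filter_events",
    "diff_event_usage",
    "diff_gene_expression",
    "classify_genes",
    "pca_variance",
    "CATEGORIES",
]

CATEGORIES = ("Diap", "Both", "Dir", "None")


# ---------------------------------------------------------------------------
# Contrast design


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; a group is a (trajectory, day) cell."""

    group_a: tuple[str, int]
    group_b: tuple[str, int]
    kind: str  # "cross_day0" | "reference" | "stepwise"

    @property
    def label(self) -> str:
        (ta, da), (tb, db) = self.group_a, self.group_b
        return f"{ta[:3]}{da:03d}_vs_{tb[:3]}{db:03d}"

    @property
    def pair(self) -> frozenset:
        return frozenset((self.group_a, self.group_b))

    def is_within(self, trajectory: str) -> bool:
        return self.group_a[0] == trajectory and self.group_b[0] == trajectory


def enumerate_comparisons(diapause_days, direct_days) -> list[Contrast]:
    """Enumerate the contrast design.

    Returns, in deterministic order: the cross-trajectory day-0 contrast,
    day 0 vs. each later day within each trajectory ("reference"), and each
    adjacent-day pair within each trajectory ("stepwise"), de-duplicated so
    the day-0-vs-first-later-day pair appears once (labeled reference).
    The full design (diapause 0/3/6/24/114/144/155, direct 0/3/6) yields 15
    contrasts.
    """
    diapause_days = [int(d) for d in diapause_days]
    direct_days = [int(d) for d in direct_days]
    for name, days in (("diapause", diapause_days), ("direct", direct_days)):
        if not days:
            raise ValueError(f"{name} day list is empty")
        if days != sorted(days):
            raise ValueError(f"{name} day list must be sorted ascending")
    contrasts: list[Contrast] = []
    seen: set[frozenset] = set()

    def add(a, b, kind):
        c = Contrast(a, b, kind)
        if c.pair not in seen:
            seen.add(c.pair)
            contrasts.append(c)

    add(("diapause", diapause_days[0]), ("direct", direct_days[0]), "cross_day0")
    for traj, days in (("diapause", diapause_days), ("direct", direct_days)):
        for d in days[1:]:
            add((traj, days[0]), (traj, d), "reference")
    for traj, days in (("diapause", diapause_days), ("direct", direct_days)):
        for d0, d1 in zip(days, days[1:]):
            add((traj, d0), (traj, d1), "stepwise")
    return contrasts


def _group_samples(design: pd.DataFrame, group: tuple[str, int], columns) -> list[str]:
    traj, day = group
    sel = design[(design["trajectory"] == traj) & (design["day"] == int(day))]
    samples = [s for s in sel["sample_id"] if s in set(columns)]
    if not samples:
        raise ValueError(f"no samples for group {group}")
    return samples


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)


@dataclass
class NormalizedMatrix:
    """Natural-log CPM values with TMM normalization factors."""

    values: pd.DataFrame  # features x samples, ln CPM
    norm_factors: pd.Series  # geometric mean 1
    effective_lib_sizes: pd.Series


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample.

    Double-trimmed (30% on M, 5% on A), precision-weighted mean of log2
    ratios, as in the published TMM algorithm.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(table: CountTable) -> NormalizedMatrix:
    """TMM normalization factors plus natural-log CPM values.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the across-sample mean; factors are rescaled to geometric mean 1 and the
    values are ``ln((count + 0.5) / (lib_size * factor + 1) * 1e6)``.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM normalization needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    values = np.log((counts + 0.5) / (eff_lib + 1.0)[None, :] * 1e6)
    samples = table.sample_ids
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=table.feature_ids, columns=samples),
        norm_factors=pd.Series(factors, index=samples),
        effective_lib_sizes=pd.Series(eff_lib, index=samples),
    )


def residual_exon_expression(norm: NormalizedMatrix, gene_of_feature: pd.Series) -> pd.DataFrame:
    """Within-gene residual exon expression.

    Each exon's normalized value minus its gene's per-sample mean over
    exons; positive residuals mark exons expressed above the within-gene
    average.  Residuals of a gene sum to zero per sample, and single-exon
    genes are identically zero.
    """
    genes = gene_of_feature.loc[norm.values.index]
    gene_means = norm.values.groupby(genes.to_numpy()).transform("mean")
    return norm.values - gene_means


def filter_low_expression(
    table: CountTable,
    design: pd.DataFrame,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> pd.Series:
    """Keep-mask for features with usable counts.

    A feature is kept iff its CPM is at least ``min_count`` divided by the
    median library size in millions, in at least k samples (k = smallest
    trajectory x day group size), and its total count is at least
    ``min_total``.  Both thresholds are inclusive.
    """
    design = design[design["sample_id"].isin(table.sample_ids)]
    k = int(design.groupby(["trajectory", "day"]).size().min())
    lib = table.library_sizes.to_numpy(dtype=float)
    cpm_cutoff = min_count / (np.median(lib) / 1e6)
    cpm = table.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = ((cpm >= cpm_cutoff).sum(axis=1) >= k) & (
        table.counts.sum(axis=1).to_numpy() >= min_total
    )
    return pd.Series(keep, index=table.feature_ids)


# ---------------------------------------------------------------------------
# Exon-level test: G-test + Simes aggregation


def simes_p(p_values) -> float:
    """Simes combination: min over sorted p of m * p_(i) / i, capped at 1."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    if m == 0:
        return np.nan
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def _g_test_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized G-test on 2x2 tables [[a, b], [c, d]] (1 df)."""
    obs = np.stack([a, b, c, d], axis=0).astype(float)
    total = obs.sum(axis=0)
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    exp = np.stack([row1 * col1, row1 * col2, row2 * col1, row2 * col2], axis=0) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum(axis=0)
    return stats.chi2.sf(np.maximum(g, 0.0), df=1)


def diff_exon_usage(
    table: CountTable,
    design: pd.DataFrame,
    contrast: Contrast,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential exon usage for one contrast.

    Per exon, a two-sided G-test of whether the exon's share of its gene's
    counts differs between the groups (2x2 table of group-summed exon vs.
    rest-of-gene counts).  Per gene, exon p-values are combined with the
    Simes rule, and genes are compared at ``alpha`` after BH adjustment
    across genes.  Genes with fewer than two tested exons get no call.

    Returns ``(gene_results, exon_results)``.
    """
    if table.level != "exon":
        raise ValueError("diff_exon_usage needs an exon-level table")
    sa = _group_samples(design, contrast.group_a, table.sample_ids)
    sb = _group_samples(design, contrast.group_b, table.sample_ids)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >=2 samples on each side of the contrast")
    exon_a = table.counts[sa].sum(axis=1)
    exon_b = table.counts[sb].sum(axis=1)
    genes = table.gene_of_feature.loc[table.feature_ids]
    gene_a = exon_a.groupby(genes.to_numpy()).transform("sum")
    gene_b = exon_b.groupby(genes.to_numpy()).transform("sum")
    rest_a = gene_a - exon_a
    rest_b = gene_b - exon_b
    testable = (gene_a > 0) & (gene_b > 0)
    n_skipped = int((~testable).sum())
    if n_skipped:
        log.info("diff_exon_usage %s: skipped %d exons with zero gene total", contrast.label, n_skipped)
    p = np.full(len(exon_a), np.nan)
    idx = testable.to_numpy()
    p[idx] = _g_test_2x2(
        exon_a.to_numpy()[idx],
        rest_a.to_numpy()[idx],
        exon_b.to_numpy()[idx],
        rest_b.to_numpy()[idx],
    )
    exon_results = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "count_a": exon_a,
            "count_b": exon_b,
            "p_value": p,
        },
        index=table.feature_ids,
    )
    tested = exon_results.dropna(subset=["p_value"])
    grouped = tested.groupby("gene_id")["p_value"]
    gene_results = pd.DataFrame(
        {
            "n_exons_tested": grouped.size(),
            "simes_p": grouped.apply(lambda s: simes_p(s.to_numpy())),
        }
    )
    callable_mask = gene_results["n_exons_tested"] >= 2
    gene_results["adjusted_p"] = np.nan
    if callable_mask.any():
        gene_results.loc[callable_mask, "adjusted_p"] = multipletests(
            gene_results.loc[callable_mask, "simes_p"].to_numpy(), method="fdr_bh"
        )[1]
    gene_results["significant"] = gene_results["adjusted_p"] < alpha
    gene_results.loc[~callable_mask, "significant"] = False
    gene_results.index.name = "gene_id"
    return gene_results, exon_results


# ---------------------------------------------------------------------------
# Event-level test: PSI + binomial LRT


def compute_psi(inclusion, skip, inc_len: int, skip_len: int):
    """Length-normalized percent spliced in.

    ``PSI = (inc/inc_len) / (inc/inc_len + skip/skip_len)``; NaN where
    inclusion + skip = 0.  Accepts scalars or arrays.
    """
    if inc_len <= 0 or skip_len <= 0:
        raise ValueError("effective lengths must be positive")
    inc = np.asarray(inclusion, dtype=float)
    sk = np.asarray(skip, dtype=float)
    if (inc < 0).any() or (sk < 0).any():
        raise ValueError("junction counts must be non-negative")
    num = inc / inc_len
    den = num + sk / skip_len
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / den, np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def filter_events(
    events,
    design: pd.DataFrame,
    contrast: Contrast,
    min_samples: int = 3,
    min_reads: int = 5,
    mode: str = "per_sample_or",
):
    """Retain events with enough read support in both groups of a contrast.

    ``per_sample_or`` (default): an event is retained iff, in each group,
    at least ``min_samples`` samples have inclusion >= ``min_reads`` OR
    skip >= ``min_reads``.  ``group_wise``: at least ``min_samples``
    samples with any reads and the group-summed inclusion or skip counts
    reach ``min_reads``.  Filtering is applied per contrast independently.
    """
    kept = []
    for ev in events:
        ok = True
        for group in (contrast.group_a, contrast.group_b):
            samples = _group_samples(design, group, ev.inclusion.index)
            inc = ev.inclusion[samples].to_numpy()
            sk = ev.skip[samples].to_numpy()
            if mode == "per_sample_or":
                n_support = int(((inc >= min_reads) | (sk >= min_reads)).sum())
                if n_support < min_samples:
                    ok = False
                    break
            elif mode == "group_wise":
                if int(((inc + sk) > 0).sum()) < min_samples or (
                    inc.sum() < min_reads and sk.sum() < min_reads
                ):
                    ok = False
                    break
            else:
                raise ValueError(f"unknown filter mode {mode!r}")
        if ok:
            kept.append(ev)
    return kept


def _binom_ll(x: float, n: float, p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return x * np.log(p) + (n - x) * np.log(1 - p)


def _event_lrt(x1: float, n1: float, x2: float, n2: float, cstat: float) -> float:
    """Binomial LRT of shared vs. separate inclusion proportion.

    The null allows the two proportions to differ by up to ``cstat``
    (effect-size floor), so biologically negligible differences never reach
    significance regardless of depth.  Returns the chi-square(1) p-value.
    """
    p1, p2 = x1 / n1, x2 / n2
    if abs(p1 - p2) <= cstat:
        return 1.0
    s = 1.0 if p1 > p2 else -1.0
    alt = _binom_ll(x1, n1, p1) + _binom_ll(x2, n2, p2)

    def neg_null(t: float) -> float:
        q1 = min(max(t, 0.0), 1.0)
        q2 = min(max(t - s * cstat, 0.0), 1.0)
        return -(_binom_ll(x1, n1, q1) + _binom_ll(x2, n2, q2))

    lo, hi = (cstat, 1.0) if s > 0 else (0.0, 1.0 - cstat)
    res = optimize.minimize_scalar(neg_null, bounds=(lo, hi), method="bounded")
    stat = max(0.0, 2.0 * (alt + res.fun))
    return float(stats.chi2.sf(stat, df=1))


def diff_event_usage(
    events,
    design: pd.DataFrame,
    contrast: Contrast,
    alpha: float = 0.01,
    min_dpsi: float = 0.05,
    cstat: float = 0.001,
) -> tuple[pd.DataFrame, pd.Series]:
    """Differential event expression for one contrast.

    Per event, group PSI means from per-sample length-normalized PSI, and a
    binomial LRT on pooled (inclusion, skip) counts with effect floor
    ``cstat``.  BH adjustment across events within the contrast; an event
    is significant iff adjusted p < ``alpha`` and |dPSI| > ``min_dpsi``.
    A gene is differentially spliced iff it has >=1 significant event.

    Returns ``(event_results, gene_calls)``.
    """
    rows = []
    for ev in events:
        sa = _group_samples(design, contrast.group_a, ev.inclusion.index)
        sb = _group_samples(design, contrast.group_b, ev.inclusion.index)
        psi_a = compute_psi(ev.inclusion[sa].to_numpy(), ev.skip[sa].to_numpy(), ev.inc_len, ev.skip_len)
        psi_b = compute_psi(ev.inclusion[sb].to_numpy(), ev.skip[sb].to_numpy(), ev.inc_len, ev.skip_len)
        if np.all(np.isnan(psi_a)) or np.all(np.isnan(psi_b)):
            log.info("event %s degenerate in contrast %s; excluded", ev.event_id, contrast.label)
            continue
        mean_a = float(np.nanmean(psi_a))
        mean_b = float(np.nanmean(psi_b))
        x1, n1 = float(ev.inclusion[sa].sum()), float(ev.inclusion[sa].sum() + ev.skip[sa].sum())
        x2, n2 = float(ev.inclusion[sb].sum()), float(ev.inclusion[sb].sum() + ev.skip[sb].sum())
        if n1 == 0 or n2 == 0:
            continue
        p = _event_lrt(x1, n1, x2, n2, cstat)
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "event_type": ev.event_type,
                "mean_psi_a": mean_a,
                "mean_psi_b": mean_b,
                "delta_psi": mean_b - mean_a,
                "p_value": p,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "event_type", "mean_psi_a", "mean_psi_b", "delta_psi", "p_value"],
    )
    if len(results):
        results["adjusted_p"] = multipletests(results["p_value"].to_numpy(), method="fdr_bh")[1]
        results["significant"] = (results["adjusted_p"] < alpha) & (
            results["delta_psi"].abs() > min_dpsi
        )
        gene_calls = results.groupby("gene_id")["significant"].any()
    else:
        results["adjusted_p"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
        gene_calls = pd.Series(dtype=bool)
    return results, gene_calls


# ---------------------------------------------------------------------------
# Whole-gene expression: NB Wald test with trended moment dispersions


def diff_gene_expression(
    table: CountTable,
    design: pd.DataFrame,
    contrast: Contrast,
    alpha: float = 0.01,
    norm: NormalizedMatrix | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial test of whole-gene expression.

    Per gene, group mean rates are estimated under TMM-scaled library
    offsets; dispersion is a method-of-moments estimate shrunk halfway
    toward a lowess trend on the mean, and the log-rate difference is
    tested with a Wald z statistic.  BH adjustment across genes;
    significant iff adjusted p < ``alpha``.
    """
    if table.level != "gene":
        raise ValueError("diff_gene_expression needs a gene-level table")
    sa = _group_samples(design, contrast.group_a, table.sample_ids)
    sb = _group_samples(design, contrast.group_b, table.sample_ids)
    if norm is None:
        norm = tmm_normalize(table)
    eff = norm.effective_lib_sizes
    y_a = table.counts[sa].to_numpy(dtype=float)
    y_b = table.counts[sb].to_numpy(dtype=float)
    lib_a = eff[sa].to_numpy()
    lib_b = eff[sb].to_numpy()
    lam_a = y_a.sum(axis=1) / lib_a.sum()
    lam_b = y_b.sum(axis=1) / lib_b.sum()

    mu_a = lam_a[:, None] * lib_a[None, :]
    mu_b = lam_b[:, None] * lib_b[None, :]
    resid = ((y_a - mu_a) ** 2 - mu_a).sum(axis=1) + ((y_b - mu_b) ** 2 - mu_b).sum(axis=1)
    denom = (mu_a**2).sum(axis=1) + (mu_b**2).sum(axis=1)
    n = len(sa) + len(sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(denom > 0, resid / denom * n / max(n - 2, 1), 0.0)
    phi_raw = np.clip(phi_raw, 0.0, 10.0)

    mean_rate = (y_a.sum(axis=1) + y_b.sum(axis=1)) / (lib_a.sum() + lib_b.sum())
    expressed = mean_rate > 0
    log_mean = np.log10(np.where(expressed, mean_rate, np.nan))
    phi_trend = np.full_like(phi_raw, np.nan)
    if expressed.sum() >= 10:
        fit = lowess(
            phi_raw[expressed], log_mean[expressed], frac=0.5, it=1, return_sorted=False
        )
        phi_trend[expressed] = np.clip(fit, 0.0, None)
    else:
        phi_trend[expressed] = np.median(phi_raw[expressed]) if expressed.any() else 0.0
    phi = np.where(expressed, 0.5 * phi_raw + 0.5 * phi_trend, 0.0)

    def group_var(y, lib, lam):
        mu = lam[:, None] * lib[None, :]
        return (mu + phi[:, None] * mu**2).sum(axis=1) / lib.sum() ** 2

    pseudo_a = 0.5 / lib_a.sum()
    pseudo_b = 0.5 / lib_b.sum()
    la = lam_a + pseudo_a
    lb = lam_b + pseudo_b
    var_log = group_var(y_a, lib_a, lam_a) / la**2 + group_var(y_b, lib_b, lam_b) / lb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(lb) - np.log(la)) / np.sqrt(var_log)
    p = np.where(expressed, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame(
        {
            "mean_rate_a": lam_a,
            "mean_rate_b": lam_b,
            "log2_fc": (np.log(lb) - np.log(la)) / np.log(2),
            "dispersion": phi,
            "p_value": p,
        },
        index=table.feature_ids,
    )
    out["adjusted_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["adjusted_p"] < alpha
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Gene classification and PCA


def classify_genes(calls: pd.DataFrame, contrasts: list[Contrast]) -> pd.Series:
    """Classify genes as Diap / Both / Dir / None from per-contrast calls.

    ``calls`` has one boolean column per contrast label.  A gene is Diap if
    significant in >=1 within-diapause contrast and none within direct,
    Dir for the converse, Both if at least one of each, else None.  The
    cross-trajectory day-0 contrast is computed elsewhere but excluded from
    classification, which targets change *through* each trajectory.
    Output is invariant to contrast ordering.
    """
    dia_labels = [c.label for c in contrasts if c.is_within("diapause")]
    dir_labels = [c.label for c in contrasts if c.is_within("direct")]
    missing = [l for l in dia_labels + dir_labels if l not in calls.columns]
    if missing:
        raise ValueError(f"missing contrast results: {missing}")
    dia_any = calls[dia_labels].fillna(False).astype(bool).any(axis=1)
    dir_any = calls[dir_labels].fillna(False).astype(bool).any(axis=1)
    category = np.where(
        dia_any & dir_any, "Both", np.where(dia_any, "Diap", np.where(dir_any, "Dir", "None"))
    )
    return pd.Series(category, index=calls.index, name="category")


def pca_variance(
    matrix: pd.DataFrame, top_n: int | None = None, complete_only: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA over samples on the highest-variance features.

    Features (rows) with missing values are dropped when ``complete_only``;
    the ``top_n`` features by variance are retained and row-centered.
    Returns sample scores and per-PC variance fractions (summing to 1).
    """
    mat = matrix
    if complete_only:
        mat = mat.dropna(axis=0)
    if len(mat) < 2:
        raise ValueError("fewer than 2 complete features")
    if top_n is not None and top_n < len(mat):
        variances = mat.var(axis=1, ddof=1)
        mat = mat.loc[variances.sort_values(ascending=False).index[:top_n]]
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x features matrix
    u, s, _vt = np.linalg.svd(x.T, full_matrices=False)
    scores = u * s
    frac = s**2 / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=mat.columns, columns=cols), frac
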