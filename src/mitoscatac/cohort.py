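"""Cohort-level statistics: mitochondrial content by cell type with pairwise
Wilcoxon significance matrices, mutation burden and mean-VAF comparisons,
shared-variant set intersections, gene activity and signature scores, and
aggregate-profile correlation.

The Wilcoxon rank-sum test is the workhorse comparison throughout (two-sided,
unpaired). Small samples are tested exactly — via the rank-sum distribution
recursion when there are no ties, or full enumeration of group assignments
when there are — and larger samples use the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "wilcoxon_rank_sum",
    "PairwiseSignificanceMatrix",
    "pairwise_content_matrix",
    "significant_pair_fraction",
    "mutation_burden",
    "burden_group_comparison",
    "mean_vaf_by_group",
    "shared_variant_sets",
    "gene_activity_scores",
    "signature_score",
    "aggregate_profile_correlation",
]


def _rank_sum_distribution(n: int, N: int) -> np.ndarray:
    """Null distribution of the rank sum of n items drawn from ranks 1..N
    (no ties): ``dist[w]`` = number of n-subsets of {1..N} with sum w."""
    max_w = n * N
    ways = np.zeros((n + 1, max_w + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, N + 1):
        # iterate k downwards so each rank is used at most once
        for k in range(min(r, n), 0, -1):
            ways[k, r:] += ways[k - 1, :-r]
    return ways[n]


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided", exact_cap: int = 26, enum_cap: int = 16
) -> float:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for pooled sizes up to ``exact_cap`` when tie-free (rank-sum
    recursion) or up to ``enum_cap`` with ties (full enumeration of group
    assignments); tie-corrected, continuity-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = len(x), len(y)
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rank_sum_x = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < N

    if not has_ties and N <= exact_cap:
        dist = _rank_sum_distribution(n, N)
        total = dist.sum()
        w = int(round(rank_sum_x))
        cdf_le = dist[: w + 1].sum() / total
        cdf_ge = dist[w:].sum() / total
    elif has_ties and N <= enum_cap:
        sums = np.array(
            [ranks[list(c)].sum() for c in combinations(range(N), n)]
        )
        cdf_le = float((sums <= rank_sum_x + 1e-9).mean())
        cdf_ge = float((sums >= rank_sum_x - 1e-9).mean())
    else:
        mu = n * (N + 1) / 2.0
        _, t = np.unique(pooled, return_counts=True)
        var = n * m * ((N + 1) - (t**3 - t).sum() / (N * (N - 1))) / 12.0
        sd = np.sqrt(max(var, 1e-300))
        # Edgeworth correction: the rank-sum null is symmetric with excess
        # kurtosis -(6/5)(n^2+m^2+nm+n+m)/(nm(N+1)) in the tie-free case
        g2 = -1.2 * (n * n + m * m + n * m + n + m) / (n * m * (N + 1))

        def cdf(z):
            return sps.norm.cdf(z) - sps.norm.pdf(z) * g2 / 24.0 * (z**3 - 3 * z)

        z_le = (rank_sum_x - mu + 0.5) / sd
        z_ge = (rank_sum_x - mu - 0.5) / sd
        cdf_le = float(np.clip(cdf(z_le), 0.0, 1.0))
        cdf_ge = float(np.clip(1.0 - cdf(z_ge), 0.0, 1.0))

    if alternative == "less":  # x tends smaller than y
        return float(min(1.0, cdf_le))
    if alternative == "greater":
        return float(min(1.0, cdf_ge))
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


@dataclass
class PairwiseSignificanceMatrix:
    """Symmetric matrix of two-sided Wilcoxon p-values over cell-type pairs,
    with the significant-pair bookkeeping used for heat-map summaries."""

    p_values: pd.DataFrame
    alpha: float
    n_significant: int
    total_pairs: int

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.total_pairs if self.total_pairs else 0.0

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values < self.alpha


def significant_pair_fraction(n_sig: int, k_types: int, digits: int = 2) -> float:
    """Reported fraction of significant pairs among C(k, 2) cell-type pairs
    (e.g. 45 of 55 -> 0.82)."""
    total = comb(k_types, 2)
    if total == 0:
        raise ValueError("need at least two cell types")
    if n_sig > total:
        raise ValueError(f"n_sig={n_sig} exceeds total pairs {total}")
    return round(n_sig / total, digits)


def pairwise_content_matrix(
    values: pd.Series, cell_types: pd.Series, alpha: float = 0.01
) -> PairwiseSignificanceMatrix:
    """All unordered cell-type pair comparisons of a per-cell quantity
    (two-sided Wilcoxon; no multiple-testing correction — raw p against
    ``alpha``, as is conventional for these significance heat maps)."""
    df = pd.DataFrame({"v": values, "t": cell_types}).dropna()
    types = sorted(df["t"].unique())
    k = len(types)
    if k < 2:
        raise ValueError("need at least two cell types with data")
    p = pd.DataFrame(np.ones((k, k)), index=types, columns=types)
    groups = {t: df.loc[df["t"] == t, "v"].to_numpy() for t in types}
    n_sig = 0
    for a, b in combinations(types, 2):
        pv = wilcoxon_rank_sum(groups[a], groups[b])
        p.loc[a, b] = p.loc[b, a] = pv
        if pv < alpha:
            n_sig += 1
    return PairwiseSignificanceMatrix(
        p_values=p, alpha=alpha, n_significant=n_sig, total_pairs=comb(k, 2)
    )


# ---------------------------------------------------------------------------
# mutation burden and VAF summaries


def mutation_burden(
    alt_counts: pd.DataFrame, min_alt_reads: int = 1
) -> pd.Series:
    """Per-cell count of variants with detected alt evidence.

    ``alt_counts`` is cells x variants with NaN marking sites of
    insufficient coverage in that cell (missing, excluded from counting —
    not imputed zero). A variant counts iff its passing alt-read count is
    at least ``min_alt_reads``.
    """
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    detected = alt_counts >= min_alt_reads
    return detected.sum(axis=1).rename("burden")


def burden_group_comparison(
    burden: pd.Series, annotation: pd.DataFrame, group_col: str = "age_group"
) -> pd.DataFrame:
    """Per-cell-type two-group burden comparison (Wilcoxon two-sided).

    ``annotation`` is indexed or keyed by barcode with columns
    ``cell_type`` and ``group_col`` (exactly two levels)."""
    ann = annotation.set_index("barcode") if "barcode" in annotation.columns else annotation
    df = pd.DataFrame({"burden": burden}).join(ann[["cell_type", group_col]], how="inner")
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups in {group_col!r}, got {levels}")
    rows = []
    for t, sub in df.groupby("cell_type"):
        a = sub.loc[sub[group_col] == levels[0], "burden"]
        b = sub.loc[sub[group_col] == levels[1], "burden"]
        if len(a) == 0 or len(b) == 0:
            continue
        rows.append(
            (t, levels[0], levels[1], float(a.mean()), float(b.mean()),
             wilcoxon_rank_sum(a, b))
        )
    return pd.DataFrame(
        rows, columns=["cell_type", "group_a", "group_b", "mean_a", "mean_b", "p_value"]
    )


def mean_vaf_by_group(
    vaf_matrix: pd.DataFrame, annotation: pd.DataFrame, group_col: str = "age_group"
) -> pd.DataFrame:
    """Per-cell mean VAF (over non-missing variants), compared between two
    groups within each cell type."""
    per_cell = vaf_matrix.mean(axis=1, skipna=True).rename("mean_vaf")
    ann = annotation.set_index("barcode") if "barcode" in annotation.columns else annotation
    df = pd.DataFrame({"mean_vaf": per_cell}).join(
        ann[["cell_type", group_col]], how="inner"
    ).dropna(subset=["mean_vaf"])
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups in {group_col!r}, got {levels}")
    rows = []
    for t, sub in df.groupby("cell_type"):
        a = sub.loc[sub[group_col] == levels[0], "mean_vaf"]
        b = sub.loc[sub[group_col] == levels[1], "mean_vaf"]
        if len(a) == 0 or len(b) == 0:
            continue
        rows.append(
            (t, levels[0], levels[1], float(a.mean()), float(b.mean()),
             wilcoxon_rank_sum(a, b))
        )
    return pd.DataFrame(
        rows, columns=["cell_type", "group_a", "group_b", "mean_a", "mean_b", "p_value"]
    )


def shared_variant_sets(variant_sets: dict) -> dict:
    """Venn-region bookkeeping over per-sample variant sets.

    Variant identity is whatever hashable key the caller uses — by
    convention ``(pos, ref, alt)`` or the ``m.<pos><ref>><alt>`` id.
    Returns region membership keyed by a frozenset of sample names, plus
    ``counts`` with the same keys.
    """
    sets = {k: set(v) for k, v in variant_sets.items()}
    names = list(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for grp in combinations(names, r):
            inside = set.intersection(*(sets[g] for g in grp))
            outside = set.union(set(), *(sets[g] for g in names if g not in grp))
            regions[frozenset(grp)] = inside - outside
    return {
        "regions": regions,
        "counts": {k: len(v) for k, v in regions.items()},
        "union": set.union(*sets.values()) if sets else set(),
    }


# ---------------------------------------------------------------------------
# gene activity & signatures


def gene_activity_scores(
    frags: pd.DataFrame, gene_table: pd.DataFrame, upstream_bp: int = 2_000
) -> pd.DataFrame:
    """Cells x genes fragment counts over gene body plus a strand-oriented
    upstream promoter window (BED coordinates in ``gene_table``:
    chrom/start/end/strand/gene)."""
    scores = {}
    for _, g in gene_table.iterrows():
        if g["strand"] == "+":
            lo, hi = g["start"] - upstream_bp, g["end"]
        else:
            lo, hi = g["start"], g["end"] + upstream_bp
        m = (
            (frags["chrom"] == g["chrom"])
            & (frags["start"] < hi)
            & (frags["end"] > lo)
        )
        scores[g["gene"]] = frags.loc[m].groupby("barcode").size()
    barcodes = pd.Index(sorted(frags["barcode"].unique()), name="barcode")
    out = pd.DataFrame(scores, index=barcodes).fillna(0).astype(int)
    return out


def signature_score(activity: pd.DataFrame, gene_set) -> pd.Series:
    """Mean of per-gene z-scored (across cells) activities over a gene set;
    zero-variance genes contribute 0."""
    genes = [g for g in gene_set if g in activity.columns]
    if not genes:
        raise ValueError("no genes of the set are present in the activity matrix")
    sub = activity[genes].astype(float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = (sub - mu).div(sd.replace(0, np.inf), axis=1)
    return z.mean(axis=1).rename("signature_score")


def aggregate_profile_correlation(
    counts_a: pd.Series, counts_b: pd.Series, log_transform: bool = True
) -> float:
    """Pearson correlation of two aggregate per-peak count profiles over the
    shared peak set (log1p-transformed by default to tame count
    heteroscedasticity)."""
    shared = counts_a.index.intersection(counts_b.index)
    if len(shared) < 2:
        raise ValueError("need at least two shared peaks")
    a = counts_a.loc[shared].to_numpy(dtype=float)
    b = counts_b.loc[shared].to_numpy(dtype=float)
    if log_transform:
        a, b = np.log1p(a), np.log1p(b)
    if a.std() == 0 or b.std() == 0:
        return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    return float(np.corrcoef(a, b)[0, 1])
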