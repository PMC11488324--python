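"""Per-barcode quality control and barnyard (species-mixing) statistics.

Cell retention follows the standard gates for droplet scATAC: TSS enrichment
of at least 1.2, between 2,000 and 50,000 unique nuclear fragments, and FRiP
above 0.2. Mitochondrial content is the percentage of a barcode's sequencing
fragments mapping to the mitochondrial genome, used throughout as a relative
proxy for mtDNA copy number.

TSS enrichment here is the insertion density (both Tn5 fragment ends) within
±100 bp of a TSS divided by the density in the distal ±[1901, 2000] bp
flanks, with a pseudocount of one insertion added to the flank count so that
cells with empty flanks get a finite score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellThresholds",
    "BarnyardReport",
    "compute_tss_enrichment",
    "compute_frip",
    "compute_mito_content",
    "compute_mito_mean_coverage",
    "coverage_fold_report",
    "apply_cell_filters",
    "select_top_cells",
    "compute_cell_metrics",
    "classify_barnyard",
]


@dataclass(frozen=True)
class CellThresholds:
    """Cell-retention gates; boundary semantics are 'at least' (TSS),
    'between' (fragment count, inclusive) and 'higher than' (FRiP)."""

    min_tss: float = 1.2
    min_fragments: int = 2_000
    max_fragments: int = 50_000
    min_frip: float = 0.2


@dataclass
class BarnyardReport:
    n_cells: int
    n_singlet: int
    n_mixed: int
    collision_rate: float
    n_contaminated: int
    contamination_rate: float
    n_excluded: int
    purity_threshold: float
    mito_minor_threshold: float


def _insertions(frags: pd.DataFrame):
    """Both ends of every fragment as (chrom, position, barcode) arrays; the
    insertion at the right end sits at ``end - 1`` (half-open interval)."""
    chrom = np.concatenate([frags["chrom"].to_numpy()] * 2)
    pos = np.concatenate([frags["start"].to_numpy(), frags["end"].to_numpy() - 1])
    bc = np.concatenate([frags["barcode"].to_numpy()] * 2)
    return chrom, pos, bc


def compute_tss_enrichment(
    frags: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 100,
    flank_inner_bp: int = 1_901,
    flank_outer_bp: int = 2_000,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-cell TSS enrichment score.

    ``tss`` needs columns ``chrom`` and ``pos``. Cells with no fragments at
    all are absent from the input; callers scoring a fixed barcode list
    should reindex and treat missing as 0 (a warning is emitted for barcodes
    with fragments but no scoreable insertions, which cannot occur with
    finite distances, so in practice only the empty case matters).
    """
    if len(tss) == 0:
        raise ValueError("at least one TSS is required")
    chrom, pos, bc = _insertions(frags)
    dist = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
    for c, sub in tss.groupby("chrom"):
        sites = np.sort(sub["pos"].to_numpy())
        m = chrom == c
        if not m.any():
            continue
        p = pos[m]
        j = np.searchsorted(sites, p)
        d_right = np.where(j < len(sites), np.abs(sites[np.clip(j, 0, len(sites) - 1)] - p), np.iinfo(np.int64).max)
        d_left = np.where(j > 0, np.abs(p - sites[np.clip(j - 1, 0, None)]), np.iinfo(np.int64).max)
        dist[m] = np.minimum(d_left, d_right)

    in_tss = dist <= window_bp
    in_flank = (dist >= flank_inner_bp) & (dist <= flank_outer_bp)
    df = pd.DataFrame({"barcode": bc, "in_tss": in_tss, "in_flank": in_flank})
    g = df.groupby("barcode", sort=True)[["in_tss", "in_flank"]].sum()
    tss_len = 2 * window_bp + 1
    flank_len = 2 * (flank_outer_bp - flank_inner_bp + 1)
    score = (g["in_tss"] / tss_len) / ((g["in_flank"] + pseudocount) / flank_len)
    return score.rename("tss_enrichment")


def compute_frip(frags: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Fraction of each cell's fragments overlapping any peak by >= 1 bp."""
    if len(peaks) == 0:
        counts = frags.groupby("barcode", sort=True).size()
        return pd.Series(0.0, index=counts.index, name="frip")
    in_peak = np.zeros(len(frags), dtype=bool)
    for c, sub in peaks.sort_values(["chrom", "start"]).groupby("chrom"):
        m = (frags["chrom"] == c).to_numpy()
        if not m.any():
            continue
        p_start = sub["start"].to_numpy()
        p_end = sub["end"].to_numpy()
        s = frags["start"].to_numpy()[m]
        e = frags["end"].to_numpy()[m]
        j = np.searchsorted(p_end, s, side="right")  # first peak ending after s
        ok = (j < len(p_start)) & (p_start[np.clip(j, 0, len(p_start) - 1)] < e)
        in_peak[m] = ok
    df = pd.DataFrame({"barcode": frags["barcode"], "in_peak": in_peak})
    g = df.groupby("barcode", sort=True)["in_peak"]
    return (g.sum() / g.size()).rename("frip")


def compute_mito_content(frags: pd.DataFrame, mito_reads: pd.DataFrame) -> pd.Series:
    """100 x mito / (mito + nuclear) sequencing fragments per barcode."""
    nuclear = frags.groupby("barcode").size()
    mito = mito_reads.groupby("barcode").size()
    idx = nuclear.index.union(mito.index)
    nuclear = nuclear.reindex(idx, fill_value=0)
    mito = mito.reindex(idx, fill_value=0)
    total = nuclear + mito
    pct = np.where(total > 0, 100.0 * mito / total.replace(0, 1), 0.0)
    return pd.Series(pct, index=idx, name="mito_content_pct")


def compute_mito_mean_coverage(mito_reads: pd.DataFrame, mito_length: int):
    """Per-cell mitochondrial coverage (aligned bases / genome length), plus
    the cohort mean with a normal-approximation 95% CI.

    Returns ``(per_cell, summary)`` where ``summary`` has keys
    ``mean``, ``ci_low``, ``ci_high``, ``n``.
    """
    if len(mito_reads) == 0:
        per_cell = pd.Series(dtype=float, name="mito_mean_coverage")
    else:
        bases = mito_reads["seq"].str.len()
        per_cell = (
            bases.groupby(mito_reads["barcode"]).sum() / mito_length
        ).rename("mito_mean_coverage")
    n = len(per_cell)
    mean = float(per_cell.mean()) if n else 0.0
    se = float(per_cell.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return per_cell, {
        "mean": mean,
        "ci_low": mean - 1.96 * se,
        "ci_high": mean + 1.96 * se,
        "n": n,
    }


def coverage_fold_report(mean_a: float, mean_b: float, digits: int = 2) -> float:
    """Fold change between two cohort mean coverages, rounded as printed in
    coverage reports (e.g. 282.87x over 4.61x -> 61.36)."""
    if mean_b <= 0:
        raise ValueError("reference mean coverage must be positive")
    return round(mean_a / mean_b, digits)


def apply_cell_filters(
    metrics: pd.DataFrame, thresholds: CellThresholds = CellThresholds()
) -> pd.Series:
    """Pass/fail per cell. Requires columns ``tss_enrichment``,
    ``n_unique_nuclear_fragments`` and ``frip``."""
    t = thresholds
    ok = (
        (metrics["tss_enrichment"] >= t.min_tss)
        & (metrics["n_unique_nuclear_fragments"] >= t.min_fragments)
        & (metrics["n_unique_nuclear_fragments"] <= t.max_fragments)
        & (metrics["frip"] > t.min_frip)
    )
    return ok.rename("pass_qc")


def select_top_cells(metrics: pd.DataFrame, n: int) -> list:
    """Top-n barcodes by chromatin complexity (unique nuclear fragment
    count, descending; ties broken lexicographically by barcode)."""
    ranked = metrics.sort_values(
        ["n_unique_nuclear_fragments", "barcode"], ascending=[False, True], kind="stable"
    )
    return ranked["barcode"].head(n).tolist()


def compute_cell_metrics(
    frags: pd.DataFrame,
    mito_reads: pd.DataFrame,
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    mito_length: int,
    thresholds: CellThresholds = CellThresholds(),
) -> pd.DataFrame:
    """Assemble the per-cell QC table and the pass flag in one pass."""
    n_frag = frags.groupby("barcode").size().rename("n_unique_nuclear_fragments")
    tss_score = compute_tss_enrichment(frags, tss)
    frip = compute_frip(frags, peaks)
    content = compute_mito_content(frags, mito_reads)
    cov, _ = compute_mito_mean_coverage(mito_reads, mito_length)
    metrics = pd.concat([n_frag, tss_score, frip, content, cov], axis=1)
    metrics.index.name = "barcode"
    metrics = metrics.fillna(
        {"n_unique_nuclear_fragments": 0, "tss_enrichment": 0.0, "frip": 0.0,
         "mito_content_pct": 0.0, "mito_mean_coverage": 0.0}
    )
    metrics["n_unique_nuclear_fragments"] = metrics["n_unique_nuclear_fragments"].astype(int)
    metrics = metrics.reset_index()
    metrics["pass_qc"] = apply_cell_filters(metrics, thresholds).to_numpy()
    return metrics


def classify_barnyard(
    frags: pd.DataFrame,
    mito_reads: pd.DataFrame,
    chrom_species: dict,
    purity_threshold: float = 0.95,
    mito_minor_threshold: float = 0.05,
):
    """Collision and contamination estimation for a two-species mixture.

    A barcode is a singlet iff its major species holds at least
    ``purity_threshold`` of its species-assignable *nuclear* fragments;
    otherwise it is mixed (a collision). Among singlets, a cell is
    contaminated iff the minor species holds at least
    ``mito_minor_threshold`` of its *mitochondrial* reads. Barcodes with no
    species-assignable nuclear fragments are excluded and counted.

    Returns ``(per_cell, BarnyardReport)``.
    """
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must be in (0.5, 1]")
    species = sorted(set(chrom_species.values()))
    if len(species) != 2:
        raise ValueError(f"need exactly two species, got {species}")

    def counts_by_species(df):
        sp = df["chrom"].map(chrom_species)
        tab = df.assign(species=sp).groupby(["barcode", "species"]).size().unstack(
            fill_value=0
        )
        return tab.reindex(columns=species, fill_value=0)

    nuc = counts_by_species(frags)
    mito = counts_by_species(mito_reads)
    idx = nuc.index.union(mito.index)
    nuc = nuc.reindex(idx, fill_value=0)
    mito = mito.reindex(idx, fill_value=0)

    nuc_total = nuc.sum(axis=1)
    excluded = nuc_total == 0
    major_frac = nuc.max(axis=1) / nuc_total.replace(0, 1)
    singlet = (~excluded) & (major_frac >= purity_threshold)
    mixed = (~excluded) & ~singlet

    major_species = nuc.idxmax(axis=1)
    maj_code = pd.Categorical(major_species, categories=species).codes
    mito_arr = mito.to_numpy(dtype=float)
    mito_total = mito_arr.sum(axis=1)
    major_mito = mito_arr[np.arange(len(idx)), np.clip(maj_code, 0, None)]
    minor_frac = np.where(
        mito_total > 0, (mito_total - major_mito) / np.maximum(mito_total, 1.0), 0.0
    )
    contaminated = singlet & (minor_frac >= mito_minor_threshold)

    per_cell = pd.DataFrame(
        {
            "barcode": idx,
            "major_species": major_species.to_numpy(),
            "nuclear_major_fraction": major_frac.to_numpy(),
            "mito_minor_fraction": minor_frac,
            "excluded": excluded.to_numpy(),
            "singlet": singlet.to_numpy(),
            "mixed": mixed.to_numpy(),
            "contaminated": contaminated.to_numpy(),
        }
    ).reset_index(drop=True)

    n_cells = int((~excluded).sum())
    n_mixed = int(mixed.sum())
    n_singlet = int(singlet.sum())
    n_contam = int(contaminated.sum())
    report = BarnyardReport(
        n_cells=n_cells,
        n_singlet=n_singlet,
        n_mixed=n_mixed,
        collision_rate=n_mixed / n_cells if n_cells else 0.0,
        n_contaminated=n_contam,
        contamination_rate=n_contam / n_singlet if n_singlet else 0.0,
        n_excluded=int(excluded.sum()),
        purity_threshold=purity_threshold,
        mito_minor_threshold=mito_minor_threshold,
    )
    return per_cell, report
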