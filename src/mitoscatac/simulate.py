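"""Seeded synthetic mtscATAC-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* per-cell nuclear Tn5 fragments concentrated in a regular peak set, with a
  configurable enrichment that simultaneously sets FRiP and TSS enrichment
  (peaks are centred on their TSS);
* per-cell mitochondrial reads with strand, MAPQ, mismatch counts and
  per-base Phred qualities, so that a configurable fraction of reads fails
  each read-level genotyping filter;
* heteroplasmic variants whose per-cell allele frequencies follow a
  zero-inflated Beta: a point mass at zero (most cells carry nothing) plus a
  Beta draw that is mostly below 1%, alongside a few near-homoplasmic sites;
* cell-type- and age-structured mitochondrial content fractions;
* planted cross-species doublets and cross-cell mitochondrial contamination
  for barnyard designs;
* carrier-status-linked accessible peaks with planted motif instances.

Every draw comes from one ``numpy.random.Generator``; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .io import ConfigError

__all__ = [
    "VariantSpec",
    "SimConfig",
    "TruthTable",
    "default_variant_spectrum",
    "make_peaks",
    "simulate_cells",
    "simulate_fragments",
    "simulate_mito_read_arrays",
    "packed_reads_to_frame",
    "simulate_barnyard",
    "embed_carrier_effects",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class VariantSpec:
    """One planted heteroplasmic site.

    ``pi`` is the probability a cell carries *no* copies (true VAF 0); in
    carrier cells the VAF is Beta(``beta_a``, ``beta_b``).
    """

    pos: int
    alt: str
    pi: float = 0.8
    beta_a: float = 0.5
    beta_b: float = 50.0

    def validate(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ConfigError(f"variant m.{self.pos}: pi={self.pi} outside [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ConfigError(f"variant m.{self.pos}: Beta parameters must be positive")
        if self.alt not in "ACGT":
            raise ConfigError(f"variant m.{self.pos}: alt {self.alt!r} not a base")

    @property
    def mean_carrier_vaf(self) -> float:
        return self.beta_a / (self.beta_a + self.beta_b)


# Age/cell-type structured mito-content Beta parameters. Means mirror the
# observed pattern: lymphocytes highest, neutrophils lowest, young > aged,
# aged more dispersed; overall mean near one half of total sequencing.
_CONTENT_BETA = {
    ("B", "young"): (30, 20), ("B", "aged"): (12, 12),
    ("CD4T", "young"): (30, 20), ("CD4T", "aged"): (12, 12),
    ("CD8T", "young"): (28, 20), ("CD8T", "aged"): (11, 12),
    ("NK", "young"): (24, 24), ("NK", "aged"): (9, 13),
    ("plasma", "young"): (22, 26), ("plasma", "aged"): (10, 12),
    ("monocyte", "young"): (22, 26), ("monocyte", "aged"): (8, 14),
    ("erythroblast", "young"): (20, 28), ("erythroblast", "aged"): (8, 15),
    ("neutrophil", "young"): (16, 32), ("neutrophil", "aged"): (6, 18),
}
_DEFAULT_TYPES = tuple(sorted({t for t, _ in _CONTENT_BETA}))


@dataclass
class SimConfig:
    """Study conditions for one simulated sample."""

    n_cells: int = 500
    seed: int = 0
    age_group: str = "young"
    tissue: str = "spleen"
    sample_id: str = "sample1"
    cell_types: tuple = _DEFAULT_TYPES
    cell_type_probs: tuple | None = None
    doublet_rate: float = 0.02
    contamination_rate: float = 0.005
    contamination_read_fraction: float = 0.15
    # nuclear fragment counts: log-normal around the cohort average of
    # ~6,400 unique fragments per cell, clipped to a plausible range
    frag_log_mean: float = float(np.log(6000.0))
    frag_log_sigma: float = 0.55
    frag_count_range: tuple = (300, 80_000)
    frag_len_log_mean: float = float(np.log(180.0))
    frag_len_log_sigma: float = 0.30
    # peaks: regular grid, centred on their TSS
    peak_width: int = 500
    peak_spacing: int = 5_000
    peak_enrichment: float = 5.0
    # mitochondrial reads
    mito_coverage: float | None = None  # reads drawn from content fraction if None
    content_beta: dict = field(default_factory=lambda: dict(_CONTENT_BETA))
    read_length: int = 100
    strand_prob: float = 0.5
    base_q: int = 30
    low_q: int = 10
    low_q_fraction: float = 0.05
    mapq_pass: int = 60
    mapq_fail: int = 20
    mapq_fail_rate: float = 0.05
    nm_fail_rate: float = 0.05
    variants: tuple | None = None  # None -> default_variant_spectrum(genome)
    designated: tuple = ()  # variant ids defining carrier status
    carrier_effect: float = 2.0

    def validate(self) -> None:
        for name in (
            "doublet_rate", "contamination_rate", "contamination_read_fraction",
            "strand_prob", "low_q_fraction", "mapq_fail_rate", "nm_fail_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_cells < 1:
            raise ConfigError(f"n_cells={self.n_cells} must be >= 1")
        if self.frag_log_sigma <= 0 or self.frag_len_log_sigma <= 0:
            raise ConfigError("log-normal sigma must be positive")
        if self.peak_width < 200 or self.peak_spacing <= self.peak_width:
            raise ConfigError("need peak_spacing > peak_width >= 200")
        if self.peak_enrichment <= 0:
            raise ConfigError(f"peak_enrichment={self.peak_enrichment} must be positive")
        if self.variants is not None:
            for v in self.variants:
                v.validate()


@dataclass
class TruthTable:
    """Ground truth for one simulated sample.

    ``cells`` has one row per barcode (species, type, age, doublet flag,
    contamination fraction, expected content fraction, carrier flag);
    ``vafs`` is barcode x variant-id true VAF; ``variants`` describes each
    planted site; ``manifest`` records the seed and conditions.
    """

    cells: pd.DataFrame
    variants: pd.DataFrame
    vafs: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def variant_id(pos: int, ref: str, alt: str) -> str:
    return f"m.{pos}{ref}>{alt}"


def default_variant_spectrum(genome: GenomeSpec, rng=None, n_low: int = 12) -> tuple:
    """The planted site spectrum: mostly-low-VAF sites plus near-homoplasmic
    ones, and — for mouse — the three designated aging-associated sites."""
    rng = np.random.default_rng(rng if rng is not None else 2024)
    specs = []
    if genome.species == "mouse":
        specs += [
            VariantSpec(9821, "T", pi=0.55, beta_a=2.0, beta_b=30.0),
            VariantSpec(15219, "C", pi=0.55, beta_a=2.0, beta_b=30.0),
            VariantSpec(15984, "T", pi=0.60, beta_a=2.0, beta_b=30.0),
        ]
    # two near-homoplasmic sites
    for _ in range(2):
        pos = int(rng.integers(200, genome.mito_length - 200))
        alt = _other_base(genome.mito_base(pos), rng)
        specs.append(VariantSpec(pos, alt, pi=0.0, beta_a=300.0, beta_b=2.0))
    # mostly sub-1% heteroplasmies
    for _ in range(n_low):
        pos = int(rng.integers(200, genome.mito_length - 200))
        alt = _other_base(genome.mito_base(pos), rng)
        specs.append(VariantSpec(pos, alt, pi=0.8, beta_a=0.5, beta_b=50.0))
    return tuple(specs)


def _other_base(ref: str, rng) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(3))]


def make_peaks(genome: GenomeSpec, config: SimConfig) -> pd.DataFrame:
    """Regular peak grid over the nuclear chromosomes (BED coordinates).
    Each peak's centre is treated as its TSS."""
    rows = []
    i = 0
    half = config.peak_width // 2
    for chrom, length in genome.chromosomes.items():
        for centre in range(config.peak_spacing // 2, length - half, config.peak_spacing):
            rows.append((chrom, centre - half, centre + half, f"peak{i}", centre))
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "tss"])


# ---------------------------------------------------------------------------
# cells


def simulate_cells(config: SimConfig, genome: GenomeSpec) -> TruthTable:
    """Draw the per-cell ground truth (no reads yet)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    barcodes = np.array([f"{config.sample_id}-BC{i:05d}" for i in range(n)])
    probs = config.cell_type_probs
    if probs is not None and abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError("cell_type_probs must sum to 1")
    types = rng.choice(np.array(config.cell_types), size=n, p=probs)
    doublet = rng.random(n) < config.doublet_rate
    partner = np.where(doublet, rng.choice(np.array(config.cell_types), size=n), "")
    contaminated = (~doublet) & (rng.random(n) < config.contamination_rate)
    contam_frac = np.where(contaminated, config.contamination_read_fraction, 0.0)

    content = np.empty(n)
    for i, t in enumerate(types):
        a, b = config.content_beta.get(
            (t, config.age_group), config.content_beta[("B", config.age_group)]
        )
        content[i] = rng.beta(a, b)

    n_frag = np.exp(rng.normal(config.frag_log_mean, config.frag_log_sigma, size=n))
    n_frag = np.clip(np.round(n_frag), *config.frag_count_range).astype(np.int64)
    n_frag[doublet] = np.round(n_frag[doublet] * 1.9).astype(np.int64)

    specs = config.variants
    if specs is None:
        specs = default_variant_spectrum(genome)
    for v in specs:
        v.validate()
    ids, vrows, vaf_cols = [], [], {}
    for v in specs:
        ref = genome.mito_base(v.pos)
        if ref == v.alt:
            raise ConfigError(f"variant m.{v.pos}: alt equals reference base {ref}")
        vid = variant_id(v.pos, ref, v.alt)
        ids.append(vid)
        carrier = rng.random(n) >= v.pi
        vaf = np.where(carrier, rng.beta(v.beta_a, v.beta_b, size=n), 0.0)
        vaf_cols[vid] = vaf
        vrows.append(
            (vid, v.pos, ref, v.alt, v.pi, v.beta_a, v.beta_b,
             "high" if v.mean_carrier_vaf >= 0.01 else "low")
        )
    vafs = pd.DataFrame(vaf_cols, index=pd.Index(barcodes, name="barcode"))
    variants = pd.DataFrame(
        vrows, columns=["id", "pos", "ref", "alt", "pi", "beta_a", "beta_b", "freq_class"]
    )

    designated = tuple(config.designated) or tuple(
        vid for vid in ids if any(f"m.{p}" in vid for p in (9821, 15219, 15984))
    )
    present = [d for d in designated if d in vafs.columns]
    carrier_flag = (
        (vafs[present].to_numpy() > 0).any(axis=1) if present else np.zeros(n, bool)
    )

    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "species": genome.species,
            "sample_id": config.sample_id,
            "tissue": config.tissue,
            "age_group": config.age_group,
            "cell_type": types,
            "doublet": doublet,
            "doublet_partner": partner,
            "contamination_frac": contam_frac,
            "mito_content": content,
            "n_nuclear": n_frag,
            "carrier": carrier_flag,
        }
    )
    manifest = {
        "seed": config.seed,
        "n_cells": n,
        "sample_id": config.sample_id,
        "age_group": config.age_group,
        "tissue": config.tissue,
        "species": genome.species,
        "doublet_rate": config.doublet_rate,
        "contamination_rate": config.contamination_rate,
        "designated": ",".join(designated),
    }
    return TruthTable(cells=cells, variants=variants, vafs=vafs, manifest=manifest)


# ---------------------------------------------------------------------------
# fragments & mitochondrial reads


def _sample_nuclear_positions(n, peaks, genome, enrichment, rng):
    """Fragment start positions: in-peak with probability set by the
    density-ratio ``enrichment``, else uniform over the non-peak genome."""
    chrom_names = list(genome.chromosomes)
    offsets = np.cumsum([0] + [genome.chromosomes[c] for c in chrom_names])
    total = offsets[-1]
    peak_len = int((peaks["end"] - peaks["start"]).sum())
    bg_len = total - peak_len
    p_in = enrichment * peak_len / (enrichment * peak_len + bg_len)
    in_peak = rng.random(n) < p_in

    gpos = np.empty(n, dtype=np.int64)
    k = int(in_peak.sum())
    if k:
        pk = rng.integers(0, len(peaks), size=k)
        starts = peaks["start"].to_numpy()[pk]
        widths = (peaks["end"] - peaks["start"]).to_numpy()[pk]
        local = starts + rng.integers(0, widths, size=k)
        chrom_idx = (
            pd.Categorical(peaks["chrom"], categories=chrom_names).codes[pk]
        )
        gpos[in_peak] = offsets[chrom_idx] + local
    m = n - k
    if m:
        # rejection-sample uniform positions outside peaks
        need = np.flatnonzero(~in_peak)
        pstart = peaks["start"].to_numpy()
        pend = peaks["end"].to_numpy()
        pchrom = pd.Categorical(peaks["chrom"], categories=chrom_names).codes
        gp_start = offsets[pchrom] + pstart
        gp_end = offsets[pchrom] + pend
        pending = need
        while len(pending):
            cand = rng.integers(0, total, size=len(pending))
            j = np.searchsorted(gp_start, cand, side="right") - 1
            inside = (j >= 0) & (cand < gp_end[np.clip(j, 0, None)])
            gpos[pending[~inside]] = cand[~inside]
            pending = pending[inside]
    return gpos, offsets, chrom_names


def simulate_fragments(
    truth: TruthTable, config: SimConfig, genome: GenomeSpec, peaks: pd.DataFrame | None = None
):
    """Generate the nuclear fragments file and the mitochondrial read file
    for a truth table produced by :func:`simulate_cells`.

    Returns ``(fragments, mito_reads)`` DataFrames in the on-disk column
    layouts of :mod:`mitoscatac.io`.
    """
    if (truth.cells["species"] != genome.species).any():
        raise ConfigError("truth table species does not match genome")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if peaks is None:
        peaks = make_peaks(genome, config)

    cells = truth.cells
    n_frag = cells["n_nuclear"].to_numpy()
    total = int(n_frag.sum())
    cell_idx = np.repeat(np.arange(len(cells)), n_frag)

    gpos, offsets, chrom_names = _sample_nuclear_positions(
        total, peaks, genome, config.peak_enrichment, rng
    )
    frag_len = np.exp(
        rng.normal(config.frag_len_log_mean, config.frag_len_log_sigma, size=total)
    )
    frag_len = np.clip(np.round(frag_len), 50, 600).astype(np.int64)
    # keep in-peak fragments inside their peak's chromosome bounds
    chrom_i = np.searchsorted(offsets, gpos, side="right") - 1
    local = gpos - offsets[chrom_i]
    chrom_len = np.array([genome.chromosomes[c] for c in chrom_names])[chrom_i]
    start = local
    end = np.minimum(local + frag_len, chrom_len)

    frags = pd.DataFrame(
        {
            "chrom": np.array(chrom_names, dtype=object)[chrom_i],
            "start": start,
            "end": end,
            "barcode": cells["barcode"].to_numpy()[cell_idx],
            "support": np.ones(total, dtype=np.int64),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    rng_reads = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    reads = _simulate_mito_reads_impl(truth, config, genome, rng_reads, packed=False)
    return frags, reads


def _simulate_mito_reads_impl(truth, config, genome, rng, packed: bool):
    cells = truth.cells
    truth.manifest.setdefault("mito_length", genome.mito_length)
    if config.mito_coverage is not None:
        lam = config.mito_coverage * genome.mito_length / config.read_length
        n_reads = rng.poisson(lam, size=len(cells))
    else:
        f = np.clip(cells["mito_content"].to_numpy(), 0.0, 0.99)
        n_reads = np.round(cells["n_nuclear"].to_numpy() * f / (1.0 - f)).astype(np.int64)

    blocks = [
        _mito_block_arrays(truth, config, genome, rng, n_reads, cells["barcode"].to_numpy())
    ]

    # cross-cell contamination: a contaminated cell receives reads generated
    # from a random donor's variant profile, relabelled with its own barcode
    contam = np.flatnonzero(cells["contamination_frac"].to_numpy() > 0)
    if len(contam) and len(cells) > 1:
        frac = cells["contamination_frac"].to_numpy()[contam]
        n_extra = np.round(frac * n_reads[contam] / (1.0 - frac)).astype(np.int64)
        for tgt, k in zip(contam, n_extra):
            if k <= 0:
                continue
            dnr = int(rng.integers(0, len(cells) - 1))
            if dnr >= tgt:
                dnr += 1  # donor is any cell other than the target
            blocks.append(
                _mito_block_arrays(
                    truth, config, genome, rng,
                    _one_hot(len(cells), dnr, int(k)),
                    np.full(len(cells), cells["barcode"].iloc[tgt]),
                )
            )
    out = _concat_packed(blocks)
    return out if packed else packed_reads_to_frame(out)


def _one_hot(n, i, k):
    out = np.zeros(n, dtype=np.int64)
    out[i] = k
    return out


def _mito_block_arrays(
    truth, config, genome, rng, n_reads, barcodes_per_cell, chunk_reads: int = 250_000
) -> dict:
    """Vectorised mitochondrial read synthesis for a per-cell read budget.

    Returns the packed-array read representation (see
    :func:`simulate_mito_read_arrays`). Works in chunks of reads to cap the
    transient (reads x read-length) matrices; per-base error draws use
    float32 and the two-level quality model avoids per-base exponentiation.
    """
    rl = config.read_length
    total = int(n_reads.sum())
    if total == 0:
        return {
            "barcode": np.empty(0, dtype=object), "chrom": genome.mito_chrom,
            "pos": np.empty(0, dtype=np.int64), "strand_code": np.empty(0, dtype=np.uint8),
            "mapq": np.empty(0, dtype=np.int64), "nm": np.empty(0, dtype=np.int64),
            "seq_codes": np.empty((0, rl), dtype=np.uint8),
            "qual": np.empty((0, rl), dtype=np.uint8),
        }
    cell_idx = np.repeat(np.arange(len(n_reads)), n_reads)
    start1 = rng.integers(1, genome.mito_length - rl + 2, size=total)  # 1-based
    strand_code = (rng.random(total) >= config.strand_prob).astype(np.uint8)
    mapq = np.where(
        rng.random(total) < config.mapq_fail_rate, config.mapq_fail, config.mapq_pass
    )
    nm = np.where(
        rng.random(total) < config.nm_fail_rate,
        rng.integers(3, 6, size=total),
        rng.integers(0, 3, size=total),
    )

    ref_codes = _CODE[np.frombuffer(genome.mito_seq.encode(), dtype=np.uint8)]
    p_err_low = 10.0 ** (-config.low_q / 10.0)
    p_err_base = 10.0 ** (-config.base_q / 10.0)
    var_pos = truth.variants["pos"].to_numpy(dtype=np.int64)
    var_alt = np.array([_CODE[ord(a)] for a in truth.variants["alt"]], dtype=np.uint8)
    var_vaf = truth.vafs.to_numpy()  # (cells, variants), column order = variants order

    seq_codes = np.empty((total, rl), dtype=np.uint8)
    qual_codes = np.empty((total, rl), dtype=np.uint8)
    for lo in range(0, total, chunk_reads):
        hi = min(lo + chunk_reads, total)
        s1 = start1[lo:hi]
        n = hi - lo
        pos0 = (s1 - 1).astype(np.int32)[:, None] + np.arange(rl, dtype=np.int32)[None, :]
        seq = ref_codes[pos0]

        # plant alt alleles per true per-cell VAF (binomial thinning per read)
        for j in range(len(var_pos)):
            p = var_pos[j]
            covers = (s1 <= p) & (p <= s1 + rl - 1)
            if not covers.any():
                continue
            idx = np.flatnonzero(covers)
            vafs = var_vaf[cell_idx[lo + idx], j]
            hit = rng.random(len(idx)) < vafs
            rows = idx[hit]
            seq[rows, p - s1[rows]] = var_alt[j]

        # two-level per-base quality, then Phred-implied errors
        qlow = rng.random((n, rl), dtype=np.float32) < config.low_q_fraction
        q = np.where(qlow, np.uint8(config.low_q), np.uint8(config.base_q))
        err = rng.random((n, rl), dtype=np.float32) < np.where(
            qlow, np.float32(p_err_low), np.float32(p_err_base)
        )
        k = int(err.sum())
        if k:
            shift = rng.integers(1, 4, size=k, dtype=np.uint8)
            seq[err] = (seq[err] + shift) % 4

        seq_codes[lo:hi] = seq
        qual_codes[lo:hi] = q

    return {
        "barcode": np.asarray(barcodes_per_cell, dtype=object)[cell_idx],
        "chrom": genome.mito_chrom,
        "pos": start1.astype(np.int64),
        "strand_code": strand_code,
        "mapq": mapq.astype(np.int64),
        "nm": nm.astype(np.int64),
        "seq_codes": seq_codes,
        "qual": qual_codes,
    }


def _concat_packed(blocks: list) -> dict:
    if len(blocks) == 1:
        return blocks[0]
    out = {"chrom": blocks[0]["chrom"]}
    for key in ("barcode", "pos", "strand_code", "mapq", "nm", "seq_codes", "qual"):
        out[key] = np.concatenate([b[key] for b in blocks])
    return out


def packed_reads_to_frame(packed: dict) -> pd.DataFrame:
    """Materialise packed read arrays as the MRF v1 DataFrame layout."""
    n, rl = packed["seq_codes"].shape
    seqs = np.frombuffer(_BASES[packed["seq_codes"]].tobytes(), dtype=f"S{rl}").astype(str) if n else []
    quals = np.frombuffer((packed["qual"] + 33).astype(np.uint8).tobytes(), dtype=f"S{rl}").astype(str) if n else []
    return pd.DataFrame(
        {
            "barcode": packed["barcode"],
            "chrom": packed["chrom"],
            "pos": packed["pos"],
            "strand": np.where(packed["strand_code"] == 0, "+", "-"),
            "mapq": packed["mapq"],
            "nm": packed["nm"],
            "seq": seqs,
            "qual": quals,
        }
    )


def simulate_mito_read_arrays(
    truth: TruthTable, config: SimConfig, genome: GenomeSpec
) -> dict:
    """Packed-array counterpart of the mitochondrial half of
    :func:`simulate_fragments`: identical reads, but held as numpy arrays
    (``seq_codes``/``qual`` as reads x read-length uint8 matrices, bases
    coded A=0..T=3, qualities as raw Phred values). This skips the string
    materialisation entirely and feeds the pileup directly; use
    :func:`packed_reads_to_frame` to obtain the MRF layout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    return _simulate_mito_reads_impl(truth, config, genome, rng, packed=True)


# ---------------------------------------------------------------------------
# barnyard


def simulate_barnyard(
    config: SimConfig,
    genome_a: GenomeSpec,
    genome_b: GenomeSpec,
    collision_rate: float = 0.02,
    n_frag_per_cell: int = 400,
    n_mito_per_cell: int = 150,
):
    """Two-species mixing experiment with planted collisions and
    contamination.

    Collisions are cross-species doublets: the barcode's fragments and mito
    reads are an even draw from both species, so a species-purity classifier
    can identify them. Contaminated singlets receive a fraction of foreign-
    species *mitochondrial* reads only, mirroring mtDNA carry-over.

    Returns ``(fragments, mito_reads, truth_cells)``.
    """
    config.validate()
    if not 0.0 <= collision_rate <= 1.0:
        raise ConfigError(f"collision_rate={collision_rate} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_cells
    barcodes = np.array([f"bar-BC{i:05d}" for i in range(n)])
    species = np.where(rng.random(n) < 0.5, genome_a.species, genome_b.species)
    collision = rng.random(n) < collision_rate
    contaminated = (~collision) & (rng.random(n) < config.contamination_rate)

    genomes = {g.species: g for g in (genome_a, genome_b)}
    other = {genome_a.species: genome_b.species, genome_b.species: genome_a.species}

    frag_blocks, read_blocks = [], []
    for sp, g in genomes.items():
        own = species == sp
        n_own = np.where(own, n_frag_per_cell, 0)
        n_own = np.where(own & collision, n_frag_per_cell // 2, n_own)
        n_foreign = np.where((species == other[sp]) & collision, n_frag_per_cell // 2, 0)
        counts = n_own + n_foreign
        frag_blocks.append(_uniform_fragments(g, barcodes, counts, rng))

        m_own = np.where(own, n_mito_per_cell, 0)
        m_own = np.where(own & collision, n_mito_per_cell // 2, m_own)
        m_foreign = np.where((species == other[sp]) & collision, n_mito_per_cell // 2, 0)
        m_contam = np.where(
            (species == other[sp]) & contaminated,
            np.round(config.contamination_read_fraction * n_mito_per_cell).astype(int),
            0,
        )
        read_blocks.append(_uniform_mito_reads(g, barcodes, m_own + m_foreign + m_contam, config, rng))

    frags = (
        pd.concat(frag_blocks, ignore_index=True)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    reads = pd.concat(read_blocks, ignore_index=True)
    truth_cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "species": species,
            "doublet": collision,
            "contaminated": contaminated,
            "contamination_frac": np.where(
                contaminated, config.contamination_read_fraction, 0.0
            ),
        }
    )
    return frags, reads, truth_cells


def _uniform_fragments(genome, barcodes, counts, rng):
    total = int(counts.sum())
    cell_idx = np.repeat(np.arange(len(barcodes)), counts)
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chroms])
    ci = rng.integers(0, len(chroms), size=total)
    start = rng.integers(0, lengths[ci] - 300)
    length = rng.integers(80, 300, size=total)
    return pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": start,
            "end": start + length,
            "barcode": barcodes[cell_idx],
            "support": 1,
        }
    )


def _uniform_mito_reads(genome, barcodes, counts, config, rng):
    total = int(counts.sum())
    from .io import MITO_READ_COLUMNS

    if total == 0:
        return pd.DataFrame({c: [] for c in MITO_READ_COLUMNS})
    rl = config.read_length
    cell_idx = np.repeat(np.arange(len(barcodes)), counts)
    start1 = rng.integers(1, genome.mito_length - rl + 2, size=total)
    seq = genome.mito_seq
    seqs = [seq[s - 1 : s - 1 + rl] for s in start1]
    qual = chr(33 + config.base_q) * rl
    return pd.DataFrame(
        {
            "barcode": barcodes[cell_idx],
            "chrom": genome.mito_chrom,
            "pos": start1,
            "strand": np.where(rng.random(total) < 0.5, "+", "-"),
            "mapq": config.mapq_pass,
            "nm": 0,
            "seq": seqs,
            "qual": qual,
        }
    )


# ---------------------------------------------------------------------------
# carrier-linked accessibility


def embed_carrier_effects(
    truth: TruthTable,
    peaks: pd.DataFrame,
    pwms,
    effect: float,
    n_affected: int = 50,
    seed: int | None = None,
    planted_motif: str | None = None,
):
    """Cells-by-peaks binary accessibility with a planted carrier signal.

    Affected peaks have their per-cell accessibility probability multiplied
    by ``effect`` in carrier cells, and carry an instance of the planted
    motif in their (synthetic) sequence. Returns
    ``(counts, peak_seqs, affected_ids, peak_truth, total_fragments)``,
    where ``total_fragments`` is the genome-wide per-cell fragment total (a
    depth covariate dominated by unaffected regions, unlike the row sums of
    a small peak matrix).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.manifest.get("seed", 0) if seed is None else seed, 3])
    )
    if effect <= 0:
        raise ConfigError(f"effect={effect} must be positive")
    n_affected = min(n_affected, len(peaks))
    cells = truth.cells
    carrier = cells["carrier"].to_numpy()

    base = rng.uniform(0.05, 0.35, size=len(peaks))
    depth = np.exp(rng.normal(0.0, 0.3, size=len(cells)))
    affected = np.zeros(len(peaks), dtype=bool)
    affected[rng.choice(len(peaks), size=n_affected, replace=False)] = True

    # per-cell depth acts on the odds scale, so depth alone never confounds a
    # logistic model with a log-depth covariate; the carrier effect multiplies
    # the detection probability itself, as a fold change on accessibility rate
    odds = depth[:, None] * (base / (1.0 - base))[None, :]
    prob = odds / (1.0 + odds)
    boost = np.where(affected[None, :] & carrier[:, None], effect, 1.0)
    prob = np.clip(prob * boost, 0.0, 0.95)
    counts = (rng.random(prob.shape) < prob).astype(np.int8)
    counts = pd.DataFrame(counts, index=cells["barcode"].to_numpy(), columns=peaks["id"])

    widths = (peaks["end"] - peaks["start"]).to_numpy()
    seqs = {}
    pwm_list = list(pwms) if pwms is not None else []
    planted = None
    if pwm_list:
        planted = next(
            (p for p in pwm_list if p.motif_id == planted_motif), pwm_list[0]
        )
    for j, pid in enumerate(peaks["id"]):
        s = _BASES[rng.integers(0, 4, size=int(widths[j]))].tobytes().decode()
        if affected[j] and planted is not None:
            inst = planted.sample(rng)
            off = int(rng.integers(0, len(s) - len(inst) + 1))
            s = s[:off] + inst + s[off + len(inst):]
        seqs[pid] = s

    peak_truth = pd.DataFrame(
        {
            "id": peaks["id"].to_numpy(),
            "baseline_rate": base,
            "carrier_log2_effect": np.where(affected, np.log2(effect), 0.0),
            "planted_motif": np.where(
                affected & (planted is not None),
                planted.motif_id if planted is not None else "",
                "",
            ),
        }
    )
    affected_ids = list(peaks["id"].to_numpy()[affected])
    total_fragments = pd.Series(
        rng.poisson(depth * 10_000), index=counts.index, name="total_fragments"
    )
    return counts, seqs, affected_ids, peak_truth, total_fragments
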