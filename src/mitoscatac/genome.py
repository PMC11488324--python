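"""Genome specifications: nuclear toy chromosomes, mitochondrial gene models,
and mitochondrial reference sequences.

Coordinate conventions
----------------------
Nuclear intervals are 0-based half-open (BED). Mitochondrial positions are
1-based, written ``m.<pos>`` as is standard for mtDNA variants. Gene-model
rows store 1-based inclusive start/end.

The bundled gene tables use the standard mouse (mm10 / NC_005089, 16,299 bp)
and human (hg19 / rCRS, 16,569 bp) mitochondrial coordinate frames. Reference
*sequences* are synthetic: seeded-random bases at the real genome length, with
a handful of anchor codons patched in so that the classic worked examples of
mitochondrial variant annotation (CYTB p.F359L, the ND4 Arg->His site, the
tRNA-Arg and D-loop sites) are reproducible from generated data. Coordinates,
not sequence content, drive every statistic in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GenomeSpec",
    "mouse_mito_genome",
    "human_mito_genome",
    "MOUSE_MITO_LENGTH",
    "HUMAN_MITO_LENGTH",
]

MOUSE_MITO_LENGTH = 16_299
HUMAN_MITO_LENGTH = 16_569

PRODUCT_CLASSES = frozenset({"protein", "tRNA", "rRNA", "D-loop"})

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_GENE_COLUMNS = ["gene", "start", "end", "strand", "klass"]

# mm10 chrM gene model (1-based inclusive). Overlapping genes (e.g. ATP8/ATP6,
# ND4L/ND4) are genuine features of the compact mitochondrial genome.
_MOUSE_GENES = [
    ("tRNA-Phe", 1, 68, "+", "tRNA"),
    ("mt-Rnr1", 70, 1024, "+", "rRNA"),
    ("tRNA-Val", 1025, 1093, "+", "tRNA"),
    ("mt-Rnr2", 1094, 2675, "+", "rRNA"),
    ("tRNA-Leu1", 2676, 2750, "+", "tRNA"),
    ("ND1", 2751, 3707, "+", "protein"),
    ("tRNA-Ile", 3706, 3774, "+", "tRNA"),
    ("tRNA-Gln", 3777, 3847, "-", "tRNA"),
    ("tRNA-Met", 3848, 3913, "+", "tRNA"),
    ("ND2", 3914, 4951, "+", "protein"),
    ("tRNA-Trp", 4950, 5016, "+", "tRNA"),
    ("tRNA-Ala", 5018, 5086, "-", "tRNA"),
    ("tRNA-Asn", 5089, 5161, "-", "tRNA"),
    ("tRNA-Cys", 5194, 5260, "-", "tRNA"),
    ("tRNA-Tyr", 5261, 5326, "-", "tRNA"),
    ("COX1", 5328, 6872, "+", "protein"),
    ("tRNA-Ser1", 6870, 6938, "-", "tRNA"),
    ("tRNA-Asp", 6942, 7011, "+", "tRNA"),
    ("COX2", 7013, 7696, "+", "protein"),
    ("tRNA-Lys", 7700, 7764, "+", "tRNA"),
    ("ATP8", 7766, 7969, "+", "protein"),
    ("ATP6", 7927, 8607, "+", "protein"),
    ("COX3", 8607, 9390, "+", "protein"),
    ("tRNA-Gly", 9391, 9458, "+", "tRNA"),
    ("ND3", 9459, 9806, "+", "protein"),
    ("tRNA-Arg", 9808, 9875, "+", "tRNA"),
    ("ND4L", 9877, 10173, "+", "protein"),
    ("ND4", 10167, 11544, "+", "protein"),
    ("tRNA-His", 11546, 11614, "+", "tRNA"),
    ("tRNA-Ser2", 11615, 11673, "+", "tRNA"),
    ("tRNA-Leu2", 11674, 11743, "+", "tRNA"),
    ("ND5", 11742, 13565, "+", "protein"),
    ("ND6", 13552, 14070, "-", "protein"),
    ("tRNA-Glu", 14071, 14139, "-", "tRNA"),
    ("CYTB", 14145, 15288, "+", "protein"),
    ("tRNA-Thr", 15289, 15355, "+", "tRNA"),
    ("tRNA-Pro", 15356, 15422, "-", "tRNA"),
    ("D-loop", 15423, 16299, "+", "D-loop"),
]

# hg19 chrM (rCRS) gene model; the control region wraps the origin and is
# stored as two D-loop rows.
_HUMAN_GENES = [
    ("D-loop", 1, 576, "+", "D-loop"),
    ("tRNA-Phe", 577, 647, "+", "tRNA"),
    ("MT-RNR1", 648, 1601, "+", "rRNA"),
    ("tRNA-Val", 1602, 1670, "+", "tRNA"),
    ("MT-RNR2", 1671, 3229, "+", "rRNA"),
    ("tRNA-Leu1", 3230, 3304, "+", "tRNA"),
    ("ND1", 3307, 4262, "+", "protein"),
    ("tRNA-Ile", 4263, 4331, "+", "tRNA"),
    ("tRNA-Gln", 4329, 4400, "-", "tRNA"),
    ("tRNA-Met", 4402, 4469, "+", "tRNA"),
    ("ND2", 4470, 5511, "+", "protein"),
    ("tRNA-Trp", 5512, 5579, "+", "tRNA"),
    ("tRNA-Ala", 5587, 5655, "-", "tRNA"),
    ("tRNA-Asn", 5657, 5729, "-", "tRNA"),
    ("tRNA-Cys", 5761, 5826, "-", "tRNA"),
    ("tRNA-Tyr", 5826, 5891, "-", "tRNA"),
    ("COX1", 5904, 7445, "+", "protein"),
    ("tRNA-Ser1", 7446, 7514, "-", "tRNA"),
    ("tRNA-Asp", 7518, 7585, "+", "tRNA"),
    ("COX2", 7586, 8269, "+", "protein"),
    ("tRNA-Lys", 8295, 8364, "+", "tRNA"),
    ("ATP8", 8366, 8572, "+", "protein"),
    ("ATP6", 8527, 9207, "+", "protein"),
    ("COX3", 9207, 9990, "+", "protein"),
    ("tRNA-Gly", 9991, 10058, "+", "tRNA"),
    ("ND3", 10059, 10404, "+", "protein"),
    ("tRNA-Arg", 10405, 10469, "+", "tRNA"),
    ("ND4L", 10470, 10766, "+", "protein"),
    ("ND4", 10760, 12137, "+", "protein"),
    ("tRNA-His", 12138, 12206, "+", "tRNA"),
    ("tRNA-Ser2", 12207, 12265, "+", "tRNA"),
    ("tRNA-Leu2", 12266, 12336, "+", "tRNA"),
    ("ND5", 12337, 14148, "+", "protein"),
    ("ND6", 14149, 14673, "-", "protein"),
    ("tRNA-Glu", 14674, 14742, "-", "tRNA"),
    ("CYTB", 14747, 15887, "+", "protein"),
    ("tRNA-Thr", 15888, 15953, "+", "tRNA"),
    ("tRNA-Pro", 15956, 16023, "-", "tRNA"),
    ("D-loop", 16024, 16569, "+", "D-loop"),
]

# Anchor patches applied to the synthetic references so that annotation of
# the canonical worked-example sites is sequence-faithful. Keys are 1-based
# start positions; values are the bases written there.
_MOUSE_ANCHORS = {
    15219: "TTC",  # CYTB codon 359 (c.1075-1077) = Phe; T>C -> Leu
    11184: "CGC",  # ND4 codon 341 (c.1018-1020) = Arg; m.11185 G>A -> His
    9821: "A",     # tRNA-Arg site
    15984: "C",    # D-loop site shared across aged tissues
    15728: "C",    # D-loop site shared between spleens
}
_HUMAN_ANCHORS = {
    310: "T",      # poly-C tract false-positive site (blacklisted)
    73: "A",
    182: "C",
}


@dataclass
class GenomeSpec:
    """A species' coordinate frame: toy nuclear chromosomes plus the real
    mitochondrial frame with gene model and (synthetic) reference sequence."""

    species: str
    chromosomes: dict  # nuclear chrom name -> length (bp)
    mito_chrom: str
    mito_length: int
    genes: pd.DataFrame = field(repr=False)  # columns: gene,start,end,strand,klass
    mito_seq: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        missing = [c for c in _GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        bad = ~self.genes["klass"].isin(PRODUCT_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown product class: {sorted(self.genes.loc[bad, 'klass'].unique())}"
            )
        if ((self.genes["start"] < 1) | (self.genes["end"] > self.mito_length)).any():
            raise ValueError("gene interval outside mitochondrial genome")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start > end")
        if self.mito_seq and len(self.mito_seq) != self.mito_length:
            raise ValueError(
                f"mito reference length {len(self.mito_seq)} != declared {self.mito_length}"
            )

    @property
    def nuclear_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def mito_base(self, pos: int) -> str:
        """Reference base at 1-based mitochondrial position."""
        if not 1 <= pos <= self.mito_length:
            raise ValueError(f"position {pos} outside mito genome [1, {self.mito_length}]")
        return self.mito_seq[pos - 1]

    def genes_at(self, pos: int) -> pd.DataFrame:
        """All gene rows whose interval covers a 1-based position."""
        g = self.genes
        return g[(g["start"] <= pos) & (g["end"] >= pos)]


def _random_reference(length: int, anchors: dict, seed: int) -> str:
    rng = np.random.default_rng(seed)
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    seq = bytearray(b"".join(bases))
    for pos, patch in anchors.items():
        seq[pos - 1 : pos - 1 + len(patch)] = patch.encode()
    return seq.decode()


def _gene_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def mouse_mito_genome(
    nuclear: dict | None = None, seed: int = 10090, mito_seq: str | None = None
) -> GenomeSpec:
    """Mouse spec: mm10 chrM gene model on a 16,299 bp frame.

    The default nuclear complement is two 1 Mb toy chromosomes — every
    nuclear statistic here is scale-free, so a desk-scale genome suffices.
    """
    if nuclear is None:
        nuclear = {"mm_chr1": 1_000_000, "mm_chr2": 1_000_000}
    seq = mito_seq or _random_reference(MOUSE_MITO_LENGTH, _MOUSE_ANCHORS, seed)
    return GenomeSpec(
        species="mouse",
        chromosomes=dict(nuclear),
        mito_chrom="mm_chrM",
        mito_length=MOUSE_MITO_LENGTH,
        genes=_gene_frame(_MOUSE_GENES),
        mito_seq=seq,
    )


def human_mito_genome(
    nuclear: dict | None = None, seed: int = 9606, mito_seq: str | None = None
) -> GenomeSpec:
    """Human spec: rCRS chrM gene model on a 16,569 bp frame."""
    if nuclear is None:
        nuclear = {"hs_chr1": 1_000_000, "hs_chr2": 1_000_000}
    seq = mito_seq or _random_reference(HUMAN_MITO_LENGTH, _HUMAN_ANCHORS, seed)
    return GenomeSpec(
        species="human",
        chromosomes=dict(nuclear),
        mito_chrom="hs_chrM",
        mito_length=HUMAN_MITO_LENGTH,
        genes=_gene_frame(_HUMAN_GENES),
        mito_seq=seq,
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid under the vertebrate mitochondrial code."""
    codon = codon.upper()
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]
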