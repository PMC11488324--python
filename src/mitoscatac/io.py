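"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* **fragments TSV** — 10x-style: ``chrom  start  end  barcode  support``,
  0-based half-open, position-sorted. Plain or gzip/bgzip (auto-detected by
  magic bytes) on read; written plain (or gzipped when the path ends ``.gz``).
* **MRF v1** — a TSV dialect for aligned mitochondrial reads:
  ``barcode  chrom  pos  strand  mapq  nm  seq  qual`` with ``pos`` the
  1-based leftmost aligned base, ``strand`` in ``{+,-}``, ``seq`` reported in
  reference orientation and ``qual`` a Phred+33 string of equal length.
  Lines beginning ``#`` are comments.
* **peaks** — BED3+name (``chrom  start  end  id``), 0-based half-open.
* **gene model** — either a 1-based TSV ``gene  start  end  strand  class``
  or BED6 with the name field written ``gene|class`` (0-based half-open).
* **variant table** — TSV with a fixed, documented column order; a VCF-lite
  exporter (CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO) is provided for
  interoperability.
* **config / manifest** — flat ``key: value`` text.

All round-trips are byte-stable for canonicalised input.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ConfigError",
    "read_fragments",
    "write_fragments",
    "read_mito_reads",
    "write_mito_reads",
    "read_peaks",
    "write_peaks",
    "read_gene_model",
    "read_variant_table",
    "write_variant_table",
    "write_vcf_lite",
    "read_flat_config",
    "write_flat_config",
    "FRAGMENT_COLUMNS",
    "MITO_READ_COLUMNS",
    "VARIANT_TABLE_COLUMNS",
]


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "support"]
MITO_READ_COLUMNS = ["barcode", "chrom", "pos", "strand", "mapq", "nm", "seq", "qual"]
VARIANT_TABLE_COLUMNS = [
    "pos", "ref", "alt", "gene", "region", "effect", "aa_change",
    "bulk_depth", "bulk_vaf", "n_cells", "plus_strand_fraction",
    "mean_coverage", "strand_concordance", "vmr",
    "pass_allele_ratio", "pass_strand_bias", "pass_bulk_depth",
    "pass_base_quality", "pass_mapq", "pass_mismatches",
    "pass_min_cells", "pass_blacklist", "pass_all",
]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _read_tsv(path, columns, dtypes):
    """Line-validated TSV reader: wrong column counts raise with line number."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise ParseError(
                    path, lineno, f"expected {len(columns)} columns, found {len(parts)}"
                )
            rows.append((lineno, parts))
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(columns, dtypes)}), []
    linenos = [r[0] for r in rows]
    df = pd.DataFrame([r[1] for r in rows], columns=columns)
    for col, dt in zip(columns, dtypes):
        if dt is int or dt is float:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(path, linenos[i], f"non-numeric value in column '{col}'")
            df[col] = converted.astype(np.int64 if dt is int else float)
    return df, linenos


def _fail_first(path, linenos, bad_mask, message):
    if bad_mask.any():
        i = int(np.flatnonzero(np.asarray(bad_mask))[0])
        raise ParseError(path, linenos[i], message)


# ---------------------------------------------------------------------------
# fragments


def read_fragments(path) -> pd.DataFrame:
    """Read a 10x-style fragments file into a DataFrame.

    Validates the half-open interval invariant (start < end, start >= 0),
    positive read support and non-empty barcodes, reporting the first
    offending line number.
    """
    df, linenos = _read_tsv(path, FRAGMENT_COLUMNS, [str, int, int, str, int])
    if len(df):
        _fail_first(path, linenos, (df["start"] < 0).to_numpy(), "negative start")
        _fail_first(
            path, linenos, (df["start"] >= df["end"]).to_numpy(),
            "start >= end violates half-open interval",
        )
        _fail_first(path, linenos, (df["support"] < 1).to_numpy(), "support must be >= 1")
        _fail_first(
            path, linenos, (df["barcode"].str.len() == 0).to_numpy(), "empty barcode"
        )
    return df


def write_fragments(frags: pd.DataFrame, path, sort: bool = False) -> None:
    """Write fragments; input must already be (chrom, start) sorted unless
    ``sort=True``."""
    frags = frags[FRAGMENT_COLUMNS]
    is_sorted = (
        frags.sort_values(["chrom", "start"], kind="stable").index.equals(frags.index)
        if len(frags)
        else True
    )
    if not is_sorted:
        if not sort:
            raise ValueError("fragments not (chrom, start)-sorted; pass sort=True")
        frags = frags.sort_values(["chrom", "start"], kind="stable")
    with _open_write(path) as fh:
        frags.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# mitochondrial reads (MRF v1)


def read_mito_reads(path) -> pd.DataFrame:
    """Read an MRF v1 file; checks strand symbols, qual/seq length equality
    and Phred+33 decodability (values in [0, 93])."""
    df, linenos = _read_tsv(path, MITO_READ_COLUMNS, [str, str, int, str, int, int, str, str])
    if len(df):
        _fail_first(
            path, linenos, (~df["strand"].isin(["+", "-"])).to_numpy(),
            "strand must be '+' or '-'",
        )
        _fail_first(
            path, linenos,
            (df["seq"].str.len() != df["qual"].str.len()).to_numpy(),
            "qual length != seq length",
        )
        _fail_first(path, linenos, (df["mapq"] < 0).to_numpy(), "negative MAPQ")
        _fail_first(path, linenos, (df["nm"] < 0).to_numpy(), "negative mismatch count")
        _fail_first(path, linenos, (df["pos"] < 1).to_numpy(), "pos is 1-based, must be >= 1")
        qual_ok = df["qual"].map(lambda q: all(33 <= ord(c) <= 126 for c in q))
        _fail_first(path, linenos, (~qual_ok).to_numpy(), "qual not Phred+33 decodable")
    return df


def write_mito_reads(reads: pd.DataFrame, path) -> None:
    with _open_write(path) as fh:
        fh.write("#MRF v1\t" + "\t".join(MITO_READ_COLUMNS) + "\n")
        reads[MITO_READ_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# peaks & gene models


def read_peaks(path) -> pd.DataFrame:
    """BED3+name; returns sorted peaks and checks they are non-overlapping
    within each chromosome."""
    df, linenos = _read_tsv(path, ["chrom", "start", "end", "id"], [str, int, int, str])
    if len(df):
        _fail_first(
            path, linenos, (df["start"] >= df["end"]).to_numpy(), "start >= end"
        )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    prev_end = df.groupby("chrom")["end"].shift()
    if ((df["start"] < prev_end).fillna(False)).any():
        raise ParseError(path, None, "overlapping peaks; merge before use")
    return df


def write_peaks(peaks: pd.DataFrame, path) -> None:
    with _open_write(path) as fh:
        peaks[["chrom", "start", "end", "id"]].to_csv(fh, sep="\t", header=False, index=False)


def read_gene_model(path) -> pd.DataFrame:
    """Parse a mito gene table (1-based TSV or BED6 with ``gene|class`` names).

    Returns the ``genome.GenomeSpec`` gene-frame layout (1-based inclusive).
    An empty file yields an empty table with a warning.
    """
    raw = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            raw.append((lineno, line.split("\t")))
    if not raw:
        warnings.warn(f"{path}: empty gene model")
        return pd.DataFrame(columns=["gene", "start", "end", "strand", "klass"])
    rows = []
    for lineno, parts in raw:
        if len(parts) == 5:  # 1-based TSV: gene start end strand class
            gene, start, end, strand, klass = parts
            start, end = int(start), int(end)
        elif len(parts) == 6:  # BED6, name = gene|class
            chrom, start, end, name, _score, strand = parts
            if "|" not in name:
                raise ParseError(path, lineno, "BED6 name must be 'gene|class'")
            gene, klass = name.split("|", 1)
            start, end = int(start) + 1, int(end)  # to 1-based inclusive
        else:
            raise ParseError(path, lineno, f"expected 5 or 6 columns, found {len(parts)}")
        from .genome import PRODUCT_CLASSES

        if klass not in PRODUCT_CLASSES:
            raise ParseError(
                path, lineno,
                f"unknown product class {klass!r}; expected one of {sorted(PRODUCT_CLASSES)}",
            )
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"bad strand {strand!r}")
        rows.append((gene, start, end, strand, klass))
    return pd.DataFrame(rows, columns=["gene", "start", "end", "strand", "klass"])


# ---------------------------------------------------------------------------
# variant tables


def write_variant_table(rows: pd.DataFrame, path) -> None:
    """Fixed-order TSV with header; an empty frame yields a header-only file."""
    out = rows.reindex(columns=VARIANT_TABLE_COLUMNS)
    with _open_write(path) as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"variant table missing columns: {missing}")
    return df[VARIANT_TABLE_COLUMNS]


def write_vcf_lite(rows: pd.DataFrame, path, chrom: str = "chrM") -> None:
    """Minimal VCF export of final variant calls (per-cell statistics do not
    fit VCF semantics; they stay in the TSV)."""
    with _open_write(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Pseudo-bulk VAF">\n')
        fh.write('##INFO=<ID=NCELLS,Number=1,Type=Integer,Description="Cells with alt evidence">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in rows.iterrows():
            filt = "PASS" if r.get("pass_all", True) else "FAIL"
            fh.write(
                f"{chrom}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t{filt}\t"
                f"VAF={r['bulk_vaf']:.6g};NCELLS={int(r['n_cells'])}\n"
            )


# ---------------------------------------------------------------------------
# flat config / manifest


def read_flat_config(path, valid_keys=None, required=()) -> dict:
    """Parse ``key: value`` lines; values are int/float/str by inference.

    Unknown keys (when ``valid_keys`` is given) and missing required keys
    raise :class:`ConfigError` naming the key.
    """
    cfg = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(path, lineno, "expected 'key: value'")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if valid_keys is not None and key not in valid_keys:
                raise ConfigError(
                    f"unknown config key {key!r}; valid keys: {sorted(valid_keys)}"
                )
            for cast in (int, float):
                try:
                    value = cast(value)
                    break
                except ValueError:
                    continue
            cfg[key] = value
    for key in required:
        if key not in cfg:
            raise ConfigError(f"missing required config key {key!r}")
    return cfg


def write_flat_config(cfg: dict, path) -> None:
    with _open_write(path) as fh:
        for key, value in cfg.items():
            fh.write(f"{key}: {value}\n")
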