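"""File-format glue: FPKM TSV, BED / TSV annotation, FISH CSV, karyotype text.

Coordinate conventions: annotation is held 1-based inclusive in memory (the
convention of the printed gene tables); BED files are 0-based half-open, and
the conversion happens here at the I/O boundary.  BED chromosome names may
carry a ``chr`` prefix, which is stripped on read and added on write.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .expression import ANNOTATION_COLUMNS, validate_annotation, validate_fpkm

__all__ = [
    "read_fpkm_tsv",
    "write_fpkm_tsv",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_annotation",
    "read_fish_csv",
    "write_fish_csv",
    "read_karyotype_table",
    "write_karyotype_table",
    "write_json",
]

FISH_COLUMNS = ("sample_id", "probe_set", "cell_index", "red", "green", "fusion")
KARYOTYPE_COLUMNS = ("replicate_id", "condition", "karyotype")


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample FPKM matrix (column 1 gene id, tab-separated)."""
    m = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    m.index.name = "gene_id"
    return validate_fpkm(m.astype(float))


def write_fpkm_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")


def _strip_chr(c: str) -> str:
    return c[3:] if c.lower().startswith("chr") else c


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    """Read gene annotation from BED (0-based half-open -> 1-based inclusive)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "bed_start", "bed_end", "gene_id"],
        dtype={"chrom": str},
    )
    ann = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"].map(_strip_chr),
            "start": bed["bed_start"].astype(int) + 1,
            "end": bed["bed_end"].astype(int),
        }
    )
    return validate_annotation(ann)


def write_annotation_bed(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann)
    bed = pd.DataFrame(
        {
            "chrom": "chr" + ann["chrom"].astype(str),
            "start": ann["start"].astype(int) - 1,
            "end": ann["end"].astype(int),
            "name": ann["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read annotation from TSV with 1-based inclusive coordinates."""
    ann = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    ann = ann[list(ANNOTATION_COLUMNS)]
    ann["chrom"] = ann["chrom"].map(_strip_chr)
    return validate_annotation(ann)


def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann)
    ann[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .bed -> BED, anything else -> TSV."""
    if str(path).endswith(".bed"):
        return read_annotation_bed(path)
    return read_annotation_tsv(path)


def read_fish_csv(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, comment="#")
    missing = set(FISH_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"FISH CSV is missing columns: {sorted(missing)}")
    for col in ("red", "green", "fusion"):
        if (cells[col] < 0).any():
            line = int(cells.index[cells[col] < 0][0]) + 2  # header is line 1
            raise ValueError(f"negative {col} count at line {line}")
    return cells


def write_fish_csv(cells: pd.DataFrame, path: str | Path) -> None:
    cells[list(FISH_COLUMNS)].to_csv(path, index=False)


def read_karyotype_table(path: str | Path) -> pd.DataFrame:
    """Read karyotype text: one ``replicate_id<TAB>condition<TAB>ISCN`` per line."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != list(KARYOTYPE_COLUMNS):
        # headerless variant
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] != 3:
            raise ValueError(
                f"karyotype file must have 3 tab-separated columns {KARYOTYPE_COLUMNS}"
            )
        df.columns = list(KARYOTYPE_COLUMNS)
    return df


def write_karyotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(KARYOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
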