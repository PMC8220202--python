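"""Shipped reference data: breakpoint-window gene catalog and replicate karyotypes."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import validate_annotation

__all__ = [
    "breakpoint_genes",
    "breakpoint_annotation",
    "replicate_karyotypes",
]


def _data_path(name: str):
    return resources.files("fishea.data").joinpath(name)


def breakpoint_genes() -> pd.DataFrame:
    """Catalog of known genes in the 2p22 / 10q22 / 16q22 breakpoint windows.

    Columns: gene_id, window, chrom, start, end (Hg19, 1-based inclusive),
    fold_change (observed BEC40W/BEC20W signed fold change in FPKM levels),
    coords_source.
    """
    with resources.as_file(_data_path("breakpoint_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"chrom": str})
    return df


def breakpoint_annotation() -> pd.DataFrame:
    """The catalog reduced to a gene annotation (gene_id, chrom, start, end)."""
    ann = breakpoint_genes()[["gene_id", "chrom", "start", "end"]].copy()
    return validate_annotation(ann)


def replicate_karyotypes() -> pd.DataFrame:
    """Karyotypes of the six replicate wells, exposed and unexposed arms.

    Columns: replicate_id, condition (unexposed | exposed), karyotype (ISCN).
    """
    with resources.as_file(_data_path("replicate_karyotypes.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)
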