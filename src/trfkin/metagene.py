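"""Strand-aware metagene coverage profiles anchored at tRNA gene boundaries.

A profile averages, over a set of gene models, the read coverage in a
window around a common anchor — the mature 3' end (the RNase Z cut, for
trailer profiles) or the gene 5' end — after flipping minus-strand genes
into transcript orientation.  Offset +1 is the first base downstream of
the anchor; negative offsets run upstream; there is no offset 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import TRNAGeneModel

__all__ = ["AnchorProfile", "compute_profile", "compare_profiles", "reads_frame"]

ANCHOR_MATURE_3P = "mature_3p"
ANCHOR_GENE_5P = "gene_5p"


@dataclass
class AnchorProfile:
    """Mean per-offset coverage over a gene set around one anchor."""

    anchor: str
    upstream: int
    downstream: int
    offsets: np.ndarray
    values: np.ndarray
    n_genes: int
    scaled_per_million: bool = False

    def __post_init__(self) -> None:
        if len(self.offsets) != self.upstream + self.downstream:
            raise ValueError("offset axis must have upstream + downstream entries")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("coverage values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_coverage": self.values})


def _offsets(upstream: int, downstream: int) -> np.ndarray:
    return np.concatenate([np.arange(-upstream, 0), np.arange(1, downstream + 1)])


def _anchor_boundary(model: TRNAGeneModel, anchor: str) -> int:
    """Genomic between-base coordinate of the anchor boundary."""
    if anchor == ANCHOR_MATURE_3P:
        a, b = model.mature_span
        return b if model.strand == "+" else a
    if anchor == ANCHOR_GENE_5P:
        return model.start if model.strand == "+" else model.end
    raise ValueError(f"unknown anchor {anchor!r}")


def _offset_positions(model: TRNAGeneModel, boundary: int, offs: np.ndarray) -> np.ndarray:
    """0-based genomic position of each transcript-orientation offset."""
    if model.strand == "+":
        return np.where(offs >= 1, boundary + offs - 1, boundary + offs)
    return np.where(offs >= 1, boundary - offs, boundary - offs - 1)


def reads_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a read-interval table from (chrom, start, end, count[, strand])."""
    rows = list(rows)
    with_strand = rows and len(rows[0]) >= 5
    cols = ["chrom", "start", "end", "count"] + (["strand"] if with_strand else [])
    return pd.DataFrame(rows, columns=cols)


def compute_profile(
    reads: pd.DataFrame,
    models: Sequence[TRNAGeneModel],
    anchor: str = ANCHOR_MATURE_3P,
    upstream: int = 0,
    downstream: int = 100,
    per_million: bool = False,
    mode: str = "coverage",
) -> AnchorProfile:
    """Aggregate coverage around an anchored window.

    ``reads`` needs columns chrom/start/end/count (0-based half-open
    genomic intervals) and, optionally, strand — when present, reads must
    match the gene's strand to contribute.  Each read adds its count to
    every offset it covers (``mode="coverage"``) or only to the offset of
    its 5' end (``mode="five_prime"``, for eCLIP-like data).  Per-offset
    value = sum over genes / number of genes, optionally scaled per
    million summed read counts.  Windows running past chromosome bounds
    are implicitly truncated (no reads can lie there).
    """
    if upstream < 0 or downstream < 0 or upstream + downstream < 1:
        raise ValueError("window must span at least one position")
    if not len(models):
        raise ValueError("no gene models supplied")
    if mode not in ("coverage", "five_prime"):
        raise ValueError(f"unknown mode {mode!r}")
    offs = _offsets(upstream, downstream)
    total = np.zeros(len(offs), float)
    has_strand = "strand" in reads.columns
    for m in models:
        boundary = _anchor_boundary(m, anchor)
        positions = _offset_positions(m, boundary, offs)
        sub = reads[reads["chrom"] == m.chrom]
        if has_strand:
            sub = sub[sub["strand"] == m.strand]
        if not len(sub):
            continue
        s = sub["start"].to_numpy(int)[:, None]
        e = sub["end"].to_numpy(int)[:, None]
        c = sub["count"].to_numpy(float)[:, None]
        if mode == "five_prime":
            five = np.where(m.strand == "+", s, e - 1)
            hit = positions[None, :] == five
        else:
            hit = (positions[None, :] >= s) & (positions[None, :] < e)
        total += (hit * c).sum(axis=0)
    values = total / len(models)
    if per_million:
        depth = float(reads["count"].sum())
        if depth > 0:
            values = values * 1e6 / depth
    return AnchorProfile(anchor, upstream, downstream, offs, values,
                         len(models), per_million)


def compare_profiles(
    a: AnchorProfile,
    b: AnchorProfile,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Offset-wise difference (b - a) and log2 ratio with pseudocount."""
    if (a.anchor, a.upstream, a.downstream) != (b.anchor, b.upstream, b.downstream):
        raise ValueError("profiles have mismatched anchor or window")
    return pd.DataFrame({
        "offset": a.offsets,
        "value_a": a.values,
        "value_b": b.values,
        "difference": b.values - a.values,
        "log2_ratio": np.log2((b.values + pseudocount) / (a.values + pseudocount)),
    })
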