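"""Positional classification of small RNAs against pre-tRNA gene models.

A precursor tRNA transcript is ``leader + mature body (possibly interrupted
by an intron) + trailer``.  Endonucleolytic maturation releases positionally
defined fragments: the leader (RNase P cut), the trailer ending at the Pol
III poly-U terminator (RNase Z cut; the tRF-1 class), and the intron (TSEN
cut).  Further fragments arise from the mature body: tRF-5s share the mature
5' end, tRF-3s share the mature 3' end (optionally carrying the
non-templated CCA), and internal fragments are miscellaneous.

This module builds a searchable reference from a genome plus gene models,
maps collapsed small-RNA sequences end-to-end with at most one mismatch, and
assigns each sequence to exactly one class by positional rules with a fixed,
configurable precedence.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping as TMapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# --------------------------------------------------------------------------
# class labels

TRF_LEADER = "tRF-leader"
TRF_1 = "tRF-1"
TRF_5 = "tRF-5"
TRF_3 = "tRF-3"
INTRON_TRF = "intron-tRF"
MISC_TRF = "misc-tRF"
MIRNA = "miRNA"
UNASSIGNED = "unassigned"

#: Closed set of class labels.
CLASS_LABELS = (
    TRF_LEADER, TRF_1, TRF_5, TRF_3, INTRON_TRF, MISC_TRF, MIRNA, UNASSIGNED,
)

#: Order in which classes win cross-locus conflicts (first wins).
DEFAULT_PRECEDENCE = (
    MIRNA, TRF_1, TRF_5, TRF_3, TRF_LEADER, INTRON_TRF, MISC_TRF,
)

#: Reads shorter than this many nucleotides are discarded before mapping.
MIN_READ_LENGTH = 15

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClassifierConfig:
    """Positional tolerances and tie-breaking rules.

    ``end_tol_mature`` absorbs ragged RNase cleavage at the mature 5'/3'
    ends (tRF-5 / tRF-3); ``end_tol_boundary`` does the same at
    leader/trailer/intron boundaries.  ``precedence`` resolves sequences
    that satisfy more than one class rule across loci.
    """

    end_tol_mature: int = 1
    end_tol_boundary: int = 2
    max_mismatches: int = 1
    min_length: int = MIN_READ_LENGTH
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE

    def __post_init__(self) -> None:
        if self.end_tol_mature < 0 or self.end_tol_boundary < 0:
            raise ValueError("tolerances must be non-negative")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")
        unknown = set(self.precedence) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown classes in precedence: {unknown}")


# --------------------------------------------------------------------------
# gene model

@dataclass(frozen=True)
class TRNAGeneModel:
    """Genomic model of one pre-tRNA locus.

    All coordinates are 0-based half-open genomic intervals.  The locus
    ``[start, end)`` is tiled, in transcript orientation, by
    leader -> mature body (exon blocks separated by introns) -> trailer.
    ``mature_blocks`` are stored in genomic order; transcript order is
    derived from ``strand``.
    """

    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    leader: tuple[int, int]
    mature_blocks: tuple[tuple[int, int], ...]
    trailer: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.trailer[1] - self.trailer[0] < 1:
            raise ValueError(f"{self.locus_id}: trailer length must be >= 1")
        blocks = sorted(self.mature_blocks)
        if tuple(blocks) != self.mature_blocks:
            raise ValueError(f"{self.locus_id}: mature blocks must be in genomic order")
        # leader/mature/trailer must tile [start, end) contiguously
        if self.strand == "+":
            order = [self.leader, *blocks, self.trailer]
        else:
            order = [self.trailer, *blocks, self.leader]
        if order[0][0] != self.start or order[-1][1] != self.end:
            raise ValueError(f"{self.locus_id}: intervals do not span the locus")
        for (a0, a1), (b0, b1) in zip(order, order[1:]):
            if a1 > b0:
                raise ValueError(f"{self.locus_id}: overlapping intervals")
        # introns strictly inside the mature span
        if len(blocks) > 1:
            span = (blocks[0][0], blocks[-1][1])
            for i0, i1 in self.introns:
                if not (span[0] < i0 and i1 < span[1]):
                    raise ValueError(f"{self.locus_id}: intron outside mature span")

    # -- genomic helpers -------------------------------------------------

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (gaps between mature blocks)."""
        blocks = self.mature_blocks
        return tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))

    @property
    def mature_span(self) -> tuple[int, int]:
        """Genomic interval from first to last mature base (introns included)."""
        return (self.mature_blocks[0][0], self.mature_blocks[-1][1])

    @property
    def discriminator(self) -> int:
        """Genomic position of the last templated mature base (before CCA)."""
        return self.mature_span[1] - 1 if self.strand == "+" else self.mature_span[0]

    # -- transcript-frame helpers (offsets from the pre-tRNA 5' end) ------

    @property
    def leader_len(self) -> int:
        return self.leader[1] - self.leader[0]

    @property
    def trailer_len(self) -> int:
        return self.trailer[1] - self.trailer[0]

    @property
    def mature_span_len(self) -> int:
        a, b = self.mature_span
        return b - a

    @property
    def spliced_len(self) -> int:
        return sum(e - s for s, e in self.mature_blocks)

    @property
    def pre_len(self) -> int:
        return self.end - self.start

    @property
    def tx_mature(self) -> tuple[int, int]:
        return (self.leader_len, self.leader_len + self.mature_span_len)

    @property
    def tx_trailer_start(self) -> int:
        return self.leader_len + self.mature_span_len

    @property
    def tx_discriminator(self) -> int:
        return self.leader_len + self.mature_span_len - 1

    def to_tx(self, gpos: int) -> int:
        """Transcript-frame offset of a genomic position."""
        return gpos - self.start if self.strand == "+" else self.end - 1 - gpos

    def tx_introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals in transcript-frame offsets, transcript order."""
        out = []
        for s, e in self.introns:
            if self.strand == "+":
                out.append((s - self.start, e - self.start))
            else:
                out.append((self.end - e, self.end - s))
        return tuple(sorted(out))

    def tx_to_genomic(self, s: int, e: int) -> tuple[int, int]:
        """Genomic interval of transcript-frame interval ``[s, e)``."""
        if self.strand == "+":
            return (self.start + s, self.start + e)
        return (self.end - e, self.end - s)


# --------------------------------------------------------------------------
# reference construction

_PRE = "pre"
_MATURE = "mature"
_MATURE_CCA = "mature_cca"
_MIRNA_KIND = "mirna"


@dataclass(frozen=True)
class ReferenceSeq:
    name: str
    kind: str          # one of pre / mature / mature_cca / mirna
    locus_id: str
    seq: str
    arr: np.ndarray = field(repr=False, compare=False)


class Reference:
    """Searchable set of transcript-oriented reference sequences."""

    def __init__(self, seqs: list[ReferenceSeq], models: dict[str, TRNAGeneModel]):
        self.seqs = seqs
        self.models = models

    def __iter__(self) -> Iterator[ReferenceSeq]:
        return iter(self.seqs)


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def build_reference(
    genome: TMapping[str, str],
    models: Iterable[TRNAGeneModel],
    mirnas: TMapping[str, str] | None = None,
) -> Reference:
    """Extract per-locus pre-tRNA, spliced-mature and mature+CCA sequences.

    Minus-strand loci are reverse-complemented so every reference sequence
    reads 5'->3' in transcript orientation.  miRNA reference sequences are
    included verbatim.  Out-of-bounds models raise ``ValueError`` naming the
    offending locus.
    """
    seqs: list[ReferenceSeq] = []
    model_map: dict[str, TRNAGeneModel] = {}
    for m in models:
        if m.chrom not in genome:
            raise ValueError(f"{m.locus_id}: chromosome {m.chrom!r} not in genome")
        chrom_seq = genome[m.chrom]
        if m.start < 0 or m.end > len(chrom_seq):
            raise ValueError(f"{m.locus_id}: interval out of chromosome bounds")
        model_map[m.locus_id] = m
        pre = chrom_seq[m.start:m.end].upper()
        blocks = [chrom_seq[s:e].upper() for s, e in m.mature_blocks]
        if m.strand == "-":
            pre = revcomp(pre)
            mature = "".join(revcomp(b) for b in reversed(blocks))
        else:
            mature = "".join(blocks)
        seqs.append(ReferenceSeq(f"{m.locus_id}|pre", _PRE, m.locus_id, pre, _as_array(pre)))
        seqs.append(ReferenceSeq(f"{m.locus_id}|mature", _MATURE, m.locus_id, mature, _as_array(mature)))
        cca = mature + "CCA"
        seqs.append(ReferenceSeq(f"{m.locus_id}|mature+CCA", _MATURE_CCA, m.locus_id, cca, _as_array(cca)))
    for name, seq in (mirnas or {}).items():
        s = seq.upper().replace("U", "T")
        seqs.append(ReferenceSeq(name, _MIRNA_KIND, name, s, _as_array(s)))
    return Reference(seqs, model_map)


# --------------------------------------------------------------------------
# mapping

@dataclass(frozen=True)
class ReadMapping:
    """End-to-end alignment of a read within one reference sequence."""

    ref_name: str
    kind: str
    locus_id: str
    start: int          # offset within the reference sequence
    end: int
    mismatches: int
    cca_softclip: bool = False


_VALID = frozenset(b"ACGTN")
_N = ord("N")


def map_sequence(
    seq: str,
    reference: Reference,
    max_mismatches: int = 1,
) -> list[ReadMapping]:
    """All end-to-end placements of ``seq`` with Hamming distance <= 1.

    Any N (in read or reference) counts as a mismatch.  If at least one
    exact placement exists, mismatched placements are dropped.
    """
    q = seq.upper().replace("U", "T")
    qarr = _as_array(q)
    if not _VALID.issuperset(qarr.tolist()):
        bad = sorted(set(q) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    m = len(qarr)
    q_is_n = qarr == _N
    hits: list[ReadMapping] = []
    for ref in reference:
        n = len(ref.arr)
        if n < m:
            continue
        win = sliding_window_view(ref.arr, m)
        mm = ((win != qarr) | (win == _N) | q_is_n).sum(axis=1)
        for pos in np.flatnonzero(mm <= max_mismatches):
            start, end = int(pos), int(pos) + m
            softclip = False
            if ref.kind == _MATURE_CCA:
                model = reference.models[ref.locus_id]
                softclip = end > model.spliced_len
                if not softclip:
                    continue  # duplicate of the plain-mature placement
            hits.append(ReadMapping(ref.name, ref.kind, ref.locus_id,
                                    start, end, int(mm[pos]), softclip))
    if any(h.mismatches == 0 for h in hits):
        hits = [h for h in hits if h.mismatches == 0]
    return hits


# --------------------------------------------------------------------------
# classification

def _labels_for_mapping(
    h: ReadMapping, models: dict[str, TRNAGeneModel], cfg: ClassifierConfig
) -> list[str]:
    """Class rules an individual placement satisfies."""
    if h.kind == _MIRNA_KIND:
        return [MIRNA]
    m = models[h.locus_id]
    t1, t2 = cfg.end_tol_mature, cfg.end_tol_boundary
    labels: list[str] = []
    if h.kind == _PRE:
        s, e = h.start, h.end
        trailer_s = m.tx_trailer_start
        # (a) trailer fragment: 5' end at the RNase Z cut, fully 3' of the
        # discriminator
        if trailer_s <= s <= trailer_s + t2:
            labels.append(TRF_1)
        # (b) leader fragment: 3' end at the RNase P cut
        if m.leader_len - t2 <= e <= m.leader_len and m.leader_len > 0:
            labels.append(TRF_LEADER)
        # (c/d) mature-end fragments in the precursor frame
        mat_s, mat_e = m.tx_mature
        if abs(s - mat_s) <= t1:
            labels.append(TRF_5)
        if abs(e - mat_e) <= t1:
            labels.append(TRF_3)
        # (e) intron fragment
        for i0, i1 in m.tx_introns():
            if i0 - t2 <= s and e <= i1 + t2:
                labels.append(INTRON_TRF)
                break
        # (f) any other mature-body overlap
        if not labels and s < mat_e and e > mat_s:
            labels.append(MISC_TRF)
    elif h.kind == _MATURE:
        if h.start <= t1:
            labels.append(TRF_5)
        if abs(h.end - m.spliced_len) <= t1:
            labels.append(TRF_3)
        if not labels:
            labels.append(MISC_TRF)
    elif h.kind == _MATURE_CCA:
        # only softclipped placements survive mapping; the read runs into
        # the non-templated CCA, so its 3' end sits at the mature terminus
        if h.start <= t1:
            labels.append(TRF_5)
        if h.end >= m.spliced_len:
            labels.append(TRF_3)
    return labels


def classify(
    mappings: Sequence[ReadMapping],
    reference: Reference,
    config: ClassifierConfig | None = None,
) -> tuple[str, ReadMapping | None]:
    """Assign one class label from a read's placements.

    Returns ``(label, winning_mapping)``; an empty mapping list yields
    ``("unassigned", None)``.  Conflicts across loci/rules are resolved by
    ``config.precedence``.
    """
    cfg = config or ClassifierConfig()
    if not mappings:
        return UNASSIGNED, None
    candidates: dict[str, ReadMapping] = {}
    for h in mappings:
        for lab in _labels_for_mapping(h, reference.models, cfg):
            candidates.setdefault(lab, h)
    for lab in cfg.precedence:
        if lab in candidates:
            return lab, candidates[lab]
    return UNASSIGNED, None


# --------------------------------------------------------------------------
# collapsing and the sequence-level driver

def collapse_and_count(
    reads: Iterable[str | tuple[str, int]],
    min_length: int = MIN_READ_LENGTH,
) -> "OrderedDict[str, int]":
    """Merge identical sequences, summing counts; drop reads < ``min_length`` nt.

    Accepts plain sequences (count 1 each) or ``(sequence, count)`` pairs,
    e.g. from a pre-collapsed FASTA.  Distinct-length isoforms remain
    distinct sequences.
    """
    counts: OrderedDict[str, int] = OrderedDict()
    for item in reads:
        if isinstance(item, tuple):
            seq, n = item
        else:
            seq, n = item, 1
        if n < 0:
            raise ValueError(f"negative count for sequence {seq!r}")
        seq = seq.upper().replace("U", "T")
        if len(seq) < min_length:
            continue
        counts[seq] = counts.get(seq, 0) + int(n)
    return counts


@dataclass
class ClassifiedRead:
    """A collapsed small-RNA sequence with its placements and class."""

    sequence: str
    count: int
    mappings: list[ReadMapping]
    assigned_class: str
    basis: ReadMapping | None

    @property
    def length(self) -> int:
        return len(self.sequence)


def classify_reads(
    collapsed: TMapping[str, int],
    reference: Reference,
    config: ClassifierConfig | None = None,
) -> list[ClassifiedRead]:
    """Map and classify every collapsed sequence once."""
    cfg = config or ClassifierConfig()
    out = []
    for seq, count in collapsed.items():
        maps = map_sequence(seq, reference, cfg.max_mismatches)
        label, basis = classify(maps, reference, cfg)
        out.append(ClassifiedRead(seq, count, maps, label, basis))
    return out


def mapping_to_genomic(
    h: ReadMapping, model: TRNAGeneModel
) -> tuple[str, int, int, str] | None:
    """Genomic interval of a placement, or None when it is not contiguous.

    Precursor-frame placements convert directly.  Spliced-mature placements
    convert only for intron-less loci; placements running into the
    non-templated CCA have no genomic footprint for the clipped bases and
    return None.
    """
    if h.kind == _PRE:
        g0, g1 = model.tx_to_genomic(h.start, h.end)
    elif h.kind == _MATURE and not model.introns:
        g0, g1 = model.tx_to_genomic(model.leader_len + h.start,
                                     model.leader_len + h.end)
    else:
        return None
    return (model.chrom, g0, g1, model.strand)
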