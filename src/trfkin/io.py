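"""File formats, configuration and run manifests.

Conventions: TSV with one header line, optional ``#``-prefixed metadata
lines before it; gene models as BED12 where the thick span is the mature
body (introns included) and the blocks are the mature exons, so leader and
trailer are the thin ends in transcript orientation; collapsed small-RNA
FASTA headers are ``id_xCOUNT``.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import TRNAGeneModel

__all__ = [
    "read_fasta", "write_fasta", "read_collapsed_fasta", "write_collapsed_fasta",
    "read_fastq_sequences", "read_models_bed12", "write_models_bed12",
    "read_models_gff3", "read_counts_tsv", "write_counts_tsv",
    "read_sample_sheet", "write_sample_sheet", "write_tsv", "read_tsv",
    "PipelineConfig", "load_config", "write_manifest",
]


# --------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_COUNT_RE = re.compile(r"^(?P<name>.*)_x(?P<count>\d+)$")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, int]]:
    """Collapsed reads with ``id_xCOUNT`` headers -> [(sequence, count)]."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_RE.match(rec.id)
        if not m:
            raise ValueError(f"collapsed FASTA header {rec.id!r} lacks _xCOUNT suffix")
        out.append((str(rec.seq).upper(), int(m.group("count"))))
    return out


def write_collapsed_fasta(path: str | Path, counts: Mapping[str, int],
                          prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(counts.items()):
            fh.write(f">{prefix}{i:05d}_x{n}\n{seq}\n")


def read_fastq_sequences(path: str | Path) -> Iterable[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()


# --------------------------------------------------------------------------
# gene models: BED12 and a minimal GFF3 dialect

def write_models_bed12(path: str | Path, models: Iterable[TRNAGeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            thick_s, thick_e = m.mature_span
            sizes = ",".join(str(e - s) for s, e in m.mature_blocks)
            starts = ",".join(str(s - m.start) for s, e in m.mature_blocks)
            fh.write("\t".join(map(str, [
                m.chrom, m.start, m.end, m.locus_id, 0, m.strand,
                thick_s, thick_e, "0,0,0", len(m.mature_blocks),
                sizes + ",", starts + ",",
            ])) + "\n")


def read_models_bed12(path: str | Path) -> list[TRNAGeneModel]:
    models = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{ln}: BED12 needs 12 fields, got {len(f)}")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        nblocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != nblocks or len(starts) != nblocks:
            raise ValueError(f"{path}:{ln}: block count mismatch")
        blocks = tuple((start + o, start + o + s) for o, s in zip(starts, sizes))
        if (blocks[0][0], blocks[-1][1]) != (thick_s, thick_e):
            raise ValueError(f"{path}:{ln}: blocks do not span the thick (mature) region")
        if strand == "+":
            leader, trailer = (start, thick_s), (thick_e, end)
        else:
            leader, trailer = (thick_e, end), (start, thick_s)
        models.append(TRNAGeneModel(
            locus_id=name, chrom=chrom, strand=strand, start=start, end=end,
            leader=leader, mature_blocks=blocks, trailer=trailer,
        ))
    return models


def read_models_gff3(
    path: str | Path, leader_len: int, trailer_len: int
) -> list[TRNAGeneModel]:
    """GFF3 alternative: tRNA features (mature span) with exon children.

    The leader/trailer flanks are not representable in plain GFF3 tRNA
    annotation, so their lengths come from configuration and extend the
    tRNA feature outward in transcript orientation.
    """
    trnas: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{ln}: GFF3 needs 9 fields")
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
        adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "tRNA":
            fid = adict.get("ID")
            if fid is None:
                raise ValueError(f"{path}:{ln}: tRNA feature lacks ID")
            trnas[fid] = {"chrom": chrom, "start": int(start) - 1,
                          "end": int(end), "strand": strand}
        elif ftype == "exon":
            parent = adict.get("Parent")
            exons.setdefault(parent, []).append((int(start) - 1, int(end)))
    models = []
    for fid, t in trnas.items():
        blocks = tuple(sorted(exons.get(fid, [(t["start"], t["end"])])))
        if t["strand"] == "+":
            start, end = t["start"] - leader_len, t["end"] + trailer_len
            leader, trailer = (start, t["start"]), (t["end"], end)
        else:
            start, end = t["start"] - trailer_len, t["end"] + leader_len
            leader, trailer = (t["end"], end), (start, t["start"])
        models.append(TRNAGeneModel(
            locus_id=fid, chrom=t["chrom"], strand=t["strand"],
            start=start, end=end, leader=leader,
            mature_blocks=blocks, trailer=trailer,
        ))
    return models


# --------------------------------------------------------------------------
# TSV tables

def write_tsv(path: str | Path, df: pd.DataFrame, index_label: str | None = None,
              meta: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def read_tsv(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_counts_tsv(path: str | Path, counts: pd.DataFrame,
                     meta: Mapping[str, str] | None = None) -> None:
    write_tsv(path, counts, index_label="sequence_id", meta=meta)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, index_col="sequence_id")
    for row, vals in df.iterrows():
        if (vals < 0).any():
            raise ValueError(f"negative count in row {row!r} of {path}")
    return df


def write_sample_sheet(path: str | Path, samples: pd.DataFrame) -> None:
    write_tsv(path, samples, index_label="library")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, index_col="library")
    required = {"timepoint_h", "replicate", "condition", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    bad = df.index[~df["fraction"].isin(["input", "rip", "total"])]
    if len(bad):
        raise ValueError(f"sample sheet {path}: invalid fraction for {bad[0]!r}")
    return df


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Paths and tunables for the command-line pipelines."""

    out_dir: str = "trfkin_out"
    genome: str | None = None
    models: str | None = None
    mirnas: str | None = None
    reads: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    seed: int = 0
    # classifier
    end_tol_mature: int = 1
    end_tol_boundary: int = 2
    max_mismatches: int = 1
    min_length: int = 15
    # half-life
    norm_mode: str = "rpm"
    cap_h: float | None = None
    min_total_reads: int = 10
    replicate_mode: str = "points"
    pseudocount: float = 0.5
    # gff flanks
    leader_len: int = 10
    trailer_len: int = 15
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.norm_mode not in ("rpm", "spike_in"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.min_length < 1 or self.min_total_reads < 0:
            raise ValueError("length/count thresholds out of range")
        for attr in ("genome", "models", "mirnas", "reads", "counts", "sample_sheet"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """YAML config file; explicit keyword overrides win over the file."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


# --------------------------------------------------------------------------
# run manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: PipelineConfig,
                   inputs: Iterable[str | Path] = (),
                   outputs: Iterable[str | Path] = ()) -> Path:
    """Record config, seed and input checksums so a run can be regenerated."""
    from . import __version__
    manifest = {
        "tool": "trfkin",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
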