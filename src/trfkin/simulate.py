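"""Synthetic small-RNA-seq generator with known ground truth.

Emulates the data structure of a transcription-shutoff (actinomycin D)
small-RNA time course and of Argonaute RIP/input library pairs:

* a toy genome carrying non-overlapping pre-tRNA loci on both strands, each
  with a leader, a mature body (optionally intron-containing), and a
  trailer ending in a poly-T Pol III terminator;
* one positionally exact fragment per locus (tRF-1, tRF-5, tRF-3,
  tRF-leader, intron-tRF or misc-tRF) plus random mature miRNAs and
  spike-in species of constant absolute abundance;
* per-class first-order decay with log-normal rate distributions and a
  stable sub-population (k = 0);
* fixed sequencing depth over a pool that shrinks under shutoff (the
  simulated species plus an unreported background mass decaying at
  ``total_rna_decay_k``), so stable species' library-relative counts
  apparently rise — the artifact decay-profile normalization corrects;
* negative-binomial count noise across replicates;
* RIP libraries whose expected composition is the input composition
  re-weighted by per-sequence enrichment folds.

All randomness flows from one ``numpy`` generator seeded by
``SimParams.seed``; the draw order is: genome/annotation -> per-sequence
kinetic truth -> library counts, so identical parameters give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import (
    INTRON_TRF, MIRNA, MISC_TRF, TRF_1, TRF_3, TRF_5, TRF_LEADER,
    TRNAGeneModel, revcomp,
)
from .halflife import LN2, TimecourseMatrix

__all__ = ["SimParams", "SimTruth", "SimData", "make_toy_genome",
           "draw_truth", "simulate_timecourse", "simulate_rip_pair",
           "simulate_dataset", "SPIKE_IN"]

SPIKE_IN = "spike-in"

_FRAGMENT_CLASSES = (TRF_1, TRF_5, TRF_3, TRF_LEADER, INTRON_TRF, MISC_TRF)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=n)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator.

    Defaults follow the measured biology of the system: a 0/1/2/4/8/12 h
    shutoff course in triplicate; tRF-1s abundant (median hundreds of
    normalized counts) and very unstable (median half-life ~0.3 h);
    mature-body fragments of intermediate stability; miRNAs mostly stable
    with literature half-lives beyond a day; Argonaute RIP enrichment high
    for miRNAs, intermediate for tRF-3s, and ~0.5-fold (depletion) for
    trailers.  ``total_rna_decay_k`` sets the decay of the unreported bulk
    of the RNA pool (default: halving over the 12 h course).
    """

    seed: int = 0
    n_genes_per_class: Mapping[str, int] = field(default_factory=lambda: {
        TRF_1: 40, TRF_5: 30, TRF_3: 30, TRF_LEADER: 5,
        INTRON_TRF: 15, MISC_TRF: 20, MIRNA: 120,
    })
    timepoints_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0)
    replicates: int = 3
    decay_rate_dist: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        TRF_1: (LN2 / 0.3, 0.5),
        TRF_5: (LN2 / 6.0, 0.5),
        TRF_3: (LN2 / 6.0, 0.5),
        TRF_LEADER: (LN2 / 2.0, 0.5),
        INTRON_TRF: (LN2 / 4.0, 0.5),
        MISC_TRF: (LN2 / 4.0, 0.5),
        MIRNA: (LN2 / 24.0, 0.5),
    })
    stable_fraction: Mapping[str, float] = field(default_factory=lambda: {
        TRF_1: 0.0, TRF_5: 0.2, TRF_3: 0.2, TRF_LEADER: 0.0,
        INTRON_TRF: 0.0, MISC_TRF: 0.1, MIRNA: 0.5,
    })
    a0_dist: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        TRF_1: (400.0, 0.8), TRF_5: (50.0, 1.0), TRF_3: (50.0, 1.0),
        TRF_LEADER: (20.0, 0.8), INTRON_TRF: (30.0, 0.8),
        MISC_TRF: (30.0, 0.8), MIRNA: (100.0, 2.0),
    })
    depth: int = 500_000
    nb_dispersion: float = 0.05
    spike_in_n: int = 52
    spike_in_abundance: float = 300.0
    total_rna_decay_k: float = LN2 / 12.0
    background_mass_ratio: float = 1.0
    rip_enrichment_dist: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        TRF_1: (0.5, 0.3), TRF_5: (1.0, 0.3), TRF_3: (1.5, 0.3),
        TRF_LEADER: (0.5, 0.3), INTRON_TRF: (0.5, 0.3),
        MISC_TRF: (0.7, 0.3), MIRNA: (8.0, 0.3),
    })
    trf1_end_jitter: int = 3

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.n_genes_per_class.values()):
            raise ValueError("n_genes_per_class must be positive for at least one class")
        if any(v < 0 for v in self.n_genes_per_class.values()):
            raise ValueError("gene counts must be non-negative")
        tps = tuple(self.timepoints_h)
        if list(tps) != sorted(tps) or (tps and tps[0] != 0):
            raise ValueError("timepoints must be sorted ascending and start at 0")
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for c, (med, sig) in self.decay_rate_dist.items():
            if med < 0 or sig < 0:
                raise ValueError(f"decay_rate_dist[{c!r}] must be non-negative")
        for c, f in self.stable_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"stable_fraction[{c!r}] must be in [0, 1]")
        if self.total_rna_decay_k < 0 or self.background_mass_ratio < 0:
            raise ValueError("background parameters must be non-negative")


# --------------------------------------------------------------------------
# genome and annotations

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_locus(rng: np.random.Generator, cls: str, params: SimParams):
    """Coding-strand parts of one pre-tRNA locus plus its fragment."""
    leader_len = 15 if cls == TRF_LEADER else int(rng.integers(8, 16))
    mature_len = int(rng.integers(70, 91))
    intron = ""
    intron_at = None
    if cls == INTRON_TRF:
        # canonical insertion one base 3' of the anticodon (mature 34-36)
        intron = _random_dna(rng, int(rng.integers(16, 31)))
        intron_at = 37
    if cls == TRF_1:
        trailer_len = int(rng.integers(18, 26))
    else:
        trailer_len = int(rng.integers(8, 26))
    leader = _random_dna(rng, leader_len)
    mature = _random_dna(rng, mature_len)
    trailer = _random_dna(rng, max(trailer_len - 4, 0)) + "TTTT"
    if intron_at is not None:
        mature_genomic = mature[:intron_at + 1] + intron + mature[intron_at + 1:]
    else:
        mature_genomic = mature

    if cls == TRF_1:
        jitter = int(rng.integers(0, params.trf1_end_jitter + 1))
        frag = trailer[: len(trailer) - jitter]
        if len(frag) < 15:
            frag = trailer[:15]
    elif cls == TRF_LEADER:
        frag = leader[-15:]
    elif cls == TRF_5:
        frag = mature[: int(rng.integers(16, 26))]
    elif cls == TRF_3:
        frag = mature[-int(rng.integers(18, 23)):]
        if rng.random() < 0.5:
            frag += "CCA"
    elif cls == INTRON_TRF:
        frag = intron
    elif cls == MISC_TRF:
        frag = mature[10:28]
    else:
        raise ValueError(f"not a fragment class: {cls}")
    return leader, mature_genomic, intron, intron_at, trailer, frag


def make_toy_genome(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TRNAGeneModel], dict[str, str], pd.DataFrame]:
    """Build the toy genome, gene models, miRNA reference and fragment table.

    Loci alternate strands and are separated by >= 50 nt of random
    sequence; every trailer ends in TTTT on the coding strand (the Pol III
    terminator).  Returns ``(genome, models, mirnas, fragments)`` where the
    fragment table maps each simulated sequence to its class and parent
    locus.
    """
    params.__post_init__()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    chrom = "chrT"
    pieces: list[str] = []
    pos = 0
    models: list[TRNAGeneModel] = []
    frag_rows: list[dict] = []
    seen: set[str] = set()
    gene_i = 0
    for cls in _FRAGMENT_CLASSES:
        for _ in range(int(params.n_genes_per_class.get(cls, 0))):
            gap = _random_dna(rng, int(rng.integers(50, 121)))
            for _attempt in range(100):
                leader, mature_g, intron, intron_at, trailer, frag = \
                    _build_locus(rng, cls, params)
                if frag not in seen:
                    break
            else:
                raise RuntimeError("could not draw a unique fragment sequence")
            seen.add(frag)
            strand = "+" if gene_i % 2 == 0 else "-"
            coding = leader + mature_g + trailer
            start = pos + len(gap)
            end = start + len(coding)
            if strand == "+":
                genome_part = coding
                leader_iv = (start, start + len(leader))
                if intron:
                    b1 = (start + len(leader), start + len(leader) + intron_at + 1)
                    i_iv = (b1[1], b1[1] + len(intron))
                    b2 = (i_iv[1], start + len(leader) + len(mature_g))
                    blocks = (b1, b2)
                else:
                    blocks = ((start + len(leader), start + len(leader) + len(mature_g)),)
                trailer_iv = (end - len(trailer), end)
            else:
                genome_part = revcomp(coding)
                leader_iv = (end - len(leader), end)
                if intron:
                    # transcript-frame block boundaries, mapped to genomic
                    b1_tx = (len(leader), len(leader) + intron_at + 1)
                    i_tx = (b1_tx[1], b1_tx[1] + len(intron))
                    b2_tx = (i_tx[1], len(leader) + len(mature_g))
                    blocks = tuple(sorted(
                        (end - e, end - s) for s, e in (b1_tx, b2_tx)))
                else:
                    blocks = ((start + len(trailer), end - len(leader)),)
                trailer_iv = (start, start + len(trailer))
            locus_id = f"tRNA-sim-{gene_i:03d}"
            models.append(TRNAGeneModel(
                locus_id=locus_id, chrom=chrom, strand=strand,
                start=start, end=end, leader=leader_iv,
                mature_blocks=blocks, trailer=trailer_iv,
            ))
            frag_rows.append({
                "sequence_id": f"{cls}:{locus_id}",
                "sequence": frag, "true_class": cls, "parent_locus": locus_id,
            })
            pieces.append(gap)
            pieces.append(genome_part)
            pos = end
            gene_i += 1
    pieces.append(_random_dna(rng, 60))
    genome = {chrom: "".join(pieces)}

    mirnas: dict[str, str] = {}
    for j in range(int(params.n_genes_per_class.get(MIRNA, 0))):
        for _attempt in range(100):
            seq = _random_dna(rng, int(rng.integers(21, 24)))
            if seq not in seen:
                break
        seen.add(seq)
        name = f"mir-sim-{j:03d}"
        mirnas[name] = seq
        frag_rows.append({
            "sequence_id": f"{MIRNA}:{name}", "sequence": seq,
            "true_class": MIRNA, "parent_locus": name,
        })
    fragments = pd.DataFrame(frag_rows)
    return genome, models, mirnas, fragments


# --------------------------------------------------------------------------
# kinetic truth

@dataclass
class SimTruth:
    """Ground truth per simulated sequence.

    One row per sequence: id, sequence, true class, parent locus, true
    decay rate k (per hour; 0 iff drawn stable), true absolute abundance
    A0 and true RIP enrichment fold.  Spike-ins carry class ``spike-in``
    and k = 0.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["sequence_id"].duplicated().any():
            raise ValueError("duplicate sequence ids in truth")

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.table["sequence_id"])

    def subset(self, classes) -> pd.DataFrame:
        return self.table[self.table["true_class"].isin(classes)]


def draw_truth(
    fragments: pd.DataFrame, params: SimParams, rng: np.random.Generator
) -> SimTruth:
    """Draw per-sequence kinetics: A0, k (with stable sub-population), RIP fold."""
    rows = []
    for cls, grp in fragments.groupby("true_class", sort=True):
        n = len(grp)
        med_a0, sig_a0 = params.a0_dist[cls]
        a0 = _lognormal(rng, med_a0, sig_a0, n)
        med_k, sig_k = params.decay_rate_dist[cls]
        k = _lognormal(rng, med_k, sig_k, n) if med_k > 0 else np.zeros(n)
        stable = rng.random(n) < params.stable_fraction.get(cls, 0.0)
        k = np.where(stable, 0.0, k)
        med_e, sig_e = params.rip_enrichment_dist[cls]
        enr = _lognormal(rng, med_e, sig_e, n)
        sub = grp.copy()
        sub["a0_true"] = a0
        sub["k_true"] = k
        sub["rip_enrichment_true"] = enr
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    spike_rows = []
    seen = set(table["sequence"])
    for j in range(params.spike_in_n):
        while True:
            seq = _random_dna(rng, int(rng.integers(20, 23)))
            if seq not in seen:
                break
        seen.add(seq)
        spike_rows.append({
            "sequence_id": f"spike-{j:02d}", "sequence": seq,
            "true_class": SPIKE_IN, "parent_locus": "spike",
            "a0_true": params.spike_in_abundance, "k_true": 0.0,
            "rip_enrichment_true": np.nan,
        })
    if spike_rows:
        table = pd.concat([table, pd.DataFrame(spike_rows)], ignore_index=True)
    return SimTruth(table)


# --------------------------------------------------------------------------
# libraries

def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draw with mean mu and variance mu + dispersion * mu^2."""
    mu = np.clip(mu, 1e-300, None)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _abundance_at(truth: SimTruth, t: float) -> np.ndarray:
    a0 = truth.table["a0_true"].to_numpy(float)
    k = truth.table["k_true"].to_numpy(float)
    return a0 * np.exp(-k * t)


def simulate_timecourse(
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    condition: str = "actD",
) -> TimecourseMatrix:
    """Sequence counts across the shutoff time course.

    Absolute abundance of sequence i at time t is ``A0_i * exp(-k_i t)``
    (spike-ins constant).  Each library sequences a fixed expected
    ``depth`` from a pool comprising the simulated species plus a
    background mass ``background_mass_ratio x pool(0)`` decaying at
    ``total_rna_decay_k``; reported counts are negative-binomial around
    ``depth x abundance_i / pool(t)``.  With ``noise=False`` the exact
    expected counts are returned (floats), for closed-form checks.
    """
    params.__post_init__()
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    ids = truth.table["sequence_id"].to_numpy()
    emitted0 = float(_abundance_at(truth, 0.0).sum())
    bg0 = params.background_mass_ratio * emitted0
    cols, data = [], {}
    sample_rows = []
    for t in params.timepoints_h:
        a = _abundance_at(truth, t)
        pool = a.sum() + bg0 * math.exp(-params.total_rna_decay_k * t)
        mu = params.depth * a / pool
        for r in range(1, params.replicates + 1):
            lib = f"{condition}_t{t:g}h_r{r}"
            counts = _nb_counts(rng, mu, params.nb_dispersion) if noise else mu
            data[lib] = counts
            cols.append(lib)
            sample_rows.append({"library": lib, "timepoint_h": t,
                                "replicate": r, "condition": condition,
                                "fraction": "total"})
    counts = pd.DataFrame(data, index=pd.Index(ids, name="sequence_id"),
                          columns=cols)
    samples = pd.DataFrame(sample_rows).set_index("library")
    classes = pd.Series(truth.table["true_class"].to_numpy(), index=ids)
    spikes = frozenset(ids[classes.to_numpy() == SPIKE_IN])
    return TimecourseMatrix(counts, samples, classes, spikes)


def simulate_rip_pair(
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    enrichment: pd.Series | None = None,
    condition: str = "control",
    noise: bool = True,
) -> tuple[TimecourseMatrix, TimecourseMatrix]:
    """Matched input / RIP libraries at steady state.

    Input composition follows A0; RIP expected abundance is input
    abundance x per-sequence enrichment fold, renormalized to the library
    depth.  Spike-ins are added at library preparation, downstream of the
    immunoprecipitation, so they enter both pools at their constant
    absolute abundance — spike-in normalization therefore recovers
    enrichment folds on an absolute scale, where plain depth scaling
    cannot.  Returns ``(input, rip)`` matrices whose sample sheets carry
    the ``fraction`` column.
    """
    params.__post_init__()
    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    tab = truth.table
    is_spike = (tab["true_class"] == SPIKE_IN).to_numpy()
    ids = tab["sequence_id"].to_numpy()
    a0 = tab["a0_true"].to_numpy(float)
    if enrichment is None:
        enr = tab["rip_enrichment_true"].to_numpy(float)
    else:
        enr = enrichment.reindex(ids).to_numpy(float)
    enr = np.where(is_spike | ~np.isfinite(enr), 1.0, enr)
    if (enr[~is_spike] < 0).any():
        raise ValueError("enrichment folds must be non-negative")

    def _matrix(abund: np.ndarray, fraction: str) -> TimecourseMatrix:
        mu = params.depth * abund / abund.sum()
        data, rows = {}, []
        for r in range(1, params.replicates + 1):
            lib = f"{condition}_{fraction}_r{r}"
            data[lib] = _nb_counts(rng, mu, params.nb_dispersion) if noise else mu
            rows.append({"library": lib, "timepoint_h": 0.0, "replicate": r,
                         "condition": condition, "fraction": fraction})
        counts = pd.DataFrame(data, index=pd.Index(ids, name="sequence_id"))
        samples = pd.DataFrame(rows).set_index("library")
        classes = pd.Series(tab["true_class"].to_numpy(), index=ids)
        return TimecourseMatrix(counts, samples, classes,
                                frozenset(ids[is_spike]))

    inp = _matrix(a0, "input")
    rip = _matrix(a0 * enr, "rip")
    return inp, rip


# --------------------------------------------------------------------------
# bundle

@dataclass
class SimData:
    """Everything one generator run produces."""

    params: SimParams
    genome: dict[str, str]
    models: list[TRNAGeneModel]
    mirnas: dict[str, str]
    truth: SimTruth
    timecourse: TimecourseMatrix


def simulate_dataset(params: SimParams | None = None, noise: bool = True) -> SimData:
    """Toy genome + annotations + truth + time-course matrix in one call."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    genome, models, mirnas, fragments = make_toy_genome(params, rng)
    truth = draw_truth(fragments, params, rng)
    tm = simulate_timecourse(truth, params, rng, noise=noise)
    return SimData(params, genome, models, mirnas, truth, tm)
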