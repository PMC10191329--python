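"""Half-life estimation from transcription-shutoff small-RNA time courses.

After actinomycin D blocks Pol II/III transcription, total cellular RNA
shrinks while sequencing depth stays fixed, so the library-relative counts
of stable species *apparently increase*.  The decay-profile normalization
implemented here corrects for this compositional artifact:

1. size-normalize each library (reads-per-million or spike-in scaling);
2. divide every sequence by its own mean t=0 level (T0 normalization);
3. call *stable* the sequences whose T0-relative trajectory rises;
4. per timepoint, the *decay factor* is the mean T0-relative level of the
   stable set; dividing all sequences by it pins the stable set at 1;
5. fit first-order decay A(t) = A0 * exp(-k t) per sequence by nonlinear
   least squares and report half-life = ln(2)/k, capped at the experiment
   duration (default 12 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TimecourseMatrix", "NormalizationProfile", "DecayFit",
    "size_normalize", "t0_normalize", "identify_stable", "decay_factors",
    "apply_decay_normalization", "fit_decay", "fit_all",
    "class_summaries", "expression_filters", "half_life_from_k",
]

LN2 = float(np.log(2.0))

#: Minimum summed raw reads across all libraries for a sequence to be kept.
MIN_TOTAL_READS = 10
#: Normalized-count level at or above which a sequence is "highly expressed".
HIGH_EXPRESSION_LEVEL = 50.0
#: Default half-life cap = duration of the shutoff experiment, hours.
DEFAULT_CAP_H = 12.0


# --------------------------------------------------------------------------
# containers

@dataclass
class TimecourseMatrix:
    """Sequence x library raw-count matrix plus its sample sheet.

    ``counts`` is indexed by sequence id with one column per library;
    ``samples`` is indexed by library name with columns ``timepoint_h``,
    ``replicate``, ``condition`` and ``fraction``.  ``classes`` optionally
    carries the per-sequence class label and ``spike_ids`` flags exogenous
    spike-in rows of constant absolute abundance.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    classes: pd.Series | None = None
    spike_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.spike_ids = frozenset(self.spike_ids)
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"libraries absent from sample sheet: {missing}")
        if (self.counts.values < 0).any():
            bad = self.counts.index[(self.counts.values < 0).any(axis=1)][0]
            raise ValueError(f"negative count for sequence {bad!r}")
        if 0 not in set(self.samples.loc[self.counts.columns, "timepoint_h"]):
            raise ValueError("no t=0 libraries present")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.samples.loc[self.counts.columns, "timepoint_h"]))

    def libs_at(self, t: float) -> list[str]:
        sub = self.samples.loc[self.counts.columns]
        return list(sub.index[sub["timepoint_h"] == t])

    @property
    def col_times(self) -> np.ndarray:
        """Timepoint of each counts column, in column order."""
        return self.samples.loc[self.counts.columns, "timepoint_h"].to_numpy(float)


@dataclass
class NormalizationProfile:
    """Bookkeeping of the decay-profile normalization."""

    size_factors: pd.Series
    stable: pd.Series                  # boolean, per retained sequence
    decay_factors: pd.Series           # per timepoint, =1 at t=0
    excluded_t0: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isclose(self.decay_factors.loc[0], 1.0):
            raise ValueError("decay factor at t=0 must equal 1")
        if (self.decay_factors <= 0).any():
            raise ValueError("decay factors must be positive")


@dataclass
class DecayFit:
    """First-order decay fit A(t) = A0 * exp(-k t) for one sequence."""

    a0: float
    k: float                  # per hour, >= 0
    half_life_h: float
    capped: bool
    rss: float
    n_points: int
    method: str = "nls"       # "nls" or the "loglin" fallback

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("decay rate k must be non-negative")
        if self.a0 <= 0:
            raise ValueError("A0 must be positive")


def half_life_from_k(k: float, cap_h: float = DEFAULT_CAP_H) -> tuple[float, bool]:
    """ln(2)/k with the experiment-duration cap; returns (half-life, capped)."""
    if k <= 0:
        return cap_h, True
    hl = LN2 / k
    if hl > cap_h:
        return cap_h, True
    return hl, False


# --------------------------------------------------------------------------
# normalization chain

def size_normalize(
    tm: TimecourseMatrix,
    mode: str = "rpm",
    spike_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Library-size normalization.

    ``rpm``: counts * 1e6 / library total.  ``spike_in``: counts scaled so
    every library has the same spike-in sum (the across-library mean),
    which converts counts to a common absolute scale when spike-ins were
    added in fixed amount per sample.

    Returns ``(normalized matrix, size factors)`` where normalized value =
    raw / size_factor.
    """
    if mode == "rpm":
        totals = tm.lib_sizes
        zero = totals.index[totals <= 0]
        if len(zero):
            raise ValueError(f"library {zero[0]!r} has zero total counts")
        factors = totals / 1e6
    elif mode == "spike_in":
        ids = frozenset(spike_ids) if spike_ids is not None else tm.spike_ids
        if not ids:
            raise ValueError("spike_in mode requires spike-in ids")
        rows = [i for i in tm.counts.index if i in ids]
        spike_sums = tm.counts.loc[rows].sum(axis=0)
        zero = spike_sums.index[spike_sums <= 0]
        if len(zero):
            raise ValueError(f"library {zero[0]!r} has zero spike-in counts")
        factors = spike_sums / spike_sums.mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return tm.counts / factors, factors


def t0_normalize(norm: pd.DataFrame, tm: TimecourseMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Divide each sequence by its mean normalized count at t=0.

    Sequences with a zero t=0 mean cannot be scaled and are excluded;
    their ids are returned alongside the matrix.
    """
    t0_libs = tm.libs_at(0)
    t0_mean = norm[t0_libs].mean(axis=1)
    keep = t0_mean > 0
    excluded = list(norm.index[~keep])
    rel = norm.loc[keep].div(t0_mean[keep], axis=0)
    return rel, excluded


def _ols_slopes(rel: pd.DataFrame, times: np.ndarray) -> pd.Series:
    """Per-row OLS slope of values against time (replicates as points)."""
    tc = times - times.mean()
    denom = float((tc ** 2).sum())
    y = rel.to_numpy(float)
    slopes = (y - y.mean(axis=1, keepdims=True)) @ tc / denom
    return pd.Series(slopes, index=rel.index)


def identify_stable(
    rel: pd.DataFrame,
    tm: TimecourseMatrix,
    exclude_spikes: bool = False,
) -> pd.Series:
    """Stable sequences: apparent increase over time.

    A sequence is stable iff its OLS slope of T0-relative values against
    time is positive and it is detected (raw count > 0) in at least one
    library of every timepoint.  Raises when the stable set is empty,
    since the decay factors would be undefined.
    """
    if len(tm.timepoints) < 2:
        raise ValueError("need at least two timepoints")
    slopes = _ols_slopes(rel, tm.col_times)
    detected = pd.Series(True, index=rel.index)
    for t in tm.timepoints:
        libs = tm.libs_at(t)
        detected &= (tm.counts.loc[rel.index, libs] > 0).any(axis=1)
    stable = (slopes > 0) & detected
    if exclude_spikes:
        stable &= ~rel.index.isin(tm.spike_ids)
    if not stable.any():
        raise ValueError(
            "no stable sequences found; decay-profile normalization is "
            "undefined — check input depth or supply a stable set explicitly"
        )
    return stable


def decay_factors(rel: pd.DataFrame, stable: pd.Series, tm: TimecourseMatrix) -> pd.Series:
    """Per-timepoint decay factor: mean T0-relative level of the stable set.

    For each stable sequence its replicate libraries at t are averaged
    first; the factor is the arithmetic mean across stable sequences.
    """
    ids = stable.index[stable]
    if len(ids) == 0:
        raise ValueError("stable set is empty")
    out = {}
    for t in tm.timepoints:
        out[t] = float(rel.loc[ids, tm.libs_at(t)].mean(axis=1).mean())
    return pd.Series(out).sort_index()


def apply_decay_normalization(
    rel: pd.DataFrame, factors: pd.Series, tm: TimecourseMatrix
) -> pd.DataFrame:
    """Divide every library by its timepoint's decay factor."""
    if (factors <= 0).any():
        raise ValueError("decay factors must be positive")
    col_factor = tm.samples.loc[rel.columns, "timepoint_h"].map(factors)
    return rel / col_factor


# --------------------------------------------------------------------------
# fitting

def _exp_model(t: np.ndarray, a0: float, k: float) -> np.ndarray:
    return a0 * np.exp(-k * t)


def _loglin_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initialize (A0, k) from a log-linear regression on positive values."""
    pos = y > 0
    if pos.sum() >= 2 and len(set(t[pos])) >= 2:
        b, a = np.polyfit(t[pos], np.log(y[pos]), 1)
        return max(float(np.exp(a)), 1e-12), max(-float(b), 0.0)
    return max(float(y.mean()), 1e-12), 1.0


def fit_decay(
    t: Sequence[float],
    y: Sequence[float],
    cap_h: float = DEFAULT_CAP_H,
) -> DecayFit:
    """Nonlinear least-squares fit of A(t) = A0 exp(-k t), A0 > 0, k >= 0.

    Initialized from a log-linear regression on the positive values; zeros
    stay in the least-squares objective.  Non-convergence falls back to the
    log-linear estimate, flagged via ``method="loglin"``.  Requires >= 3
    points over >= 2 distinct timepoints.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal length")
    if len(t) < 3 or len(set(t.tolist())) < 2:
        raise ValueError("need >= 3 points spanning >= 2 distinct timepoints")
    a0_init, k_init = _loglin_init(t, y)
    method = "nls"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_model, t, y, p0=(a0_init, k_init),
                bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        a0, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        a0, k, method = a0_init, k_init, "loglin"
    rss = float(((y - _exp_model(t, a0, k)) ** 2).sum())
    # boundary check: if the flat model (k = 0, A0 = mean) fits at least as
    # well, the optimum sits on the k = 0 boundary and is reported exactly
    a0_flat = float(y.mean())
    if a0_flat > 0:
        rss_flat = float(((y - a0_flat) ** 2).sum())
        if rss_flat <= rss + 1e-12 * max(rss, 1.0):
            a0, k, rss = a0_flat, 0.0, rss_flat
    hl, capped = half_life_from_k(k, cap_h)
    return DecayFit(a0=a0, k=k, half_life_h=hl, capped=capped,
                    rss=rss, n_points=len(t), method=method)


def fit_all(
    decnorm: pd.DataFrame,
    tm: TimecourseMatrix,
    cap_h: float | None = None,
    replicate_mode: str = "points",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Fit every sequence in a decay-normalized matrix.

    ``replicate_mode="points"`` feeds every replicate library as its own
    point; ``"mean"`` first averages replicates per timepoint.  Returns a
    fits table and a dict of skipped ids -> reason.
    """
    if cap_h is None:
        cap_h = float(max(tm.timepoints))
    times = tm.samples.loc[decnorm.columns, "timepoint_h"].to_numpy(float)
    rows, skipped = [], {}
    for seq_id, row in decnorm.iterrows():
        y = row.to_numpy(float)
        t = times
        if replicate_mode == "mean":
            grouped = row.groupby(times).mean()
            t, y = grouped.index.to_numpy(float), grouped.to_numpy(float)
        elif replicate_mode != "points":
            raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
        try:
            fit = fit_decay(t, y, cap_h=cap_h)
        except ValueError as exc:
            skipped[seq_id] = str(exc)
            continue
        rows.append({
            "sequence_id": seq_id, "a0": fit.a0, "k": fit.k,
            "half_life_h": fit.half_life_h, "capped": fit.capped,
            "rss": fit.rss, "n_points": fit.n_points, "method": fit.method,
        })
    fits = pd.DataFrame(rows).set_index("sequence_id") if rows else pd.DataFrame(
        columns=["a0", "k", "half_life_h", "capped", "rss", "n_points", "method"])
    return fits, skipped


# --------------------------------------------------------------------------
# filters and summaries

def expression_filters(
    tm: TimecourseMatrix,
    norm: pd.DataFrame | None = None,
    min_total_reads: int = MIN_TOTAL_READS,
    high_level: float = HIGH_EXPRESSION_LEVEL,
) -> tuple[TimecourseMatrix, pd.Series]:
    """Drop low-count sequences and flag highly expressed ones.

    Sequences with summed raw counts < ``min_total_reads`` across all
    libraries are removed.  The returned boolean flag marks sequences whose
    normalized count reaches ``high_level`` in any library (inclusive).
    """
    keep = tm.counts.sum(axis=1) >= min_total_reads
    counts = tm.counts.loc[keep]
    classes = tm.classes.loc[counts.index] if tm.classes is not None else None
    filtered = TimecourseMatrix(counts, tm.samples, classes, tm.spike_ids)
    if norm is not None:
        high = (norm.loc[norm.index.intersection(counts.index)] >= high_level).any(axis=1)
        high = high.reindex(counts.index, fill_value=False)
    else:
        high = pd.Series(False, index=counts.index)
    return filtered, high


def log2_fold_changes(
    norm: pd.DataFrame,
    tm: TimecourseMatrix,
    t_a: float,
    t_b: float,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-sequence log2((mean at t_b + pc) / (mean at t_a + pc))."""
    a = norm[tm.libs_at(t_a)].mean(axis=1)
    b = norm[tm.libs_at(t_b)].mean(axis=1)
    return np.log2((b + pseudocount) / (a + pseudocount))


def class_summaries(
    fits: pd.DataFrame,
    norm: pd.DataFrame,
    tm: TimecourseMatrix,
    classes: pd.Series,
    fc_pairs: Sequence[tuple[float, float]] = ((0.0, 1.0),),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-class turnover summary.

    For every class with members: n, median half-life (capped values enter
    at the cap), median normalized expression at t=0, and the median
    per-sequence log2 fold change for each requested timepoint pair.
    """
    t0_expr = norm[tm.libs_at(0)].mean(axis=1)
    fcs = {
        (ta, tb): log2_fold_changes(norm, tm, ta, tb, pseudocount)
        for ta, tb in fc_pairs
    }
    rows = []
    for label in pd.unique(classes):
        ids = classes.index[classes == label]
        fit_ids = fits.index.intersection(ids)
        if len(fit_ids) == 0:
            continue
        row = {
            "class": label,
            "n": len(fit_ids),
            "median_half_life_h": float(fits.loc[fit_ids, "half_life_h"].median()),
            "median_expr_t0": float(t0_expr.reindex(fit_ids).median()),
        }
        for (ta, tb), fc in fcs.items():
            row[f"median_log2fc_{ta:g}h_{tb:g}h"] = float(fc.reindex(fit_ids).median())
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


# --------------------------------------------------------------------------
# one-call driver

@dataclass
class HalflifeResult:
    fits: pd.DataFrame
    summary: pd.DataFrame
    profile: NormalizationProfile
    decnorm: pd.DataFrame
    norm: pd.DataFrame
    skipped: dict[str, str]


def run_halflife(
    tm: TimecourseMatrix,
    mode: str = "rpm",
    cap_h: float | None = None,
    min_total_reads: int = MIN_TOTAL_READS,
    replicate_mode: str = "points",
    fc_pairs: Sequence[tuple[float, float]] = ((0.0, 1.0),),
    pseudocount: float = 0.5,
    exclude_spikes_from_stable: bool = False,
) -> HalflifeResult:
    """End-to-end half-life pipeline on one time-course matrix."""
    filtered, _high = expression_filters(tm, min_total_reads=min_total_reads)
    norm, size_factors = size_normalize(filtered, mode=mode)
    rel, excluded = t0_normalize(norm, filtered)
    stable = identify_stable(rel, filtered, exclude_spikes=exclude_spikes_from_stable)
    factors = decay_factors(rel, stable, filtered)
    decnorm = apply_decay_normalization(rel, factors, filtered)
    fit_rows = decnorm.drop(index=[i for i in decnorm.index if i in filtered.spike_ids])
    fits, skipped = fit_all(fit_rows, filtered, cap_h=cap_h,
                            replicate_mode=replicate_mode)
    profile = NormalizationProfile(size_factors, stable, factors, excluded)
    if filtered.classes is not None:
        classes = filtered.classes.reindex(fits.index).dropna()
        summary = class_summaries(fits, norm, filtered, classes,
                                  fc_pairs=fc_pairs, pseudocount=pseudocount)
    else:
        summary = pd.DataFrame()
    return HalflifeResult(fits, summary, profile, decnorm, norm, skipped)
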