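"""Argonaute RIP vs input enrichment and condition-wise shifts.

Quantifies how strongly each small RNA (and each class) associates with an
immunoprecipitated Argonaute fraction relative to the matched input, and
how that association shifts between conditions (e.g. control vs XRN2
knockdown).  Effect sizes only — significance testing is deliberately out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["RIPDesign", "fold_enrichment", "class_shift",
           "total_class_abundance", "enrichment_table"]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class RIPDesign:
    """Normalized counts plus the condition -> input/RIP library layout.

    ``counts`` holds library-size-normalized values (sequence x library);
    ``conditions`` maps each condition label to its ``input`` and ``rip``
    library name lists.  ``classes`` optionally labels sequences by class.
    """

    counts: pd.DataFrame
    conditions: Mapping[str, Mapping[str, Sequence[str]]]
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        for cond, groups in self.conditions.items():
            for frac in ("input", "rip"):
                libs = list(groups.get(frac, []))
                if not libs:
                    raise ValueError(f"condition {cond!r} has no {frac} libraries")
                missing = [l for l in libs if l not in self.counts.columns]
                if missing:
                    raise ValueError(
                        f"condition {cond!r}: libraries {missing} not in counts")

    def libs(self, condition: str, fraction: str) -> list[str]:
        return list(self.conditions[condition][fraction])


def fold_enrichment(
    design: RIPDesign,
    seq_id: str,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """RIP/input fold for one sequence in one condition.

    fold = (mean normalized RIP count + pc) / (mean normalized input count
    + pc); the pseudocount keeps the ratio finite for dropout sequences.
    """
    if seq_id not in design.counts.index:
        raise KeyError(f"sequence {seq_id!r} not in count matrix")
    row = design.counts.loc[seq_id]
    rip = float(row[design.libs(condition, "rip")].mean())
    inp = float(row[design.libs(condition, "input")].mean())
    return (rip + pseudocount) / (inp + pseudocount)


def enrichment_table(
    design: RIPDesign,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-sequence RIP/input folds for one condition (vectorized)."""
    rip = design.counts[design.libs(condition, "rip")].mean(axis=1)
    inp = design.counts[design.libs(condition, "input")].mean(axis=1)
    out = pd.DataFrame({
        "mean_input": inp, "mean_rip": rip,
        "fold_enrichment": (rip + pseudocount) / (inp + pseudocount),
    })
    if design.classes is not None:
        out.insert(0, "class", design.classes.reindex(out.index))
    return out


def class_shift(
    design: RIPDesign,
    class_label: str,
    condition_a: str,
    condition_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict:
    """Shift of a class's RIP association between two conditions.

    Per sequence of the class: log2((mean RIP_b + pc) / (mean RIP_a + pc)).
    Returns ``{"median_log2fc", "n", "table"}``; an empty class yields an
    empty summary (n = 0, NaN median).
    """
    if design.classes is None:
        raise ValueError("design has no class labels")
    ids = design.classes.index[design.classes == class_label]
    ids = design.counts.index.intersection(ids)
    a = design.counts.loc[ids, design.libs(condition_a, "rip")].mean(axis=1)
    b = design.counts.loc[ids, design.libs(condition_b, "rip")].mean(axis=1)
    log2fc = np.log2((b + pseudocount) / (a + pseudocount))
    table = pd.DataFrame({
        "mean_rip_a": a, "mean_rip_b": b, "log2fc": log2fc,
    })
    return {
        "median_log2fc": float(log2fc.median()) if len(ids) else float("nan"),
        "n": int(len(ids)),
        "table": table,
    }


def total_class_abundance(
    design: RIPDesign,
    fraction: str,
    class_label: str,
) -> pd.Series:
    """Summed mean normalized counts of a class per condition, one fraction."""
    if fraction not in ("input", "rip"):
        raise ValueError("fraction must be 'input' or 'rip'")
    if design.classes is None:
        raise ValueError("design has no class labels")
    ids = design.classes.index[design.classes == class_label]
    ids = design.counts.index.intersection(ids)
    out = {}
    for cond in design.conditions:
        libs = design.libs(cond, fraction)
        out[cond] = float(design.counts.loc[ids, libs].mean(axis=1).sum()) if len(ids) else 0.0
    return pd.Series(out, name=f"total_{class_label}_{fraction}")
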