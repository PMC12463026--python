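"""Confusion-matrix bookkeeping and detector performance metrics.

Ground truth is whether selective suppression was applied when the dataset
was generated.  A verdict of Present on a biased dataset is a true
positive; Present on an unbiased dataset a false positive, and so on.
Non-verdicts (INCONSISTENT, UNPARSEABLE) are scored as incorrect for the
true label: FN when bias is present, FP when absent.

Metrics are the standard diagnostic suite — sensitivity, specificity, PPV,
NPV, F1, and the consistency rate (accuracy).  A metric whose denominator
is zero (e.g. sensitivity on a no-bias cell, which has no positives) is
reported as missing (None), never coerced to 0 or 1.  Uncertainty is
summarized by percentile intervals across simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .llm import Verdict

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "score_decision",
    "compute_metrics",
    "replication_ci",
    "metrics_table",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, cell: str) -> None:
        setattr(self, cell.lower(), getattr(self, cell.lower()) + 1)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The six performance metrics; None marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    consistency: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def score_decision(verdict: Verdict, truth_present: bool) -> str:
    """Map one (verdict, truth) pair to its confusion-matrix cell."""
    if verdict is Verdict.PRESENT:
        return "TP" if truth_present else "FP"
    if verdict is Verdict.ABSENT:
        return "FN" if truth_present else "TN"
    # Strict agreement failed: incorrect for whichever label is true.
    return "FN" if truth_present else "FP"


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Evaluate the metric suite on a confusion table (total must be > 0)."""
    if counts.total == 0:
        raise ValueError("no scored decisions")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return MetricSet(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        consistency=_ratio(tp + tn, counts.total),
    )


def replication_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval across replicate-level values.

    Quantiles use linear interpolation; with 100 replicates and the default
    level this is the (2.5%, 97.5%) interval.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicate values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    q = np.quantile(arr, [lo, 1.0 - lo], method="linear")
    return float(q[0]), float(q[1])


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy table of metric values with CIs, one row per (detector, input, metric).

    Each input row must carry 'detector', 'input_mode', 'metric', and the
    per-replicate 'values'; the output mirrors the usual reporting layout
    (point estimate = mean across replicates, percentile CI).
    """
    out = []
    for row in rows:
        vals = [v for v in row["values"] if v is not None]
        if not vals:
            est = lo = hi = None
        else:
            est = float(np.mean(vals))
            lo, hi = replication_ci(vals) if len(vals) >= 2 else (est, est)
        out.append(
            {
                "detector": row["detector"],
                "input_mode": row["input_mode"],
                "metric": row["metric"],
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "n_replicates": len(vals),
            }
        )
    return pd.DataFrame(out)
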