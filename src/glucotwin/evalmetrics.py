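"""Clinical scoring of glucose predictions and closed-loop trajectories.

Clarke Error Grid region assignment follows the canonical published boundary
inequalities (region A: prediction within 20% of the reference, or both
readings in the hypoglycemic corner; region E: readings that would confuse
treatment of hypoglycemia for hyperglycemia and vice versa).  Time-in-range
metrics use the reporting band [80, 180] mg/dl with inclusive bounds; this is
deliberately independent of the 70 mg/dl corner inside the Clarke inequalities
— the two ranges serve different metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["clarke_region", "clarke_counts", "range_fractions",
           "compare_returns", "GlycemicReport"]

REGIONS = ("A", "B", "C", "D", "E")


def clarke_region(ref: float, pred: float) -> str:
    """Clarke Error Grid region for one (reference, predicted) glucose pair."""
    if ref <= 0 or pred <= 0:
        raise ValueError("glucose values must be positive")
    if (ref <= 70 and pred <= 70) or abs(pred - ref) <= 0.2 * ref:
        return "A"
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    if ((70 <= ref <= 290 and pred >= ref + 110)
            or (130 <= ref <= 180 and pred <= 7.0 / 5.0 * ref - 182)):
        return "C"
    if ((ref >= 240 and 70 <= pred <= 180)
            or (ref <= 175.0 / 3.0 and 70 <= pred <= 180)
            or (175.0 / 3.0 <= ref <= 70 and pred >= 6.0 / 5.0 * ref)):
        return "D"
    return "B"


def clarke_counts(ref, pred) -> dict[str, int]:
    """Region counts for paired reference/prediction series."""
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction must have equal length")
    counts = dict.fromkeys(REGIONS, 0)
    for r, p in zip(ref, pred):
        counts[clarke_region(r, p)] += 1
    return counts


def range_fractions(g, lo: float = 80.0, hi: float = 180.0
                    ) -> tuple[float, float, float]:
    """(TIR, TAR, TBR): fractions of samples in [lo, hi], above hi, below lo.

    Bounds are inclusive for in-range, so the three fractions sum to 1.
    """
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty glucose series")
    tir = float(np.mean((g >= lo) & (g <= hi)))
    tar = float(np.mean(g > hi))
    tbr = float(np.mean(g < lo))
    return tir, tar, tbr


def compare_returns(returns_a, returns_b, method: str = "ranksums",
                    ) -> tuple[float, float]:
    """Two-sided nonparametric comparison of two groups of episode returns.

    ``method="ranksums"`` (default): Wilcoxon rank-sum for independent groups;
    ``method="wilcoxon"``: signed-rank test for declared pairing (requires
    equal lengths).  Degenerate all-equal inputs return p = 1 with a warning.
    """
    a = np.asarray(returns_a, dtype=float)
    b = np.asarray(returns_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 returns per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("degenerate comparison: all returns equal")
        return 0.0, 1.0
    if method == "ranksums":
        res = stats.ranksums(a, b)
    elif method == "wilcoxon":
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        res = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GlycemicReport:
    """Clarke-grid counts plus range and return statistics for one policy."""

    clarke: dict[str, int]
    tir: float
    tar: float
    tbr: float
    mean_return: float
    return_sd: float
    n_points: int
    test: dict = field(default_factory=dict)  # optional significance result

    @classmethod
    def from_series(cls, g, returns=None, ref=None) -> "GlycemicReport":
        g = np.asarray(g, dtype=float)
        counts = clarke_counts(ref, g) if ref is not None \
            else dict.fromkeys(REGIONS, 0)
        tir, tar, tbr = range_fractions(g)
        returns = np.asarray([] if returns is None else returns, dtype=float)
        return cls(clarke=counts, tir=tir, tar=tar, tbr=tbr,
                   mean_return=float(returns.mean()) if returns.size else float("nan"),
                   return_sd=float(returns.std(ddof=1)) if returns.size > 1 else float("nan"),
                   n_points=int(g.size))

    def to_dict(self) -> dict:
        def _num(x):
            return None if not np.isfinite(x) else x
        return {"clarke": dict(self.clarke), "tir": self.tir, "tar": self.tar,
                "tbr": self.tbr, "mean_return": _num(self.mean_return),
                "return_sd": _num(self.return_sd), "n_points": self.n_points,
                "test": dict(self.test)}
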