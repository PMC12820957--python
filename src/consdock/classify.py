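"""KDE-based binder/nonbinder threshold classification and confusion
metrics.

The decision threshold for a scoring function is read off the crossing of
the two class-conditional Gaussian kernel density estimates: ligands on
the side where the positive class density dominates are called positive
(e.g. "IFDScore lower than the crossing" = predicted complex-I inhibitor).
Performance is summarized with the Matthews correlation coefficient (MCC)
and balanced accuracy (BAC), which remain informative on the small,
mildly imbalanced ligand sets typical of cross-docking studies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DensityCurve",
    "ThresholdModel",
    "ClassificationMetrics",
    "kde_density",
    "intersection_threshold",
    "classify_by_threshold",
    "classification_metrics",
]

BandwidthRule = Literal["scott", "silverman", "fixed"]
Label = Literal["positive", "negative"]


@dataclass
class DensityCurve:
    """A Gaussian KDE evaluated on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class ThresholdModel:
    """A score (or rank) cutoff with its side convention.

    ``positive_side`` says on which side of ``threshold`` the positive
    class density dominates; classification is strict on that side and a
    score exactly at the threshold is negative.  ``crossings`` lists every
    density crossing found, for audit when the two classes overlap heavily.
    """

    function_name: str
    threshold: float
    positive_side: Literal["below", "above"]
    domain: Literal["score", "rank"] = "score"
    bandwidth_pos: float | None = None
    bandwidth_neg: float | None = None
    crossings: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        return cls(**json.loads(text))


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    bac: float
    precision_pos: float
    recall_pos: float
    f1_pos: float
    precision_neg: float
    recall_neg: float
    f1_neg: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ClassificationMetrics":
        """Derive MCC, BAC and per-class precision/recall/F1 from the four
        confusion counts.  MCC is defined as 0 when any marginal is empty."""
        for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)

        def _safe(num: float, den: float) -> float:
            return num / den if den > 0 else 0.0

        rec_p = _safe(tp, tp + fn)
        rec_n = _safe(tn, tn + fp)
        bac = (rec_p + rec_n) / 2.0
        prec_p = _safe(tp, tp + fp)
        prec_n = _safe(tn, tn + fn)
        return cls(
            tp=tp, fp=fp, fn=fn, tn=tn, mcc=mcc, bac=bac,
            precision_pos=prec_p, recall_pos=rec_p,
            f1_pos=_safe(2 * prec_p * rec_p, prec_p + rec_p),
            precision_neg=prec_n, recall_neg=rec_n,
            f1_neg=_safe(2 * prec_n * rec_n, prec_n + rec_n),
        )

    def to_json(self) -> str:
        d = asdict(self)
        rounded = {k: round(v, 3) for k, v in d.items() if isinstance(v, float)}
        return json.dumps({**d, "rounded": rounded}, indent=2)


# ---------------------------------------------------------------------------


def _bandwidth(values: np.ndarray, rule: BandwidthRule, fixed_h: float | None) -> float:
    s = float(np.std(values, ddof=1))
    n = len(values)
    if rule == "scott":
        return s * n ** (-1 / 5)
    if rule == "silverman":
        return 0.9 * min(s, (np.percentile(values, 75) - np.percentile(values, 25)) / 1.349) * n ** (-1 / 5)
    if rule == "fixed":
        if fixed_h is None or fixed_h <= 0:
            raise ValueError("fixed bandwidth rule requires a positive fixed_h")
        return float(fixed_h)
    raise ValueError(f"unknown bandwidth rule {rule!r}")


def _kde(values: np.ndarray, h: float) -> gaussian_kde:
    s = float(np.std(values, ddof=1))
    # force the exact bandwidth h regardless of rule
    return gaussian_kde(values, bw_method=h / s)


def kde_density(
    values: Sequence[float],
    bandwidth_rule: BandwidthRule = "scott",
    fixed_h: float | None = None,
    grid_points: int = 512,
) -> DensityCurve:
    """Gaussian KDE of a 1-D sample on a uniform grid spanning
    [min - 3h, max + 3h].

    Scott's rule uses h = s * n**(-1/5) with s the sample standard
    deviation; three bandwidths of tail padding keep the truncated density
    mass above 0.98.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct values for a density estimate")
    h = _bandwidth(x, bandwidth_rule, fixed_h)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    density = _kde(x, h)(grid)
    return DensityCurve(grid=grid, density=density, bandwidth=h, n_samples=len(x))


def intersection_threshold(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    bandwidth_rule: BandwidthRule = "scott",
    fixed_h: float | None = None,
    grid_points: int = 512,
    function_name: str = "",
    domain: Literal["score", "rank"] = "score",
) -> ThresholdModel:
    """Locate the crossing of the two class-conditional KDEs.

    Both densities are evaluated on a common grid; each sign change of
    f_pos - f_neg is refined by linear interpolation.  The crossing lying
    between the two class medians is preferred (that is the decision
    boundary a density plot suggests); if none falls there, the crossing
    nearest the midpoint of the medians is used.  All crossings are kept on
    the model for audit.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(np.unique(pos)) < 2 or len(np.unique(neg)) < 2:
        raise ValueError("each class needs >= 2 distinct values")
    h_pos = _bandwidth(pos, bandwidth_rule, fixed_h)
    h_neg = _bandwidth(neg, bandwidth_rule, fixed_h)
    pad = 3 * max(h_pos, h_neg)
    lo = min(pos.min(), neg.min()) - pad
    hi = max(pos.max(), neg.max()) + pad
    grid = np.linspace(lo, hi, grid_points)
    f_pos = _kde(pos, h_pos)(grid)
    f_neg = _kde(neg, h_neg)(grid)
    diff = f_pos - f_neg

    crossings: list[float] = []
    sides: list[str] = []
    for i in range(len(grid) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            continue
        if a * b < 0:
            t = a / (a - b)
            crossings.append(float(grid[i] + t * (grid[i + 1] - grid[i])))
            # side where the positive density dominates, adjacent to crossing
            sides.append("below" if a > 0 else "above")
    if not crossings:
        raise ValueError(
            "no intersection: class densities do not cross on the grid"
        )

    med_pos, med_neg = float(np.median(pos)), float(np.median(neg))
    m_lo, m_hi = min(med_pos, med_neg), max(med_pos, med_neg)
    between = [k for k, c in enumerate(crossings) if m_lo <= c <= m_hi]
    if between:
        # innermost crossing if several lie between the medians
        mid = (m_lo + m_hi) / 2
        k = min(between, key=lambda j: abs(crossings[j] - mid))
    else:
        mid = (m_lo + m_hi) / 2
        k = min(range(len(crossings)), key=lambda j: abs(crossings[j] - mid))
    return ThresholdModel(
        function_name=function_name,
        threshold=crossings[k],
        positive_side=sides[k],  # type: ignore[arg-type]
        domain=domain,
        bandwidth_pos=h_pos,
        bandwidth_neg=h_neg,
        crossings=crossings,
    )


def classify_by_threshold(
    scores: Mapping[str, float], model: ThresholdModel
) -> dict[str, Label]:
    """Label each ligand by the threshold model.

    Strict inequality on the positive side; a score exactly at the
    threshold is negative.  A missing (NaN) score is labeled negative —
    a ligand that failed to dock exhibits no favorable binding evidence —
    and reported in a warning.
    """
    out: dict[str, Label] = {}
    missing: list[str] = []
    for lig, s in scores.items():
        if s is None or (isinstance(s, float) and math.isnan(s)):
            out[lig] = "negative"
            missing.append(lig)
            continue
        if model.positive_side == "below":
            out[lig] = "positive" if s < model.threshold else "negative"
        else:
            out[lig] = "positive" if s > model.threshold else "negative"
    if missing:
        warnings.warn(
            f"ligand(s) with missing scores labeled negative: {missing}",
            stacklevel=2,
        )
    return out


def classification_metrics(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> ClassificationMetrics:
    """Confusion counts and derived metrics for binary labels
    ``positive``/``negative`` over identical ligand sets."""
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must cover the same ligands")
    valid = {"positive", "negative"}
    tp = fp = fn = tn = 0
    for lig in truth:
        p, t = predicted[lig], truth[lig]
        if p not in valid or t not in valid:
            raise ValueError(f"invalid label for {lig!r}: {p!r}/{t!r}")
        if t == "positive":
            tp += p == "positive"
            fn += p == "negative"
        else:
            fp += p == "positive"
            tn += p == "negative"
    return ClassificationMetrics.from_counts(tp=tp, fp=fp, fn=fn, tn=tn)
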