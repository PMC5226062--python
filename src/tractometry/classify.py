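"""ROC analysis and the two-threshold combined outcome rule.

ROC curves are swept over the sorted unique observed values (plus a
sentinel), calling a subject positive when its value is >= the threshold
(or <= when low values indicate the positive class); AUC is the trapezoid
under the empirical curve, which equals the Mann-Whitney concordance with
ties counted one half. The combined rule calls a subject positive when the
ipsilateral fornix MD and contralateral parahippocampal MD both strictly
exceed their thresholds (defaults 1.12 and 0.93 um^2/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def _percent(x: float) -> float:
    """Ratio -> integer percent, rounding half away from zero (0.5625 -> 56)."""
    if not np.isfinite(x):
        return float("nan")
    return float(math.floor(abs(x) * 100 + 0.5) * (1 if x >= 0 else -1))


@dataclass
class ROCCurve:
    label: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_high: bool = True


def roc_curve(
    values: np.ndarray,
    labels: np.ndarray,
    positive_high: bool = True,
    label: str = "",
) -> ROCCurve:
    """Empirical ROC over the observed values; both classes must be present."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be aligned 1D arrays")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    uniq = np.unique(v)
    if positive_high:
        # sweep decreasing thresholds; sentinel above the maximum gives (0, 1)
        thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1]])
        pred = v[None, :] >= thresholds[:, None]
    else:
        thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
        pred = v[None, :] <= thresholds[:, None]
    tp = (pred & y).sum(axis=1)
    fp = (pred & ~y).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        label=label,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_high=positive_high,
    )


@dataclass
class CombinedRule:
    """Positive iff both MD features strictly exceed their thresholds (um^2/ms)."""

    threshold_ff_ipsi: float = 1.12
    threshold_pwmb_contra: float = 0.93


def apply_combined_rule(
    ff_md: float, pwmb_md: float, rule: CombinedRule | None = None
) -> bool | None:
    """Two-threshold rule; None (unclassifiable) when a feature is missing."""
    rule = rule or CombinedRule()
    if ff_md is None or pwmb_md is None or not (np.isfinite(ff_md) and np.isfinite(pwmb_md)):
        return None
    return bool(ff_md > rule.threshold_ff_ipsi and pwmb_md > rule.threshold_pwmb_contra)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_percent(self) -> dict[str, float]:
        return {
            "sensitivity": _percent(self.sensitivity),
            "specificity": _percent(self.specificity),
            "ppv": _percent(self.ppv),
            "npv": _percent(self.npv),
        }


def confusion_summary(predictions: np.ndarray, labels: np.ndarray) -> ConfusionSummary:
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("need aligned, non-empty prediction/label vectors")
    return ConfusionSummary(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def threshold_classifier(
    values: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    positive_low: bool = True,
) -> ConfusionSummary:
    """Single-cutoff classifier: positive iff value < cutoff (positive_low)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("need both classes present")
    pred = v < cutoff if positive_low else v > cutoff
    return confusion_summary(pred, y)
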