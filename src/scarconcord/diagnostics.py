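"""Diagnostic accuracy of voltage and S-QRS tests against LGE scar.

The LGE-derived scar location is the structural gold standard: a point or
vertex is truth-positive if it lies in LGE scar, test-positive if its
bipolar voltage is low (or its S-QRS delay long). Sensitivity, specificity,
PPV and NPV derive from the 2x2 confusion table; counts may be real-valued
so that expected tables can be reconstructed from a prevalence and a
(sensitivity, specificity) pair. ROC curves sweep all observed score
thresholds, group tied scores at one operating point, and integrate by the
trapezoidal rule — which makes the AUC identical to the Mann–Whitney
probability that a random positive scores more abnormally than a random
negative (ties counting one half).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DiagnosticsError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """2x2 confusion table; real-valued to allow expected counts."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise DiagnosticsError(f"{name} must be >= 0")
        if self.tp + self.fp + self.tn + self.fn <= 0:
            raise DiagnosticsError("confusion table is empty")


@dataclass
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV; ``None`` marks an undefined rate."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    orientation: str


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(getattr(labels, "labels", labels))
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise DiagnosticsError(f"labels must be binary, found {uniq}")
    return arr.astype(int)


def confusion_counts(test, truth) -> ConfusionCounts:
    """Exact confusion counts of a binary test against binary truth."""
    t = _as_binary(test)
    g = _as_binary(truth)
    if t.shape != g.shape:
        raise DiagnosticsError(f"length mismatch: {t.shape} vs {g.shape}")
    return ConfusionCounts(
        tp=float(np.sum((t == 1) & (g == 1))),
        fp=float(np.sum((t == 1) & (g == 0))),
        tn=float(np.sum((t == 0) & (g == 0))),
        fn=float(np.sum((t == 0) & (g == 1))),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def diagnostic_summary(c: ConfusionCounts) -> DiagnosticSummary:
    """Rates from a confusion table; zero-denominator rates are ``None``."""
    return DiagnosticSummary(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def reconstruct_confusion(n_pos: float, n_neg: float,
                          sens: float, spec: float) -> ConfusionCounts:
    """Expected confusion counts from class sizes and (sens, spec).

    Real-valued, no rounding: tp = sens*n_pos, tn = spec*n_neg, etc. This is
    the bridge from published sensitivity/specificity and prevalence to the
    predictive values, PPV = sens*pi / (sens*pi + (1-spec)(1-pi)).
    """
    if n_pos < 0 or n_neg < 0:
        raise DiagnosticsError("class sizes must be >= 0")
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise DiagnosticsError("sens and spec must be in [0, 1]")
    return ConfusionCounts(tp=sens * n_pos, fn=(1 - sens) * n_pos,
                           tn=spec * n_neg, fp=(1 - spec) * n_neg)


def roc_from_scores(scores, truth, orientation: str = "high-positive") -> RocCurve:
    """ROC curve and trapezoidal AUC over all unique score thresholds.

    ``orientation`` declares which direction indicates disease:
    "low-positive" for bipolar voltage (scar is low voltage),
    "high-positive" for S-QRS delay (scar conducts slowly).
    """
    scores = np.asarray(scores, dtype=float)
    g = _as_binary(truth)
    if scores.shape != g.shape:
        raise DiagnosticsError("scores and truth must have equal length")
    n_pos = int(g.sum())
    n_neg = len(g) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DiagnosticsError("ROC needs at least one positive and one negative")
    if orientation == "low-positive":
        s = -scores
    elif orientation == "high-positive":
        s = scores
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    g_sorted = g[order]
    # group tied scores at a single operating point
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp_cum = np.cumsum(g_sorted)[distinct]
    fp_cum = np.cumsum(1 - g_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    if orientation == "low-positive":
        thresholds = -thresholds
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc, orientation)
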