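"""Nodal Sørensen–Dice concordance between scar and low-voltage maps.

With A the set of voltage-abnormal vertices and B the set of LGE-scar
vertices:

    scar DSC    = 2|A ∩ B| / (|A| + |B|)
    normal DSC  = 2|Aᶜ ∩ Bᶜ| / (|Aᶜ| + |Bᶜ|)
    total DSC   = (2|A ∩ B| + 2|Aᶜ ∩ Bᶜ|) / (|A| + |B| + |Aᶜ| + |Bᶜ|)

The total is the micro-averaged two-class Dice, which is algebraically the
fraction of vertices on which the two maps agree; the macro average (mean
of the two class coefficients) is available via ``average="macro"``. A
class empty in both maps scores 1 (perfect vacuous agreement); empty in
exactly one scores 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import NodeBinaryMap, NodeScalarMap
from .eam import binarize_map


class ConcordanceError(ValueError):
    pass


@dataclass
class DiceReport:
    threshold_mV: float | None
    dsc_total: float
    dsc_scar: float
    dsc_normal: float
    # agreement cells over vertices (test = voltage map, truth = LGE map)
    n_both_scar: int
    n_both_normal: int
    n_voltage_only: int
    n_lge_only: int

    @property
    def n_vertices(self) -> int:
        return self.n_both_scar + self.n_both_normal + self.n_voltage_only + self.n_lge_only


def _class_dice(n_inter: int, n_a: int, n_b: int) -> float:
    if n_a == 0 and n_b == 0:
        return 1.0
    return 2.0 * n_inter / (n_a + n_b)


def dice_binary(voltage_bin: NodeBinaryMap, scar_bin: NodeBinaryMap,
                threshold_mV: float | None = None,
                average: str = "micro") -> DiceReport:
    """Dice coefficients between a binarized voltage map and an LGE scar map."""
    a = voltage_bin.labels.astype(bool)
    b = scar_bin.labels.astype(bool)
    if a.shape != b.shape:
        raise ConcordanceError(f"map lengths differ: {a.shape[0]} vs {b.shape[0]}")
    n11 = int(np.sum(a & b))
    n00 = int(np.sum(~a & ~b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    dsc_scar = _class_dice(n11, int(a.sum()), int(b.sum()))
    dsc_normal = _class_dice(n00, int((~a).sum()), int((~b).sum()))
    if average == "micro":
        dsc_total = (2.0 * n11 + 2.0 * n00) / (2.0 * a.shape[0])
    elif average == "macro":
        dsc_total = 0.5 * (dsc_scar + dsc_normal)
    else:
        raise ValueError(f"unknown average {average!r}")
    return DiceReport(threshold_mV, dsc_total, dsc_scar, dsc_normal,
                      n11, n00, n10, n01)


def dice_threshold_sweep(voltage: NodeScalarMap, scar_bin: NodeBinaryMap,
                         thresholds=None, average: str = "micro",
                         restrict_to: np.ndarray | None = None) -> list[DiceReport]:
    """One DiceReport per voltage threshold (default 0.5–3.5 mV, step 0.5).

    ``restrict_to`` optionally limits the comparison to a vertex subset
    (e.g. only vertices with measured electrograms).
    """
    if thresholds is None:
        thresholds = np.arange(0.5, 3.51, 0.5)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ConcordanceError("threshold list is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ConcordanceError("thresholds must be strictly ascending")
    reports = []
    for t in thresholds:
        vbin = binarize_map(voltage, t)
        if restrict_to is not None:
            vbin = NodeBinaryMap(vbin.labels[restrict_to])
            sbin = NodeBinaryMap(scar_bin.labels[restrict_to])
        else:
            sbin = scar_bin
        reports.append(dice_binary(vbin, sbin, threshold_mV=float(t), average=average))
    return reports
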