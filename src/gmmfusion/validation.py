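"""Confusion-matrix validation: overall accuracy, precision, Cohen's kappa.

Rows of the confusion matrix are the actual (ground-truth) classes,
columns the predicted ones; unlabeled (0) ground-truth sites are
excluded before counting.  Kappa corrects the observed agreement p_o
for the chance agreement p_e = aᵀb obtained from the matrix margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .raster_io import LabelRaster

#: Agreement bands for Cohen's kappa (upper bound, label); half-open on
#: the left so every real value lands in exactly one band.
KAPPA_BANDS = (
    (0.0, "Poor agreement"),          # kappa < 0
    (0.20, "Slight agreement"),
    (0.40, "Fair agreement"),
    (0.60, "Moderate agreement"),
    (0.80, "Substantial agreement"),
    (1.00, "Almost perfect agreement"),
)


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = actual, columns = predicted."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise DataError(f"confusion matrix must be square, got shape {self.C.shape}")
        if (self.C < 0).any():
            raise DataError("confusion matrix has negative counts")
        self.C = self.C.astype(np.int64)
        if self.C.sum() == 0:
            raise DataError("confusion matrix is empty (n = 0)")

    @property
    def K(self) -> int:
        return self.C.shape[0]

    @property
    def n(self) -> int:
        return int(self.C.sum())


def confusion(gt: LabelRaster, pred: LabelRaster, K: int | None = None) -> ConfusionMatrix:
    """Count C_ij = #{r : gt(r)=i, pred(r)=j}, skipping unlabeled gt sites."""
    if gt.shape != pred.shape:
        raise DataError(f"ground truth shape {gt.shape} != prediction shape {pred.shape}")
    K = K or max(gt.K, pred.K)
    g = gt.labels.ravel()
    p = pred.labels.ravel()
    mask = g > 0
    if not mask.any():
        raise DataError("no labeled ground-truth sites remain after excluding 0")
    g, p = g[mask], p[mask]
    if p.min() < 1:
        raise DataError("prediction contains unlabeled (0) sites")
    C = np.zeros((K, K), dtype=np.int64)
    np.add.at(C, (g - 1, p - 1), 1)
    return ConfusionMatrix(C)


def metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy, per-class precision, and Cohen's kappa.

    Precision of class j is C_jj over the j-th column sum (NaN where
    nothing was predicted in class j); kappa is (p_o − p_e)/(1 − p_e)
    with p_e = aᵀb from the normalized column (a) and row (b) sums,
    NaN when p_e = 1.
    """
    C = cm.C.astype(np.float64)
    n = C.sum()
    oa = float(np.trace(C) / n)
    col = C.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, np.diag(C) / np.where(col > 0, col, 1.0), np.nan)
    a = col / n
    b = C.sum(axis=1) / n
    pe = float(a @ b)
    kappa = float((oa - pe) / (1.0 - pe)) if pe < 1.0 else float("nan")
    return {
        "overall_accuracy": oa,
        "precision": precision,
        "p_o": oa,
        "p_e": pe,
        "kappa": kappa,
    }


def kappa_interpretation(kappa: float) -> str:
    """Map a kappa value to its conventional agreement band."""
    if kappa > 1.0:
        raise DataError(f"kappa cannot exceed 1, got {kappa}")
    if np.isnan(kappa):
        return "Undefined (chance agreement is 1)"
    if kappa < 0:
        return KAPPA_BANDS[0][1]
    for hi, label in KAPPA_BANDS[1:]:
        if kappa <= hi:
            return label
    return KAPPA_BANDS[-1][1]


def evaluate(gt: LabelRaster, pred: LabelRaster, K: int | None = None) -> dict:
    """Confusion matrix plus all derived measures in one call."""
    cm = confusion(gt, pred, K)
    m = metrics(cm)
    m["confusion"] = cm.C
    m["n"] = cm.n
    m["interpretation"] = kappa_interpretation(m["kappa"])
    return m
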