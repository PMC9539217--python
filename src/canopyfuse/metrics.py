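"""Confusion-matrix accuracy assessment and segmentation-rate arithmetic.

The confusion matrix follows the predicted-rows x reference-columns
orientation, so user's accuracy (precision) reads along rows and
producer's accuracy (recall) down columns; commission = 100 - UA and
omission = 100 - PA.  Overall accuracy is the trace over the grand
total, and the Kappa coefficient is the chance-corrected agreement
(p_o - p_e) / (1 - p_e) with expected agreement p_e from the row and
column marginals.  Displayed values round half-up to two decimals; full
precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed accuracy
    tables), as opposed to banker's rounding."""
    value = float(value)
    if not np.isfinite(value):
        return value
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Per-class and overall accuracy measures, in percent (Kappa unitless).

    ``*_pct`` dicts are keyed by class label and rounded for display;
    ``oa_raw`` / ``kappa_raw`` keep full precision.
    """

    labels: list
    producer_accuracy: dict
    user_accuracy: dict
    commission: dict
    omission: dict
    oa: float
    kappa: float
    oa_raw: float = None
    kappa_raw: float = None
    producer_accuracy_raw: dict = field(default_factory=dict)
    user_accuracy_raw: dict = field(default_factory=dict)
    missing_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "producer_accuracy": self.producer_accuracy,
            "user_accuracy": self.user_accuracy,
            "commission": self.commission,
            "omission": self.omission,
            "OA": self.oa,
            "Kappa": self.kappa,
        }


def confusion_from_predictions(y_true, y_pred, labels=None) -> pd.DataFrame:
    """Predicted-rows x reference-columns count matrix."""
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    m = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        m.loc[p, t] += 1
    m.index.name = "predicted"
    m.columns.name = "reference"
    return m


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    m = pd.DataFrame(matrix).copy()
    if m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not (m.to_numpy() >= 0).all():
        raise ValueError("confusion matrix counts must be nonnegative")
    if list(m.index) != list(m.columns):
        m.columns = m.index
    return m


def evaluate(matrix: pd.DataFrame) -> EvaluationReport:
    """Full accuracy report from a predicted x reference count matrix.

    A class with an empty row (column) has undefined UA (PA); such
    classes are listed in ``missing_classes`` with NaN entries.
    """
    m = _validate_matrix(matrix)
    counts = m.to_numpy(float)
    labels = list(m.index)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)

    p_o = diag.sum() / total
    p_e = float((row_tot * col_tot).sum()) / total**2
    kappa_raw = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    oa_raw = 100.0 * p_o

    ua, pa, com, om = {}, {}, {}, {}
    ua_raw, pa_raw = {}, {}
    missing = []
    for i, lab in enumerate(labels):
        if row_tot[i] > 0:
            u = 100.0 * diag[i] / row_tot[i]
            ua_raw[lab] = u
            ua[lab] = round_half_up(u)
            com[lab] = round_half_up(100.0 - u)
        else:
            ua[lab] = com[lab] = ua_raw[lab] = float("nan")
            missing.append(lab)
        if col_tot[i] > 0:
            p = 100.0 * diag[i] / col_tot[i]
            pa_raw[lab] = p
            pa[lab] = round_half_up(p)
            om[lab] = round_half_up(100.0 - p)
        else:
            pa[lab] = om[lab] = pa_raw[lab] = float("nan")
            if lab not in missing:
                missing.append(lab)

    return EvaluationReport(
        labels=labels,
        producer_accuracy=pa,
        user_accuracy=ua,
        commission=com,
        omission=om,
        oa=round_half_up(oa_raw),
        kappa=round_half_up(kappa_raw),
        oa_raw=oa_raw,
        kappa_raw=kappa_raw,
        producer_accuracy_raw=pa_raw,
        user_accuracy_raw=ua_raw,
        missing_classes=missing,
    )


def segmentation_rates(n_reference: int, n_detected: int, n_correct: int):
    """Detection rate and total segmentation accuracy, in percent.

    detection_rate = 100 * detected / reference (may exceed 100 when the
    segmenter over-detects; the returned dict flags that case);
    total_accuracy = 100 * correct / reference.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not (0 <= n_correct <= n_detected):
        raise ValueError("need 0 <= n_correct <= n_detected")
    det = 100.0 * n_detected / n_reference
    tot = 100.0 * n_correct / n_reference
    return {
        "detection_rate": round_half_up(det),
        "total_accuracy": round_half_up(tot),
        "over_detection": n_detected > n_reference,
    }


def read_confusion_csv(path) -> pd.DataFrame:
    """Read a confusion matrix CSV with class labels in the header row
    and first column (predicted rows x reference columns)."""
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return _validate_matrix(m)


def write_confusion_csv(matrix: pd.DataFrame, path) -> None:
    _validate_matrix(matrix).to_csv(path)


def render_report(matrix: pd.DataFrame, report: EvaluationReport = None) -> str:
    """Text rendering in the style of printed accuracy tables."""
    m = _validate_matrix(matrix)
    if report is None:
        report = evaluate(m)
    labels = report.labels
    widths = max(6, max(len(str(l)) for l in labels) + 2)

    def fmt(x):
        return f"{x:>{widths}}"

    lines = [
        "".join([fmt("Class")] + [fmt(l) for l in labels]
                + [fmt("UA(%)"), fmt("Com(%)")])
    ]
    for i, lab in enumerate(labels):
        row = [fmt(lab)] + [fmt(int(m.iloc[i, j])) for j in range(len(labels))]
        row += [fmt(f"{report.user_accuracy[lab]:.2f}"),
                fmt(f"{report.commission[lab]:.2f}")]
        lines.append("".join(row))
    lines.append(
        "".join([fmt("PA(%)")]
                + [fmt(f"{report.producer_accuracy[l]:.2f}") for l in labels]
                + [fmt("OA(%)"), fmt(f"{report.oa:.2f}")])
    )
    lines.append(
        "".join([fmt("Om(%)")]
                + [fmt(f"{report.omission[l]:.2f}") for l in labels]
                + [fmt("Kappa"), fmt(f"{report.kappa:.2f}")])
    )
    return "\n".join(lines)
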