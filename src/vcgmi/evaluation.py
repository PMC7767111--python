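"""Multiclass confusion matrices and one-vs-rest ACC/SEN/SPE metrics.

Per class: TP is the diagonal entry, FN the remainder of the row, FP the
remainder of the column and TN everything else; accuracy, sensitivity and
specificity follow the usual one-vs-rest definitions. Overall metrics are
the micro accuracy (trace over total) and unweighted macro averages of the
per-class sensitivities and specificities. Display values are rounded
half-up to two decimals; full precision is kept internally.

Reference confusion matrices from a published single-lead derived-VCG MI
study are bundled as TSV fixtures (see :func:`load_reference_confusion`)
and serve as golden values for the metric definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np

from .synthetic_ecg import CLASS_LABELS

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "per_class_metrics",
    "overall_metrics",
    "round_half_up",
    "read_confusion_tsv",
    "write_confusion_tsv",
    "load_reference_confusion",
    "REFERENCE_TABLES",
]

#: Bundled golden fixtures: classifier confusion matrices for four lead
#: configurations (measured lead I; derived Y; derived Z; derived XYZ).
REFERENCE_TABLES = (
    "confusion_lead_i",
    "confusion_vy_hat",
    "confusion_vz_hat",
    "confusion_xyz_hat",
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (table display convention), e.g. 0.125 -> 0.13."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table; rows are true (notated) classes, columns predicted."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def one_vs_rest(self, label: str) -> dict[str, int]:
        """TP/FN/FP/TN marginals for one class."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.total - tp - fn - fp
        return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add confusion matrices with different label sets")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


def confusion_matrix(
    y_true, y_pred, labels: tuple[str, ...] = CLASS_LABELS
) -> ConfusionMatrix:
    """Count table from paired true/predicted labels (strings or indices)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    k = len(labels)
    lookup = {lab: idx for idx, lab in enumerate(labels)}

    def to_idx(arr):
        if arr.dtype.kind in "iu":
            if np.any((arr < 0) | (arr >= k)):
                raise KeyError("class index out of range")
            return arr.astype(int)
        try:
            return np.array([lookup[v] for v in arr])
        except KeyError as exc:
            raise KeyError(f"unknown label {exc.args[0]!r}") from None

    ti, pi = to_idx(y_true), to_idx(y_pred)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts, labels)


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float | None]]:
    """One-vs-rest ACC/SEN/SPE per class, in percent at full precision.

    SEN is ``None`` for a class with no true instances.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, dict[str, float | None]] = {}
    for label in cm.labels:
        m = cm.one_vs_rest(label)
        tp, fn, fp, tn = m["TP"], m["FN"], m["FP"], m["TN"]
        acc = 100.0 * (tp + tn) / (tp + fp + tn + fn)
        sen = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
        spe = 100.0 * tn / (fp + tn) if (fp + tn) > 0 else None
        out[label] = {"ACC": acc, "SEN": sen, "SPE": spe, **m}
    return out


def overall_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Micro accuracy plus unweighted macro sensitivity/specificity (percent)."""
    per_class = per_class_metrics(cm)
    sens = [v["SEN"] for v in per_class.values() if v["SEN"] is not None]
    spes = [v["SPE"] for v in per_class.values() if v["SPE"] is not None]
    return {
        "micro_accuracy": 100.0 * float(np.trace(cm.counts)) / cm.total,
        "macro_sensitivity": float(np.mean(sens)),
        "macro_specificity": float(np.mean(spes)),
    }


# ---------------------------------------------------------------------------
# delimited-text confusion tables
# ---------------------------------------------------------------------------


def write_confusion_tsv(cm: ConfusionMatrix, path: str) -> None:
    with open(path, "w") as f:
        f.write("\t".join(("",) + cm.labels) + "\n")
        for label, row in zip(cm.labels, cm.counts):
            f.write("\t".join([label] + [str(int(v)) for v in row]) + "\n")


def read_confusion_tsv(path_or_text: str) -> ConfusionMatrix:
    """Read a confusion table: header of predicted labels, one row per true label."""
    if "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as f:
            lines = f.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    header = lines[0].split("\t")
    labels = tuple(h for h in header if h)
    counts = []
    row_labels = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row_labels.append(cells[0])
        counts.append([int(v) for v in cells[1:]])
    if tuple(row_labels) != labels:
        raise ValueError("confusion table row labels do not match column labels")
    return ConfusionMatrix(np.array(counts), labels)


def load_reference_confusion(name: str) -> ConfusionMatrix:
    """Load one of the bundled reference matrices (see ``REFERENCE_TABLES``)."""
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; available: {REFERENCE_TABLES}")
    text = resources.files("vcgmi").joinpath(f"data/{name}.tsv").read_text()
    return read_confusion_tsv(text)
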