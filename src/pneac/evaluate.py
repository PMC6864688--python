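"""Scoring partitions against beat annotations.

Each cluster is typed by the majority annotation symbol of its members;
members with any other symbol count as errors.  Confusion matrices are
built from (assigned cluster type, true symbol) pairs, with per-class
sensitivity (Se, column-normalized) and positive predictivity (P+,
row-normalized); classes never assigned by the clustering get an
undefined P+, rendered as "-".  Symbols can be collapsed to the five
AAMI EC57 super-classes (N, S, V, F, Q) first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AAMI_CLASSES",
    "DEFAULT_AAMI_MAP",
    "aami_map",
    "majority_label_error",
    "cluster_types",
    "ConfusionReport",
    "confusion_report",
]

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

# EC57 grouping of the MIT-BIH beat symbols.  The placement of '!'
# (ventricular flutter wave) varies across studies; default here is Q,
# override by passing your own mapping.
DEFAULT_AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "P": "Q", "f": "Q", "Q": "Q", "!": "Q",
}


def aami_map(symbol: str, mapping: dict | None = None, default: str | None = None) -> str:
    """Collapse one annotation symbol to its AAMI super-class."""
    mapping = DEFAULT_AAMI_MAP if mapping is None else mapping
    if symbol in mapping:
        return mapping[symbol]
    if default is not None:
        return default
    raise KeyError(f"no AAMI group configured for annotation symbol {symbol!r}")


def cluster_types(labels: np.ndarray, truth) -> dict[int, str]:
    """Majority annotation symbol per cluster; ties go to the
    lexicographically first symbol (deterministic)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth, dtype=object)
    if labels.shape != truth.shape:
        raise ValueError("labels and annotations must have the same length")
    if labels.size == 0:
        raise ValueError("empty partition")
    types = {}
    for c in np.unique(labels):
        counts = Counter(truth[labels == c])
        best = max(sorted(counts), key=counts.__getitem__)
        types[int(c)] = best
    return types


def majority_label_error(labels: np.ndarray, truth) -> tuple[int, float]:
    """Errors under majority typing: members whose symbol differs from
    their cluster's majority symbol.  Returns (count, percentage)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth, dtype=object)
    types = cluster_types(labels, truth)
    assigned = np.array([types[int(c)] for c in labels], dtype=object)
    errors = int(np.sum(assigned != truth))
    return errors, 100.0 * errors / len(labels)


@dataclass
class ConfusionReport:
    """Assigned-type × true-type counts with Se and P+ percentages."""

    matrix: pd.DataFrame          # rows: assigned type, columns: true type
    sensitivity: pd.Series        # per true type, %
    positive_predictivity: pd.Series  # per assigned type, %; NaN = undefined

    def to_frame(self) -> pd.DataFrame:
        """Printable table mirroring the usual layout, "-" for undefined."""
        out = self.matrix.astype(object).copy()
        out.loc["Se (%)"] = [
            "-" if np.isnan(v) else f"{v:.1f}" for v in self.sensitivity
        ]
        ppv = self.positive_predictivity.reindex(self.matrix.index)
        out["P+ (%)"] = ["-" if np.isnan(v) else f"{v:.1f}" for v in ppv] + [""]
        return out


def confusion_report(labels: np.ndarray, truth, class_map: dict | None = None,
                     default_class: str | None = None) -> ConfusionReport:
    """Confusion matrix of cluster-assigned types against annotations.

    ``class_map`` optionally collapses symbols (e.g. to AAMI groups)
    before typing; unknown symbols stay as their own class unless a
    ``default_class`` is given.
    """
    truth = np.asarray(truth, dtype=object)
    if class_map is not None:
        truth = np.array(
            [class_map.get(s, default_class if default_class is not None else s)
             for s in truth], dtype=object)
    labels = np.asarray(labels)
    types = cluster_types(labels, truth)
    assigned = np.array([types[int(c)] for c in labels], dtype=object)

    all_classes = sorted(set(truth))
    matrix = pd.DataFrame(0, index=all_classes, columns=all_classes, dtype=int)
    for a, t in zip(assigned, truth):
        matrix.loc[a, t] += 1

    diag = pd.Series(np.diag(matrix), index=all_classes, dtype=float)
    col = matrix.sum(axis=0).astype(float)
    row = matrix.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = 100.0 * diag / col.replace(0, np.nan)
        ppv = 100.0 * diag / row.replace(0, np.nan)
    return ConfusionReport(matrix=matrix, sensitivity=se, positive_predictivity=ppv)
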