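"""Confusion-chart scoring of predicted against observed activity labels.

Two normalization conventions are supported, matching how lab and
free-living results are conventionally charted:

* ``row`` — each observed-activity row sums to 1, showing how the windows of
  one activity were classified (lab charts);
* ``total`` — all cells sum to 1, so the chart shows the joint distribution
  of observed and predicted activity (free-living charts, where class
  prevalence is wildly uneven).

Margins use the field's chart conventions: *sensitivity* is row-wise recall
(the proportion of observed windows of a class classified correctly), and
the *specificity margin* is column-wise precision (the proportion of windows
classified as a class whose observation agrees). The latter is deliberately
not the epidemiological true-negative-rate specificity; the name is kept
because it is what activity-recognition confusion charts print. Margins of
empty rows or columns are undefined and rendered blank, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import labels as L

NORMALIZATIONS = ("none", "row", "total")


@dataclass
class ConfusionResult:
    classes: tuple[str, ...]
    counts: np.ndarray  # (K, K) ints, observed rows x predicted columns
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be square over classes")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else float("nan")

    @property
    def matrix(self) -> np.ndarray:
        """Counts under the chosen normalization (rows sum to 1 / cells sum to 1)."""
        c = self.counts.astype(float)
        if self.normalization == "row":
            rowsum = c.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = c / rowsum
            out[rowsum[:, 0] == 0] = 0.0
            return out
        if self.normalization == "total":
            return c / self.total if self.total else c
        return c

    @property
    def sensitivity(self) -> np.ndarray:
        """Row-wise recall per class; NaN marks classes never observed."""
        rowsum = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.diag(self.counts) / rowsum
        return out

    @property
    def specificity_margin(self) -> np.ndarray:
        """Column-wise precision per class; NaN marks classes never predicted."""
        colsum = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.diag(self.counts) / colsum
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path: str | Path) -> None:
        """Counts, both normalizations and margins in one readable CSV."""
        blocks = []
        for norm in NORMALIZATIONS:
            cr = ConfusionResult(self.classes, self.counts, norm)
            df = cr.to_frame()
            df.insert(0, "block", f"matrix_{norm}")
            blocks.append(df.reset_index(names="observed"))
        margins = pd.DataFrame(
            {
                "block": "margins",
                "observed": list(self.classes),
                "sensitivity": self.sensitivity,
                "specificity_margin": self.specificity_margin,
            }
        )
        out = pd.concat(blocks + [margins], ignore_index=True)
        out.to_csv(path, index=False, na_rep="")  # undefined margins stay blank

    def to_dict(self) -> dict:
        def _clean(v: np.ndarray) -> list:
            return [None if not np.isfinite(x) else float(x) for x in v]

        return {
            "classes": list(self.classes),
            "counts": self.counts.astype(int).tolist(),
            "normalization": self.normalization,
            "accuracy": self.accuracy,
            "sensitivity": _clean(self.sensitivity),
            "specificity_margin": _clean(self.specificity_margin),
        }


def confusion(
    observed,
    predicted,
    classes: tuple[str, ...] | list[str],
    normalization: str = "none",
) -> ConfusionResult:
    """Confusion matrix of (observed row, predicted column) counts."""
    observed = np.asarray(observed, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted"
        )
    L.validate_labels(observed, classes)
    L.validate_labels(predicted, classes)
    counts = confusion_matrix(
        observed.astype(str), predicted.astype(str), labels=list(classes)
    )
    return ConfusionResult(tuple(classes), counts, normalization)


def merge_labels(seq, mapping: dict[str, str] | None = None) -> list[str]:
    """Map a 7-class label sequence to the merged 5-class vocabulary."""
    return L.map_labels(seq, L.SEVEN_TO_FIVE if mapping is None else mapping)


def merge_confusion(
    cr: ConfusionResult, mapping: dict[str, str] | None = None
) -> ConfusionResult:
    """Merge a confusion matrix by summing constituent rows and columns.

    Equivalent to rebuilding the confusion from mapped label sequences; the
    merged class order follows the 5-class convention.
    """
    mapping = L.SEVEN_TO_FIVE if mapping is None else mapping
    merged_classes = list(dict.fromkeys(mapping[c] for c in cr.classes))
    # keep conventional order where applicable
    if set(merged_classes) <= set(L.FIVE_CLASSES):
        merged_classes = [c for c in L.FIVE_CLASSES if c in merged_classes]
    K = len(merged_classes)
    pos = {c: i for i, c in enumerate(merged_classes)}
    out = np.zeros((K, K), dtype=cr.counts.dtype)
    for i, ci in enumerate(cr.classes):
        for j, cj in enumerate(cr.classes):
            out[pos[mapping[ci]], pos[mapping[cj]]] += cr.counts[i, j]
    return ConfusionResult(tuple(merged_classes), out, cr.normalization)


def subgroup_eval(
    observed,
    predicted,
    groups,
    group: str,
    classes: tuple[str, ...] | list[str],
    normalization: str = "none",
) -> ConfusionResult:
    """Confusion restricted to windows carrying the given group tag."""
    groups = np.asarray(groups, dtype=object)
    observed = np.asarray(observed, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if not (len(groups) == len(observed) == len(predicted)):
        raise ValueError("observed, predicted and groups must have equal length")
    mask = groups == group
    if not mask.any():
        raise ValueError(
            f"unknown or empty group {group!r}; present: {sorted(set(groups))}"
        )
    return confusion(observed[mask], predicted[mask], classes, normalization)


def plot_confusion(cr: ConfusionResult, path: str | Path, title: str = "") -> None:
    """Render the normalized confusion matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = cr.matrix
    fig, ax = plt.subplots(figsize=(1.2 * len(cr.classes) + 2, 1.0 * len(cr.classes) + 2))
    im = ax.imshow(mat, cmap="Blues", vmin=0)
    ax.set_xticks(range(len(cr.classes)), cr.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(cr.classes)), cr.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    if title:
        ax.set_title(title)
    for i in range(len(cr.classes)):
        for j in range(len(cr.classes)):
            ax.text(
                j,
                i,
                f"{mat[i, j]:.2f}" if cr.normalization != "none" else f"{int(mat[i, j])}",
                ha="center",
                va="center",
                fontsize=8,
            )
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
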