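"""Robust cleaning of the labelled calibration feature table.

Within each activity separately, a window (row) is discarded when any of its
feature values deviates from that feature's median by more than a threshold
(default 3) times the scaled median absolute deviation. The scaled MAD uses
the normal-consistency constant 1.4826, so it estimates the standard
deviation under normality. Cleaning is a single pass; it is deliberately not
iterated.

A feature column whose scaled MAD is zero (common for stationary activities,
where many features are constant) flags exactly the values that differ from
the column median: any deviation from an otherwise constant column is an
outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import FeatureSet

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD estimate the SD of a normal sample.
MAD_SCALE = 1.4826

DEFAULT_THRESHOLD = 3.0


@dataclass
class OutlierReport:
    activity: str
    n_before: int
    n_removed: int
    removed_window_ids: list[int]

    def __post_init__(self) -> None:
        if self.n_removed > self.n_before or min(self.n_before, self.n_removed) < 0:
            raise ValueError("inconsistent outlier counts")


def scaled_mad(values: np.ndarray) -> tuple[float, float]:
    """Median and scaled MAD (``1.4826 * median(|x - median|)``) of a vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("scaled_mad of an empty vector")
    m = float(np.median(values))
    return m, MAD_SCALE * float(np.median(np.abs(values - m)))


def outlier_mask(X: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean mask of rows flagged by the any-column scaled-MAD rule."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=0)
    smad = MAD_SCALE * np.median(np.abs(X - med), axis=0)
    dev = np.abs(X - med)
    flagged = np.where(smad > 0, dev > threshold * smad, dev > 0)
    return flagged.any(axis=1)


def remove_outliers(
    fs: FeatureSet, threshold: float = DEFAULT_THRESHOLD
) -> tuple[FeatureSet, list[OutlierReport]]:
    """Remove outlier windows per activity; returns the filtered set and reports.

    The criterion is applied within each activity group independently, so a
    value typical of one activity is never judged against another's
    distribution.
    """
    frame = fs.frame
    labels = frame["label"].to_numpy(dtype=object)
    keep = np.ones(len(frame), dtype=bool)
    reports: list[OutlierReport] = []
    for activity in dict.fromkeys(labels):  # preserves first-seen order
        idx = np.flatnonzero(labels == activity)
        if idx.size == 0:
            reports.append(OutlierReport(activity, 0, 0, []))
            continue
        X = frame.iloc[idx][list(fs.feature_names)].to_numpy(dtype=float)
        bad = outlier_mask(X, threshold)
        keep[idx[bad]] = False
        reports.append(
            OutlierReport(activity, int(idx.size), int(bad.sum()), idx[bad].tolist())
        )
        logger.info(
            "outlier removal: %s: removed %d of %d windows",
            activity,
            int(bad.sum()),
            int(idx.size),
        )
    return fs.subset(keep), reports


def reports_to_csv(reports: list[OutlierReport], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "activity": [r.activity for r in reports],
            "n_before": [r.n_before for r in reports],
            "n_removed": [r.n_removed for r in reports],
        }
    ).to_csv(path, index=False)
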