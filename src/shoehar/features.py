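"""Sliding-window segmentation and the 26-dimensional signal-feature vector.

Recordings are cut into 2 s windows with 50 % overlap; each window yields a
feature vector combining time-domain moments, inter-axis correlations,
vector-magnitude statistics, posture (tilt) and frequency-domain summaries.
The default feature set is:

========================  =====================================================
``mean_x/y/z``            per-axis mean acceleration (g)
``std_x/y/z``             per-axis sample standard deviation (g)
``corr_xy/xz/yz``         pairwise Pearson correlation (0 if an axis is
                          constant within the window)
``mag_mean``              mean of the vector magnitude (g)
``mag_std``               SD of the vector magnitude (g)
``mag_range``             max - min of the magnitude (g)
``mag_iqr``               interquartile range of the magnitude (g)
``mag_skewness``          magnitude skewness (population moments; 0 if constant)
``mag_kurtosis``          magnitude excess kurtosis (0 if constant)
``sma``                   signal magnitude area, mean(|ax|+|ay|+|az|) (g)
``tilt_mean_deg``         mean angle between the acceleration vector and the
                          sensor z-axis (degrees); 0 for a zero vector
``mag_mcr``               magnitude mean-crossing rate, crossings/(L-1)
``domfreq_x/y/z``         per-axis dominant frequency (Hz) from an L-point
                          periodogram excluding the DC bin; 0 for a flat
                          spectrum
``dompow_x/y/z``          periodogram power at the dominant frequency
``mag_domfreq``           dominant frequency of the magnitude (Hz)
``mag_spec_entropy``      normalized spectral entropy of the magnitude
                          periodogram (DC excluded), in [0, 1]; 0 for a flat
                          spectrum
========================  =====================================================

The periodogram is ``|rfft(x)|^2 / L`` with a rectangular window and no
detrending beyond exclusion of the DC bin. Spectra whose non-DC peak is
below a relative floor (1e-12 of total power) are treated as flat so that
constant windows produce exactly zero frequency features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import labels as L
from .signal_io import AccelRecording, AnnotationLog, Interval, sample_interval_index

FEATURE_NAMES: tuple[str, ...] = (
    "mean_x",
    "mean_y",
    "mean_z",
    "std_x",
    "std_y",
    "std_z",
    "corr_xy",
    "corr_xz",
    "corr_yz",
    "mag_mean",
    "mag_std",
    "mag_range",
    "mag_iqr",
    "mag_skewness",
    "mag_kurtosis",
    "sma",
    "tilt_mean_deg",
    "mag_mcr",
    "domfreq_x",
    "domfreq_y",
    "domfreq_z",
    "dompow_x",
    "dompow_y",
    "dompow_z",
    "mag_domfreq",
    "mag_spec_entropy",
)

#: Relative floor below which a non-DC periodogram peak counts as flat.
_SPECTRAL_FLOOR = 1e-12

WINDOW_S_DEFAULT = 2.0
OVERLAP_DEFAULT = 0.5

# Calibration rule: keep the 6th..55th second of the final minute of each
# activity interval, i.e. [end-54, end-5), a 49 s segment.
CALIBRATION_OFFSET_START = 54.0
CALIBRATION_OFFSET_END = 5.0


@dataclass
class FeatureWindow:
    subject_id: str
    t_start: float
    t_end: float
    features: np.ndarray
    label: str
    label_purity: float = 1.0


@dataclass
class FeatureSet:
    """Windows-by-features table with labels, the pipeline's working container.

    ``frame`` holds one row per window with columns ``subject_id, t_start,
    t_end, label, label_purity`` followed by the feature columns.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    provenance: str = "lab_calibration"  # or "free_living"

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature columns missing from frame: {missing}")
        dup = self.frame.duplicated(subset=["subject_id", "t_start"])
        if dup.any():
            raise ValueError("duplicate (subject_id, t_start) windows")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=object)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy(dtype=object)

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            self.frame.loc[mask].reset_index(drop=True),
            self.feature_names,
            self.provenance,
        )

    def to_csv(self, path: str | Path) -> None:
        cols = ["subject_id", "t_start", "t_end", "label", "label_purity"] + list(
            self.feature_names
        )
        with open(path, "w") as fh:
            fh.write(f"# shoehar feature set v1; provenance={self.provenance}\n")
            self.frame[cols].to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "lab_calibration") -> "FeatureSet":
        df = pd.read_csv(path, comment="#")
        names = tuple(
            c
            for c in df.columns
            if c not in ("subject_id", "t_start", "t_end", "label", "label_purity")
        )
        return cls(df, names, provenance)


def segment_windows(
    samples: np.ndarray,
    fs: float,
    window_s: float = WINDOW_S_DEFAULT,
    overlap: float = OVERLAP_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a (n, 3) signal into overlapping windows.

    Returns ``(windows, starts)`` where ``windows`` has shape (W, L, 3) with
    ``L = window_s * fs`` and stride ``S = L * (1 - overlap)`` samples, and
    ``starts`` holds the first-sample index of each window. The trailing
    partial window is discarded; a recording shorter than one window yields
    zero windows. The count satisfies ``floor((n - L) / S) + 1``.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    length = int(round(window_s * fs))
    stride = int(round(length * (1.0 - overlap)))
    if length < 2 or stride < 1:
        raise ValueError("window too short for the sampling rate")
    if n < length:
        return np.empty((0, length, 3)), np.empty(0, dtype=int)
    count = (n - length) // stride + 1
    starts = np.arange(count) * stride
    windows = np.lib.stride_tricks.sliding_window_view(samples, length, axis=0)
    windows = windows[starts].transpose(0, 2, 1)
    return windows, starts


def extract_calibration_segment(log: AnnotationLog) -> AnnotationLog:
    """Restrict each protocol interval to the 49 s calibration segment.

    For an activity interval [a, b) the retained segment is [b-54, b-5): the
    6th through 55th second of the interval's final minute. Intervals shorter
    than 60 s are a protocol violation and raise, naming the activity.
    """
    segments = []
    for iv in log.intervals:
        if iv.end - iv.start < 60.0:
            raise ValueError(
                f"activity {iv.label!r}: interval of {iv.end - iv.start:.1f} s is "
                "shorter than the 60 s the calibration rule requires"
            )
        segments.append(
            Interval(
                iv.end - CALIBRATION_OFFSET_START,
                iv.end - CALIBRATION_OFFSET_END,
                iv.label,
                source=iv.source,
            )
        )
    return AnnotationLog(subject_id=log.subject_id, intervals=segments, group=log.group)


def _periodogram(windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum |rfft|^2/L per window; returns (power, freqs)."""
    length = windows.shape[-1]
    spec = np.fft.rfft(windows, axis=-1)
    power = (spec.real**2 + spec.imag**2) / length
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    return power, freqs


def _dominant(power: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dominant non-DC frequency and its power; flat spectra give (0, 0)."""
    ac = power[..., 1:]
    peak_idx = np.argmax(ac, axis=-1)
    peak_pow = np.take_along_axis(ac, peak_idx[..., None], axis=-1)[..., 0]
    total = power.sum(axis=-1)
    flat = peak_pow <= _SPECTRAL_FLOOR * np.maximum(total, 1e-300)
    domfreq = freqs[1:][peak_idx]
    domfreq = np.where(flat, 0.0, domfreq)
    peak_pow = np.where(flat, 0.0, peak_pow)
    return domfreq, peak_pow


def compute_feature_matrix(windows: np.ndarray, fs: float) -> np.ndarray:
    """Compute the 26 features for a batch of windows of shape (W, L, 3)."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[2] != 3:
        raise ValueError("windows must have shape (W, L, 3)")
    if windows.shape[1] < 2:
        raise ValueError("windows must contain at least 2 samples")
    if not np.all(np.isfinite(windows)):
        raise ValueError("non-finite sample in window")
    W, length, _ = windows.shape

    mean = windows.mean(axis=1)  # (W, 3)
    centered = windows - mean[:, None, :]
    # sample SD (ddof=1)
    ss = (centered**2).sum(axis=1)
    std = np.sqrt(ss / (length - 1))

    def corr(i: int, j: int) -> np.ndarray:
        num = (centered[:, :, i] * centered[:, :, j]).sum(axis=1)
        den = np.sqrt(ss[:, i] * ss[:, j])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return np.where(den > 0, r, 0.0)

    corr_xy, corr_xz, corr_yz = corr(0, 1), corr(0, 2), corr(1, 2)

    mag = np.sqrt((windows**2).sum(axis=2))  # (W, L)
    mag_mean = mag.mean(axis=1)
    mag_c = mag - mag_mean[:, None]
    m2 = (mag_c**2).mean(axis=1)
    m3 = (mag_c**3).mean(axis=1)
    m4 = (mag_c**4).mean(axis=1)
    mag_std = np.sqrt((mag_c**2).sum(axis=1) / (length - 1))
    mag_range = mag.max(axis=1) - mag.min(axis=1)
    q75, q25 = np.percentile(mag, [75, 25], axis=1)
    mag_iqr = q75 - q25
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    mag_skew = np.where(m2 > 0, skew, 0.0)
    mag_kurt = np.where(m2 > 0, kurt, 0.0)

    sma = np.abs(windows).sum(axis=2).mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cos_tilt = windows[:, :, 2] / mag
    cos_tilt = np.where(mag > 0, np.clip(cos_tilt, -1.0, 1.0), 1.0)
    tilt_mean = np.degrees(np.arccos(cos_tilt)).mean(axis=1)

    sign = np.sign(mag_c)
    crossings = (sign[:, :-1] * sign[:, 1:] < 0).sum(axis=1)
    mag_mcr = crossings / (length - 1)

    axes = windows.transpose(0, 2, 1)  # (W, 3, L)
    power, freqs = _periodogram(axes, fs)
    domfreq, dompow = _dominant(power, freqs)  # (W, 3)

    mag_power, _ = _periodogram(mag, fs)
    mag_domfreq, _ = _dominant(mag_power, freqs)

    ac = mag_power[:, 1:]
    ac_total = ac.sum(axis=1)
    flat = ac.max(axis=1) <= _SPECTRAL_FLOOR * np.maximum(
        mag_power.sum(axis=1), 1e-300
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / ac_total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1) / np.log(ac.shape[1])
    entropy = np.where(flat, 0.0, entropy)

    return np.column_stack(
        [
            mean,
            std,
            corr_xy,
            corr_xz,
            corr_yz,
            mag_mean,
            mag_std,
            mag_range,
            mag_iqr,
            mag_skew,
            mag_kurt,
            sma,
            tilt_mean,
            mag_mcr,
            domfreq,
            dompow,
            mag_domfreq,
            entropy,
        ]
    )


def compute_features(window: np.ndarray, fs: float) -> np.ndarray:
    """Compute the named 26-feature vector for a single (L, 3) window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError("window must have shape (L, 3)")
    return compute_feature_matrix(window[None], fs)[0]


def _majority_label(code_window: np.ndarray, n_codes: int) -> tuple[int, float]:
    """Majority label code and purity; ties go to the code appearing earliest."""
    counts = np.bincount(code_window, minlength=n_codes)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        winner = tied[0]
    else:
        tied_set = set(tied.tolist())
        winner = next(c for c in code_window if c in tied_set)
    return int(winner), top / len(code_window)


def build_feature_set(
    rec: AccelRecording,
    log: AnnotationLog,
    mode: str,
    window_s: float = WINDOW_S_DEFAULT,
    overlap: float = OVERLAP_DEFAULT,
    min_purity: float = 0.5,
) -> FeatureSet:
    """Segment, featurize and label one recording.

    ``lab`` mode keeps only windows inside the per-activity calibration
    segments, labelled by protocol activity (mapped to the 7-class
    vocabulary). ``free_living`` mode windows the whole recording and labels
    each window by majority vote over per-sample observer labels (ties broken
    toward the earlier interval's label); windows whose majority label is
    ``unannotated`` or whose purity is below ``min_purity`` are dropped.
    """
    if mode not in ("lab", "free_living"):
        raise ValueError(f"unknown mode {mode!r}")

    rows: list[dict] = []
    feats: list[np.ndarray] = []

    if mode == "lab":
        segments = extract_calibration_segment(log)
        t0 = rec.start_time
        for iv in segments.intervals:
            i0 = int(round((iv.start - t0) * rec.fs))
            i1 = int(round((iv.end - t0) * rec.fs))
            i0, i1 = max(i0, 0), min(i1, rec.n_samples)
            windows, starts = segment_windows(
                rec.samples[i0:i1], rec.fs, window_s, overlap
            )
            if not len(windows):
                continue
            feats.append(compute_feature_matrix(windows, rec.fs))
            label = L.to_seven(iv.label)
            for s in starts:
                t_start = t0 + (i0 + s) / rec.fs
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "t_start": t_start,
                        "t_end": t_start + window_s,
                        "label": label,
                        "label_purity": 1.0,
                    }
                )
        provenance = "lab_calibration"
    else:
        windows, starts = segment_windows(rec.samples, rec.fs, window_s, overlap)
        if len(windows):
            # interval index per sample; -1 (unannotated) mapped to the last code
            iv_idx = sample_interval_index(rec, log)
            n_iv = len(log.intervals)
            codes = np.where(iv_idx < 0, n_iv, iv_idx)
            length = windows.shape[1]
            fmat = compute_feature_matrix(windows, rec.fs)
            iv_labels = [L.to_seven(iv.label) for iv in log.intervals]
            for k, s in enumerate(starts):
                win_codes = codes[s : s + length]
                # vote over interval indices: earlier interval wins ties by
                # construction since codes increase with interval order
                counts = np.bincount(win_codes, minlength=n_iv + 1)
                # aggregate by label (distinct bouts may share a label)
                label_counts: dict[str, int] = {}
                first_seen: dict[str, int] = {}
                for code in range(n_iv + 1):
                    c = counts[code]
                    if c == 0:
                        continue
                    lab = iv_labels[code] if code < n_iv else L.UNANNOTATED
                    label_counts[lab] = label_counts.get(lab, 0) + int(c)
                    first_seen.setdefault(lab, code)
                top = max(label_counts.values())
                tied = [lab for lab, c in label_counts.items() if c == top]
                winner = min(tied, key=lambda lab: first_seen[lab])
                purity = top / length
                if winner == L.UNANNOTATED or purity < min_purity:
                    continue
                t_start = rec.start_time + s / rec.fs
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "t_start": t_start,
                        "t_end": t_start + window_s,
                        "label": winner,
                        "label_purity": purity,
                    }
                )
                feats.append(fmat[k : k + 1])
        provenance = "free_living"

    if not rows:
        frame = pd.DataFrame(
            columns=["subject_id", "t_start", "t_end", "label", "label_purity"]
            + list(FEATURE_NAMES)
        )
        return FeatureSet(frame, FEATURE_NAMES, provenance)

    X = np.vstack(feats)
    frame = pd.DataFrame(rows)
    frame[list(FEATURE_NAMES)] = X
    return FeatureSet(frame, FEATURE_NAMES, provenance)


def concat_feature_sets(sets: list[FeatureSet]) -> FeatureSet:
    """Concatenate per-subject feature sets sharing names and provenance."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty feature sets to concatenate")
    names = sets[0].feature_names
    prov = sets[0].provenance
    for s in sets[1:]:
        if s.feature_names != names:
            raise ValueError("feature name mismatch between sets")
    frame = pd.concat([s.frame for s in sets], ignore_index=True)
    return FeatureSet(frame, names, prov)
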