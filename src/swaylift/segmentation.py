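"""Lift-event segmentation of a lumbar acceleration recording.

Lifts are detected on the anteroposterior (z) axis, the channel with the
largest amplitude excursions during a lift.  The detection signal is built in
three steps: a 4th-order Butterworth band-pass (1--50 Hz) removes offset and
drift, the filtered signal is rectified, and a 2nd-order Savitzky--Golay
filter with a long frame (1501 samples at 128 Hz) turns the rectified trace
into a smooth activity envelope.  Regions of interest (ROIs) are the maximal
runs where the envelope sits at or above a threshold; the threshold is either
supplied or calibrated automatically so that a session yields the expected
number of lifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal


class SegmentationError(ValueError):
    """Invalid segmentation input or parameters."""


class CalibrationError(SegmentationError):
    """No threshold reproduces the expected ROI count."""

    def __init__(self, expected: int, achievable: set[int]):
        self.expected = expected
        self.achievable = achievable
        super().__init__(
            f"no threshold yields {expected} regions; achievable counts: "
            f"{sorted(achievable)}"
        )


class ROI(NamedTuple):
    """Half-open sample-index interval [start_idx, stop_idx) of one lift."""

    start_idx: int
    stop_idx: int

    def duration_s(self, fs: float) -> float:
        return (self.stop_idx - self.start_idx) / fs


@dataclass
class SegmentationParams:
    """Tunables of the lift-detection pipeline.

    ``sg_frame`` is in samples; at 128 Hz the default 1501 corresponds to an
    ~11.7 s smoothing window.  ``threshold`` overrides automatic calibration
    when set; ``expected_rois`` drives the calibration when it is not.
    """

    bp_order: int = 4
    bp_band: tuple[float, float] = (1.0, 50.0)
    sg_order: int = 2
    sg_frame: int = 1501
    min_roi_duration: float = 0.5
    expected_rois: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order:
            raise SegmentationError("sg_frame must be odd and exceed sg_order")
        low, high = self.bp_band
        if not 0 < low < high:
            raise SegmentationError("band edges must satisfy 0 < low < high")


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 1.0, high: float = 50.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward and backward (``sosfiltfilt``) so burst
    centres are not delayed and ROI boundaries derived from the output line
    up with the raw signal.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high:
        raise SegmentationError("band edges must satisfy 0 < low < high")
    if high >= fs / 2:
        raise SegmentationError(f"high edge {high} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_envelope(x: np.ndarray, sg_order: int = 2, sg_frame: int = 1501) -> np.ndarray:
    """Rectify a signal and smooth it into an activity envelope.

    If the requested frame is longer than the signal it is reduced to the
    largest valid odd length (with a warning) rather than failing, so short
    test signals remain usable.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < sg_order + 1:
        raise SegmentationError("signal shorter than sg_order + 1 samples")
    if sg_frame % 2 == 0 or sg_frame <= sg_order:
        raise SegmentationError("sg_frame must be odd and exceed sg_order")
    if sg_frame > len(x):
        reduced = len(x) if len(x) % 2 == 1 else len(x) - 1
        if reduced <= sg_order:
            reduced = sg_order + 1 if (sg_order + 1) % 2 == 1 else sg_order + 2
        warnings.warn(
            f"sg_frame {sg_frame} exceeds signal length {len(x)}; using {reduced}"
        )
        sg_frame = reduced
    return signal.savgol_filter(np.abs(x), sg_frame, sg_order)


def detect_rois(
    envelope: np.ndarray, threshold: float, min_roi_duration: float, fs: float
) -> list[ROI]:
    """Maximal runs where ``envelope >= threshold``.

    Runs shorter than ``min_roi_duration`` are treated as noise spikes and
    dropped; runs touching the first or last sample are partial lifts and
    dropped as well.
    """
    if threshold <= 0:
        raise SegmentationError("threshold must be positive")
    envelope = np.asarray(envelope, dtype=float)
    above = envelope >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [len(envelope)]))
    min_len = min_roi_duration * fs
    rois = []
    for s, e in zip(starts, stops):
        if s == 0 or e == len(envelope):
            continue  # partial burst at a recording edge
        if e - s >= min_len:
            rois.append(ROI(int(s), int(e)))
    return rois


def calibrate_threshold(
    envelope: np.ndarray,
    expected_rois: int,
    min_roi_duration: float,
    fs: float,
    n_candidates: int = 512,
) -> float:
    """Find a threshold producing exactly ``expected_rois`` regions.

    Candidate thresholds are scanned between the 5th and 99.9th envelope
    percentiles.  Among contiguous runs of candidates that all yield the
    expected count, the widest run is chosen and its midpoint returned, which
    makes the calibration insensitive to small envelope perturbations.
    """
    if expected_rois < 1:
        raise SegmentationError("expected_rois must be >= 1")
    envelope = np.asarray(envelope, dtype=float)
    lo = np.percentile(envelope, 5)
    hi = np.percentile(envelope, 99.9)
    if not hi > lo or not hi > 0:
        raise CalibrationError(expected_rois, set())
    lo = max(lo, hi * 1e-9)  # thresholds must stay positive
    cands = np.linspace(lo, hi, n_candidates)
    counts = np.array(
        [len(detect_rois(envelope, t, min_roi_duration, fs)) for t in cands]
    )
    hit = counts == expected_rois
    if not hit.any():
        raise CalibrationError(expected_rois, set(counts.tolist()))
    # widest contiguous plateau of matching candidates
    best = (0, -1, -1)  # (width, i, j)
    i = 0
    while i < len(cands):
        if hit[i]:
            j = i
            while j + 1 < len(cands) and hit[j + 1]:
                j += 1
            width = cands[j] - cands[i]
            if width > best[0] or best[1] < 0:
                best = (width, i, j)
            i = j + 1
        else:
            i += 1
    _, i, j = best
    return float(0.5 * (cands[i] + cands[j]))


def segment_signal(
    z: np.ndarray, fs: float, params: SegmentationParams | None = None
) -> tuple[list[ROI], float]:
    """Full detection pipeline on a z-axis signal.

    Returns the detected ROIs and the threshold used (given or calibrated).
    """
    params = params or SegmentationParams()
    filtered = bandpass_filter(z, fs, *params.bp_band, order=params.bp_order)
    env = compute_envelope(filtered, params.sg_order, params.sg_frame)
    if params.threshold is not None:
        thr = params.threshold
    else:
        if params.expected_rois is None:
            raise SegmentationError("either threshold or expected_rois is required")
        thr = calibrate_threshold(
            env, params.expected_rois, params.min_roi_duration, fs
        )
    return detect_rois(env, thr, params.min_roi_duration, fs), thr


def extract_roi_segments(
    z: np.ndarray,
    y: np.ndarray,
    fs: float,
    rois: Sequence[ROI],
    params: SegmentationParams | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut matched z/y windows from the band-pass-filtered signals.

    Windows are pure slices of the 1--50 Hz filtered z and y series (not of
    the envelope), one pair per ROI.
    """
    params = params or SegmentationParams()
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(z) != len(y):
        raise SegmentationError("z and y must have equal length")
    for roi in rois:
        if not 0 <= roi.start_idx < roi.stop_idx <= len(z):
            raise SegmentationError(f"ROI {roi} out of bounds for length {len(z)}")
    zf = bandpass_filter(z, fs, *params.bp_band, order=params.bp_order)
    yf = bandpass_filter(y, fs, *params.bp_band, order=params.bp_order)
    return [(zf[r.start_idx : r.stop_idx], yf[r.start_idx : r.stop_idx]) for r in rois]


# ---------------------------------------------------------------------------
# CSV interfaces


def read_recording_csv(path) -> tuple[pd.DataFrame, float]:
    """Read a recording CSV (columns t_s, acc_x, acc_y, acc_z).

    Returns the frame and the sampling rate inferred from the time column.
    """
    df = pd.read_csv(path)
    required = {"t_s", "acc_x", "acc_y", "acc_z"}
    if not required.issubset(df.columns):
        raise SegmentationError(f"recording CSV must have columns {sorted(required)}")
    dt = np.median(np.diff(df["t_s"].to_numpy()))
    return df, float(1.0 / dt)


def write_rois_csv(rois_by_recording: dict[str, Sequence[ROI]], path) -> None:
    rows = [
        {"recording_id": rid, "start_idx": r.start_idx, "stop_idx": r.stop_idx}
        for rid, rois in rois_by_recording.items()
        for r in rois
    ]
    pd.DataFrame(rows, columns=["recording_id", "start_idx", "stop_idx"]).to_csv(
        path, index=False
    )


def read_rois_csv(path) -> dict[str, list[ROI]]:
    df = pd.read_csv(path)
    out: dict[str, list[ROI]] = {}
    for rid, grp in df.groupby("recording_id", sort=False):
        out[str(rid)] = [
            ROI(int(s), int(e))
            for s, e in zip(grp["start_idx"], grp["stop_idx"])
        ]
    return out
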