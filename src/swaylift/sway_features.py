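"""Postural-sway statistics on acceleration stabilograms.

A stabilogram is the planar trajectory of anteroposterior (AP) versus
mediolateral (ML) sway within one lift window.  The classical formulary was
defined for force-platform centre-of-pressure traces (Prieto et al.); here
it is applied unchanged to zero-mean lumbar centre-of-mass acceleration, so
the "distances" are in m/s^2.

Preprocessing per window: resample to 20 Hz (polyphase, anti-aliased),
3rd-order Butterworth low-pass at 5 Hz (zero-phase), then subtract the mean
of each channel.  Fourteen statistics are computed: nine distance measures
(mean / range / RMS of the resultant, AP and ML series), mean velocity MV,
sway area SA, and three spectral-moment measures of the resultant-distance
power spectrum (mean frequency MF, centroidal frequency CF, frequency
dispersion DF).

One deliberate departure from the naive reading of the formulary: the
directional mean distances are means of *absolute* deviations,
``MDIST_AP = mean(|AP|)``.  On a mean-removed channel the plain mean is
identically zero, so the absolute form (the one the COP literature actually
uses) is the only meaningful reading.  Similarly the sway-area shoelace sum
is taken in absolute value so SA is a genuine area rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

FEATURE_NAMES = [
    "MDIST",
    "MDIST_AP",
    "MDIST_ML",
    "RDIST",
    "RDIST_AP",
    "RDIST_ML",
    "RMS_DIST",
    "RMS_DIST_AP",
    "RMS_DIST_ML",
    "MV",
    "SA",
    "MF",
    "CF",
    "DF",
]

FEATURE_TABLE_COLUMNS = ["roi_id", "subject_id", "label"] + FEATURE_NAMES


class FeatureError(ValueError):
    """Segment unusable for sway-feature extraction."""


class DegenerateSignalError(FeatureError):
    """Signal with no power; frequency features are undefined."""


@dataclass
class Stabilogram:
    """Zero-mean AP/ML acceleration pair at the stabilogram rate (20 Hz)."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float = 20.0

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if len(self.ap) != len(self.ml):
            raise FeatureError("AP and ML must have equal length")
        if len(self.ap) < 4:
            raise FeatureError("stabilogram needs at least 4 samples")

    @property
    def n(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class SpectralDensity:
    """One-sided power spectral density of the resultant distance.

    The DC bin is dropped: spectral moments describe the oscillatory
    content, and any residual mean would otherwise dominate them.
    """

    freqs: np.ndarray
    G: np.ndarray
    delta_f: float


def make_stabilogram(
    z_segment: np.ndarray,
    y_segment: np.ndarray,
    fs_in: float,
    fs_out: float = 20.0,
    lowpass_hz: float = 5.0,
    lowpass_order: int = 3,
) -> Stabilogram:
    """Resample, low-pass and de-mean one lift's AP (z) / ML (y) windows."""
    z = np.asarray(z_segment, dtype=float)
    y = np.asarray(y_segment, dtype=float)
    if len(z) != len(y):
        raise FeatureError("segments must have equal length")
    if fs_in <= 2 * fs_out:
        raise FeatureError(f"input rate {fs_in} Hz too low to resample to {fs_out} Hz")
    if len(z) < fs_in:
        raise FeatureError("segment shorter than 1 s")
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    ap = signal.resample_poly(z, ratio.numerator, ratio.denominator)
    ml = signal.resample_poly(y, ratio.numerator, ratio.denominator)
    sos = signal.butter(lowpass_order, lowpass_hz, btype="lowpass", fs=fs_out, output="sos")
    ap = signal.sosfiltfilt(sos, ap)
    ml = signal.sosfiltfilt(sos, ml)
    return Stabilogram(ap - ap.mean(), ml - ml.mean(), fs=fs_out)


def resultant_distance(stab: Stabilogram) -> np.ndarray:
    """RD(n) = sqrt(AP(n)^2 + ML(n)^2)."""
    return np.hypot(stab.ap, stab.ml)


def time_domain_features(stab: Stabilogram) -> dict[str, float]:
    """The eleven time-domain sway statistics."""
    if stab.n < 2:
        raise FeatureError("time-domain features need at least 2 samples")
    ap, ml = stab.ap, stab.ml
    rd = resultant_distance(stab)
    t = stab.duration
    totex = float(np.hypot(np.diff(ap), np.diff(ml)).sum())
    shoelace = float(ap[1:] @ ml[:-1] - ap[:-1] @ ml[1:])
    return {
        "MDIST": float(rd.mean()),
        "MDIST_AP": float(np.abs(ap).mean()),
        "MDIST_ML": float(np.abs(ml).mean()),
        "RDIST": float(rd.max() - rd.min()),
        "RDIST_AP": float(ap.max() - ap.min()),
        "RDIST_ML": float(ml.max() - ml.min()),
        "RMS_DIST": float(np.sqrt((rd**2).mean())),
        "RMS_DIST_AP": float(np.sqrt((ap**2).mean())),
        "RMS_DIST_ML": float(np.sqrt((ml**2).mean())),
        "MV": totex / t,
        "SA": abs(shoelace) / (2.0 * t),
        "TOTEX": totex,  # carried for MF; not part of the feature vector
    }


def power_spectral_density(
    rd: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
) -> SpectralDensity:
    """Periodogram of the mean-removed resultant-distance series.

    Plain (boxcar, un-averaged) periodogram with delta_f = fs / N; the DC
    bin is excluded.  ``band`` optionally restricts the retained bins (e.g.
    the 0.15--5 Hz band customary for quiet-stance COP analysis).
    """
    rd = np.asarray(rd, dtype=float)
    if len(rd) < 8:
        raise FeatureError("PSD needs at least 8 samples")
    freqs, G = signal.periodogram(
        rd - rd.mean(), fs=fs, window="boxcar", detrend=False
    )
    freqs, G = freqs[1:], G[1:]
    if band is not None:
        keep = (freqs >= band[0]) & (freqs <= band[1])
        freqs, G = freqs[keep], G[keep]
    return SpectralDensity(freqs=freqs, G=G, delta_f=fs / len(rd))


def spectral_moment(psd: SpectralDensity, k: int) -> float:
    """mu_k = sum_m (m * delta_f)^k G(m) over the retained bins."""
    if k not in (0, 1, 2):
        raise ValueError("spectral moments are defined here for k in {0, 1, 2}")
    return float(np.sum(psd.freqs**k * psd.G))


def frequency_domain_features(
    stab: Stabilogram, td: dict[str, float] | None = None
) -> dict[str, float]:
    """MF, CF and DF from the resultant-distance spectrum.

    MF is the rotation rate of an equivalent circular path: the frequency at
    which a point circling at radius MDIST would cover the observed total
    excursion.  CF is the RMS frequency of the spectrum; DF measures how
    spread the spectral mass is (0 for a pure tone, towards 1 for broadband).
    """
    td = td or time_domain_features(stab)
    if td["MDIST"] <= 0:
        raise DegenerateSignalError("MDIST is zero; MF undefined")
    psd = power_spectral_density(resultant_distance(stab), stab.fs)
    mu0 = spectral_moment(psd, 0)
    mu2 = spectral_moment(psd, 2)
    if mu0 <= 0 or mu2 <= 0:
        raise DegenerateSignalError("spectrum has no power; CF/DF undefined")
    mu1 = spectral_moment(psd, 1)
    mf = td["TOTEX"] / (2.0 * np.pi * td["MDIST"] * stab.duration)
    cf = float(np.sqrt(mu2 / mu0))
    df = float(np.sqrt(max(1.0 - mu1**2 / (mu0 * mu2), 0.0)))
    return {"MF": mf, "CF": cf, "DF": df}


def compute_feature_vector(
    z_segment: np.ndarray,
    y_segment: np.ndarray,
    fs_in: float,
    label: str | None = None,
    roi_id: str | None = None,
    subject_id: str | None = None,
) -> dict[str, float | str | None]:
    """The full 14-feature sway vector for one lift window."""
    stab = make_stabilogram(z_segment, y_segment, fs_in)
    td = time_domain_features(stab)
    fd = frequency_domain_features(stab, td)
    features = {name: td[name] for name in FEATURE_NAMES if name in td}
    features.update(fd)
    return {"roi_id": roi_id, "subject_id": subject_id, "label": label, **features}


def feature_table_from_recordings(
    recordings: Sequence,
    rois_by_recording: dict[str, Sequence] | None = None,
    params=None,
) -> pd.DataFrame:
    """Build the per-ROI feature table for a set of recordings.

    ``rois_by_recording`` maps recording_id to ROI lists (e.g. detected by
    the segmentation stage); when omitted, generator ground-truth windows
    are used.  Windows are cut from the band-pass-filtered z/y signals.
    """
    from .segmentation import extract_roi_segments

    rows = []
    for rec in recordings:
        rois = (
            rois_by_recording[rec.recording_id]
            if rois_by_recording is not None
            else rec.true_rois
        )
        segments = extract_roi_segments(
            rec.acc_z, rec.acc_y, rec.sampling_rate, rois, params
        )
        for i, (z_seg, y_seg) in enumerate(segments):
            rows.append(
                compute_feature_vector(
                    z_seg,
                    y_seg,
                    rec.sampling_rate,
                    label=rec.class_label,
                    roi_id=f"{rec.recording_id}_roi{i:02d}",
                    subject_id=rec.subject_id,
                )
            )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table[FEATURE_TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FeatureError(f"feature table missing columns {sorted(missing)}")
    return df
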