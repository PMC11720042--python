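"""Synthetic lumbar-accelerometer recordings of repetitive lifting sessions.

The study design this emulates: each subject performs two sessions of 20
lifts wearing a single IMU on the lumbar spine (128 Hz).  One session is a
No-Risk task (light load, 2.5 lifts/min), the other a Risk task (heavy load,
6 lifts/min).  Heavier loads displace the body + load centre of mass and
increase postural sway, predominantly in the anteroposterior (AP, sensor z)
direction; the generator encodes that class effect as a larger AP sway scale
for Risk sessions, with a milder mediolateral (ML, sensor y) increase.

A lift appears in the signal as a burst of band-limited (1--5 Hz)
oscillation under a smooth Hann envelope, inside the passband the analysis
retains (1--50 Hz segmentation band-pass, 5 Hz stabilogram low-pass), standing on a quiet white-noise
baseline.  This is a signal model, not biomechanics: it reproduces the
amplitude and frequency structure the downstream pipeline relies on while
keeping exact ground-truth lift boundaries available for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .segmentation import ROI

NO_RISK = "No-Risk"
RISK = "Risk"
CLASS_LABELS = (NO_RISK, RISK)


class ConfigurationError(ValueError):
    """Simulation configuration that cannot produce a valid recording."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Sway scales are dimensionless multipliers on ``burst_amplitude``; the
    Risk/No-Risk AP ratio (the class separation delta) is 1.8 by default.
    ``lift_scale_jitter`` and ``subject_scale_jitter`` are log-normal sigmas
    for per-lift and per-subject amplitude heterogeneity.  Cadences are the
    two sessions' lift frequencies in lifts/min.
    """

    n_subjects: int = 8
    lifts_per_session: int = 20
    sampling_rate: float = 128.0
    lift_duration: tuple[float, float] = (2.0, 4.0)
    cadence_norisk: float = 2.5
    cadence_risk: float = 6.0
    burst_amplitude: float = 2.0
    ap_sway_scale_norisk: float = 1.0
    ap_sway_scale_risk: float = 1.8
    ml_sway_scale_norisk: float = 0.5
    ml_sway_scale_risk: float = 0.65
    lift_scale_jitter: float = 0.03
    subject_scale_jitter: float = 0.03
    noise_sd: float = 0.05
    burst_band: tuple[float, float] = (1.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lifts_per_session < 1:
            raise ConfigurationError("lifts_per_session must be >= 1")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        lo, hi = self.lift_duration
        if not 0 < lo <= hi:
            raise ConfigurationError("lift_duration range must be positive")
        for name in (
            "cadence_norisk",
            "cadence_risk",
            "burst_amplitude",
            "ap_sway_scale_norisk",
            "ap_sway_scale_risk",
            "ml_sway_scale_norisk",
            "ml_sway_scale_risk",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.ap_sway_scale_norisk > 0:
            if self.ap_sway_scale_risk / self.ap_sway_scale_norisk < 1:
                raise ConfigurationError(
                    "Risk AP sway scale must not be below the No-Risk scale"
                )

    @property
    def delta(self) -> float:
        """Risk / No-Risk AP sway-scale ratio (class separation)."""
        return self.ap_sway_scale_risk / self.ap_sway_scale_norisk

    def cadence(self, class_label: str) -> float:
        return self.cadence_norisk if class_label == NO_RISK else self.cadence_risk

    def sway_scales(self, class_label: str) -> tuple[float, float]:
        if class_label == NO_RISK:
            return self.ap_sway_scale_norisk, self.ml_sway_scale_norisk
        if class_label == RISK:
            return self.ap_sway_scale_risk, self.ml_sway_scale_risk
        raise ConfigurationError(f"unknown class label {class_label!r}")


@dataclass
class SyntheticRecording:
    """One session's tri-axial acceleration with ground-truth lift windows."""

    acc_x: np.ndarray
    acc_y: np.ndarray  # ML
    acc_z: np.ndarray  # AP
    sampling_rate: float
    subject_id: str
    class_label: str
    true_rois: list[ROI] = field(default_factory=list)

    @property
    def recording_id(self) -> str:
        suffix = "norisk" if self.class_label == NO_RISK else "risk"
        return f"{self.subject_id}_{suffix}"

    def __len__(self) -> int:
        return len(self.acc_z)


def generate_lift_burst(
    duration_s: float,
    fs: float,
    ap_scale: float,
    ml_scale: float,
    burst_amplitude: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (1.0, 5.0),
) -> tuple[np.ndarray, np.ndarray]:
    """One lift's AP and ML acceleration burst.

    Band-limited Gaussian noise is normalised to unit variance and shaped by
    a Hann envelope; the channel standard deviations then scale as
    ``burst_amplitude * ap_scale`` and ``burst_amplitude * ml_scale``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("burst too short for the sampling rate")
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    window = np.hanning(n)

    def channel(scale: float) -> np.ndarray:
        white = rng.standard_normal(n)
        x = signal.sosfiltfilt(sos, white)
        sd = x.std()
        if sd > 0:
            x = x / sd
        return burst_amplitude * scale * x * window

    return channel(ap_scale), channel(ml_scale)


def generate_recording(
    config: SimulationConfig,
    class_label: str,
    subject_id: str,
    seed: int,
) -> SyntheticRecording:
    """One session: quiet standing baseline with lifts at the class cadence.

    Bursts are centred at half-period, 3/2-period, ... so the recording spans
    ``lifts_per_session`` full cadence periods.  A small uniform start jitter
    (up to 0.25 s) desynchronises lifts from the exact grid.
    """
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    period = 60.0 / config.cadence(class_label)
    dur_lo, dur_hi = config.lift_duration
    if dur_hi + 0.5 >= period:
        raise ConfigurationError(
            f"cadence {config.cadence(class_label)} lifts/min leaves no quiet "
            f"gap for lifts of up to {dur_hi} s"
        )
    n_total = int(round(config.lifts_per_session * period * fs))
    noise = (
        rng.normal(0.0, config.noise_sd, (3, n_total))
        if config.noise_sd > 0
        else np.zeros((3, n_total))
    )
    acc_x, acc_y, acc_z = noise
    ap_scale, ml_scale = config.sway_scales(class_label)
    subject_factor = float(np.exp(rng.normal(0.0, config.subject_scale_jitter)))

    true_rois: list[ROI] = []
    for i in range(config.lifts_per_session):
        duration = rng.uniform(dur_lo, dur_hi)
        start_jitter = rng.uniform(-0.25, 0.25)
        lift_factor = float(np.exp(rng.normal(0.0, config.lift_scale_jitter)))
        centre = (i + 0.5) * period + start_jitter
        start = int(round((centre - duration / 2) * fs))
        ap, ml = generate_lift_burst(
            duration,
            fs,
            ap_scale * subject_factor * lift_factor,
            ml_scale * subject_factor * lift_factor,
            config.burst_amplitude,
            rng,
            band=config.burst_band,
        )
        stop = start + len(ap)
        if true_rois and start <= true_rois[-1].stop_idx:
            raise ConfigurationError("lift bursts overlap at the configured cadence")
        acc_z[start:stop] += ap
        acc_y[start:stop] += ml
        true_rois.append(ROI(start, stop))

    return SyntheticRecording(
        acc_x=acc_x,
        acc_y=acc_y,
        acc_z=acc_z,
        sampling_rate=fs,
        subject_id=subject_id,
        class_label=class_label,
        true_rois=true_rois,
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[SyntheticRecording], pd.DataFrame]:
    """All subjects' sessions: one No-Risk and one Risk recording each.

    Deterministic under ``config.seed``; per-recording seeds are drawn from a
    generator seeded with it.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[SyntheticRecording] = []
    rows = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for class_label in CLASS_LABELS:
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_recording(config, class_label, subject_id, rec_seed)
            recordings.append(rec)
            rows.append(
                {
                    "recording_id": rec.recording_id,
                    "subject_id": subject_id,
                    "class_label": class_label,
                }
            )
    return recordings, pd.DataFrame(rows)


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A class-null variant: identical sway scales for both classes.

    Under this configuration the class label carries no signal-derived
    information, which is the negative control for the classification stage.
    """
    base = config or SimulationConfig()
    return replace(
        base,
        ap_sway_scale_risk=base.ap_sway_scale_norisk,
        ml_sway_scale_risk=base.ml_sway_scale_norisk,
        **overrides,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def write_recording_csv(rec: SyntheticRecording, path) -> None:
    t = np.arange(len(rec)) / rec.sampling_rate
    pd.DataFrame(
        {"t_s": t, "acc_x": rec.acc_x, "acc_y": rec.acc_y, "acc_z": rec.acc_z}
    ).to_csv(path, index=False, float_format="%.6f")


def write_dataset_csv(
    recordings: list[SyntheticRecording], labels: pd.DataFrame, out_dir
) -> None:
    """One CSV per recording plus a manifest and a ground-truth ROI table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = labels.copy()
    manifest["file"] = [rec.recording_id + ".csv" for rec in recordings]
    for rec in recordings:
        write_recording_csv(rec, out_dir / (rec.recording_id + ".csv"))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    roi_rows = [
        {
            "recording_id": rec.recording_id,
            "start_idx": roi.start_idx,
            "stop_idx": roi.stop_idx,
        }
        for rec in recordings
        for roi in rec.true_rois
    ]
    pd.DataFrame(roi_rows).to_csv(out_dir / "true_rois.csv", index=False)
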