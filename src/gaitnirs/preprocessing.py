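"""Data-quality gate and signal cleaning.

Channel QC excludes channels with hardware gain at or above the threshold
(default 7) or with a raw-intensity coefficient of variation above the
noise threshold (default 0.15, worst wavelength); a subject with strictly
more than the allowed number of bad channels (default 8) is excluded.

Cleaning order in the pipeline is: discontinuity removal -> spike removal
-> zero-phase Butterworth bandpass.  None of the operators change series
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, InvalidInputError
from .synthetic_fnirs import RawRecording

_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


@dataclass(frozen=True)
class QCThresholds:
    gain_threshold: int = 7          # channel excluded when gain >= this
    cv_threshold: float = 0.15       # raw-intensity CV above this = noisy channel
    max_bad_channels: int = 8        # subject excluded when bad count > this

    def __post_init__(self) -> None:
        if self.gain_threshold <= 0 or self.cv_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.max_bad_channels < 0:
            raise ConfigurationError("max_bad_channels must be >= 0")


@dataclass
class QCReport:
    channel_status: dict = field(default_factory=dict)   # id -> "retained"|"excluded"
    channel_reasons: dict = field(default_factory=dict)  # id -> set of reasons
    subject_status: str = "included"
    bad_channel_count: int = 0
    subject_id: str = ""

    @property
    def retained_ids(self) -> list[str]:
        return [c for c, s in self.channel_status.items() if s == "retained"]

    @property
    def excluded_ids(self) -> list[str]:
        return [c for c, s in self.channel_status.items() if s == "excluded"]

    def retained_mask(self, channel_ids: list[str]) -> np.ndarray:
        return np.array(
            [self.channel_status.get(c) == "retained" for c in channel_ids], dtype=bool
        )


def qc_channels(
    raw: RawRecording, thresholds: QCThresholds | None = None
) -> QCReport:
    """Flag bad channels (gain, intensity CV) and decide subject inclusion.

    A channel is excluded iff gain >= gain_threshold OR its worst-wavelength
    intensity CV (SD/mean) exceeds cv_threshold.  The subject is excluded
    iff strictly more than ``max_bad_channels`` channels are excluded.
    """
    thresholds = thresholds or QCThresholds()
    if raw.n_samples == 0:
        raise InvalidInputError("empty recording")
    intensity = raw.intensity
    mean = intensity.mean(axis=0)                 # (ch, 2)
    sd = intensity.std(axis=0, ddof=0)
    cv = np.divide(sd, mean, out=np.full_like(sd, np.inf), where=mean > 0)
    worst_cv = cv.max(axis=1)                     # worst wavelength per channel

    report = QCReport(subject_id=raw.subject_id)
    for i, cid in enumerate(raw.montage.channel_ids):
        reasons: set[str] = set()
        if raw.gains[i] >= thresholds.gain_threshold:
            reasons.add("gain")
        if worst_cv[i] > thresholds.cv_threshold:
            reasons.add("snr")
        report.channel_status[cid] = "excluded" if reasons else "retained"
        report.channel_reasons[cid] = reasons
    report.bad_channel_count = len(report.excluded_ids)
    report.subject_status = (
        "excluded" if report.bad_channel_count > thresholds.max_bad_channels
        else "included"
    )
    return report


def _robust_z(dx: np.ndarray) -> np.ndarray:
    med = np.median(dx)
    mad = np.median(np.abs(dx - med))
    scale = _MAD_SCALE * mad
    if scale == 0:
        sd = dx.std(ddof=0)
        if sd == 0:
            return np.zeros_like(dx)
        scale = sd
    return np.abs(dx - med) / scale


def remove_spikes(series: np.ndarray, z_threshold: float = 5.0) -> np.ndarray:
    """Replace spike samples by linear interpolation between retained
    neighbours.

    A sample is flagged when the robust z-score of an adjacent first
    difference (|dx - median dx| / (1.4826 * MAD dx), entering or leaving
    the sample) exceeds ``z_threshold``, so runs of adjacent impulses are
    caught; with zero MAD on a non-constant series the plain SD is used
    instead, and a constant series is returned unchanged.  Flagged runs
    touching the boundary are filled with the nearest retained value.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 5:
        raise InvalidInputError("series too short for spike removal")
    dx = np.diff(series)
    z = _robust_z(dx)
    anomalous = z > z_threshold
    bad = np.zeros(series.size, dtype=bool)
    bad[1:] |= anomalous       # difference entering the sample
    bad[:-1] |= anomalous      # difference leaving the sample
    if not bad.any():
        return series.copy()
    good = ~bad
    if not good.any():
        return series.copy()
    out = series.copy()
    idx = np.arange(series.size)
    out[bad] = np.interp(idx[bad], idx[good], series[good])
    return out


def remove_discontinuities(
    series: np.ndarray,
    step_threshold: float | None = None,
    window: int = 10,
) -> np.ndarray:
    """Correct sustained baseline shifts by subtracting the jump from all
    subsequent samples.

    A candidate step is a first difference exceeding ``step_threshold``
    whose post-segment median differs from the pre-segment median by more
    than the threshold (medians over up to ``window`` samples on each
    side).  Steps are corrected left-to-right, so the output differences
    equal the input differences everywhere except at corrected indices.
    When ``step_threshold`` is None it defaults to 8 robust sigmas of the
    first differences.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 5:
        raise InvalidInputError("series too short for discontinuity removal")
    dx = np.diff(series)
    if step_threshold is None:
        med = np.median(dx)
        sigma = _MAD_SCALE * np.median(np.abs(dx - med))
        if sigma == 0:
            sigma = dx.std(ddof=0)
        if sigma == 0:
            return series.copy()
        step_threshold = 8.0 * sigma
    out = series.copy()
    candidates = np.flatnonzero(np.abs(dx) > step_threshold) + 1
    for k in candidates:
        pre = out[max(0, k - window):k]
        post = out[k:k + window]
        if pre.size == 0 or post.size == 0:
            continue
        if np.abs(np.median(post) - np.median(pre)) > step_threshold:
            out[k:] -= out[k] - out[k - 1]
    return out


def bandpass_filter(
    series: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.20,
    fs: float = 3.46,
    order: int = 3,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass.

    Defaults keep the block fundamental (1/60 s ~ 0.017 Hz) and reject
    cardiac (~1.1 Hz) and drift.  Output length equals input length.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ConfigurationError(
            f"invalid band ({low_hz}, {high_hz}) at fs={fs}"
        )
    series = np.asarray(series, dtype=float)
    b, a = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)
    return filtfilt(b, a, series, axis=axis)


def clean_series(
    series: np.ndarray,
    fs: float,
    spike_z: float = 5.0,
    step_threshold: float | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.20,
    bypass_filter: bool = False,
) -> np.ndarray:
    """Full cleaning chain for one series: discontinuities -> spikes ->
    bandpass (optionally bypassed for diagnostic runs)."""
    out = remove_discontinuities(series, step_threshold)
    out = remove_spikes(out, spike_z)
    if not bypass_filter:
        out = bandpass_filter(out, low_hz, high_hz, fs)
    return out
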