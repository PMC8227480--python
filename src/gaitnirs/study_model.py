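"""Structural objects of the study: optode montage, block task design,
subject metadata, and synthetic-cohort scenario definitions.

The default montage is an abstract 48-channel layout (16 sources, 16
detectors, 24 channels per hemisphere at 3 cm separation) with hemisphere
and region labels only; no scalp coordinates are modelled because no
downstream computation uses geometry beyond separation and hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidDesignError, ConfigurationError

HEMISPHERES = ("left", "right")
REGIONS = ("M1", "SMC", "PM")
TIMEPOINTS = ("T0", "T1", "T2")
TREATMENTS = ("RAGT", "OW", "none")
COHORTS = ("PwMS", "healthy")

#: sources/detectors per hemisphere in the default layout
_N_OPTODES_PER_SIDE = 8
_N_CHANNELS_PER_HEMI = 24


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    channel_id: str
    source_id: str
    detector_id: str
    hemisphere: str        # "left" | "right"
    region: str            # "M1" | "SMC" | "PM"
    separation_m: float    # source-detector distance

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ConfigurationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.separation_m <= 0:
            raise ConfigurationError("separation must be positive")


@dataclass(frozen=True)
class Montage:
    """Ordered channel list; the spatial frame for all per-channel data."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        """Positional indices of the channels on one hemisphere."""
        if hemisphere not in HEMISPHERES:
            raise ConfigurationError(f"unknown hemisphere {hemisphere!r}")
        return np.array(
            [i for i, c in enumerate(self.channels) if c.hemisphere == hemisphere],
            dtype=int,
        )

    def region_indices(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
        return np.array(
            [i for i, c in enumerate(self.channels) if c.region == region], dtype=int
        )

    def to_json(self) -> str:
        return json.dumps(
            {"channels": [asdict(c) for c in self.channels]}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        doc = json.loads(text)
        return cls(tuple(Channel(**c) for c in doc["channels"]))


def build_default_montage(separation_m: float = 0.03) -> Montage:
    """Default 48-channel layout: 24 channels per hemisphere.

    Per hemisphere, 8 sources are each paired with 3 of 8 detectors in a
    fixed ring pattern.  Region labels follow the documented convention:
    channels 1-6 of each hemisphere are M1, 7-12 SMC, 13-24 PM.
    Deterministic: two calls return identical montages.
    """
    channels: list[Channel] = []
    for h_idx, hemi in enumerate(HEMISPHERES):
        base = h_idx * _N_OPTODES_PER_SIDE
        for k in range(_N_CHANNELS_PER_HEMI):
            src = k // 3
            det = (src + k % 3) % _N_OPTODES_PER_SIDE
            region = "M1" if k < 6 else ("SMC" if k < 12 else "PM")
            channels.append(
                Channel(
                    channel_id=f"CH{h_idx * _N_CHANNELS_PER_HEMI + k + 1:02d}",
                    source_id=f"S{base + src + 1:02d}",
                    detector_id=f"D{base + det + 1:02d}",
                    hemisphere=hemi,
                    region=region,
                    separation_m=separation_m,
                )
            )
    return Montage(tuple(channels))


@dataclass(frozen=True)
class TaskDesign:
    """Block design: alternating walk/rest cycles after a pre-task baseline."""

    sampling_rate_hz: float = 3.46
    cycles: int = 4
    walk_s: float = 30.0
    rest_s: float = 30.0
    baseline_s: float = 30.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvalidDesignError("sampling rate must be positive")
        if self.cycles < 1:
            raise InvalidDesignError("need at least one cycle")
        if self.walk_s < 0 or self.rest_s < 0 or self.baseline_s < 0:
            raise InvalidDesignError("durations must be non-negative")

    @property
    def walk_onsets_s(self) -> tuple[float, ...]:
        """Walk-block onsets: baseline + k*(walk+rest), k = 0..cycles-1."""
        period = self.walk_s + self.rest_s
        return tuple(self.baseline_s + k * period for k in range(self.cycles))

    @property
    def total_duration_s(self) -> float:
        return self.baseline_s + self.cycles * (self.walk_s + self.rest_s)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        return cls(**json.loads(text))


def build_task_design(
    sampling_rate: float = 3.46,
    cycles: int = 4,
    walk_s: float = 30.0,
    rest_s: float = 30.0,
    baseline_s: float = 30.0,
) -> TaskDesign:
    """Construct a validated TaskDesign (defaults: 3.46 Hz, 4x(30 s + 30 s),
    30 s pre-task baseline)."""
    return TaskDesign(
        sampling_rate_hz=sampling_rate,
        cycles=cycles,
        walk_s=walk_s,
        rest_s=rest_s,
        baseline_s=baseline_s,
    )


@dataclass
class SubjectMeta:
    """Per-subject metadata; clinical scores are keyed by timepoint."""

    subject_id: str
    cohort: str                      # "PwMS" | "healthy"
    treatment: str = "none"          # "RAGT" | "OW" | "none"
    timepoints: tuple[str, ...] = ("T0",)
    edss: float | None = None
    phenotype: str = "none"          # "primary progressive" | "secondary progressive" | "none"
    impaired_side: str | None = None  # more-impaired limb (dominant limb for healthy)
    age: float | None = None
    sex: str | None = None           # "M" | "F"
    t25fw_speed: dict = field(default_factory=dict)   # m/s per timepoint
    six_mwd: dict = field(default_factory=dict)       # m per timepoint
    bbs: dict = field(default_factory=dict)           # 0-56 per timepoint

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"unknown cohort {self.cohort!r}")
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        for tp in self.timepoints:
            if tp not in TIMEPOINTS:
                raise ConfigurationError(f"unknown timepoint {tp!r}")


@dataclass
class CohortDistribution:
    """Amplitude model for one cohort: subject-level plateau oxy-Hb amplitude
    (micromolar) and the more-affected-hemisphere asymmetry factor."""

    amp_mean_um: float
    amp_sd_um: float
    maff_factor: float = 1.0        # MAff-hemisphere amplitudes scaled by this
    channel_spread_sigma: float = 0.4  # lognormal sigma of per-channel factors

    def __post_init__(self) -> None:
        if self.amp_sd_um < 0:
            raise ConfigurationError("amplitude SD must be >= 0")


@dataclass
class ScenarioConfig:
    """Everything needed to synthesize a cohort reproducibly."""

    n_ragt: int = 12
    n_ow: int = 12
    n_healthy: int = 5
    pwms: CohortDistribution = field(
        default_factory=lambda: CohortDistribution(
            1.5, 0.4, maff_factor=1.35, channel_spread_sigma=0.35
        )
    )
    healthy: CohortDistribution = field(
        default_factory=lambda: CohortDistribution(
            0.35, 0.1, maff_factor=1.0, channel_spread_sigma=0.35
        )
    )
    # multiplicative longitudinal effect on subject amplitude, per arm
    effect_multipliers: dict = field(
        default_factory=lambda: {
            "RAGT": {"T0": 1.0, "T1": 0.85, "T2": 0.50},
            "OW": {"T0": 1.0, "T1": 1.20, "T2": 1.75},
        }
    )
    pwms_timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    bad_channel_prob: float = 0.0    # per-channel probability of an injected bad channel
    noise_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ragt, self.n_ow, self.n_healthy) < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if not 0.0 <= self.bad_channel_prob <= 1.0:
            raise ConfigurationError("bad_channel_prob must be in [0, 1]")
        for tp in self.pwms_timepoints:
            if tp not in TIMEPOINTS:
                raise ConfigurationError(f"unknown timepoint {tp!r}")


def study_like_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """12 RAGT + 12 OW + 5 healthy, activation higher in PwMS and in the
    more-affected hemisphere, opposite longitudinal trends per arm."""
    return ScenarioConfig(seed=seed, **overrides)


def null_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Both arms drawn from one distribution, no longitudinal effects —
    used for type-I-error calibration of the statistical battery."""
    kwargs = dict(
        n_healthy=0,
        effect_multipliers={
            "RAGT": {"T0": 1.0, "T1": 1.0, "T2": 1.0},
            "OW": {"T0": 1.0, "T1": 1.0, "T2": 1.0},
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
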