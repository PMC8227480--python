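"""Synthetic dual-wavelength fNIRS generator.

Builds raw intensity recordings with known ground truth so every downstream
stage (QC, cleaning, MBLL inversion, AUC extraction, statistics) can be
tested without real trial data.  Concentration time courses are a boxcar
over the walk blocks convolved with a canonical double-gamma hemodynamic
response; the forward MBLL (shared parameters with :mod:`gaitnirs.mbll`)
converts them to optical density, physiological noise is added in the OD
domain, and intensity is I0 * 10**(-dOD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError
from .mbll import MBLLParams, hemoglobin_to_od
from .study_model import (
    CohortDistribution,
    Montage,
    ScenarioConfig,
    SubjectMeta,
    TaskDesign,
    build_default_montage,
)


@dataclass
class NoiseModel:
    """Additive OD-domain noise components.

    Sinusoid amplitudes are OD units; drift is a random walk with the given
    per-sample step SD; spikes and baseline shifts are Poisson events.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.004
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.006
    mayer_hz: float = 0.1
    mayer_amp: float = 0.008
    drift_step_sd: float = 2e-4
    white_sd: float = 0.003
    spike_rate_per_min: float = 0.0
    spike_magnitude: float = 0.05
    shift_rate_per_min: float = 0.0
    shift_magnitude: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "cardiac_amp", "respiratory_amp", "mayer_amp", "drift_step_sd",
            "white_sd", "spike_rate_per_min", "spike_magnitude",
            "shift_rate_per_min", "shift_magnitude",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(
            cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0,
            drift_step_sd=0.0, white_sd=0.0,
            spike_rate_per_min=0.0, shift_rate_per_min=0.0,
        )


@dataclass
class GroundTruth:
    """Injected activation amplitudes and bad-channel set for one recording."""

    hbo_amp_um: np.ndarray                 # (n_channels,) plateau amplitude, uM
    hbr_amp_um: np.ndarray                 # (n_channels,) typically negative
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    bad_channels: dict = field(default_factory=dict)  # channel_id -> {"gain","snr"} reasons
    seed: int = 0

    @classmethod
    def from_hbo(cls, hbo_amp_um: np.ndarray, **kwargs) -> "GroundTruth":
        """HbR amplitude defaults to -1/3 of HbO (typical inverse response)."""
        hbo = np.asarray(hbo_amp_um, dtype=float)
        return cls(hbo_amp_um=hbo, hbr_amp_um=-hbo / 3.0, **kwargs)


@dataclass
class RawRecording:
    """Dual-wavelength raw intensity recording.

    ``intensity`` has shape (n_samples, n_channels, 2) with the last axis
    ordered like ``wavelengths_nm``; units are arbitrary detector units and
    strictly positive.
    """

    montage: Montage
    design: TaskDesign
    intensity: np.ndarray
    gains: np.ndarray                      # (n_channels,) hardware gain 1-8
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    subject_id: str = ""
    timepoint: str = "T0"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.gains = np.asarray(self.gains, dtype=int)
        n_ch = self.montage.n_channels
        if self.intensity.ndim != 3 or self.intensity.shape[1:] != (n_ch, 2):
            raise ConfigurationError(
                f"intensity must be (n_samples, {n_ch}, 2), got {self.intensity.shape}"
            )
        if self.gains.shape != (n_ch,):
            raise ConfigurationError("gains must be one per channel")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def sampling_rate_hz(self) -> float:
        return self.design.sampling_rate_hz


def double_gamma_hrf(
    fs: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalised to 1."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    # shape/scale chosen so each gamma's mode lands at the requested time
    peak = gamma_dist.pdf(t, a=peak_s + 1, scale=1.0)
    under = gamma_dist.pdf(t, a=undershoot_s + 1, scale=1.0)
    h = peak / peak.max() - undershoot_ratio * under / under.max()
    return h / h.max()


def walk_boxcar(design: TaskDesign) -> np.ndarray:
    """Indicator of walking (1 during walk blocks) sampled on the design grid."""
    t = np.arange(design.n_samples) / design.sampling_rate_hz
    box = np.zeros(design.n_samples)
    for onset in design.walk_onsets_s:
        box[(t >= onset) & (t < onset + design.walk_s)] = 1.0
    return box


def _concentration_courses(
    design: TaskDesign, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """(n_samples, n_channels) HbO and HbR courses in uM."""
    box = walk_boxcar(design)
    hrf = double_gamma_hrf(
        design.sampling_rate_hz,
        peak_s=truth.hrf_peak_s,
        undershoot_s=truth.hrf_undershoot_s,
        undershoot_ratio=truth.hrf_undershoot_ratio,
    )
    response = fftconvolve(box, hrf)[: design.n_samples]
    peak = response.max()
    if peak > 0:
        response = response / peak        # plateau ~= injected amplitude
    hbo = np.outer(response, truth.hbo_amp_um)
    hbr = np.outer(response, truth.hbr_amp_um)
    return hbo, hbr


def _noise_realization(
    n_samples: int, n_series: int, fs: float, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """OD-domain noise, one column per channel x wavelength series."""
    t = np.arange(n_samples) / fs
    out = np.zeros((n_samples, n_series))
    for freq, amp in (
        (noise.cardiac_hz, noise.cardiac_amp),
        (noise.respiratory_hz, noise.respiratory_amp),
        (noise.mayer_hz, noise.mayer_amp),
    ):
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, n_series)
            amps = amp * rng.uniform(0.5, 1.5, n_series)
            out += amps * np.sin(2 * np.pi * freq * t[:, None] + phases)
    if noise.drift_step_sd > 0:
        out += np.cumsum(rng.normal(0, noise.drift_step_sd, (n_samples, n_series)), axis=0)
    if noise.white_sd > 0:
        out += rng.normal(0, noise.white_sd, (n_samples, n_series))
    duration_min = n_samples / fs / 60.0
    for rate, mag, width in (
        (noise.spike_rate_per_min, noise.spike_magnitude, True),
        (noise.shift_rate_per_min, noise.shift_magnitude, False),
    ):
        if rate <= 0:
            continue
        for j in range(n_series):
            for _ in range(rng.poisson(rate * duration_min)):
                idx = rng.integers(2, n_samples - 2)
                sign = rng.choice([-1.0, 1.0])
                size = mag * rng.uniform(0.8, 1.5)
                if width:                       # 1-2 sample spike
                    out[idx, j] += sign * size
                    if rng.random() < 0.5:
                        out[idx + 1, j] += sign * size * 0.6
                else:                           # sustained baseline shift
                    out[idx:, j] += sign * size
    return out


def simulate_subject_recording(
    montage: Montage,
    design: TaskDesign,
    ground_truth: GroundTruth,
    noise_model: NoiseModel | None = None,
    seed: int | None = None,
    mbll_params: MBLLParams | None = None,
    i0: float = 1.0,
    subject_id: str = "",
    timepoint: str = "T0",
) -> RawRecording:
    """Forward-simulate one raw recording; pure function of (inputs, seed)."""
    noise_model = noise_model or NoiseModel()
    mbll_params = mbll_params or MBLLParams()
    n_ch = montage.n_channels
    truth_hbo = np.asarray(ground_truth.hbo_amp_um, dtype=float)
    if truth_hbo.shape != (n_ch,):
        raise ConfigurationError(
            f"ground truth has {truth_hbo.shape} amplitudes for {n_ch} channels"
        )
    unknown = set(ground_truth.bad_channels) - set(montage.channel_ids)
    if unknown:
        raise ConfigurationError(f"bad channels not in montage: {sorted(unknown)}")

    rng = np.random.default_rng(ground_truth.seed if seed is None else seed)
    hbo, hbr = _concentration_courses(design, ground_truth)
    od760, od850 = hemoglobin_to_od(hbo, hbr, mbll_params)
    od = np.stack([od760, od850], axis=-1)          # (n, ch, 2)

    n = design.n_samples
    noise = _noise_realization(n, n_ch * 2, design.sampling_rate_hz, noise_model, rng)
    noise = noise.reshape(n, n_ch, 2)

    gains = np.ones(n_ch, dtype=int)
    id_to_idx = {cid: i for i, cid in enumerate(montage.channel_ids)}
    for cid, reasons in ground_truth.bad_channels.items():
        i = id_to_idx[cid]
        if "gain" in reasons:
            gains[i] = 8
        if "snr" in reasons:
            # white noise inflated far past the CV threshold
            noise[:, i, :] += rng.normal(0, 0.25, (n, 2))

    intensity = i0 * np.power(10.0, -(od + noise))
    return RawRecording(
        montage=montage,
        design=design,
        intensity=intensity,
        gains=gains,
        subject_id=subject_id,
        timepoint=timepoint,
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_subject_meta(
    rng: np.random.Generator, subject_id: str, cohort: str, treatment: str,
    timepoints: tuple[str, ...],
) -> SubjectMeta:
    """Clinical covariates from truncated normals centred on the cohort's
    published baseline summaries; T1/T2 apply mild improvement drifts."""
    if cohort == "PwMS":
        speed0 = _truncated_normal(rng, 0.55, 0.30, 0.15, 1.6)
        mwd0 = _truncated_normal(rng, 145.0, 90.0, 30.0, 500.0)
        bbs0 = round(_truncated_normal(rng, 34.0, 13.0, 5.0, 56.0))
        edss = round(_truncated_normal(rng, 6.3, 0.3, 6.0, 7.0) * 2) / 2
        phenotype = "primary progressive" if rng.random() < 0.42 else "secondary progressive"
        age = _truncated_normal(rng, 56.0, 10.0, 25.0, 80.0)
    else:
        speed0 = _truncated_normal(rng, 1.3, 0.2, 0.8, 2.0)
        mwd0 = _truncated_normal(rng, 520.0, 60.0, 350.0, 800.0)
        bbs0 = 56
        edss = None
        phenotype = "none"
        age = _truncated_normal(rng, 50.0, 10.0, 25.0, 80.0)
    speeds, mwds, bbss = {}, {}, {}
    for k, tp in enumerate(timepoints):
        gain = 1.0 + 0.06 * k * rng.uniform(0.0, 2.0) if cohort == "PwMS" else 1.0
        speeds[tp] = speed0 * gain
        mwds[tp] = mwd0 * gain
        bbss[tp] = min(56, round(bbs0 * (1.0 + 0.02 * k)))
    return SubjectMeta(
        subject_id=subject_id,
        cohort=cohort,
        treatment=treatment,
        timepoints=timepoints,
        edss=edss,
        phenotype=phenotype,
        impaired_side="left" if rng.random() < 0.5 else "right",
        age=age,
        sex="M" if rng.random() < 0.55 else "F",
        t25fw_speed=speeds,
        six_mwd=mwds,
        bbs=bbss,
    )


def _draw_channel_amplitudes(
    rng: np.random.Generator, montage: Montage, dist: CohortDistribution,
    maff_hemisphere: str,
) -> np.ndarray:
    base = max(0.05, rng.normal(dist.amp_mean_um, dist.amp_sd_um))
    factors = rng.lognormal(0.0, dist.channel_spread_sigma, montage.n_channels)
    amps = base * factors
    amps[montage.hemisphere_indices(maff_hemisphere)] *= dist.maff_factor
    return amps


def simulate_cohort(
    scenario: ScenarioConfig,
    montage: Montage | None = None,
    design: TaskDesign | None = None,
    mbll_params: MBLLParams | None = None,
) -> tuple[list[RawRecording], list[SubjectMeta], list[GroundTruth]]:
    """Generate one recording per subject per scheduled timepoint.

    PwMS subjects are recorded at ``scenario.pwms_timepoints``; healthy
    controls at T0 only.  Longitudinal effect multipliers scale the whole
    amplitude vector at T1/T2 per treatment arm.
    """
    montage = montage or build_default_montage()
    design = design or TaskDesign()
    rng = np.random.default_rng(scenario.seed)
    noise = NoiseModel(**scenario.noise_overrides) if scenario.noise_overrides else NoiseModel()

    recordings: list[RawRecording] = []
    metas: list[SubjectMeta] = []
    truths: list[GroundTruth] = []

    roster = (
        [("PwMS", "RAGT")] * scenario.n_ragt
        + [("PwMS", "OW")] * scenario.n_ow
        + [("healthy", "none")] * scenario.n_healthy
    )
    for s_idx, (cohort, treatment) in enumerate(roster):
        subject_id = f"{'HC' if cohort == 'healthy' else treatment}{s_idx + 1:03d}"
        timepoints = scenario.pwms_timepoints if cohort == "PwMS" else ("T0",)
        meta = _draw_subject_meta(rng, subject_id, cohort, treatment, timepoints)
        metas.append(meta)
        dist = scenario.pwms if cohort == "PwMS" else scenario.healthy
        from .activation_auc import assign_affected_hemisphere

        maff = assign_affected_hemisphere(meta)["MAff"]
        base_amps = _draw_channel_amplitudes(rng, montage, dist, maff)
        multipliers = scenario.effect_multipliers.get(treatment, {})
        for tp in timepoints:
            mult = multipliers.get(tp, 1.0)
            bad: dict = {}
            if scenario.bad_channel_prob > 0:
                for cid in montage.channel_ids:
                    if rng.random() < scenario.bad_channel_prob:
                        u = rng.random()
                        bad[cid] = (
                            {"gain"} if u < 0.4 else
                            {"snr"} if u < 0.8 else
                            {"gain", "snr"}
                        )
            rec_seed = int(rng.integers(0, 2**31 - 1))
            truth = GroundTruth.from_hbo(
                base_amps * mult, bad_channels=bad, seed=rec_seed
            )
            truths.append(truth)
            recordings.append(
                simulate_subject_recording(
                    montage, design, truth, noise, seed=rec_seed,
                    mbll_params=mbll_params, subject_id=subject_id, timepoint=tp,
                )
            )
    return recordings, metas, truths


def simulate_training_logs(
    metas: list[SubjectMeta], seed: int = 0, n_sessions: int = 12
):
    """Per-session speed / body-weight-support logs for the PwMS subjects.

    Returns a list of :class:`gaitnirs.training_intensity.TrainingLog`.
    """
    from .training_intensity import TrainingLog

    rng = np.random.default_rng(seed)
    logs = []
    for meta in metas:
        if meta.cohort != "PwMS":
            continue
        ref = meta.t25fw_speed.get("T0", 0.5)
        ratio = rng.uniform(0.4, 1.4)
        speeds = np.maximum(0.05, ref * ratio * rng.uniform(0.9, 1.1, n_sessions))
        if meta.treatment == "RAGT":
            bws = np.clip(rng.normal(0.40, 0.10, n_sessions), 0.0, 0.6)
        else:
            bws = np.zeros(n_sessions)
        logs.append(
            TrainingLog(
                subject_id=meta.subject_id,
                treatment=meta.treatment,
                session_speeds=speeds,
                bws_fractions=bws,
                reference_speed=ref,
            )
        )
    return logs
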