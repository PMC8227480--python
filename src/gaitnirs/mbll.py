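"""Modified Beer-Lambert law: raw intensity -> optical-density change ->
oxy-/deoxy-hemoglobin concentration change.

The relation inverted here is

    dOD(lambda) = (eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR) * d * DPF(lambda)

with concentrations in mol/L, separation ``d`` in cm and molar extinction
coefficients in cm^-1 M^-1.  Outputs are reported in micromolar.  The same
parameter object drives the forward model in :mod:`gaitnirs.synthetic_fnirs`,
so simulation/inversion roundtrips are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidSignalError
from .study_model import Montage, TaskDesign

#: Molar extinction coefficients [cm^-1 / (mol/L)], rows = (760 nm, 850 nm),
#: columns = (HbO, HbR).  Values from the standard hemoglobin compilation
#: used throughout continuous-wave NIRS.
DEFAULT_EXTINCTION = np.array(
    [
        [586.0, 1548.52],   # 760 nm
        [1058.0, 691.32],   # 850 nm
    ]
)

DEFAULT_WAVELENGTHS_NM = (760.0, 850.0)


@dataclass
class MBLLParams:
    """Extinction matrix, differential pathlength factors and separation."""

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    separation_cm: float = 3.0
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ConfigurationError("extinction matrix must be 2x2")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        if min(self.dpf) <= 0:
            raise ConfigurationError("DPF must be positive")
        if self.separation_cm <= 0:
            raise ConfigurationError("separation must be positive")

    @property
    def pathlengths_cm(self) -> np.ndarray:
        """Effective pathlength d*DPF per wavelength."""
        return self.separation_cm * np.asarray(self.dpf, dtype=float)


def intensity_to_od(
    intensity: np.ndarray, reference: float, channel: str | None = None
) -> np.ndarray:
    """Optical-density change dOD(t) = log10(reference / I(t)).

    ``reference`` is conventionally the mean intensity over the pre-task
    baseline window (see :func:`baseline_reference`).
    """
    intensity = np.asarray(intensity, dtype=float)
    if reference <= 0:
        raise InvalidSignalError(
            f"non-positive reference intensity{f' on channel {channel}' if channel else ''}"
        )
    if intensity.size and np.nanmin(intensity) <= 0:
        raise InvalidSignalError(
            f"non-positive intensity sample{f' on channel {channel}' if channel else ''}"
        )
    return np.log10(reference / intensity)


def baseline_reference(
    intensity: np.ndarray, design: TaskDesign | None = None
) -> float:
    """Reference intensity: mean over the pre-task baseline window,
    falling back to the whole-recording mean when no baseline exists."""
    intensity = np.asarray(intensity, dtype=float)
    if design is not None and design.baseline_s > 0:
        n = int(round(design.baseline_s * design.sampling_rate_hz))
        n = max(1, min(n, intensity.shape[0]))
        return float(np.mean(intensity[:n]))
    return float(np.mean(intensity))


def od_to_hemoglobin(
    od_760: np.ndarray, od_850: np.ndarray, params: MBLLParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 2x2 MBLL system per sample; returns (dHbO, dHbR) in uM."""
    params = params or MBLLParams()
    od_760 = np.asarray(od_760, dtype=float)
    od_850 = np.asarray(od_850, dtype=float)
    if od_760.shape != od_850.shape:
        raise InvalidSignalError("wavelength series must have equal length")
    pl = params.pathlengths_cm
    rhs = np.stack([od_760 / pl[0], od_850 / pl[1]])       # (2, ...)
    inv = np.linalg.inv(params.extinction)
    conc = np.tensordot(inv, rhs, axes=(1, 0))             # mol/L
    return conc[0] * 1e6, conc[1] * 1e6


def hemoglobin_to_od(
    hbo_um: np.ndarray, hbr_um: np.ndarray, params: MBLLParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL (used by the simulator): concentrations in uM -> dOD."""
    params = params or MBLLParams()
    conc = np.stack([np.asarray(hbo_um, float), np.asarray(hbr_um, float)]) * 1e-6
    od = np.tensordot(params.extinction, conc, axes=(1, 0))  # (2, ...), unit path
    pl = params.pathlengths_cm
    return od[0] * pl[0], od[1] * pl[1]


@dataclass
class HemoRecording:
    """Per-channel hemoglobin concentration changes (uM).

    ``hbo``/``hbr`` are (n_samples, n_channels); columns of excluded
    channels are NaN and flagged False in ``retained``.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    montage: Montage
    design: TaskDesign
    retained: np.ndarray
    subject_id: str = ""
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ConfigurationError("HbO/HbR shapes differ")
        if self.hbo.shape[1] != self.montage.n_channels:
            raise ConfigurationError("channel count mismatch with montage")
        if self.retained.shape != (self.montage.n_channels,):
            raise ConfigurationError("retained mask has wrong shape")
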