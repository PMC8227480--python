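"""Walking-block oxy-Hb AUC biomarker.

Per channel, the AUC of one walk block is the plain sum of the oxy-Hb
samples falling in the half-open window [onset, onset + walk_s); the
channel value is the mean over blocks.  Hemisphere values are sums of the
retained channels' mean AUCs, mapped to the more-affected (MAff, the
hemisphere controlling the more impaired limb, i.e. contralateral to it)
and less-affected (LAff) sides, and the total is their sum — so
Tot = MAff + LAff holds exactly for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidDesignError,
    InvalidInputError,
    InvalidMetadataError,
    InvalidSubjectError,
)
from .mbll import HemoRecording
from .preprocessing import QCReport
from .study_model import Montage, SubjectMeta, TaskDesign

EXPECTED_CHANNELS_PER_HEMI = 24


@dataclass
class ActivationResult:
    """Per-channel block AUCs plus the Tot/MAff/LAff summary triplet (a.u.)."""

    channel_mean_auc: dict                 # channel_id -> mean-of-blocks AUC
    channel_block_auc: dict                # channel_id -> list of per-block AUCs
    maff_oxy_auc: float
    laff_oxy_auc: float
    tot_oxy_auc: float
    affected_mapping: dict                 # {"MAff": hemi, "LAff": hemi}
    retained_per_hemisphere: dict          # hemi -> retained channel count
    rescaled: bool = False
    subject_id: str = ""
    timepoint: str = "T0"


def segment_blocks(
    design: TaskDesign, n_samples: int, fs: float | None = None
) -> list[np.ndarray]:
    """Sample-index windows for the walk blocks.

    One half-open window [onset, onset + walk_s) per cycle, realised as the
    sample indices k with onset <= k/fs < onset + walk_s.
    """
    fs = design.sampling_rate_hz if fs is None else fs
    if design.walk_s <= 0:
        raise InvalidDesignError("walk duration must be positive")
    k = np.arange(n_samples)
    t = k / fs
    windows = []
    for onset in design.walk_onsets_s:
        if onset + design.walk_s > n_samples / fs + 0.5 / fs:
            raise InvalidDesignError(
                f"walk block at {onset:g} s extends past the recording end"
            )
        windows.append(k[(t >= onset) & (t < onset + design.walk_s)])
    return windows


def block_auc(hbo_series: np.ndarray, window: np.ndarray) -> float:
    """Sum of the oxy-Hb samples in one walk window (sign preserved)."""
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise InvalidInputError("empty block window")
    hbo_series = np.asarray(hbo_series, dtype=float)
    if window.min() < 0 or window.max() >= hbo_series.shape[0]:
        raise InvalidInputError("window indices outside the series")
    return float(hbo_series[window].sum())


def mean_block_auc(per_block_aucs) -> float:
    """Arithmetic mean of the per-block AUCs."""
    per_block_aucs = list(per_block_aucs)
    if not per_block_aucs:
        raise InvalidInputError("no block AUCs to average")
    return float(np.mean(per_block_aucs))


def assign_affected_hemisphere(meta: SubjectMeta) -> dict:
    """MAff = hemisphere contralateral to the more impaired limb (dominant
    limb for healthy controls); LAff = the other hemisphere."""
    side = meta.impaired_side
    if side not in ("left", "right"):
        raise InvalidMetadataError(
            f"subject {meta.subject_id}: missing more-impaired/dominant limb side"
        )
    maff = "left" if side == "right" else "right"
    return {"MAff": maff, "LAff": "left" if maff == "right" else "right"}


def aggregate_activation(
    per_channel_aucs: dict,
    montage: Montage,
    mapping: dict,
    qc: QCReport | None = None,
    rescale_missing: bool = False,
    subject_id: str = "",
    timepoint: str = "T0",
    channel_block_auc: dict | None = None,
) -> ActivationResult:
    """Sum retained channels' mean AUCs per hemisphere and form the triplet.

    With ``rescale_missing`` each hemisphere sum is scaled by
    24 / (retained channels in that hemisphere) to compensate for excluded
    channels; default off, matching the all-48-channel reading.
    """
    retained = {
        cid: auc for cid, auc in per_channel_aucs.items()
        if qc is None or qc.channel_status.get(cid) == "retained"
    }
    hemi_sum: dict[str, float] = {}
    hemi_count: dict[str, int] = {}
    for hemi in ("left", "right"):
        ids = [
            montage.channels[i].channel_id
            for i in montage.hemisphere_indices(hemi)
        ]
        vals = [retained[cid] for cid in ids if cid in retained]
        hemi_count[hemi] = len(vals)
        if not vals:
            raise InvalidSubjectError(
                f"subject {subject_id or '?'}: no retained channels on the "
                f"{hemi} hemisphere"
            )
        total = float(np.sum(vals))
        if rescale_missing:
            total *= EXPECTED_CHANNELS_PER_HEMI / len(vals)
        hemi_sum[hemi] = total

    maff = hemi_sum[mapping["MAff"]]
    laff = hemi_sum[mapping["LAff"]]
    return ActivationResult(
        channel_mean_auc=dict(retained),
        channel_block_auc=channel_block_auc or {},
        maff_oxy_auc=maff,
        laff_oxy_auc=laff,
        tot_oxy_auc=maff + laff,
        affected_mapping=dict(mapping),
        retained_per_hemisphere=hemi_count,
        rescaled=rescale_missing,
        subject_id=subject_id,
        timepoint=timepoint,
    )


def compute_activation(
    hemo: HemoRecording,
    meta: SubjectMeta,
    qc: QCReport | None = None,
    rescale_missing: bool = False,
) -> ActivationResult:
    """End-to-end biomarker from a hemoglobin recording: per-channel block
    AUCs, mean over blocks, hemisphere aggregation."""
    windows = segment_blocks(hemo.design, hemo.hbo.shape[0])
    mapping = assign_affected_hemisphere(meta)
    mean_aucs: dict[str, float] = {}
    block_aucs: dict[str, list[float]] = {}
    for i, cid in enumerate(hemo.montage.channel_ids):
        if not hemo.retained[i]:
            continue
        per_block = [block_auc(hemo.hbo[:, i], w) for w in windows]
        block_aucs[cid] = per_block
        mean_aucs[cid] = mean_block_auc(per_block)
    return aggregate_activation(
        mean_aucs,
        hemo.montage,
        mapping,
        qc=qc,
        rescale_missing=rescale_missing,
        subject_id=hemo.subject_id or meta.subject_id,
        timepoint=hemo.timepoint,
        channel_block_auc=block_aucs,
    )
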