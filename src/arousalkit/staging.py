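"""Per-second EEG-vigilance staging from scalp-region band powers.

Each valid 1-s segment gets one of the seven vigilance stages.  The stage
phenomenology is expressed on scalp topography: occipitally dominant alpha
marks relaxed wakefulness (A1), progressive anteriorisation of alpha marks
A2/A3, dominant delta/theta marks drowsiness (B2/3), low-voltage non-alpha
EEG is stage 0 (without slow horizontal eye movements) or B1 (with them),
and sleep graphoelements (spindles, K-complexes) mark sleep onset (C).
Source localisation plays no part here; an anterior/posterior alpha-power
ratio stands in for it, which is the package's largest declared deviation
from the staging tool the published analysis used (see README).

The alpha-dominance threshold adapts to the subject: it is a configured
fraction (default 1/3) of the median posterior alpha power over the
recording's alpha-rich segments, floored for alpha-free recordings.

Decision cascade per segment, first match wins (deeper-stage evidence
dominates):

1. graphoelement annotation          -> C
2. slow-wave dominance + not low-voltage -> B2/3
3. alpha dominance                   -> A1 / A2 / A3 by anteriorisation
4. otherwise                         -> B1 with SEM evidence, else 0
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .core import REGIONS, EEGRecording, StageSequence
from .preprocess import SegmentedRecording
from .spectral import BANDS, window_band_powers

logger = logging.getLogger(__name__)

_BAND_NAMES = tuple(BANDS)
_POSTERIOR = ("parietal", "occipital")
_ANTERIOR = ("frontal", "central")


@dataclass
class SegmentFeatures:
    """Spectral and ocular evidence for one 1-s segment.

    ``roi_power[region][band]`` holds absolute power in uV^2 averaged over
    the region's channels.  ``alpha_anteriorization`` is
    (frontal + central alpha) / (parietal + occipital alpha), None when the
    denominator is zero.
    """

    roi_power: dict
    alpha_anteriorization: float | None
    sem_present: bool
    graphoelement_present: bool

    def roi_mean(self, band: str) -> float:
        return float(np.mean([self.roi_power[r][band] for r in REGIONS]))

    @property
    def posterior_alpha(self) -> float:
        return float(np.mean([self.roi_power[r]["alpha"] for r in _POSTERIOR]))

    @property
    def global_alpha(self) -> float:
        return self.roi_mean("alpha")

    @property
    def total_power(self) -> float:
        return float(sum(self.roi_mean(b) for b in _BAND_NAMES))


@dataclass
class StagingCalibration:
    """Subject-adaptive thresholds (all uV^2 except the ratio)."""

    alpha_threshold: float
    low_voltage_threshold: float
    slow_ratio_threshold: float

    def __post_init__(self) -> None:
        if min(self.alpha_threshold, self.low_voltage_threshold, self.slow_ratio_threshold) <= 0:
            raise ValueError("calibration thresholds must be positive")


class StagingMontageError(KeyError):
    """A channel required for staging features is missing."""


def _region_indices(rec: EEGRecording) -> dict:
    out = {}
    missing = []
    for region, chans in REGIONS.items():
        try:
            out[region] = [rec.channel_index(c) for c in chans]
        except KeyError:
            missing.extend(c for c in chans if not rec.has_channel(c))
    if missing:
        raise StagingMontageError(f"missing staging channels: {sorted(set(missing))}")
    return out


def _batch_roi_powers(segrec: SegmentedRecording) -> dict:
    """region -> (n_segments, n_bands) power arrays for all segments."""
    rec = segrec.recording
    idx = _region_indices(rec)
    blocks = segrec.blocks()
    out = {}
    for region, chans in idx.items():
        bp = window_band_powers(blocks[chans], rec.sfreq)     # ch x seg x band
        out[region] = bp.mean(axis=0)
    return out


def compute_segment_features(segrec: SegmentedRecording, i: int,
                             sem_flags: np.ndarray | None = None,
                             grapho_flags: np.ndarray | None = None) -> SegmentFeatures:
    """Features for segment i: per-region band powers plus ocular/graphoelement flags."""
    rec = segrec.recording
    idx = _region_indices(rec)
    block = segrec.segment(i)
    roi_power = {}
    for region, chans in idx.items():
        bp = window_band_powers(block[chans], rec.sfreq)      # ch x band
        roi_power[region] = dict(zip(_BAND_NAMES, bp.mean(axis=0)))
    ant = sum(roi_power[r]["alpha"] for r in _ANTERIOR)
    post = sum(roi_power[r]["alpha"] for r in _POSTERIOR)
    ratio = ant / post if post > 0 else None
    sem = bool(sem_flags[i]) if sem_flags is not None else False
    grapho = (bool(grapho_flags[i]) if grapho_flags is not None
              else _graphoelement_flags(rec, segrec.n_segments)[i])
    return SegmentFeatures(roi_power, ratio, sem, grapho)


# ---------------------------------------------------------------------------
# Slow eye movements

def detect_sem(rec: EEGRecording, n_segments: int,
               config: PipelineConfig | None = None) -> np.ndarray:
    """Per-segment SEM evidence from the horizontal EOG.

    The HEOG is filtered to 0.1-1 Hz; a segment carries SEM evidence when a
    window of +-2 s around it contains a deflection exceeding the amplitude
    threshold (default 30 uV) for at least the minimum duration (default
    0.5 s).  Without an HEOG channel all segments are False and a warning is
    logged once.
    """
    cfg = config or PipelineConfig.default()
    if not rec.has_channel("HEOG"):
        logger.warning("no HEOG channel: SEM evidence treated as absent")
        return np.zeros(n_segments, dtype=bool)
    x = rec.channel("HEOG")
    sos = signal.butter(2, [0.1, 1.0], btype="bandpass", fs=rec.sfreq, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    sps = int(round(rec.sfreq))
    min_run = int(round(cfg.staging.sem_min_s * rec.sfreq))
    above = np.abs(filt) >= cfg.staging.sem_amp_uv
    # run[j] = length of the run of over-threshold samples ending at j
    c = np.cumsum(above)
    run = c - np.maximum.accumulate(np.where(above, 0, c))
    qualifies = run >= min_run   # a full-length deflection ends at j
    csum = np.concatenate([[0], np.cumsum(qualifies)])
    flags = np.zeros(n_segments, dtype=bool)
    for i in range(n_segments):
        ws = max((i - 2) * sps, 0)
        we = min((i + 3) * sps, len(above))
        lo = min(ws + min_run - 1, we)
        flags[i] = csum[we] - csum[lo] > 0
    return flags


def _graphoelement_flags(rec: EEGRecording, n_segments: int) -> np.ndarray:
    flags = np.zeros(n_segments, dtype=bool)
    for ann in rec.annotations:
        if ann.label not in ("spindle", "k_complex"):
            continue
        first = max(int(np.floor(ann.onset)), 0)
        last = min(int(np.ceil(ann.onset + ann.duration)), n_segments)
        flags[first:last] = True
    return flags


# ---------------------------------------------------------------------------
# Calibration and classification

class CalibrationError(ValueError):
    """Too few valid segments to calibrate the alpha threshold."""


def calibrate(posterior_alpha: np.ndarray, config: PipelineConfig | None = None) -> StagingCalibration:
    """Subject-adaptive alpha threshold from valid-segment posterior alpha.

    Threshold = ``alpha_fraction`` (default 1/3) of the median posterior
    alpha power over segments whose alpha reaches the recording's 25th
    percentile, floored at ``alpha_floor_uv2`` so alpha-free recordings do
    not collapse the threshold onto noise.
    """
    cfg = config or PipelineConfig.default()
    pa = np.asarray(posterior_alpha, dtype=float)
    if pa.size < cfg.staging.min_calibration_segments:
        raise CalibrationError(
            f"{pa.size} valid segments; calibration needs >= "
            f"{cfg.staging.min_calibration_segments}"
        )
    q25 = np.percentile(pa, 25)
    rich = pa[pa >= q25]
    thr = cfg.staging.alpha_fraction * float(np.median(rich))
    return StagingCalibration(
        alpha_threshold=max(thr, cfg.staging.alpha_floor_uv2),
        low_voltage_threshold=cfg.staging.low_voltage_uv2,
        slow_ratio_threshold=cfg.staging.slow_ratio,
    )


def classify_segment(features: SegmentFeatures, calibration: StagingCalibration,
                     config: PipelineConfig | None = None) -> str:
    """Apply the decision cascade to one segment's features."""
    cfg = config or PipelineConfig.default()
    if features.graphoelement_present:
        return "C"
    slow = features.roi_mean("delta") + features.roi_mean("theta")
    alpha = features.roi_mean("alpha")
    if (slow > calibration.slow_ratio_threshold * alpha
            and features.total_power > calibration.low_voltage_threshold):
        return "B2/3"
    if (features.posterior_alpha > calibration.alpha_threshold
            or features.global_alpha > calibration.alpha_threshold):
        r = features.alpha_anteriorization
        if r is not None:
            if r < cfg.staging.a1_max:
                return "A1"
            if r > cfg.staging.a3_min:
                return "A3"
            return "A2"
        # undefined ratio (zero posterior alpha) falls through
    return "B1" if features.sem_present else "0"


def stage_recording(segrec: SegmentedRecording,
                    config: PipelineConfig | None = None) -> StageSequence:
    """Stage every valid segment of a preprocessed, segmented recording.

    Deterministic for identical input and configuration.  Invalid segments
    carry no stage.  Raises on a missing staging montage or on too few valid
    segments for calibration.
    """
    cfg = config or PipelineConfig.default()
    rec = segrec.recording
    valid = segrec.valid
    n_seg = segrec.n_segments
    if not valid.any():
        warnings.warn("all segments invalid: empty staged sequence", stacklevel=2)
        return StageSequence(np.full(n_seg, -1, dtype=np.int8), np.zeros(n_seg, dtype=bool))
    roi = _batch_roi_powers(segrec)                 # region -> (n_seg, n_band)
    alpha_j = _BAND_NAMES.index("alpha")
    posterior_alpha = np.mean([roi[r][:, alpha_j] for r in _POSTERIOR], axis=0)
    calib = calibrate(posterior_alpha[valid], cfg)
    sem_flags = detect_sem(rec, n_seg, cfg)
    grapho_flags = _graphoelement_flags(rec, n_seg)

    labels: list = []
    for i in range(n_seg):
        if not valid[i]:
            labels.append(None)
            continue
        feats = SegmentFeatures(
            roi_power={r: dict(zip(_BAND_NAMES, roi[r][i])) for r in REGIONS},
            alpha_anteriorization=_ratio(roi, i, alpha_j),
            sem_present=bool(sem_flags[i]),
            graphoelement_present=bool(grapho_flags[i]),
        )
        labels.append(classify_segment(feats, calib, cfg))
    return StageSequence.from_labels(labels, valid)


def _ratio(roi: dict, i: int, alpha_j: int) -> float | None:
    ant = sum(roi[r][i, alpha_j] for r in _ANTERIOR)
    post = sum(roi[r][i, alpha_j] for r in _POSTERIOR)
    return ant / post if post > 0 else None
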