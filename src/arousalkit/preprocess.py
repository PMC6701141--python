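"""Filtering, referencing, 1-s segmentation and automatic artifact masking.

The published pipeline band-passed 0.5-70 Hz with a 50 Hz notch, re-referenced
to common average, cut the recording into continuous 1-s segments, and
excluded manually marked artifact spans; ocular/cardiac components were
removed by ICA in commercial software.  Here the manual marking is replaced
by explicit amplitude rules (configurable peak-to-peak ceiling and flat-line
floor) applied on top of any artifact annotations carried by the recording,
and the ICA step by an optional deterministic least-squares EOG regression.
Filters are zero-phase (forward-backward) so segment boundaries are not
phase-shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .core import EOG_LABELS, AnnotationSpan, EEGRecording


def filter_recording(rec: EEGRecording, low_hz: float = 0.5, high_hz: float = 70.0,
                     notch_hz: float | None = 50.0,
                     eog_low_hz: float | None = None) -> EEGRecording:
    """Zero-phase band-pass plus notch on all channels.

    EOG channels receive the same band-pass unless ``eog_low_hz`` gives them
    a lower high-pass edge (slow eye movements live below 0.5 Hz).  Set
    ``notch_hz`` to None to skip the notch.
    """
    nyq = rec.sfreq / 2
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    eog_idx = [i for i, c in enumerate(rec.channel_labels) if c in EOG_LABELS]
    if eog_idx and eog_low_hz is not None and eog_low_hz != low_hz:
        sos_eog = signal.butter(
            4, [eog_low_hz, high_hz], btype="bandpass", fs=rec.sfreq, output="sos"
        )
        data[eog_idx] = signal.sosfiltfilt(sos_eog, rec.data[eog_idx], axis=1)
    if notch_hz is not None and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=rec.sfreq)
        data = signal.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data=data)


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample mean of the EEG channels from each EEG channel.

    EOG channels are excluded from the average and left untouched.
    Idempotent: re-applying changes nothing.
    """
    eeg_idx = [i for i, c in enumerate(rec.channel_labels) if c not in EOG_LABELS]
    if len(eeg_idx) < 2:
        raise ValueError("common average reference needs >= 2 EEG channels")
    data = rec.data.copy()
    avg = data[eeg_idx].mean(axis=0)
    data[eeg_idx] -= avg
    return rec.copy_with(data=data, reference="car")


def regress_eog(rec: EEGRecording) -> EEGRecording:
    """Subtract the least-squares projection of HEOG/VEOG from each EEG channel.

    A deterministic stand-in for component-based ocular correction; channels
    without EOG coverage are returned unchanged.
    """
    eog_idx = [i for i, c in enumerate(rec.channel_labels) if c in EOG_LABELS]
    if not eog_idx:
        return rec
    eeg_idx = [i for i, c in enumerate(rec.channel_labels) if c not in EOG_LABELS]
    data = rec.data.copy()
    E = data[eog_idx].T                      # samples x n_eog
    E = E - E.mean(axis=0)
    coef, *_ = np.linalg.lstsq(E, data[eeg_idx].T, rcond=None)
    data[eeg_idx] -= (E @ coef).T
    return rec.copy_with(data=data)


@dataclass
class SegmentedRecording:
    """1-s segmentation of a recording with a validity mask."""

    recording: EEGRecording
    valid: np.ndarray = field(repr=False)     # (n_segments,) bool

    @property
    def n_segments(self) -> int:
        return len(self.valid)

    @property
    def samples_per_segment(self) -> int:
        return int(round(self.recording.sfreq))

    def segment(self, i: int) -> np.ndarray:
        """Channel x sample block of segment i (the interval [i, i+1) s)."""
        sps = self.samples_per_segment
        return self.recording.data[:, i * sps:(i + 1) * sps]

    def blocks(self) -> np.ndarray:
        """(n_channels, n_segments, samples_per_segment) view of all segments."""
        sps = self.samples_per_segment
        n = self.n_segments
        return self.recording.data[:, : n * sps].reshape(
            self.recording.n_channels, n, sps
        )


def segment_and_mask(rec: EEGRecording, config: PipelineConfig | None = None) -> SegmentedRecording:
    """Cut into 1-s segments and mask artifacts.

    A segment is invalid when it overlaps an ``artifact`` annotation, when
    any EEG channel's peak-to-peak amplitude exceeds the configured ceiling
    (default 200 uV), or when any EEG channel is flat (peak-to-peak below
    0.5 uV).  Graphoelement annotations (spindle, K-complex) do not
    invalidate segments.  Masking is monotone in the annotation set: adding
    an artifact can only invalidate further segments.
    """
    cfg = config or PipelineConfig.default()
    n_seg = int(rec.duration_s)
    if n_seg < 1:
        raise ValueError("recording shorter than 1 s cannot be segmented")
    sps = int(round(rec.sfreq))
    eeg_idx = [i for i, c in enumerate(rec.channel_labels) if c not in EOG_LABELS]
    blocks = rec.data[eeg_idx, : n_seg * sps].reshape(len(eeg_idx), n_seg, sps)
    pp = blocks.max(axis=2) - blocks.min(axis=2)   # channels x segments
    valid = ~(
        np.any(pp > cfg.artifact.pp_max_uv, axis=0)
        | np.any(pp < cfg.artifact.flat_min_uv, axis=0)
    )
    for ann in rec.annotations:
        if ann.label != "artifact":
            continue
        first = max(int(np.floor(ann.onset)), 0)
        last = min(int(np.ceil(ann.onset + ann.duration)), n_seg)
        valid[first:last] = False
    return SegmentedRecording(recording=rec, valid=valid)


def preprocess(rec: EEGRecording, config: PipelineConfig | None = None) -> SegmentedRecording:
    """Standard chain: band-pass/notch, optional EOG regression, common
    average reference, segmentation with artifact masking."""
    cfg = config or PipelineConfig.default()
    notch = cfg.filter.notch_hz if cfg.filter.notch_hz and cfg.filter.notch_hz < rec.sfreq / 2 else None
    out = filter_recording(rec, cfg.filter.low_hz, cfg.filter.high_hz, notch,
                           eog_low_hz=cfg.filter.eog_low_hz)
    if cfg.preprocess.eog_regression:
        out = regress_eog(out)
    out = rereference_common_average(out)
    return segment_and_mask(out, cfg)
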