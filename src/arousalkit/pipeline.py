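"""End-to-end convenience chains: raw EEG -> stages -> stability score."""

from __future__ import annotations

from .config import PipelineConfig
from .core import EEGRecording, StageSequence
from .preprocess import preprocess
from .stability import StabilityScore, VigilanceTimeCourse, mean_vigilance_timecourse, stability_score
from .staging import stage_recording


def stage_eeg(rec: EEGRecording, config: PipelineConfig | None = None) -> StageSequence:
    """Preprocess a raw recording and stage every valid 1-s segment."""
    cfg = config or PipelineConfig.default()
    return stage_recording(preprocess(rec, cfg), cfg)


def score_eeg(rec: EEGRecording, config: PipelineConfig | None = None
              ) -> tuple[StabilityScore, VigilanceTimeCourse, StageSequence]:
    """Full chain: preprocess, stage, stability score and vigilance time course."""
    cfg = config or PipelineConfig.default()
    seq = stage_eeg(rec, cfg)
    return stability_score(seq, cfg), mean_vigilance_timecourse(seq), seq
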