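"""Shared domain types: recordings, annotations, stages and stage sequences.

EEG-vigilance is described on a seven-stage scale ordered by arousal level,
from cognitively active wakefulness (stage 0) through relaxed wakefulness with
progressively anteriorised alpha (A1, A2, A3) and drowsiness (B1, B2/3) to
sleep onset (C).  One stage is assigned per 1-s segment of a resting
eyes-closed recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Stages ordered from highest arousal (0) to lowest (C).
STAGES: tuple[str, ...] = ("0", "A1", "A2", "A3", "B1", "B2/3", "C")

#: Numeric vigilance value used for the mean EEG-vigilance time course
#: (higher = more aroused).
STAGE_VALUE: dict[str, int] = {
    "0": 7, "A1": 6, "A2": 5, "A3": 4, "B1": 3, "B2/3": 2, "C": 1,
}

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Scalp regions used for band-power averaging and for staging features.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4", "FZ"),
    "central": ("C3", "C4", "CZ"),
    "parietal": ("P3", "P4", "PZ"),
    "occipital": ("O1", "O2"),
}

EOG_LABELS: tuple[str, ...] = ("HEOG", "VEOG")

ANNOTATION_LABELS = ("artifact", "k_complex", "spindle")


def normalize_channel_label(label: str) -> str:
    """Map a channel name onto its canonical upper-case 10-20 form.

    Idempotent: ``normalize_channel_label(normalize_channel_label(x)) == x``.
    """
    return label.strip().upper()


@dataclass
class AnnotationSpan:
    """A labelled time span: an artifact or a sleep graphoelement."""

    onset: float          # seconds from recording start
    duration: float       # seconds, > 0
    label: str            # artifact | k_complex | spindle | other:<text>

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"annotation onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"annotation duration must be > 0, got {self.duration}")
        if self.label not in ANNOTATION_LABELS and not self.label.startswith("other:"):
            raise ValueError(f"unknown annotation label {self.label!r}")

    def overlaps(self, start: float, stop: float) -> bool:
        """True when the span intersects the half-open interval [start, stop)."""
        return self.onset < stop and self.onset + self.duration > start


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts with optional annotations.

    ``data`` has shape (n_channels, n_samples); all channels share one
    sampling rate.  ``reference`` is a free tag recording the referencing
    scheme (e.g. "linked", "car").
    """

    channel_labels: list[str]
    sfreq: float
    data: np.ndarray
    reference: str = "unknown"
    annotations: list[AnnotationSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        self.channel_labels = [normalize_channel_label(c) for c in self.channel_labels]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in EOG_LABELS]

    def channel_index(self, label: str) -> int:
        label = normalize_channel_label(label)
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def has_channel(self, label: str) -> bool:
        return normalize_channel_label(label) in self.channel_labels

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        out.annotations = list(out.annotations)
        return out


class StageSequence:
    """Per-second EEG-vigilance stages with a validity mask.

    Seconds invalidated by artifacts carry no stage.  Internally stages are
    stored as int8 codes into :data:`STAGES`, -1 for "no stage".
    """

    def __init__(self, codes: np.ndarray, valid: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        valid = np.asarray(valid, dtype=bool)
        if codes.shape != valid.shape or codes.ndim != 1:
            raise ValueError("codes and valid must be 1-D arrays of equal length")
        if codes.size == 0:
            raise ValueError("empty stage sequence")
        if np.any((codes < -1) | (codes >= len(STAGES))):
            raise ValueError("stage codes out of range")
        if np.any(valid & (codes < 0)):
            raise ValueError("valid seconds must carry a stage")
        self.codes = codes
        self.valid = valid

    @classmethod
    def from_labels(cls, labels, valid=None) -> "StageSequence":
        """Build from stage tokens; ``None``/"" entries are invalid seconds."""
        codes = np.empty(len(labels), dtype=np.int8)
        implied_valid = np.ones(len(labels), dtype=bool)
        for i, lab in enumerate(labels):
            if lab is None or lab == "":
                codes[i] = -1
                implied_valid[i] = False
            else:
                try:
                    codes[i] = STAGE_INDEX[lab]
                except KeyError:
                    raise ValueError(f"unknown stage token {lab!r} at second {i}") from None
        if valid is None:
            valid = implied_valid
        else:
            valid = np.asarray(valid, dtype=bool) & implied_valid
        return cls(codes, valid)

    def labels(self) -> list:
        return [STAGES[c] if c >= 0 else None for c in self.codes]

    def __len__(self) -> int:
        return self.codes.size

    @property
    def duration_s(self) -> int:
        return len(self)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def values(self) -> np.ndarray:
        """Numeric vigilance values (7..1); NaN where invalid."""
        table = np.array([STAGE_VALUE[s] for s in STAGES], dtype=float)
        out = np.full(len(self), np.nan)
        out[self.valid] = table[self.codes[self.valid]]
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, StageSequence):
            return NotImplemented
        return (
            np.array_equal(self.valid, other.valid)
            and np.array_equal(self.codes[self.valid], other.codes[other.valid])
        )

    def __repr__(self) -> str:
        return f"StageSequence({len(self)} s, {self.n_valid} valid)"
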