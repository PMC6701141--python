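"""Test utilities: fixture writers and sequence builders (synthetic only)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from arousalkit.core import StageSequence, STAGE_INDEX


def write_brainvision(path_vhdr: Path, labels, sfreq: float, data_uv: np.ndarray) -> None:
    """Write a minimal synthetic BrainVision triplet (float32 multiplexed).

    Only used to generate reader fixtures at test time; the package itself
    treats BrainVision as read-only.
    """
    path_vhdr = Path(path_vhdr)
    stem = path_vhdr.stem
    eeg_name, vmrk_name = f"{stem}.eeg", f"{stem}.vmrk"
    interval_us = 1e6 / sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(labels)}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    path_vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    (path_vhdr.parent / vmrk_name).write_text("\n".join(marker) + "\n", encoding="utf-8")
    np.asarray(data_uv, dtype="<f4").T.tofile(path_vhdr.parent / eeg_name)


def seq_from_spans(spans, valid=None) -> StageSequence:
    """Build a stage sequence from (stage, n_seconds) spans."""
    labels = []
    for stage, n in spans:
        labels.extend([stage] * n)
    return StageSequence.from_labels(labels, valid)


def constant_seq(stage: str, n: int) -> StageSequence:
    return seq_from_spans([(stage, n)])


def random_stage_sequence(rng: np.random.Generator) -> StageSequence:
    """Random sequences mixing iid stages, long dwells and partial validity."""
    n = int(rng.integers(300, 901))
    style = int(rng.integers(0, 3))
    if style == 0:
        codes = rng.integers(0, 7, n)
    elif style == 1:
        codes = []
        while len(codes) < n:
            codes.extend([int(rng.integers(0, 7))] * int(rng.integers(5, 120)))
        codes = np.array(codes[:n])
    else:  # staircase decline
        step = int(rng.integers(30, 200))
        codes = np.minimum(np.arange(n) // step + int(rng.integers(0, 3)), 6)
    valid = rng.random(n) > rng.uniform(0, 0.3)
    if valid.sum() < 300:
        valid = np.ones(n, dtype=bool)
    return StageSequence(np.asarray(codes, dtype=np.int8), valid)
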