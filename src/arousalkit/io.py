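"""Reading and writing: EEG (EDF, BrainVision), stage sequences, cohorts.

EDF is the canonical on-disk EEG format (the synthetic generator writes it);
BrainVision (.vhdr/.eeg/.vmrk) is supported read-only.  Reading goes through
MNE.  Writing uses a minimal 16-bit EDF encoder implemented here; its output
is round-trip checked against the MNE reader in the test suite.  Annotations
travel in a plain-text CSV sidecar (``<stem>_annotations.csv``) with columns
onset, duration, label.

Stage sequences are CSVs with columns ``second_index`` (0-based, each row
covering the half-open interval [i, i+1) seconds), ``stage`` (one of
0, A1, A2, A3, B1, B2/3, C; empty for invalid seconds) and ``valid`` (0/1).
Cohort tables are typed CSVs with one row per subject; missing cells stay
missing and are never imputed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationSpan, EEGRecording, StageSequence, normalize_channel_label

# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, rec: EEGRecording) -> None:
    """Minimal EDF encoder: 16-bit, one 1-s data record per second."""
    sps = int(round(rec.sfreq))
    if abs(rec.sfreq - sps) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = rec.n_samples // sps
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * sps]
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.0001, 1.0)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X", 80),
        _edf_field("X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field("1", 8),
        _edf_field(ns, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
        b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(sps, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    records = digital.reshape(ns, n_records, sps).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())


def _annotation_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + "_annotations.csv")


def write_annotations(annotations, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset", "duration", "label"])
        for ann in annotations:
            writer.writerow([f"{ann.onset:.6g}", f"{ann.duration:.6g}", ann.label])


def read_annotations(path) -> list:
    out = []
    with open(Path(path), newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(AnnotationSpan(float(row["onset"]), float(row["duration"]),
                                      row["label"]))
    return out


def write_eeg(rec: EEGRecording, path) -> None:
    """Write a recording as EDF plus (if any) an annotation CSV sidecar."""
    path = Path(path)
    _write_edf(path, rec)
    if rec.annotations:
        write_annotations(rec.annotations, _annotation_sidecar(path))


def _map_native_annotation(description: str) -> str:
    d = description.lower()
    if "artifact" in d or "artefact" in d or d.startswith("bad"):
        return "artifact"
    if "spindle" in d:
        return "spindle"
    if "k-complex" in d or "k_complex" in d or "kcomplex" in d:
        return "k_complex"
    return f"other:{description}"


def read_eeg(path, format_hint: str | None = None) -> EEGRecording:
    """Read an EDF file or a BrainVision triplet (via its .vhdr header).

    Channel labels are normalised to upper-case 10-20 names; data are
    returned in microvolts.  Format-native markers and any annotation CSV
    sidecar are carried over.  A missing required channel is not an error
    here; downstream operations enforce their own montage needs.
    """
    import mne

    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        reader = mne.io.read_raw_edf
    elif fmt in ("vhdr", "brainvision"):
        reader = mne.io.read_raw_brainvision
    else:
        raise ValueError(f"unsupported EEG format {fmt!r} for {path.name}")
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise OSError(f"could not read {path} as {fmt}: {exc}") from exc

    data = raw.get_data() * 1e6  # volts -> microvolts
    annotations = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if duration <= 0:
            duration = 1e-3
        annotations.append(AnnotationSpan(max(float(onset), 0.0), float(duration),
                                          _map_native_annotation(str(desc))))
    sidecar = _annotation_sidecar(path)
    if sidecar.exists():
        annotations.extend(read_annotations(sidecar))
    return EEGRecording(
        channel_labels=[normalize_channel_label(c) for c in raw.ch_names],
        sfreq=float(raw.info["sfreq"]),
        data=data,
        reference="unknown",
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Stage sequences


def write_stage_sequence(seq: StageSequence, path) -> None:
    labels = seq.labels()
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["second_index", "stage", "valid"])
        for i in range(len(seq)):
            writer.writerow([i, labels[i] or "", int(seq.valid[i])])


def read_stage_sequence(path) -> StageSequence:
    """Exact inverse of :func:`write_stage_sequence`."""
    labels, valid = [], []
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader):
            idx = int(row["second_index"])
            if idx != lineno:
                raise ValueError(
                    f"second_index must increase by 1 from 0; row {lineno} has {idx}"
                )
            stage = row["stage"].strip()
            labels.append(stage or None)
            valid.append(bool(int(row["valid"])))
    if not labels:
        raise ValueError("empty stage sequence")
    try:
        return StageSequence.from_labels(labels, valid)
    except ValueError as exc:
        raise ValueError(f"{exc} in {path}") from exc


# ---------------------------------------------------------------------------
# Cohort tables

_COHORT_NUMERIC = (
    "stability_score", "age", "sleep_hours", "bdi",
    "caars_dsm_ia", "caars_dsm_hyi", "caars_dsm_g",
    "asrs_a_cutoff", "asrs_a_sum", "asrs_b_cutoff", "asrs_b_sum", "wursk",
)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(Path(path), index=False)


def read_cohort(path) -> pd.DataFrame:
    """Typed cohort table; missing cells stay missing (NaN).

    Raises on duplicate subject ids and on non-numeric entries in numeric
    columns; warns on T-scores outside the plausible [20, 120] range.
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("cohort table needs a subject_id column")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id values: {dupes}")
    numeric = [c for c in df.columns
               if c in _COHORT_NUMERIC or any(
                   c.startswith(b + "_") for b in ("delta", "theta", "alpha", "beta"))]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not numeric: {exc}") from exc
    if "bdi" in df.columns and (df["bdi"].dropna() < 0).any():
        raise ValueError("BDI scores must be >= 0")
    import warnings

    for col in ("caars_dsm_ia", "caars_dsm_hyi", "caars_dsm_g"):
        if col in df.columns:
            vals = df[col].dropna()
            if len(vals) and ((vals < 20) | (vals > 120)).any():
                warnings.warn(f"{col}: T-scores outside plausible range [20, 120]",
                              stacklevel=2)
    return df
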