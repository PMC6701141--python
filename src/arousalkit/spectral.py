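"""Absolute band-power analysis of the full recording.

The recording is down-sampled to 256 Hz, cut into the same non-overlapping
1-s windows used for staging, Hanning-tapered, and transformed.  Each 1-s
window is zero-padded to 2 s so the bin spacing is 0.5 Hz (a stated
resolution of 0.5 Hz is not attainable from an unpadded 1-s window; the
padding is a config switch for sensitivity checks).  Band powers are the sum
over bins whose centre frequency lies inside the band, normalised so that a
sinusoid of amplitude a at an in-band integer frequency contributes its true
power a^2/2 (the Hanning window energy is compensated exactly, which makes
the Parseval check in the tests exact up to leakage).

Band limits (Hz): delta 1-3, theta 4-7, alpha 8-12, beta 13-30.  Window
powers are averaged per channel, channels averaged per region, and the
region averages ln-transformed last.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .config import PipelineConfig
from .core import REGIONS, EEGRecording

#: Band limits in Hz, inclusive on both edges at the analysis bin spacing.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

TARGET_SFREQ = 256.0


def resample_256(rec: EEGRecording) -> EEGRecording:
    """Down-sample all channels to 256 Hz with anti-alias filtering.

    Rates below 256 Hz are refused (no upsampling); 256 Hz input is returned
    unchanged.
    """
    if rec.sfreq < TARGET_SFREQ:
        raise ValueError(f"sampling rate {rec.sfreq} Hz is below 256 Hz; will not upsample")
    if rec.sfreq == TARGET_SFREQ:
        return rec
    ratio = Fraction(TARGET_SFREQ / rec.sfreq).limit_denominator(1000)
    data = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return rec.copy_with(data=data, sfreq=TARGET_SFREQ)


def window_band_powers(windows: np.ndarray, sfreq: float, zero_pad: bool = True,
                       bands: dict | None = None) -> np.ndarray:
    """Band powers for a batch of 1-s windows.

    ``windows`` has shape (..., n_samples) with n_samples = sfreq; returns
    powers with shape (..., n_bands) in band order.  Callers needing the
    Parseval residual use :func:`_band_power_detail`.
    """
    powers, _, _ = _band_power_detail(windows, sfreq, zero_pad, bands)
    return powers


def _band_power_detail(windows, sfreq, zero_pad=True, bands=None):
    bands = bands or BANDS
    x = np.asarray(windows, dtype=float)
    n = x.shape[-1]
    if n != int(round(sfreq)):
        raise ValueError(f"expected 1-s windows of {int(sfreq)} samples, got {n}")
    w = signal.get_window("hann", n, fftbins=True)
    n_fft = 2 * n if zero_pad else n
    spec = np.fft.rfft(x * w, n=n_fft, axis=-1)
    # One-sided power normalised by window energy: a sinusoid of amplitude a
    # at an in-band frequency sums to a^2 / 2 across its bins.
    p = np.abs(spec) ** 2
    mult = np.full(p.shape[-1], 2.0)
    mult[0] = 1.0
    if n_fft % 2 == 0:
        mult[-1] = 1.0
    p = p * mult / (n_fft * np.sum(w**2))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    band_powers = np.empty(x.shape[:-1] + (len(bands),))
    covered = np.zeros(freqs.shape, dtype=bool)
    for j, (lo, hi) in enumerate(bands.values()):
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        covered |= mask
        band_powers[..., j] = p[..., mask].sum(axis=-1)
    out_of_band = p[..., ~covered].sum(axis=-1)
    total = p.sum(axis=-1)
    return band_powers, out_of_band, total


def band_powers(rec: EEGRecording, validity_mask: np.ndarray | None = None,
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """Region x band ln absolute power table for one subject.

    The recording must be at 256 Hz.  ``validity_mask`` marks the 1-s windows
    to include (shared with the staging segmentation); at least the
    configured minimum number of valid windows (default 30) is required.
    Returns a DataFrame indexed by region with one column per band, values
    in ln uV^2.
    """
    cfg = config or PipelineConfig.default()
    if rec.sfreq != TARGET_SFREQ:
        raise ValueError("band_powers expects a 256 Hz recording; call resample_256 first")
    n_sec = int(rec.n_samples // int(TARGET_SFREQ))
    if validity_mask is None:
        validity_mask = np.ones(n_sec, dtype=bool)
    validity_mask = np.asarray(validity_mask, dtype=bool)
    if len(validity_mask) != n_sec:
        raise ValueError("validity mask length must equal the number of 1-s windows")
    if validity_mask.sum() < cfg.spectral.min_windows:
        raise ValueError(
            f"only {int(validity_mask.sum())} valid windows; "
            f"need >= {cfg.spectral.min_windows}"
        )
    missing = [r for r, chans in REGIONS.items()
               if any(not rec.has_channel(c) for c in chans)]
    if missing:
        raise KeyError(f"regions with missing channels: {missing}")

    n = int(TARGET_SFREQ)
    rows = {}
    for region, chans in REGIONS.items():
        idx = [rec.channel_index(c) for c in chans]
        blocks = rec.data[idx, : n_sec * n].reshape(len(idx), n_sec, n)
        blocks = blocks[:, validity_mask, :]
        bp = window_band_powers(blocks, TARGET_SFREQ, cfg.spectral.zero_pad)
        # average over windows, then channels, ln last
        mean_power = bp.mean(axis=1).mean(axis=0)
        if np.any(mean_power <= 0):
            raise FloatingPointError(f"non-positive average band power in region {region}")
        rows[region] = np.log(mean_power)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BANDS))


def band_power_columns(table: pd.DataFrame) -> dict[str, float]:
    """Flatten a region x band table to '{band}_{region}' keys."""
    return {
        f"{band}_{region}": float(table.loc[region, band])
        for band in table.columns for region in table.index
    }


def group_power_contrast(power_table: pd.DataFrame, groups,
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per region x band two-group contrast of subject ln powers.

    ``power_table`` has one row per subject with '{band}_{region}' columns;
    ``groups`` is an aligned iterable of 'unstable'/'stable' labels.  Sign
    convention: t = unstable - stable.  Returns t, df, p and Cohen's d per
    region x band.
    """
    from .stats import GroupSummary, cohens_d, pooled_t, welch_t

    cfg = config or PipelineConfig.default()
    groups = np.asarray(list(groups))
    rows = []
    for band in BANDS:
        for region in REGIONS:
            col = f"{band}_{region}"
            x1 = power_table.loc[groups == "unstable", col].dropna().to_numpy()
            x2 = power_table.loc[groups == "stable", col].dropna().to_numpy()
            if len(x1) < 2 or len(x2) < 2:
                raise ValueError(f"degenerate group for {col}")
            s = GroupSummary.from_values(x1, x2)
            v1, v2 = s.sd1**2, s.sd2**2
            use_welch = min(v1, v2) > 0 and max(v1, v2) / min(v1, v2) > cfg.stats.welch_variance_ratio
            res = welch_t(s) if use_welch else pooled_t(s)
            rows.append({
                "band": band, "region": region, "t": res["t"], "df": res["df"],
                "p": res["p"], "cohens_d": cohens_d(s) if s.sd1 + s.sd2 > 0 else math.nan,
            })
    return pd.DataFrame(rows)
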