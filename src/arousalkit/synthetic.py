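"""Synthetic inputs: stage trajectories, raw EEG realising them, and cohorts.

Three generators cover everything the pipeline consumes:

* :func:`simulate_stage_sequence` -- a first-order Markov walk over the
  ordered vigilance stages with direction-biased transition rates; the
  simplest process that produces the monotone arousal declines the stability
  score was built to grade, with controllable steepness.  It returns the
  sequence together with the ground-truth stability score evaluated by the
  literal rule evaluator, so classifier round-trips can be checked.

* :func:`synthesize_eeg` -- raw multichannel EEG realising a stage sequence
  from per-stage spectral recipes (band-limited noise with stage-typical
  region weights: occipitally dominant alpha for A1, anteriorised alpha for
  A2/A3, dominant delta/theta for B2/3, low-voltage broadband for 0/B1),
  slow-eye-movement waveforms in the horizontal EOG during B1, and
  spindle/K-complex annotations during C.  No physiological detail beyond
  that (no 1/f calibration, no ECG).

* :func:`simulate_cohort` -- subject-level tables with the published group
  structure: per-group stability-score, questionnaire, demographic and ln
  band-power distributions parameterised from the embedded reference
  summaries.  Group labels come from the pipeline's own median split on the
  drawn scores.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from . import reference_values as ref
from .config import PipelineConfig
from .core import REGIONS, AnnotationSpan, EEGRecording, StageSequence, STAGES
from .stability import CoverageError, StabilityScore, stability_score_bruteforce

# ---------------------------------------------------------------------------
# Stage trajectories


@dataclass
class TrajectoryParams:
    """Markov-walk parameters for a per-second stage trajectory.

    ``decline_rate``/``recovery_rate`` are per-second probabilities of moving
    one stage down (toward C) / up (toward 0).  ``sem_rate`` is the chance a
    B1 second carries a slow-eye-movement waveform; ``graphoelement_rate``
    the chance a C second carries a tagged spindle or K-complex.
    """

    decline_rate: float = 0.01
    recovery_rate: float = 0.003
    start_stage: str = "A1"
    sem_rate: float = 0.9
    graphoelement_rate: float = 0.9
    duration_s: int = 900

    def __post_init__(self) -> None:
        for p in (self.decline_rate, self.recovery_rate, self.sem_rate,
                  self.graphoelement_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.decline_rate + self.recovery_rate > 1:
            raise ValueError("decline_rate + recovery_rate must be <= 1")
        if self.duration_s < 60:
            raise ValueError("duration must be >= 60 s")
        if self.start_stage not in STAGES:
            raise ValueError(f"unknown start stage {self.start_stage!r}")

    @classmethod
    def unstable(cls, **kw) -> "TrajectoryParams":
        """Rapid arousal decline: reaches B2/3 or C within the recording."""
        return cls(decline_rate=0.025, recovery_rate=0.004, **kw)

    @classmethod
    def stable(cls, **kw) -> "TrajectoryParams":
        """Sustained wakefulness: recovery-biased walk staying in 0/A stages."""
        return cls(decline_rate=0.005, recovery_rate=0.02, **kw)

    @classmethod
    def random_subject(cls, rng: np.random.Generator, **kw) -> "TrajectoryParams":
        """Decline-dominant parameters spanning the full score range."""
        decline = 10 ** rng.uniform(math.log10(0.003), math.log10(0.03))
        recovery = decline * rng.uniform(0.05, 0.4)
        return cls(decline_rate=decline, recovery_rate=recovery, **kw)


@dataclass
class SimulatedTrajectory:
    """A simulated sequence with its analytic ground truth and ocular events."""

    sequence: StageSequence
    true_score: StabilityScore
    sem_onsets: list        # seconds where a SEM waveform starts (B1 spans)
    graphoelements: list    # AnnotationSpan (spindle / k_complex) in C spans


def simulate_stage_sequence(params: TrajectoryParams,
                            rng: np.random.Generator) -> SimulatedTrajectory:
    """Markov walk over the seven ordered stages.

    The ground-truth stability score is evaluated on the emitted sequence by
    the brute-force rule evaluator, independent of the staging classifier.
    """
    order = list(STAGES)
    idx = order.index(params.start_stage)
    codes = np.empty(params.duration_s, dtype=np.int8)
    moves = rng.random(params.duration_s)
    for t in range(params.duration_s):
        codes[t] = idx
        if moves[t] < params.decline_rate:
            idx = min(idx + 1, len(order) - 1)
        elif moves[t] < params.decline_rate + params.recovery_rate:
            idx = max(idx - 1, 0)
    seq = StageSequence(codes, np.ones(params.duration_s, dtype=bool))

    sem_onsets = []
    graphoelements = []
    b1 = order.index("B1")
    c = order.index("C")
    for t in range(params.duration_s):
        if codes[t] == b1 and rng.random() < params.sem_rate:
            sem_onsets.append(t + rng.uniform(0.0, 0.3))
        elif codes[t] == c and rng.random() < params.graphoelement_rate:
            label = "spindle" if rng.random() < 0.5 else "k_complex"
            graphoelements.append(
                AnnotationSpan(onset=t + rng.uniform(0.0, 0.3), duration=0.6, label=label)
            )
    try:
        true = stability_score_bruteforce(seq)
    except CoverageError:
        true = None  # too short to score; sequence still usable for synthesis
    return SimulatedTrajectory(seq, true, sem_onsets, graphoelements)


# ---------------------------------------------------------------------------
# EEG synthesis

#: Per-stage band RMS amplitudes in uV per channel, as
#: (frontal, central, parietal, occipital).  Designed around the stage
#: phenomenology: A stages differ in where alpha sits, B2/3 is slow-wave
#: dominated, 0 and B1 are low-voltage desynchronised.
STAGE_RECIPES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "0":    {"delta": (0.8,) * 4, "theta": (0.8,) * 4,
             "alpha": (1.2,) * 4, "beta": (2.5,) * 4},
    "A1":   {"delta": (1.0,) * 4, "theta": (1.0,) * 4,
             "alpha": (3.0, 5.0, 15.0, 20.0), "beta": (1.5,) * 4},
    "A2":   {"delta": (1.0,) * 4, "theta": (1.0,) * 4,
             "alpha": (10.0, 13.0, 13.0, 13.0), "beta": (1.5,) * 4},
    "A3":   {"delta": (1.0,) * 4, "theta": (1.2,) * 4,
             "alpha": (16.0, 15.0, 8.0, 7.0), "beta": (1.5,) * 4},
    "B1":   {"delta": (0.8,) * 4, "theta": (0.8,) * 4,
             "alpha": (1.2,) * 4, "beta": (2.0,) * 4},
    "B2/3": {"delta": (12.0,) * 4, "theta": (10.0,) * 4,
             "alpha": (1.2,) * 4, "beta": (1.5,) * 4},
    "C":    {"delta": (13.0,) * 4, "theta": (10.0,) * 4,
             "alpha": (1.2,) * 4, "beta": (2.0,) * 4},
}

#: Noise bands used to realise the recipes (synthesis side; analysis bands
#: live in :mod:`arousalkit.spectral`).
_SYNTH_BANDS = {"delta": (1.0, 3.0), "theta": (4.0, 7.0),
                "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}

EEG_CHANNELS = ("F3", "F4", "FZ", "C3", "C4", "CZ", "P3", "P4", "PZ", "O1", "O2")
ALL_CHANNELS = EEG_CHANNELS + ("HEOG", "VEOG")

_REGION_OF = {c: r for r, chans in REGIONS.items() for c in chans}
_REGION_POS = {"frontal": 0, "central": 1, "parietal": 2, "occipital": 3}


@dataclass
class EEGSynthesisParams:
    """Synthesis knobs: sampling rate, noise floor, SEM morphology."""

    sfreq: float = 256.0
    noise_rms_uv: float = 0.7
    sem_amp_uv: float = 60.0
    sem_freq_hz: float = 0.4
    sem_duration_s: float = 2.5
    eog_noise_rms_uv: float = 4.0
    crossfade_s: float = 0.1
    recipes: dict = field(default_factory=lambda: STAGE_RECIPES)


def _band_noise(rng, n_ch, n_samp, band, sfreq):
    """Unit-RMS noise restricted to a frequency band, per channel."""
    x = rng.standard_normal((n_ch, n_samp))
    sos = signal.butter(3, band, btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    return x / x.std(axis=1, keepdims=True)


def synthesize_eeg(traj: SimulatedTrajectory | StageSequence,
                   params: EEGSynthesisParams | None = None,
                   rng: np.random.Generator | None = None) -> EEGRecording:
    """Raw EEG (uV) realising a stage trajectory.

    Per-second recipe amplitudes modulate band-limited unit noise with
    smooth crossfades at stage changes; SEM waveforms go into the HEOG during
    B1 seconds and graphoelement annotations are attached for C seconds.
    Given the same trajectory, params and rng state the output is
    byte-identical.
    """
    params = params or EEGSynthesisParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    if isinstance(traj, StageSequence):
        traj = SimulatedTrajectory(traj, None, [], [])
        # events not provided: no SEM/graphoelements will be realised
    seq = traj.sequence
    labels = seq.labels()
    for lab in set(l for l in labels if l is not None):
        if lab not in params.recipes:
            raise KeyError(f"no synthesis recipe for stage {lab!r}")

    sfreq = params.sfreq
    sps = int(round(sfreq))
    n_sec = len(seq)
    n_samp = n_sec * sps
    n_eeg = len(EEG_CHANNELS)
    smooth = max(int(round(params.crossfade_s * sfreq)), 1)

    data = np.zeros((len(ALL_CHANNELS), n_samp))
    region_pos = np.array([_REGION_POS[_REGION_OF[c]] for c in EEG_CHANNELS])
    for band, lims in _SYNTH_BANDS.items():
        noise = _band_noise(rng, n_eeg, n_samp, lims, sfreq)
        amp_sec = np.empty((n_eeg, n_sec))
        for t, lab in enumerate(labels):
            recipe = params.recipes[lab if lab is not None else "0"][band]
            amp_sec[:, t] = np.asarray(recipe)[region_pos]
        env = np.repeat(amp_sec, sps, axis=1)
        env = uniform_filter1d(env, size=smooth, axis=1, mode="nearest")
        data[:n_eeg] += env * noise
    data[:n_eeg] += params.noise_rms_uv * rng.standard_normal((n_eeg, n_samp))

    # EOG: slow baseline noise plus SEM waveforms in HEOG
    sos_slow = signal.butter(2, [0.1, 3.0], btype="bandpass", fs=sfreq, output="sos")
    for ch in ("HEOG", "VEOG"):
        i = ALL_CHANNELS.index(ch)
        x = signal.sosfiltfilt(sos_slow, rng.standard_normal(n_samp))
        data[i] = params.eog_noise_rms_uv * x / x.std()
    heog = ALL_CHANNELS.index("HEOG")
    tvec = np.arange(n_samp) / sfreq
    # SEMs are a continuous slow roving of gaze: merge event seconds that
    # touch into one coherent oscillation per span, so dense B1 stretches do
    # not self-cancel through phase-shifted overlaps
    sem_seconds = sorted({int(o) for o in traj.sem_onsets})
    spans: list[list[int]] = []
    for s in sem_seconds:
        if spans and s - spans[-1][1] <= 1:
            spans[-1][1] = s
        else:
            spans.append([s, s])
    for s0, s1 in spans:
        a = int(round(s0 * sfreq))
        b = min(int(round((s1 + params.sem_duration_s) * sfreq)), n_samp)
        if b <= a:
            continue
        tt = tvec[a:b] - tvec[a]
        span_s = (b - a) / sfreq
        taper = signal.windows.tukey(b - a, alpha=min(1.0, 1.0 / span_s))
        data[heog, a:b] += params.sem_amp_uv * np.sin(
            2 * np.pi * params.sem_freq_hz * tt) * taper

    # cosmetic spindle bursts on central channels during tagged graphoelements
    central = [ALL_CHANNELS.index(c) for c in ("C3", "C4", "CZ")]
    for ann in traj.graphoelements:
        a = int(round(ann.onset * sfreq))
        b = min(a + int(round(ann.duration * sfreq)), n_samp)
        if b <= a:
            continue
        burst = 4.0 * np.sin(2 * np.pi * 13.0 * (tvec[a:b] - ann.onset))
        burst *= signal.windows.tukey(b - a, alpha=0.5)
        data[central, a:b] += burst

    return EEGRecording(
        channel_labels=list(ALL_CHANNELS),
        sfreq=sfreq,
        data=data,
        reference="linked",
        annotations=list(traj.graphoelements),
    )


# ---------------------------------------------------------------------------
# Cohorts

#: Per-group discrete stability-score distributions.  Means/SDs match the
#: published 3.08 (1.04) and 8.89 (1.37); the stable support starts at 7 so
#: the data-driven median split reproduces the designed groups (see methods
#: note).
SCORE_DIST = {
    "unstable": {1: 0.07, 2: 0.22, 3: 0.37, 4: 0.24, 5: 0.10},
    "stable": {7: 0.18, 8: 0.24, 9: 0.23, 10: 0.21, 11: 0.14},
}

#: Baseline ln absolute power (ln uV^2) per band and its between-subject SD.
BASE_LN_POWER = {"delta": 3.0, "theta": 2.5, "alpha": 3.0, "beta": 1.5}
LN_POWER_SD = 0.8


def _metric_param(name):
    (n1, m1, s1), (n2, m2, s2), _ = ref.METRIC_SUMMARIES[name]
    return {"unstable": (m1, s1), "stable": (m2, s2)}


@dataclass
class CohortParams:
    """Cohort generator parameters, defaulted from the published summaries."""

    n_unstable: int = 13
    n_stable: int = 18
    score_dist: dict = field(default_factory=lambda: {g: dict(d) for g, d in SCORE_DIST.items()})
    # metric variables: group -> (mean, sd)
    metric: dict = field(default_factory=lambda: {
        "bdi": _metric_param("bdi"),
        "caars_dsm_ia": _metric_param("caars_dsm_ia"),
        "caars_dsm_hyi": _metric_param("caars_dsm_hyi"),
        "caars_dsm_g": _metric_param("caars_dsm_g"),
        "asrs_a_cutoff": _metric_param("asrs_a_cutoff"),
        "asrs_a_sum": _metric_param("asrs_a_sum"),
        "asrs_b_cutoff": _metric_param("asrs_b_cutoff"),
        "asrs_b_sum": _metric_param("asrs_b_sum"),
        "wursk": _metric_param("wursk"),
        "age": _metric_param("age"),
        "sleep_hours": _metric_param("general_sleep"),
    })
    # binary variables: group -> P(yes); counts from the contingency tables
    binary: dict = field(default_factory=lambda: {
        "gender": {"unstable": 6 / 13, "stable": 8 / 18},          # P(woman)
        "smoker": {"unstable": 3 / 12, "stable": 14 / 18},
        "alcohol_user": {"unstable": 10 / 12, "stable": 16 / 18},
    })
    categorical: dict = field(default_factory=lambda: {
        "marital_status": {
            "levels": ("single", "married", "divorced"),
            "unstable": (12 / 13, 0.0, 1 / 13), "stable": (15 / 18, 3 / 18, 0.0),
        },
        "graduation": {
            "levels": ("9th", "10th", "12th"),
            "unstable": (4 / 13, 1 / 13, 8 / 13), "stable": (3 / 18, 6 / 18, 9 / 18),
        },
    })
    # per-variable missingness (unstable, stable), from available n in print
    missing: dict = field(default_factory=lambda: {
        "bdi": (1 / 13, 1 / 18),
        "sleep_hours": (2 / 13, 1 / 18),
        "smoker": (1 / 13, 0.0),
        "alcohol_user": (1 / 13, 0.0),
        "caars_dsm_ia": (0.0, 1 / 18),
        "caars_dsm_hyi": (0.0, 1 / 18),
        "caars_dsm_g": (0.0, 1 / 18),
        "asrs_a_cutoff": (0.0, 1 / 18),
        "asrs_a_sum": (0.0, 1 / 18),
        "asrs_b_cutoff": (0.0, 1 / 18),
        "asrs_b_sum": (0.0, 1 / 18),
        "wursk": (0.0, 1 / 18),
    })
    ln_power_base: dict = field(default_factory=lambda: dict(BASE_LN_POWER))
    ln_power_sd: float = LN_POWER_SD
    # standardised unstable-minus-stable shift per (band, region); defaults
    # derived from the published T statistics at n = 13/18
    power_effects: dict = field(default_factory=lambda: {
        (band, region): ref.power_contrast_effect_size(band, region)
        if band in ("delta", "theta") else 0.0
        for band in ("delta", "theta", "alpha", "beta")
        for region in ("frontal", "central", "parietal", "occipital")
    })

    @classmethod
    def null(cls) -> "CohortParams":
        """Zero group effects everywhere except the score (which defines groups)."""
        p = cls()
        for var, groups in p.metric.items():
            m1, s1 = groups["unstable"]
            m2, s2 = groups["stable"]
            pooled = ((m1 + m2) / 2, math.sqrt((s1**2 + s2**2) / 2))
            p.metric[var] = {"unstable": pooled, "stable": pooled}
        for var, groups in p.binary.items():
            q = (groups["unstable"] + groups["stable"]) / 2
            p.binary[var] = {"unstable": q, "stable": q}
        for var, spec_ in p.categorical.items():
            mix = tuple((a + b) / 2 for a, b in zip(spec_["unstable"], spec_["stable"]))
            p.categorical[var] = {"levels": spec_["levels"], "unstable": mix, "stable": mix}
        p.power_effects = {k: 0.0 for k in p.power_effects}
        return p


def _precompensated_mean(target_mean: float, sd: float) -> float:
    """Mean mu such that E[max(N(mu, sd), 0)] equals ``target_mean``.

    E[max(X, 0)] = mu * Phi(mu/sd) + sd * phi(mu/sd); solved by fixed-point
    iteration (the clipping bias is small and smooth).
    """
    from scipy.stats import norm

    mu = target_mean
    for _ in range(8):
        clipped = mu * norm.cdf(mu / sd) + sd * norm.pdf(mu / sd)
        mu -= clipped - target_mean
    return mu


def simulate_cohort(params: CohortParams | None = None,
                    rng: np.random.Generator | None = None,
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Draw a subject-level cohort table.

    Subjects are drawn independently from the per-group distributions; the
    ``group`` column is then assigned by the pipeline's median split on the
    drawn stability scores, and missingness is applied per variable.
    """
    from .stability import median_split

    params = params or CohortParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    groups = ["unstable"] * params.n_unstable + ["stable"] * params.n_stable
    n = len(groups)
    rows = {"subject_id": [f"S{i + 1:03d}" for i in range(n)]}
    scores = []
    for g in groups:
        vals, probs = zip(*sorted(params.score_dist[g].items()))
        scores.append(int(rng.choice(vals, p=np.asarray(probs) / sum(probs))))
    rows["stability_score"] = scores

    for var, by_group in params.metric.items():
        if var == "bdi":
            # non-negative score: clip at 0 with the generating mean
            # pre-compensated so the clipped mean matches the target
            draws = [max(rng.normal(_precompensated_mean(*by_group[g]), by_group[g][1]), 0.0)
                     for g in groups]
        else:
            draws = [rng.normal(*by_group[g]) for g in groups]
        rows[var] = draws
    for var, by_group in params.binary.items():
        rows[var] = [int(rng.random() < by_group[g]) for g in groups]
    for var, spec_ in params.categorical.items():
        levels = spec_["levels"]
        rows[var] = [
            str(rng.choice(levels, p=np.asarray(spec_[g]) / sum(spec_[g])))
            for g in groups
        ]
    for (band, region), d in params.power_effects.items():
        base = params.ln_power_base[band]
        sd = params.ln_power_sd
        shift = d * sd / 2
        rows[f"{band}_{region}"] = [
            rng.normal(base + shift if g == "unstable" else base - shift, sd)
            for g in groups
        ]

    df = pd.DataFrame(rows)
    df["group"] = median_split(df["stability_score"], config).to_numpy()
    for var, (p1, p2) in params.missing.items():
        if var not in df.columns:
            continue
        p_miss = np.where(np.asarray(groups) == "unstable", p1, p2)
        mask = rng.random(n) < p_miss
        df.loc[mask, var] = np.nan
    return df


def analytic_signed_eta(params: CohortParams, variable: str) -> float:
    """Population correlation ratio implied by the generator for a metric variable.

    Uses mixture moments with weights proportional to the expected available
    n per group: Eta^2 = Vb / (Vb + Vw) with Vb the between-group variance of
    the mixture and Vw the weighted within-group variance.  The sign follows
    the reporting convention (stable minus unstable).
    """
    m1, s1 = params.metric[variable]["unstable"]
    m2, s2 = params.metric[variable]["stable"]
    p1, p2 = params.missing.get(variable, (0.0, 0.0))
    w1 = params.n_unstable * (1 - p1)
    w2 = params.n_stable * (1 - p2)
    w1, w2 = w1 / (w1 + w2), w2 / (w1 + w2)
    grand = w1 * m1 + w2 * m2
    vb = w1 * (m1 - grand) ** 2 + w2 * (m2 - grand) ** 2
    vw = w1 * s1**2 + w2 * s2**2
    eta = math.sqrt(vb / (vb + vw))
    return math.copysign(eta, m2 - m1)
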