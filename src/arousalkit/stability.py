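"""Arousal stability score and mean EEG-vigilance time course.

The stability score (1-11, or ``unclassified``) indexes the steepness of the
arousal decline over a nominally 15-min resting recording.  Sliding 60-s
epochs (step 1 s) are scanned for occupancy criteria:

* an epoch "fulfils B1" / "fulfils B2/3" when at least 1/3 of its valid
  seconds carry that stage;
* stage C "occurs" when any valid second is staged C;
* fulfilments are attributed to five-minute thirds of the recording by the
  epoch's start second (C occurrence by the segment's own second);
* the deepest fulfilled stage wins (C over B2/3 over B1), within it the
  earliest third: C -> 1/2/3, B2/3 -> 4/5/6, B1 -> 7/8/9 for
  first/second/third five minutes;
* if nothing fulfils, a whole-recording fraction of {0, A1} over valid
  seconds > 2/3 gives 11, else {0, A1, A2, A3} > 2/3 gives 10;
* otherwise the score is ``unclassified``.

Low scores mean rapid decline (unstable regulation), high scores sustained
wakefulness (stable regulation).

``stability_score_bruteforce`` is an intentionally naive re-implementation
(explicit epoch enumeration, per-epoch counting) kept as an independent
reference for the optimised scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import STAGE_INDEX, STAGES, StageSequence

EPOCH_S = 60
THIRD_S = 300
FRACTION_CRITERION = 1.0 / 3
WHOLE_CRITERION = 2.0 / 3

_IDX_B1 = STAGE_INDEX["B1"]
_IDX_B23 = STAGE_INDEX["B2/3"]
_IDX_C = STAGE_INDEX["C"]
_IDX_0 = STAGE_INDEX["0"]
_IDX_A1 = STAGE_INDEX["A1"]
_A_SET = (STAGE_INDEX["0"], STAGE_INDEX["A1"], STAGE_INDEX["A2"], STAGE_INDEX["A3"])

#: score for (stage, third): stage "C" thirds 0/1/2 -> 1/2/3, etc.
_SCORE_TABLE = {
    "C": (1, 2, 3),
    "B2/3": (4, 5, 6),
    "B1": (7, 8, 9),
}


@dataclass
class StabilityScore:
    """Result of the stability-score rules.

    ``value`` is 1-11 or None for ``unclassified``; ``condition`` names the
    triggering rule and ``epoch_start`` the second of the earliest
    fulfilment (epoch start for B1/B2-3, segment second for C; None for
    whole-recording rules 10/11).
    """

    value: int | None
    condition: str
    epoch_start: int | None = None

    @property
    def unclassified(self) -> bool:
        return self.value is None


class CoverageError(ValueError):
    """Too few valid seconds to assign a stability score."""


def _third_of(second: int) -> int:
    return min(int(second) // THIRD_S, 2)


def epoch_occupancy(seq: StageSequence, epoch_start_s: int, config: PipelineConfig | None = None) -> dict:
    """Per-stage fraction of valid seconds in the epoch [start, start+60).

    Fractions are over the epoch's *valid* seconds only.  The result carries
    ``low_coverage=True`` when fewer than the configured minimum (default 45)
    of the 60 seconds are valid.
    """
    cfg = config or PipelineConfig.default()
    if epoch_start_s < 0 or epoch_start_s + EPOCH_S > len(seq):
        raise IndexError(
            f"epoch [{epoch_start_s}, {epoch_start_s + EPOCH_S}) outside recording "
            f"of {len(seq)} s"
        )
    sl = slice(epoch_start_s, epoch_start_s + EPOCH_S)
    codes = seq.codes[sl]
    valid = seq.valid[sl]
    n_valid = int(valid.sum())
    fractions = {}
    for stage, idx in STAGE_INDEX.items():
        count = int(np.sum(valid & (codes == idx)))
        fractions[stage] = count / n_valid if n_valid else 0.0
    return {
        "fractions": fractions,
        "n_valid": n_valid,
        "low_coverage": n_valid < cfg.stability.min_epoch_valid,
    }


def _whole_recording_rule(codes: np.ndarray, valid: np.ndarray) -> StabilityScore:
    n_valid = int(valid.sum())
    vc = codes[valid]
    frac_0a1 = np.sum((vc == _IDX_0) | (vc == _IDX_A1)) / n_valid
    frac_0a = np.sum(np.isin(vc, _A_SET)) / n_valid
    if frac_0a1 > WHOLE_CRITERION:
        return StabilityScore(11, "unique occurrence of 0 and A1")
    if frac_0a > WHOLE_CRITERION:
        return StabilityScore(10, "unique occurrence of 0 and A")
    return StabilityScore(None, "unclassified")


def stability_score(seq: StageSequence, config: PipelineConfig | None = None) -> StabilityScore:
    """Assign the arousal stability score to a staged recording.

    Uses cumulative stage counts so each sliding epoch is evaluated in O(1);
    semantics are checked against :func:`stability_score_bruteforce`.
    """
    cfg = config or PipelineConfig.default()
    if seq.n_valid < cfg.stability.min_coverage_s:
        raise CoverageError(
            f"only {seq.n_valid} valid seconds; need >= {cfg.stability.min_coverage_s}"
        )
    codes, valid = seq.codes, seq.valid
    n = len(seq)

    # C occurrence: by the segment's own second.
    c_seconds = np.flatnonzero(valid & (codes == _IDX_C))
    if c_seconds.size:
        t = int(c_seconds[0])
        third = _third_of(t)
        return StabilityScore(_SCORE_TABLE["C"][third], "occurrence of stage C", t)

    if n >= EPOCH_S:
        cum_valid = np.concatenate([[0], np.cumsum(valid)])
        starts = np.arange(n - EPOCH_S + 1)
        win_valid = cum_valid[starts + EPOCH_S] - cum_valid[starts]
        eligible = win_valid >= cfg.stability.min_epoch_valid
        for stage_idx, stage_name in ((_IDX_B23, "B2/3"), (_IDX_B1, "B1")):
            hits = valid & (codes == stage_idx)
            cum = np.concatenate([[0], np.cumsum(hits)])
            win = cum[starts + EPOCH_S] - cum[starts]
            fulfils = eligible & (win_valid > 0) & (win / np.maximum(win_valid, 1) >= FRACTION_CRITERION)
            idx = np.flatnonzero(fulfils)
            if idx.size:
                t = int(idx[0])
                third = _third_of(t)
                return StabilityScore(
                    _SCORE_TABLE[stage_name][third],
                    f"stage {stage_name} epoch fulfilment", t,
                )

    return _whole_recording_rule(codes, valid)


def stability_score_bruteforce(seq: StageSequence, config: PipelineConfig | None = None) -> StabilityScore:
    """Literal rule-by-rule evaluator: enumerate every 60-s epoch explicitly.

    Kept deliberately simple and independent of :func:`stability_score`.
    """
    cfg = config or PipelineConfig.default()
    if seq.n_valid < cfg.stability.min_coverage_s:
        raise CoverageError("insufficient valid coverage")
    codes = np.asarray(seq.codes)
    valid = np.asarray(seq.valid)
    n = len(codes)
    is_b1 = valid & (codes == _IDX_B1)
    is_b23 = valid & (codes == _IDX_B23)

    fulfil_thirds: dict[str, list] = {"B1": [], "B2/3": []}
    first_start: dict[str, int] = {}
    for start in range(0, n - EPOCH_S + 1):
        stop = start + EPOCH_S
        n_valid = int(valid[start:stop].sum())
        if n_valid < cfg.stability.min_epoch_valid:
            continue
        for stage, hits in (("B1", is_b1), ("B2/3", is_b23)):
            count = int(hits[start:stop].sum())
            if count / n_valid >= FRACTION_CRITERION:
                third = _third_of(start)
                if third not in fulfil_thirds[stage]:
                    fulfil_thirds[stage].append(third)
                first_start.setdefault(stage, start)

    c_idx = np.flatnonzero(valid & (codes == _IDX_C))
    if c_idx.size:
        first_c = int(c_idx[0])
        c_thirds = [_third_of(int(i)) for i in c_idx]
        return StabilityScore(_SCORE_TABLE["C"][min(c_thirds)], "occurrence of stage C", first_c)
    for stage in ("B2/3", "B1"):
        if fulfil_thirds[stage]:
            third = min(fulfil_thirds[stage])
            return StabilityScore(
                _SCORE_TABLE[stage][third], f"stage {stage} epoch fulfilment",
                first_start[stage],
            )

    n_valid = int(valid.sum())
    vcodes = codes[valid]
    frac_0a1 = float(np.sum((vcodes == _IDX_0) | (vcodes == _IDX_A1))) / n_valid
    frac_0a = float(np.sum(np.isin(vcodes, _A_SET))) / n_valid
    if frac_0a1 > WHOLE_CRITERION:
        return StabilityScore(11, "unique occurrence of 0 and A1")
    if frac_0a > WHOLE_CRITERION:
        return StabilityScore(10, "unique occurrence of 0 and A")
    return StabilityScore(None, "unclassified")


# ---------------------------------------------------------------------------
# Mean EEG-vigilance time course

BLOCK_S = 180


@dataclass
class VigilanceTimeCourse:
    """Mean numeric vigilance (7..1) per 3-min block."""

    block_means: np.ndarray          # NaN where a block has no valid second
    block_starts: np.ndarray         # seconds
    block_valid_counts: np.ndarray

    def __len__(self) -> int:
        return len(self.block_means)


def mean_vigilance_timecourse(seq: StageSequence) -> VigilanceTimeCourse:
    """Average the numeric vigilance values in consecutive 3-min blocks.

    Stages map to 0->7, A1->6, A2->5, A3->4, B1->3, B2/3->2, C->1; the mean
    is over valid seconds only.  Requires at least one complete block.
    """
    n_blocks = len(seq) // BLOCK_S
    if n_blocks < 1:
        raise ValueError(f"recording of {len(seq)} s has no complete 3-min block")
    vals = seq.values()[: n_blocks * BLOCK_S].reshape(n_blocks, BLOCK_S)
    counts = np.sum(~np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.nansum(vals, axis=1) / counts
    means[counts == 0] = np.nan
    return VigilanceTimeCourse(
        block_means=means,
        block_starts=np.arange(n_blocks) * BLOCK_S,
        block_valid_counts=counts,
    )


# ---------------------------------------------------------------------------
# Median split

def median_split(scores, config: PipelineConfig | None = None):
    """Dichotomise stability scores at their sample median.

    Scores below the median are "unstable", above it "stable"; scores equal
    to the median go to the side named by ``stability.at_median`` (default
    "stable"; "drop" labels them "unassigned").  Missing scores are
    "unassigned".  Returns a pandas Series aligned with the input.
    """
    cfg = config or PipelineConfig.default()
    s = pd.Series(scores, dtype=float)
    present = s.dropna()
    if len(present) < 2:
        raise ValueError("need >= 2 scores for a median split")
    med = float(present.median())
    if present.nunique() == 1:
        import warnings

        warnings.warn("degenerate median split: all scores identical", stacklevel=2)
    out = pd.Series("unassigned", index=s.index, dtype=object)
    out[s < med] = "unstable"
    out[s > med] = "stable"
    at = cfg.stability.at_median
    if at not in ("stable", "unstable", "drop"):
        raise ValueError(f"invalid at_median setting {at!r}")
    if at != "drop":
        out[s == med] = at
    return out
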