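"""Two-group statistics from raw values or published group summaries.

Implements the statistics the cohort analysis reports: pooled and Welch
two-sample t, Pearson chi-square, the correlation ratio Eta (and Eta-squared),
and Cohen's d.  All are written from their textbook formulas so they can be
recomputed from printed group summaries (n, mean, SD) as well as from raw
columns; p-values come from the corresponding scipy reference distributions.

Conventions (matching the published tables this package models):
  * group 1 = unstable, group 2 = stable;
  * t sign = mean(unstable) - mean(stable);
  * signed Eta carries the sign of mean(stable) - mean(unstable);
  * SDs are sample SDs (n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sample SD) for two groups."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SD must be >= 0")

    @classmethod
    def from_values(cls, x1, x2) -> "GroupSummary":
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        x1 = x1[~np.isnan(x1)]
        x2 = x2[~np.isnan(x2)]
        return cls(
            len(x1), float(np.mean(x1)), float(np.std(x1, ddof=1)),
            len(x2), float(np.mean(x2)), float(np.std(x2, ddof=1)),
        )


def pooled_t(s: GroupSummary) -> dict:
    """Equal-variance two-sample t-test from group summaries.

    df = n1 + n2 - 2; two-sided p.
    """
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    diff = s.mean1 - s.mean2
    if sp2 == 0:
        if diff == 0:
            return {"t": 0.0, "df": df, "p": 1.0}
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1 / s.n1 + 1 / s.n2))
    p = 2 * sps.t.sf(abs(t), df)
    return {"t": t, "df": df, "p": float(p)}


def welch_t(s: GroupSummary) -> dict:
    """Unequal-variance t-test with Welch-Satterthwaite fractional df."""
    v1 = s.sd1**2 / s.n1
    v2 = s.sd2**2 / s.n2
    diff = s.mean1 - s.mean2
    if v1 + v2 == 0:
        if diff == 0:
            return {"t": 0.0, "df": float(s.n1 + s.n2 - 2), "p": 1.0}
        raise ZeroDivisionError("zero variance with unequal means")
    t = diff / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return {"t": t, "df": float(df), "p": float(p)}


def chi_square(table) -> dict:
    """Pearson chi-square on a 2 x k contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return {"x2": x2, "df": df, "p": float(sps.chi2.sf(x2, df))}


def eta_from_summaries(groups) -> dict:
    """Correlation ratio from per-group (n, mean, sd) triples.

    Eta^2 = SSB / (SSB + SSW) with SSB = sum n_i (m_i - M)^2 and
    SSW = sum (n_i - 1) s_i^2.  For two groups ``signed_eta`` carries the
    sign of mean(group2) - mean(group1), i.e. stable minus unstable under
    the (unstable, stable) ordering convention.
    """
    groups = [(int(n), float(m), float(s)) for n, m, s in groups]
    if len(groups) < 2 or any(n < 1 for n, _, _ in groups):
        raise ValueError("need >= 2 groups with >= 1 value each")
    N = sum(n for n, _, _ in groups)
    grand = sum(n * m for n, m, _ in groups) / N
    ssb = sum(n * (m - grand) ** 2 for n, m, _ in groups)
    ssw = sum((n - 1) * s**2 for n, _, s in groups)
    sst = ssb + ssw
    if sst == 0:
        return {"eta": np.nan, "eta2": np.nan, "signed_eta": np.nan, "undefined": True}
    eta2 = ssb / sst
    eta = math.sqrt(eta2)
    signed = eta
    if len(groups) == 2:
        signed = math.copysign(eta, groups[1][1] - groups[0][1]) if eta > 0 else 0.0
    return {"eta": eta, "eta2": eta2, "signed_eta": signed, "undefined": False}


def eta(values, group_labels) -> dict:
    """Correlation ratio from raw values and group labels (NaN values dropped)."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    keep = ~np.isnan(values)
    values, group_labels = values[keep], group_labels[keep]
    uniq = list(pd.unique(group_labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    summaries = []
    for g in uniq:
        x = values[group_labels == g]
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        summaries.append((len(x), float(np.mean(x)), sd))
    return eta_from_summaries(summaries)


def cohens_d(s: GroupSummary) -> float:
    """|mean difference| / pooled SD (n-1 weighted pooling)."""
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / (s.n1 + s.n2 - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled SD")
    return abs(s.mean1 - s.mean2) / math.sqrt(sp2)


# ---------------------------------------------------------------------------
# Cohort-level analysis

#: Metric questionnaire/demographic variables (t, Eta); band-power columns are
#: detected by name and additionally get Cohen's d.
METRIC_VARIABLES = (
    "age", "sleep_hours",
    "caars_dsm_ia", "caars_dsm_hyi", "caars_dsm_g",
    "asrs_a_cutoff", "asrs_a_sum", "asrs_b_cutoff", "asrs_b_sum",
    "wursk", "bdi",
)

NOMINAL_VARIABLES = ("gender", "smoker", "alcohol_user", "marital_status", "graduation")

BANDS_ORDER = ("delta", "theta", "alpha", "beta")
REGIONS_ORDER = ("frontal", "central", "parietal", "occipital")

POWER_COLUMNS = tuple(f"{b}_{r}" for b in BANDS_ORDER for r in REGIONS_ORDER)


def _metric_row(name: str, x_unstable, x_stable, cfg: PipelineConfig, is_power: bool) -> dict | None:
    x1 = np.asarray(x_unstable, dtype=float)
    x2 = np.asarray(x_stable, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        return None
    s = GroupSummary.from_values(x1, x2)
    v1, v2 = s.sd1**2, s.sd2**2
    use_welch = False
    if min(v1, v2) > 0:
        use_welch = max(v1, v2) / min(v1, v2) > cfg.stats.welch_variance_ratio
    res = welch_t(s) if use_welch else pooled_t(s)
    try:
        e = eta(np.concatenate([x1, x2]),
                np.array(["unstable"] * len(x1) + ["stable"] * len(x2)))
    except ValueError:
        e = {"eta": np.nan, "eta2": np.nan, "signed_eta": np.nan}
    d = np.nan
    if is_power:
        try:
            d = cohens_d(s)
        except ZeroDivisionError:
            pass
    return {
        "variable": name, "kind": "metric", "test": "welch_t" if use_welch else "pooled_t",
        "statistic": res["t"], "df": res["df"], "p": res["p"],
        "eta": e["signed_eta"], "eta2": e["eta2"], "cohens_d": d,
        "n_unstable": s.n1, "n_stable": s.n2,
        "mean_unstable": s.mean1, "sd_unstable": s.sd1,
        "mean_stable": s.mean2, "sd_stable": s.sd2,
    }


def _nominal_row(name: str, g_unstable: pd.Series, g_stable: pd.Series) -> dict | None:
    g1 = g_unstable.dropna()
    g2 = g_stable.dropna()
    levels = sorted(set(g1) | set(g2), key=str)
    if len(levels) < 2 or len(g1) == 0 or len(g2) == 0:
        return None
    table = [[int((g == lev).sum()) for lev in levels] for g in (g1, g2)]
    try:
        res = chi_square(table)
    except ValueError:
        return None
    return {
        "variable": name, "kind": "nominal", "test": "chi_square",
        "statistic": res["x2"], "df": res["df"], "p": res["p"],
        "eta": np.nan, "eta2": np.nan, "cohens_d": np.nan,
        "n_unstable": len(g1), "n_stable": len(g2),
        "mean_unstable": np.nan, "sd_unstable": np.nan,
        "mean_stable": np.nan, "sd_stable": np.nan,
    }


def cohort_analysis(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Group statistics report for an unstable-vs-stable cohort table.

    If the ``group`` column is absent but ``stability_score`` is present the
    median split is applied first.  Metric variables get a t-test (Welch when
    the group variance ratio exceeds the configured trigger) plus signed Eta
    and Eta^2; nominal variables get Pearson chi-square; region x band ln
    power columns additionally get Cohen's d.
    """
    cfg = config or PipelineConfig.default()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cohort = cohort.copy()
    if "group" not in cohort.columns or cohort["group"].isna().all():
        from .stability import median_split  # late import avoids a cycle
        cohort["group"] = median_split(cohort["stability_score"], cfg)
    un = cohort[cohort["group"] == "unstable"]
    st = cohort[cohort["group"] == "stable"]
    if len(un) < 2 or len(st) < 2:
        raise ValueError("need >= 2 subjects per group")

    rows = []
    for name in METRIC_VARIABLES:
        if name in cohort.columns:
            row = _metric_row(name, un[name], st[name], cfg, is_power=False)
            if row:
                rows.append(row)
    for name in NOMINAL_VARIABLES:
        if name in cohort.columns:
            row = _nominal_row(name, un[name], st[name])
            if row:
                rows.append(row)
    for name in POWER_COLUMNS:
        if name in cohort.columns:
            row = _metric_row(name, un[name], st[name], cfg, is_power=True)
            if row:
                rows.append(row)
    report = pd.DataFrame(rows)
    if cfg.stats.fdr and len(report):
        from statsmodels.stats.multitest import multipletests
        report["p_fdr"] = multipletests(report["p"], method="fdr_bh")[1]
    return report
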