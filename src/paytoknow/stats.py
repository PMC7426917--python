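"""Model-free indices and the inferential contrasts of the pipeline.

Covers the knowing ratio and costly knowing ratio (TK choices on trials
paying no more than NTK, Δm ≤ 0), the subject-wise self-relevance filter,
and the test battery: one-sample and paired t, Cohen's d for dependent
samples (mean difference / SD of differences), a continuity-corrected
(Yates) χ² for 2×2 counts, Pearson correlation, and a 2×2 mixed ANOVA
(within: valence; between: evaluation source) with an optional
covariate-adjusted variant.

The Yates correction is the default for the 2×2 χ² because counts of
unknown-averse participants are small in one cell; cells with |O − E| ≤ 0.5
are clamped to zero contribution, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import PayToKnowError, ZeroVarianceError
from .task import records_to_frame

__all__ = [
    "RelevanceFilterResult",
    "TTestResult",
    "Chi2Result",
    "self_relevance_filter",
    "knowing_indices",
    "yates_chi2",
    "one_sample_t",
    "paired_t",
    "cohens_d_dependent",
    "mixed_anova_2x2",
    "pearson_r",
]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# self-relevance filter

@dataclass
class RelevanceFilterResult:
    records: pd.DataFrame
    retention: pd.DataFrame      # per subject: n_total, n_retained
    skipped: bool = False        # True when ratings were missing and no filter applied
    message: str = ""


def self_relevance_filter(records) -> RelevanceFilterResult:
    """Retain trials rated at least as self-relevant as the subject's mean.

    The split point is each subject's own mean rating over all trait words;
    ties (rating exactly at the mean) are retained.  If any rating is
    missing the filter is skipped with a warning flag rather than silently
    dropping trials.
    """
    df = _as_frame(records)
    if df["self_relevance"].isna().any():
        retention = df.groupby("subject_id").size().rename("n_total").reset_index()
        retention["n_retained"] = retention["n_total"]
        return RelevanceFilterResult(df, retention, skipped=True,
                                     message="missing self-relevance ratings; filter skipped")
    means = df.groupby("subject_id")["self_relevance"].transform("mean")
    keep = df["self_relevance"] >= means
    retained = df[keep]
    retention = (
        pd.DataFrame({"subject_id": df["subject_id"], "kept": keep})
        .groupby("subject_id")["kept"]
        .agg(n_total="size", n_retained="sum")
        .reset_index()
    )
    return RelevanceFilterResult(retained.reset_index(drop=True), retention)


# ---------------------------------------------------------------------------
# knowing indices

def knowing_indices(records, by: Sequence[str] = ("subject_id",)) -> pd.DataFrame:
    """Knowing ratio and costly knowing ratio per grouping cell.

    Costly trials are exactly those with Δm ≤ 0 (knowing pays no more than
    not knowing).  Cells with no costly trials get a missing costly ratio,
    never zero.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise PayToKnowError("no records")
    by = list(by)
    tk = (df["choice"] == "TK").astype(float)
    costly = df["delta_m"] <= 0
    out = (
        df.assign(tk=tk, costly=costly)
        .groupby(by, observed=True)
        .apply(lambda g: pd.Series({
            "knowing_ratio": g["tk"].mean(),
            "costly_knowing_ratio": g.loc[g["costly"], "tk"].mean() if g["costly"].any() else np.nan,
            "n_trials": len(g),
            "n_costly_trials": int(g["costly"].sum()),
        }), include_groups=False)
        .reset_index()
    )
    out["n_trials"] = out["n_trials"].astype(int)
    out["n_costly_trials"] = out["n_costly_trials"].astype(int)
    return out


# ---------------------------------------------------------------------------
# classical tests

@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float
    mean: float                 # mean (of differences, for paired)
    ci95: tuple[float, float]
    cohens_d: Optional[float] = None


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    corrected: bool


def yates_chi2(table, correction: bool = True) -> Chi2Result:
    """χ² for a 2×2 contingency table, continuity-corrected by default.

    statistic = Σ (max(|O − E| − 0.5, 0))² / E  with df = 1.
    """
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise PayToKnowError("need a 2x2 table of counts")
    if (obs < 0).any() or not np.allclose(obs, np.rint(obs)):
        raise PayToKnowError("counts must be non-negative integers")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ZeroVarianceError("chi-square undefined with a zero margin")
    expected = row @ col / total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return Chi2Result(statistic=stat, df=1, p_value=p, corrected=correction)


def _t_ci(mean: float, se: float, df: float) -> tuple[float, float]:
    half = sps.t.ppf(0.975, df) * se
    return (mean - half, mean + half)


def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    x = np.asarray(values, float)
    if x.size < 2:
        raise PayToKnowError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("one-sample t undefined with zero variance")
    res = sps.ttest_1samp(x, popmean)
    se = sd / np.sqrt(x.size)
    m = float(x.mean() - popmean)
    return TTestResult(float(res.statistic), float(x.size - 1), float(res.pvalue),
                       m, _t_ci(m, se, x.size - 1), cohens_d=m / sd)


def cohens_d_dependent(a, b) -> float:
    """Standardized mean change: mean(a − b) / SD(a − b)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0
        raise ZeroVarianceError("difference scores have zero variance with nonzero mean")
    return float(d.mean() / sd)


def paired_t(a, b) -> TTestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise PayToKnowError("paired inputs must have equal length")
    if a.size < 2:
        raise PayToKnowError("need n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("paired t undefined with zero-variance differences")
    res = sps.ttest_rel(a, b)
    se = sd / np.sqrt(a.size)
    m = float(diff.mean())
    return TTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue),
                       m, _t_ci(m, se, a.size - 1), cohens_d=m / sd)


def pearson_r(x, y) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise PayToKnowError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ZeroVarianceError("correlation undefined with zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# 2x2 mixed ANOVA

def mixed_anova_2x2(data: pd.DataFrame, dv: str = "knowing_ratio",
                    within: str = "valence", between: str = "source",
                    subject: str = "subject_id",
                    covariates: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mixed-design ANOVA with one within- and one between-subject factor.

    ``data`` is long-form with one row per subject × within-level.  Each
    subject must have a complete, balanced set of within-factor cells.  When
    ``covariates`` (per-subject columns) are given, the dependent variable is
    residualized on them first — the control analysis for nuisance ratings.
    Returns a tidy table with F, df1, df2, p and partial eta² per effect.
    """
    df = data.copy()
    counts = df.groupby(subject)[within].nunique()
    n_levels = df[within].nunique()
    bad = counts[counts < n_levels]
    if len(bad):
        raise PayToKnowError(
            f"subjects missing within-factor cells: {', '.join(map(str, bad.index))}"
        )
    if df[dv].std() == 0:
        raise ZeroVarianceError("ANOVA undefined: dependent variable is constant")
    if covariates:
        import statsmodels.api as sm

        X = sm.add_constant(df[list(covariates)].astype(float))
        df[dv] = sm.OLS(df[dv].astype(float), X).fit().resid
    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between,
                         subject=subject, correction=False)
    out = aov.rename(columns={"Source": "effect", "DF1": "df1", "DF2": "df2",
                              "p-unc": "p_value", "p_unc": "p_value",
                              "np2": "partial_eta_sq"})
    return out[["effect", "F", "df1", "df2", "p_value", "partial_eta_sq"]]
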