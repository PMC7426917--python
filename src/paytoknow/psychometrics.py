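"""Psychometric curves and the point of subjective equivalence (PSE).

The knowing ratio (proportion of "to-know" choices) is plotted against the
payoff difference Δm and fitted with a four-parameter base-10 sigmoid

    f(x) = m_i + (m_j − m_i) / (1 + 10^{−b·(x − x0)})

with lower/upper asymptotes m_i, m_j, slope b and midpoint x0.  The PSE is
the abscissa where the fitted curve crosses 50%:

    PSE = x0 − (1/b)·log10((m_j − 0.5) / (0.5 − m_i)),

defined when the asymptotes straddle 0.5.  A negative PSE means the curve
crosses 50% at a monetary loss for knowing — subjects pay to know.

Group PSEs are estimated by resampling subjects with replacement (200
iterations by default), averaging per-Δm knowing ratios across the
resampled subjects, fitting the sigmoid and inverting it.  Per-subject PSEs
from individual curves are exposed separately.  For the softmax-lapse
generative model with homogeneous parameters the true indifference point is
Δm = −β/α, which serves as the analytic oracle for all of this machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import PayToKnowError, UndefinedPSEError
from .task import records_to_frame

__all__ = [
    "SigmoidFit",
    "BootstrapPSE",
    "PSEDifference",
    "sigmoid",
    "knowing_curve",
    "fit_sigmoid",
    "pse_from_fit",
    "per_subject_pse",
    "bootstrap_group_pse",
    "pse_difference_test",
]

# parameter bounds: asymptotes must straddle 0.5 so the 50% crossing exists
_LOWER = np.array([0.0, 0.5 + 1e-4, 1e-4, -5.0])
_UPPER = np.array([0.5 - 1e-4, 1.0, 20.0, 5.0])


def sigmoid(x, lower_asym, upper_asym, slope, midpoint):
    """The base-10 four-parameter psychometric function."""
    x = np.asarray(x, float)
    return lower_asym + (upper_asym - lower_asym) / (1.0 + 10.0 ** (-slope * (x - midpoint)))


@dataclass
class SigmoidFit:
    lower_asym: float
    upper_asym: float
    slope: float
    midpoint: float
    r_squared: float
    ok: bool = True
    message: str = ""

    @property
    def pse(self) -> Optional[float]:
        try:
            return pse_from_fit(self)
        except (UndefinedPSEError, PayToKnowError):
            return None


@dataclass
class BootstrapPSE:
    n_iter: int
    pse_samples: np.ndarray          # one entry per iteration, NaN = failed fit
    mean: float
    ci95: tuple[float, float]
    seed: int
    n_failed: int = 0
    warning: str = ""


@dataclass
class PSEDifference:
    """Bootstrap distribution of PSE(a) − PSE(b)."""

    n_iter: int
    diff_samples: np.ndarray
    mean: float
    ci95: tuple[float, float]
    significant: bool                # 0 outside the 95% percentile interval
    seed: int
    n_failed: int = 0


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def knowing_curve(records, valence: Optional[str] = None) -> pd.DataFrame:
    """Knowing ratio per Δm level: columns (delta_m, ratio, n)."""
    df = _as_frame(records)
    if valence is not None:
        df = df[df["valence"] == valence]
    if len(df) == 0:
        raise PayToKnowError("no trials for knowing curve")
    g = df.groupby("delta_m")["choice"]
    out = pd.DataFrame({
        "delta_m": g.count().index.to_numpy(),
        "ratio": g.apply(lambda s: float(np.mean(s == "TK"))).to_numpy(),
        "n": g.count().to_numpy(),
    })
    return out.sort_values("delta_m", ignore_index=True)


def _init_guesses(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    lo = float(np.clip(y.min(), _LOWER[0], _UPPER[0]))
    hi = float(np.clip(y.max(), _LOWER[1], _UPPER[1]))
    steps = np.diff(y)
    mid = float(x[np.argmax(steps)] + 0.5) if len(x) > 1 else 0.0
    mid = float(np.clip(mid, -5.0, 5.0))
    guesses = [np.array([lo, hi, 1.0, mid])]
    for s in (0.3, 3.0):
        guesses.append(np.array([lo, hi, s, 0.0]))
    return guesses


def _sigmoid_jac(x, lower_asym, upper_asym, slope, midpoint):
    x = np.asarray(x, float)
    t = 10.0 ** (-slope * (x - midpoint))
    denom = 1.0 + t
    core = 1.0 / denom
    dcore = t * np.log(10.0) / denom**2          # d core / d(slope*(x-midpoint))
    span = upper_asym - lower_asym
    return np.column_stack([
        1.0 - core,
        core,
        span * dcore * (x - midpoint),
        -span * dcore * slope,
    ])


def fit_sigmoid(curve: pd.DataFrame) -> SigmoidFit:
    """Bounded nonlinear least squares of the psychometric function.

    Requires ≥4 distinct Δm levels.  A curve with no variance (or any other
    optimizer failure after all restarts) is returned flagged ``ok=False``
    rather than raised, so bootstrap iterations can record it as missing.
    """
    x = np.asarray(curve["delta_m"], float)
    y = np.asarray(curve["ratio"], float)
    if len(np.unique(x)) < 4:
        raise PayToKnowError("need at least 4 distinct delta_m levels to fit a sigmoid")
    if np.ptp(y) < 1e-12:
        return SigmoidFit(0.0, 1.0, 1.0, 0.0, r_squared=np.nan, ok=False,
                          message="degenerate: constant knowing ratio, slope unidentified")
    best = None
    sst = float(np.sum((y - y.mean()) ** 2))
    for p0 in _init_guesses(x, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(sigmoid, x, y, p0=p0, jac=_sigmoid_jac,
                                    bounds=(_LOWER, _UPPER), maxfev=5000)
        except Exception:
            continue
        resid = y - sigmoid(x, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt)
        # the data-driven first guess almost always suffices; fall back to the
        # generic restarts only when the fit is visibly poor
        if best is not None and best[0] <= 1e-3 * max(sst, 1e-12):
            break
    if best is None:
        return SigmoidFit(0.0, 1.0, 1.0, 0.0, r_squared=np.nan, ok=False,
                          message="sigmoid fit failed to converge from all starts")
    sse, popt = best
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return SigmoidFit(*(float(v) for v in popt), r_squared=r2)


def pse_from_fit(fit: SigmoidFit) -> float:
    """Closed-form inversion of the fitted curve at 50%."""
    if not fit.ok:
        raise PayToKnowError(f"cannot invert a failed fit: {fit.message}")
    mi, mj, b, x0 = fit.lower_asym, fit.upper_asym, fit.slope, fit.midpoint
    if not (mi < 0.5 < mj):
        raise UndefinedPSEError(
            f"asymptotes [{mi:.3f}, {mj:.3f}] do not straddle 0.5; PSE undefined"
        )
    return x0 - (1.0 / b) * np.log10((mj - 0.5) / (0.5 - mi))


# ---------------------------------------------------------------------------
# bootstrap machinery

def _subject_ratio_matrix(records, valence: Optional[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(subjects x Δm-levels) knowing-ratio matrix plus level values and ids."""
    df = _as_frame(records)
    if valence is not None:
        df = df[df["valence"] == valence]
    if len(df) == 0:
        raise PayToKnowError("no trials after filtering")
    tk = (df["choice"] == "TK").astype(float)
    piv = df.assign(tk=tk).pivot_table(index="subject_id", columns="delta_m",
                                       values="tk", aggfunc="mean")
    if piv.shape[0] < 2:
        raise PayToKnowError("bootstrap needs at least 2 subjects")
    return piv.to_numpy(), piv.columns.to_numpy(float), [str(s) for s in piv.index]


def _fit_curve_pse(levels: np.ndarray, mean_ratios: np.ndarray) -> float:
    curve = pd.DataFrame({"delta_m": levels, "ratio": mean_ratios})
    fit = fit_sigmoid(curve)
    if not fit.ok:
        return np.nan
    try:
        return pse_from_fit(fit)
    except UndefinedPSEError:
        return np.nan


def _summarize(samples: np.ndarray, n_iter: int, seed: int) -> BootstrapPSE:
    good = samples[~np.isnan(samples)]
    n_failed = int(n_iter - good.size)
    warning = ""
    if n_failed > 0.2 * n_iter:
        warning = f"{n_failed}/{n_iter} bootstrap fits failed"
    if good.size == 0:
        return BootstrapPSE(n_iter, samples, np.nan, (np.nan, np.nan), seed,
                            n_failed, warning or "all bootstrap fits failed")
    ci = (float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5)))
    return BootstrapPSE(n_iter, samples, float(good.mean()), ci, seed, n_failed, warning)


def bootstrap_group_pse(records, valence: Optional[str] = None,
                        n_iter: int = 200, seed: int = 0) -> BootstrapPSE:
    """Group-level PSE by resampling subjects with replacement.

    Each iteration draws subjects with replacement, averages their per-Δm
    knowing ratios, fits the sigmoid and inverts it; failed fits are recorded
    as missing (never re-drawn) and counted.
    """
    mat, levels, _ = _subject_ratio_matrix(records, valence)
    rng = np.random.default_rng(seed)
    n_sub = mat.shape[0]
    samples = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.integers(0, n_sub, n_sub)
        samples[i] = _fit_curve_pse(levels, np.nanmean(mat[idx], axis=0))
    return _summarize(samples, n_iter, seed)


def per_subject_pse(records, valence: Optional[str] = None) -> pd.DataFrame:
    """PSE from each participant's own choice curve (NaN where undefined)."""
    mat, levels, subjects = _subject_ratio_matrix(records, valence)
    rows = []
    for sid, ratios in zip(subjects, mat):
        rows.append({"subject_id": sid, "pse": _fit_curve_pse(levels, ratios)})
    return pd.DataFrame(rows)


def pse_difference_test(records_a, records_b, paired: bool = False,
                        valence_a: Optional[str] = None,
                        valence_b: Optional[str] = None,
                        n_iter: int = 200, seed: int = 0) -> PSEDifference:
    """Bootstrap test of PSE(a) − PSE(b).

    ``paired=True`` requires the same subjects in both conditions and
    resamples them jointly; the contrast is significant when 0 falls outside
    the 95% percentile interval of the difference distribution.
    """
    mat_a, lev_a, sub_a = _subject_ratio_matrix(records_a, valence_a)
    mat_b, lev_b, sub_b = _subject_ratio_matrix(records_b, valence_b)
    if paired:
        if sub_a != sub_b:
            raise PayToKnowError("paired test requires identical subjects in both conditions")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_iter)
    for i in range(n_iter):
        idx_a = rng.integers(0, mat_a.shape[0], mat_a.shape[0])
        idx_b = idx_a if paired else rng.integers(0, mat_b.shape[0], mat_b.shape[0])
        pa = _fit_curve_pse(lev_a, np.nanmean(mat_a[idx_a], axis=0))
        pb = _fit_curve_pse(lev_b, np.nanmean(mat_b[idx_b], axis=0))
        diffs[i] = pa - pb
    good = diffs[~np.isnan(diffs)]
    n_failed = int(n_iter - good.size)
    if good.size == 0:
        return PSEDifference(n_iter, diffs, np.nan, (np.nan, np.nan), False, seed, n_failed)
    ci = (float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5)))
    significant = not (ci[0] <= 0.0 <= ci[1])
    return PSEDifference(n_iter, diffs, float(good.mean()), ci, significant, seed, n_failed)
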