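"""Softmax-lapse value models of pay-to-know choices and their estimation.

The core model values the to-know option relative to not-to-know as

    ΔV = α·Δm + β_v·d(t)

where Δm is the token payoff difference (TK − NTK), β_v is the unknown-
aversion weight (shared, or valence-specific: β_pos for positive traits,
β_neg for negative), and d(t) is an optional per-trial discount on the value
of knowing.  A loss-aversion variant replaces the money term with the
difference of per-option utilities u(m) = m for m ≥ 0, λ·m for m < 0.
Choice probabilities follow a softmax with symmetric lapse,

    P(TK) = (1 − 2ε)·σ(γ·ΔV) + ε,

so probabilities are compressed into [ε, 1 − ε].

Identifiability: the likelihood depends on (γα, γβ, ε) only — rescaling
(α, β) by c and γ by 1/c leaves it unchanged.  Estimation therefore pins
α = 1 (money as the numeraire) by default, making fitted β the identified
ratio β/α, in token units, and fitted γ the product γα.  ``fit_alpha=True``
frees α but leaves the model scale-unidentified; use it only for likelihood
values, never for parameter interpretation.

Per-subject models are scored by BIC = k·ln(n) + 2·NLL and compared at the
group level by summing BICs across subjects; the lowest group BIC wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import qmc

from .errors import NonConvergenceError, PayToKnowError
from .parameters import PARAM_BOUNDS, SubjectParameters
from .task import ChoiceRecord, TrialDesign, records_to_frame

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelComparison",
    "MODEL_GRID",
    "value_difference",
    "softmax_lapse",
    "negative_log_likelihood",
    "fit_mle",
    "prediction_accuracy",
    "compare_models",
]

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    Free parameters are the enabled value terms plus γ and ε; α joins them
    only when ``fit_alpha`` is set (see module docstring on identifiability).
    """

    name: str
    valence_specific_beta: bool = False
    temporal_discounting: bool = False
    money_loss_aversion: bool = False
    fit_alpha: bool = False

    @property
    def free_params(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.fit_alpha:
            names.append("alpha")
        if self.valence_specific_beta:
            names += ["beta_pos", "beta_neg"]
        else:
            names.append("beta")
        if self.temporal_discounting:
            names.append("discount")
        if self.money_loss_aversion:
            names.append("loss_lambda")
        names += ["gamma", "epsilon"]
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.free_params)


#: The comparison grid mirroring the study's model family: the
#: valence-specific winner for social evaluations, the shared-aversion winner
#: for nonsocial ones, and the rejected discounting / loss-aversion variants.
MODEL_GRID: tuple[ModelSpec, ...] = (
    ModelSpec(name="valence_specific", valence_specific_beta=True),
    ModelSpec(name="shared_beta"),
    ModelSpec(name="temporal_discounting", valence_specific_beta=True, temporal_discounting=True),
    ModelSpec(name="loss_aversion", valence_specific_beta=True, money_loss_aversion=True),
)


@dataclass
class FitResult:
    spec: ModelSpec
    params: SubjectParameters
    neg_log_lik: float
    bic: float
    n_trials: int
    accuracy: float
    n_starts: int
    converged: bool
    best_start_seed: int
    at_bounds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = self.spec.n_free_params * np.log(self.n_trials) + 2 * self.neg_log_lik
        if not np.isclose(self.bic, expected, rtol=0, atol=1e-8):
            raise PayToKnowError("BIC inconsistent with n_free_params and NLL")


@dataclass
class ModelComparison:
    per_subject_bic: pd.DataFrame      # units (subject-sessions) x model names
    group_bic: pd.Series               # per-model column sums over complete rows
    winner: str
    fits: dict = field(default_factory=dict)   # (unit, model name) -> FitResult
    failures: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# value and likelihood

def _money_utility(m: np.ndarray, lam: float) -> np.ndarray:
    return np.where(m >= 0, m, lam * m)


def value_difference(
    design: TrialDesign,
    params: SubjectParameters,
    spec: ModelSpec = ModelSpec(name="valence_specific", valence_specific_beta=True),
    trial_position: int = 1,
) -> float:
    """ΔV for one trial in the TK−NTK frame.

    Equivalent to the left/right formulation with Δe = ±1 for any screen
    side: writing value differences left-minus-right and flipping sign when
    TK is on the right recovers exactly this quantity.
    """
    if trial_position < 1:
        raise PayToKnowError("trial_position must be >= 1")
    if spec.temporal_discounting and params.discount is None:
        raise PayToKnowError(f"model {spec.name!r} needs params.discount")
    if spec.money_loss_aversion and params.loss_lambda is None:
        raise PayToKnowError(f"model {spec.name!r} needs params.loss_lambda")
    lam = params.loss_lambda if spec.money_loss_aversion else 1.0
    du = float(_money_utility(np.asarray([design.payoff_tk], float), lam)[0]
               - _money_utility(np.asarray([design.payoff_ntk], float), lam)[0])
    beta_v = params.beta_for(design.valence) if spec.valence_specific_beta else params.beta
    d = params.discount ** (trial_position - 1) if spec.temporal_discounting else 1.0
    return params.alpha * du + beta_v * d


def softmax_lapse(dv, gamma: float, epsilon: float):
    """P(choose TK) under the softmax rule with symmetric lapse."""
    return (1.0 - 2.0 * epsilon) * expit(gamma * np.asarray(dv, float)) + epsilon


@dataclass
class _TrialArrays:
    m_tk: np.ndarray
    m_ntk: np.ndarray
    pos: np.ndarray        # bool: positive-valence trait
    t: np.ndarray          # 1-based position within the session
    y: np.ndarray          # bool: chose TK

    @property
    def n(self) -> int:
        return self.y.size


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(data)


def _prepare(data) -> _TrialArrays:
    df = _as_frame(data)
    if len(df) == 0:
        raise PayToKnowError("no trials to fit")
    return _TrialArrays(
        m_tk=df["payoff_tk"].to_numpy(float),
        m_ntk=df["payoff_ntk"].to_numpy(float),
        pos=(df["valence"].to_numpy() == "positive"),
        t=np.arange(1, len(df) + 1, dtype=float),
        y=(df["choice"].to_numpy() == "TK"),
    )


def _nll_grad(theta: np.ndarray, names: tuple[str, ...], arr: _TrialArrays,
              spec: ModelSpec) -> tuple[float, np.ndarray]:
    p = dict(zip(names, theta))
    alpha = p.get("alpha", 1.0)
    gamma, eps = p["gamma"], p["epsilon"]
    lam = p.get("loss_lambda", 1.0)
    disc = p.get("discount", 1.0)

    du = _money_utility(arr.m_tk, lam) - _money_utility(arr.m_ntk, lam)
    if spec.valence_specific_beta:
        beta_v = np.where(arr.pos, p["beta_pos"], p["beta_neg"])
    else:
        beta_v = np.full(arr.n, p["beta"])
    d = disc ** (arr.t - 1.0) if spec.temporal_discounting else 1.0
    dv = alpha * du + beta_v * d
    s = expit(gamma * dv)
    prob = (1.0 - 2.0 * eps) * s + eps
    prob = np.clip(prob, _P_FLOOR, 1.0 - _P_FLOOR)
    nll = -np.where(arr.y, np.log(prob), np.log1p(-prob)).sum()

    # gradient
    r = np.where(arr.y, 1.0 / prob, -1.0 / (1.0 - prob))
    w = r * (1.0 - 2.0 * eps) * s * (1.0 - s)          # dnll/dz pre-sign
    grad = np.empty(len(names))
    for i, name in enumerate(names):
        if name == "gamma":
            g = w * dv
        elif name == "epsilon":
            g = r * (1.0 - 2.0 * s)
        elif name == "alpha":
            g = w * gamma * du
        elif name == "beta":
            g = w * gamma * d
        elif name == "beta_pos":
            g = w * gamma * arr.pos * d
        elif name == "beta_neg":
            g = w * gamma * (~arr.pos) * d
        elif name == "discount":
            dd = (arr.t - 1.0) * disc ** (arr.t - 2.0)
            g = w * gamma * beta_v * dd
        elif name == "loss_lambda":
            dlam = np.minimum(arr.m_tk, 0.0) - np.minimum(arr.m_ntk, 0.0)
            g = w * gamma * alpha * dlam
        else:  # pragma: no cover
            raise PayToKnowError(f"unknown parameter {name!r}")
        grad[i] = -np.sum(g)
    return float(nll), grad


def negative_log_likelihood(data, params: SubjectParameters, spec: ModelSpec) -> float:
    """−Σ log P(observed choice) in nats; probability-floored when ε = 0."""
    arr = _prepare(data)
    names = spec.free_params
    theta = []
    for name in names:
        if name == "beta":
            theta.append(params.beta)
        else:
            v = getattr(params, name)
            if v is None:
                raise PayToKnowError(f"model {spec.name!r} needs params.{name}")
            theta.append(v)
    if not spec.fit_alpha:
        # likelihood still honours the alpha stored on params
        names = ("alpha",) + names
        theta = [params.alpha] + theta
    nll, _ = _nll_grad(np.asarray(theta, float), names, arr, spec)
    return nll


_BOUND_KEY = {"beta": "beta_pos"}  # shared beta uses the common beta bounds


def _bounds_for(names: Sequence[str]) -> list[tuple[float, float]]:
    return [PARAM_BOUNDS[_BOUND_KEY.get(n, n)] for n in names]

_CENTER_START = {"alpha": 1.0, "beta": 0.2, "beta_pos": 0.2, "beta_neg": 0.2,
                 "gamma": 3.0, "epsilon": 0.05, "discount": 0.95, "loss_lambda": 1.5}


#: Default weakly-informative lognormal prior on the inverse temperature,
#: (median, log-SD).  The likelihood of the lapse-softmax model has a nearly
#: flat ridge toward very large gamma, where the choice rule degenerates into
#: a step function and beta becomes arbitrary within a payoff level; a mild
#: penalty on log-gamma regularizes estimation without touching the value
#: parameters.  Pass ``gamma_prior=None`` for pure maximum likelihood.
DEFAULT_GAMMA_PRIOR: tuple[float, float] = (3.0, 1.0)


def fit_mle(data, spec: ModelSpec, n_starts: int = 20, seed: int = 0,
            gamma_prior: tuple[float, float] | None = DEFAULT_GAMMA_PRIOR) -> FitResult:
    """Maximum-likelihood fit of one model to one subject-session.

    Runs bounded L-BFGS-B from ``n_starts`` Latin-hypercube starting points
    plus one field-typical centre start and keeps the best optimum;
    deterministic given (data, spec, n_starts, seed).  By default the
    objective adds a weak lognormal penalty on gamma (see
    :data:`DEFAULT_GAMMA_PRIOR`); the reported ``neg_log_lik`` and ``bic``
    are always the *unpenalized* likelihood at the returned parameters.
    Parameters landing on a bound are flagged in ``at_bounds``.
    """
    if n_starts < 1:
        raise PayToKnowError("n_starts must be >= 1")
    arr = _prepare(data)
    names = spec.free_params
    bounds = _bounds_for(names)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    g_idx = names.index("gamma")

    def objective(x):
        f, g = _nll_grad(x, names, arr, spec)
        if gamma_prior is not None:
            mu, sig = gamma_prior
            lg = np.log(x[g_idx])
            f += 0.5 * ((lg - np.log(mu)) / sig) ** 2
            g = g.copy()
            g[g_idx] += (lg - np.log(mu)) / (sig**2 * x[g_idx])
        return f, g

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_starts)
    starts = lo + (0.02 + 0.96 * unit) * (hi - lo)
    starts = np.vstack([[_CENTER_START[n] for n in names], starts])

    best = None
    best_idx = -1
    diagnostics = []
    for idx, x0 in enumerate(starts):
        try:
            res = minimize(objective, x0, jac=True,
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500})
        except Exception as e:  # optimizer blow-up on a bad start
            diagnostics.append({"start": idx, "error": str(e)})
            continue
        if not np.isfinite(res.fun):
            diagnostics.append({"start": idx, "error": "non-finite objective"})
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best, best_idx = res, idx
    if best is None:
        raise NonConvergenceError("all optimization starts failed", diagnostics)

    fitted = dict(zip(names, best.x))
    at_bounds = tuple(
        n for n, v, (l, h) in zip(names, best.x, bounds)
        if abs(v - l) < 1e-6 or abs(v - h) < 1e-6
    )
    beta_pos = fitted.get("beta_pos", fitted.get("beta"))
    beta_neg = fitted.get("beta_neg", fitted.get("beta"))
    params = SubjectParameters(
        alpha=fitted.get("alpha", 1.0),
        beta_pos=float(beta_pos), beta_neg=float(beta_neg),
        gamma=float(fitted["gamma"]), epsilon=float(fitted["epsilon"]),
        discount=float(fitted["discount"]) if "discount" in fitted else None,
        loss_lambda=float(fitted["loss_lambda"]) if "loss_lambda" in fitted else None,
    )
    nll = float(_nll_grad(best.x, names, arr, spec)[0])
    k = spec.n_free_params
    fit = FitResult(
        spec=spec, params=params, neg_log_lik=nll,
        bic=k * float(np.log(arr.n)) + 2.0 * nll,
        n_trials=arr.n,
        accuracy=_accuracy(arr, params, spec),
        n_starts=n_starts, converged=bool(best.success),
        best_start_seed=best_idx, at_bounds=at_bounds,
    )
    return fit


def _prob_tk(arr: _TrialArrays, params: SubjectParameters, spec: ModelSpec) -> np.ndarray:
    lam = params.loss_lambda if spec.money_loss_aversion else 1.0
    du = _money_utility(arr.m_tk, lam) - _money_utility(arr.m_ntk, lam)
    if spec.valence_specific_beta:
        beta_v = np.where(arr.pos, params.beta_pos, params.beta_neg)
    else:
        beta_v = params.beta
    d = params.discount ** (arr.t - 1.0) if spec.temporal_discounting else 1.0
    dv = params.alpha * du + beta_v * d
    return softmax_lapse(dv, params.gamma, params.epsilon)


def _accuracy(arr: _TrialArrays, params: SubjectParameters, spec: ModelSpec) -> float:
    p = _prob_tk(arr, params, spec)
    credit = np.where(p == 0.5, 0.5, (p > 0.5) == arr.y)
    return float(np.mean(credit))


def prediction_accuracy(data, fit: FitResult) -> float:
    """In-sample fraction of trials whose higher-probability option matches
    the observed choice; exact ties credit 0.5."""
    return _accuracy(_prepare(data), fit.params, fit.spec)


# ---------------------------------------------------------------------------
# group-level comparison

def _iter_units(datasets) -> Iterable[tuple[str, pd.DataFrame]]:
    if isinstance(datasets, Mapping):
        yield from datasets.items()
        return
    df = _as_frame(datasets)
    keys = ["subject_id"]
    if df["treatment"].nunique() > 1:
        keys.append("treatment")
    for key, sub in df.groupby(keys, sort=True):
        label = key[0] if len(keys) == 1 else "/".join(str(k) for k in key)
        yield str(label), sub


def compare_models(datasets, specs: Sequence[ModelSpec], n_starts: int = 20,
                   seed: int = 0, keep_fits: bool = True) -> ModelComparison:
    """Fit every model to every subject-session and select by group BIC.

    Per-unit non-convergence is recorded as a missing cell; models with any
    missing cell are excluded from the winner computation.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise PayToKnowError("need at least 2 model specs to compare")
    units = list(_iter_units(datasets))
    bic = pd.DataFrame(index=[u for u, _ in units],
                       columns=[s.name for s in specs], dtype=float)
    fits: dict = {}
    failures: dict = {}
    for j, spec in enumerate(specs):
        for i, (unit, sub) in enumerate(units):
            try:
                fit = fit_mle(sub, spec, n_starts=n_starts,
                              seed=(seed + 7919 * i) % (2**31))
            except NonConvergenceError as e:
                failures[(unit, spec.name)] = str(e)
                continue
            bic.loc[unit, spec.name] = fit.bic
            if keep_fits:
                fits[(unit, spec.name)] = fit
    group = bic.sum(axis=0, skipna=False)
    complete = group.dropna()
    if complete.empty:
        raise NonConvergenceError("no model converged on every subject")
    winner = str(complete.idxmin())
    return ModelComparison(per_subject_bic=bic, group_bic=group, winner=winner,
                           fits=fits, failures=failures)
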