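"""Statistical models and tests for the phrasing analysis.

* mixed-effects logistic regression of the 1AP/2AP outcome on discourse
  status x group with crossed random intercepts for participant and item
  (in-package Laplace ML, :mod:`prosocontrast.glmm`);
* linear mixed models on log-transformed S2 duration and H f0 with the
  same fixed/random structure (statsmodels MixedLM, ML);
* pooled-variance two-sample t-tests, from raw vectors or from printed
  group summaries;
* Spearman rank correlation;
* AIC comparison between nested random-effect structures.

Outcome coding: TWO_AP = 1, so a positive discourse-status coefficient
means more separate-AP phrasings under contrastive status.  Treatment
coding uses reference levels ``given`` and ``HC``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import glmm
from .errors import (
    ComparisonError,
    ConvergenceError,
    UndefinedStatisticError,
)

CONDITION_REF = "given"
GROUP_REF = "HC"


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    std_error: float
    statistic: float  # Wald z (GLMM) or t (LMM)
    p_value: float


@dataclass
class ModelFit:
    formula: dict
    fixed_effects: list[FixedEffect]
    variance_components: dict[str, float]
    log_likelihood: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    kind: str = "glmm"
    message: str = ""

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(
            f"no fixed effect {name!r}; have "
            + ", ".join(repr(fe.name) for fe in self.fixed_effects)
        )

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "kind": self.kind,
            "fixed_effects": [
                {
                    "name": fe.name,
                    "estimate": fe.estimate,
                    "std_error": fe.std_error,
                    "statistic": fe.statistic,
                    "p_value": fe.p_value,
                }
                for fe in self.fixed_effects
            ],
            "variance_components": self.variance_components,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "message": self.message,
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p_value": self.p_value,
            "mean_1": self.mean_1,
            "mean_2": self.mean_2,
            "sd_1": self.sd_1,
            "sd_2": self.sd_2,
            "n_1": self.n_1,
            "n_2": self.n_2,
        }


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float

    def to_dict(self) -> dict:
        return {"rho": self.rho, "n": self.n, "p_value": self.p_value}


# ---------------------------------------------------------------------------
# two-sample t-tests

def t_test_from_summary(
    mean_1: float,
    sd_1: float,
    n_1: int,
    mean_2: float,
    sd_2: float,
    n_2: int,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test from group summaries.

    Pooled-variance by default (df = n_1 + n_2 - 2); the sign follows
    mean_1 - mean_2; two-tailed p.
    """
    if n_1 < 2 or n_2 < 2:
        raise UndefinedStatisticError("each group needs n >= 2")
    if sd_1 < 0 or sd_2 < 0:
        raise UndefinedStatisticError("standard deviations must be >= 0")
    if sd_1 == 0 and sd_2 == 0 and mean_1 == mean_2:
        raise UndefinedStatisticError(
            "t is undefined: zero variance in both groups and equal means"
        )
    t, p = sps.ttest_ind_from_stats(
        mean_1, sd_1, n_1, mean_2, sd_2, n_2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd_1**2 / n_1, sd_2**2 / n_2
        df = (v1 + v2) ** 2 / (v1**2 / (n_1 - 1) + v2**2 / (n_2 - 1))
    else:
        df = n_1 + n_2 - 2
    return TTestResult(
        t=float(t),
        df=float(df),
        p_value=float(p),
        mean_1=mean_1,
        mean_2=mean_2,
        sd_1=sd_1,
        sd_2=sd_2,
        n_1=n_1,
        n_2=n_2,
    )


def t_test_raw(values_1, values_2, welch: bool = False) -> TTestResult:
    """Two-sample t-test from raw vectors; equals the summary version
    applied to the vectors' means, SDs (ddof=1) and sizes."""
    x = np.asarray(values_1, dtype=float)
    y = np.asarray(values_2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise UndefinedStatisticError("each group needs n >= 2")
    return t_test_from_summary(
        float(x.mean()),
        float(x.std(ddof=1)),
        int(x.size),
        float(y.mean()),
        float(y.std(ddof=1)),
        int(y.size),
        welch=welch,
    )


# ---------------------------------------------------------------------------
# Spearman correlation

def spearman(x, y, method: str = "t", seed: int = 0) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    ``method="t"`` uses the large-sample t approximation (df = n - 2);
    ``method="permutation"`` enumerates all permutations exactly for
    n <= 8 and otherwise uses a seeded Monte Carlo permutation test
    (100000 draws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UndefinedStatisticError("vectors must have equal length")
    n = int(x.size)
    if n < 3:
        raise UndefinedStatisticError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError(
            "Spearman correlation is undefined for a constant vector"
        )
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if method == "t":
        return CorrelationResult(rho=rho, n=n, p_value=float(p_t))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(perm_ry):
        c = np.corrcoef(rx, perm_ry)[0, 1]
        return c

    observed = abs(rho)
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rho(ry[list(perm)])) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        draws = 100_000
        count = 1  # the identity permutation
        for _ in range(draws):
            if abs(_rho(rng.permutation(ry))) >= observed - 1e-12:
                count += 1
        p = count / (draws + 1)
    return CorrelationResult(rho=rho, n=n, p_value=float(p))


# ---------------------------------------------------------------------------
# mixed models

_REQUIRED_COLUMNS = ("condition", "group", "participant_id", "item_id")


def _design(
    data: pd.DataFrame, include_interaction: bool
) -> tuple[np.ndarray, list[str], bool]:
    """Treatment-coded fixed-effect design (reference: given, HC)."""
    cond = (data["condition"].astype(str) == "contrastive").to_numpy(float)
    groups = sorted(data["group"].astype(str).unique())
    multi_group = len(groups) > 1
    cols = [np.ones(len(data)), cond]
    names = ["(Intercept)", "condition[contrastive]"]
    if multi_group:
        grp = (data["group"].astype(str) != GROUP_REF).to_numpy(float)
        cols.append(grp)
        names.append("group[SZ]")
        if include_interaction:
            cols.append(cond * grp)
            names.append("condition[contrastive]:group[SZ]")
    X = np.column_stack(cols)
    return X, names, multi_group


def _check_columns(data: pd.DataFrame, extra: Sequence[str] = ()) -> None:
    missing = [c for c in (*_REQUIRED_COLUMNS, *extra) if c not in data.columns]
    if missing:
        raise KeyError("model data is missing column(s): " + ", ".join(missing))


def fit_mixed_logit(
    data: pd.DataFrame,
    include_interaction: bool = True,
    outcome: str = "outcome",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ModelFit:
    """Binomial GLMM (logit link) with crossed participant/item random
    intercepts, estimated by Laplace-approximate maximum likelihood.

    ``data[outcome]`` is binary with TWO_AP = 1.  With single-group data
    the group and interaction terms are dropped automatically.
    """
    _check_columns(data, (outcome,))
    y = np.asarray(data[outcome], dtype=float)
    X, names, _ = _design(data, include_interaction)
    raw = glmm.fit_crossed_logit(
        y,
        X,
        {
            "participant": data["participant_id"].to_numpy(),
            "item": data["item_id"].to_numpy(),
        },
        max_iter=max_iter,
        tol=tol,
    )
    effects = []
    for name, est, se in zip(names, raw.beta, raw.beta_se):
        z = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        effects.append(FixedEffect(name, float(est), float(se), float(z), float(p)))
    return ModelFit(
        formula={
            "response": outcome,
            "fixed": names[1:],
            "random_intercepts": ["participant", "item"],
        },
        fixed_effects=effects,
        variance_components=raw.variances,
        log_likelihood=raw.loglik,
        aic=raw.aic,
        n_obs=raw.n_obs,
        n_params=raw.n_params,
        converged=raw.converged,
        kind="glmm",
        message=raw.message,
    )


def fit_lmm_log(
    data: pd.DataFrame,
    response_kind: str,
    include_interaction: bool = True,
    pvalue_method: str = "normal",
) -> ModelFit:
    """Linear mixed model on the natural-log response with crossed
    participant/item random intercepts (ML estimation).

    ``response_kind`` is ``"duration"`` (log dur_s2) or ``"f0"``
    (log f0_h).  p-values: ``"normal"`` Wald (default) or
    ``"containment"`` — t with df = n - rank(X) - (number of random
    levels), a conservative containment-style approximation.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    response_col = {"duration": "dur_s2", "f0": "f0_h"}.get(response_kind)
    if response_col is None:
        raise ValueError("response_kind must be 'duration' or 'f0'")
    _check_columns(data, (response_col,))
    values = np.asarray(data[response_col], dtype=float)
    if np.any(values <= 0):
        raise UndefinedStatisticError(
            f"{response_col} must be strictly positive for the log transform"
        )

    X, names, _ = _design(data, include_interaction)
    df = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(1, X.shape[1])])
    df["log_resp"] = np.log(values)
    df["participant_id"] = data["participant_id"].to_numpy()
    df["item_id"] = data["item_id"].to_numpy()
    df["_all"] = 1
    terms = " + ".join(df.columns[: X.shape[1] - 1]) if X.shape[1] > 1 else "1"
    model = MixedLM.from_formula(
        f"log_resp ~ {terms}",
        groups="_all",
        vc_formula={
            "participant": "0 + C(participant_id)",
            "item": "0 + C(item_id)",
        },
        re_formula="0",
        data=df,
    )
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    try:
        # boundary/non-convergence is reported through ModelFit.converged,
        # so the warning chatter is redundant here; variance components at
        # zero often trip lbfgs, in which case powell gets a second try
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            result = model.fit(reml=False, method="lbfgs", maxiter=500)
            converged = bool(getattr(result, "converged", True))
            if not converged:
                retry = model.fit(reml=False, method="powell", maxiter=2000)
                if bool(getattr(retry, "converged", False)):
                    result, converged = retry, True
    except Exception as exc:  # noqa: BLE001 - surfaced as ConvergenceError
        raise ConvergenceError(f"linear mixed model failed: {exc}") from exc

    n_obs = int(len(df))
    n_fixed = X.shape[1]
    vc_names = list(model.exog_vc.names)
    variance = {name: float(v) for name, v in zip(vc_names, result.vcomp)}
    variance["residual"] = float(result.scale)
    n_levels = df["participant_id"].nunique() + df["item_id"].nunique()
    df_contain = max(n_obs - n_fixed - n_levels, 1)

    effects = []
    fe = result.fe_params
    bse = result.bse_fe
    for design_name, pretty in zip(["Intercept"] + [f"x{i}" for i in range(1, n_fixed)], names):
        est = float(fe.iloc[list(fe.index).index(design_name)])
        se = float(bse.iloc[list(bse.index).index(design_name)])
        t = est / se if se > 0 else np.nan
        if pvalue_method == "normal":
            p = 2.0 * sps.norm.sf(abs(t))
        elif pvalue_method == "containment":
            p = 2.0 * sps.t.sf(abs(t), df_contain)
        else:
            raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
        effects.append(FixedEffect(pretty, est, se, float(t), float(p)))

    n_params = n_fixed + len(vc_names) + 1  # + residual variance
    llf = float(result.llf)
    return ModelFit(
        formula={
            "response": f"log({response_col})",
            "fixed": names[1:],
            "random_intercepts": ["participant", "item"],
        },
        fixed_effects=effects,
        variance_components=variance,
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * n_params,
        n_obs=n_obs,
        n_params=n_params,
        converged=converged,
        kind=f"lmm-{response_kind}",
    )


# ---------------------------------------------------------------------------
# AIC comparison

@dataclass(frozen=True)
class AICComparison:
    preferred: str  # "a" or "b" (ties go to "a" by convention)
    delta: float  # |AIC_a - AIC_b|
    signed_delta: float  # AIC_a - AIC_b (antisymmetric under swap)
    tie: bool


def compare_aic(fit_a: ModelFit, fit_b: ModelFit) -> AICComparison:
    """Prefer the lower-AIC fit; both fits must describe the same data."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ComparisonError(
            f"cannot compare fits on different data (n={fit_a.n_obs} vs {fit_b.n_obs})"
        )
    if not (fit_a.converged and fit_b.converged):
        raise ComparisonError("both fits must have converged for AIC comparison")
    signed = fit_a.aic - fit_b.aic
    tie = signed == 0.0
    preferred = "a" if fit_a.aic <= fit_b.aic else "b"
    return AICComparison(
        preferred=preferred, delta=abs(signed), signed_delta=signed, tie=tie
    )
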