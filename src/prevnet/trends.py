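"""Tests for linear trend over waves via generalized estimating equations.

Each outcome is regressed on the wave index (1..4, treated as numeric, so
the coefficient is the change per subsequent time point) with clustering
on the participant id and a robust sandwich covariance.  Binary outcomes
use a logistic GEE and report an odds ratio per time point; continuous
belief outcomes use a linear GEE and report the raw slope.  The working
correlation defaults to exchangeable — a standard choice for repeated
questionnaire waves — with independence available as a cross-check (its
point estimates coincide with pooled regression; only the robust standard
errors differ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .synthetic import PanelData

__all__ = ["TrendResult", "fit_gee_trend", "trend_sensitivity_all_predictors"]

log = logging.getLogger(__name__)

SEPARATION_BOUND = 10.0


@dataclass
class TrendResult:
    outcome: str
    family: str                  # "binomial" or "gaussian"
    effect: float                # OR per time point (binomial) or slope (gaussian)
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_clusters: int
    term: str = "wave"
    flagged: bool = False        # possible separation (|raw coefficient| > 10)

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "term": self.term,
            "family": self.family,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "flagged": self.flagged,
        }


def _families(family: str):
    if family == "binomial":
        return sm.families.Binomial()
    if family == "gaussian":
        return sm.families.Gaussian()
    raise ValueError("family must be 'binomial' or 'gaussian'")


def _cov_struct(working_correlation: str):
    if working_correlation == "exchangeable":
        return sm.cov_struct.Exchangeable()
    if working_correlation == "independence":
        return sm.cov_struct.Independence()
    raise ValueError("working_correlation must be 'exchangeable' or 'independence'")


def _check_panel(df: pd.DataFrame, outcome: str) -> None:
    if df["wave"].nunique() < 2:
        raise ValueError("trend undefined: outcome observed at fewer than 2 waves")
    sizes = df.groupby("participant_id").size()
    if (sizes >= 2).sum() < 2:
        # with singleton clusters GEE collapses to ordinary regression;
        # allowed, but the clustering adjustment is vacuous
        warnings.warn("fewer than 2 clusters with repeated observations; "
                      "GEE reduces to ordinary regression", stacklevel=3)
    if df[outcome].nunique() < 2:
        raise ValueError(f"degenerate outcome {outcome!r}: constant")


def _fit_gee(df: pd.DataFrame, outcome: str, covariates: list[str], family: str,
             working_correlation: str):
    exog = sm.add_constant(df[covariates].astype(float), has_constant="add")
    model = sm.GEE(
        df[outcome].astype(float),
        exog,
        groups=df["participant_id"],
        family=_families(family),
        cov_struct=_cov_struct(working_correlation),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not getattr(res, "converged", True):  # pragma: no cover
        raise RuntimeError("GEE did not converge within 100 iterations")
    return res


def _term_result(res, df, outcome, term, family) -> TrendResult:
    coef = float(res.params[term])
    se = float(res.bse[term])
    z = coef / se if se > 0 else np.inf
    p = float(2 * norm.sf(abs(z)))
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    flagged = abs(coef) > SEPARATION_BOUND
    if family == "binomial":
        effect, lo, hi = np.exp(coef), np.exp(lo), np.exp(hi)
    else:
        effect = coef
    return TrendResult(
        outcome=outcome,
        family=family,
        effect=float(effect),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_obs=len(df),
        n_clusters=df["participant_id"].nunique(),
        term=term,
        flagged=flagged,
    )


def fit_gee_trend(
    panel: PanelData | pd.DataFrame,
    outcome: str,
    family: str = "binomial",
    working_correlation: str = "exchangeable",
) -> TrendResult:
    """Test for linear trend of one outcome across waves.

    Returns the OR per subsequent time point (binomial) or the per-wave
    slope (gaussian) with a 95% robust Wald interval and two-sided p.
    """
    df = panel.df if isinstance(panel, PanelData) else panel
    df = df[["participant_id", "wave", outcome]].dropna()
    _check_panel(df, outcome)
    res = _fit_gee(df, outcome, ["wave"], family, working_correlation)
    return _term_result(res, df, outcome, "wave", family)


def trend_sensitivity_all_predictors(
    panel: PanelData,
    outcome: str,
    working_correlation: str = "exchangeable",
) -> list[TrendResult]:
    """Multivariable logistic GEE: time plus all other roster nodes.

    One model per outcome (PrEP or VLS); returns a TrendResult per
    covariate (wave, then every other node).  Covariates with |raw
    coefficient| > 10 are flagged as possibly separated but kept.
    """
    if outcome not in ("PrEP", "VLS"):
        raise ValueError("sensitivity outcome must be 'PrEP' or 'VLS'")
    covars = [c for c in panel.node_codes if c != outcome]
    df = panel.df[["participant_id", "wave", outcome] + covars].dropna()
    _check_panel(df, outcome)
    res = _fit_gee(df, outcome, ["wave"] + covars, "binomial", working_correlation)
    out = [_term_result(res, df, outcome, term, "binomial") for term in ["wave"] + covars]
    for r in out:
        if r.flagged:
            log.warning("possible separation for covariate %s (outcome %s)", r.term, outcome)
    return out
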