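"""Phenotypic constraints on information use: Poisson count models.

Per-individual counts of social-information acquisition, application
and exploitation are regressed on six phenotypic predictors — relative
rank, boldness, age, sex, strength in the 10 m proximity network and
strength in the directed grooming network — with a troop-level
intercept, followed by backward elimination of non-significant terms.

Two troop-intercept engines are available. With only two troops a
random intercept is weakly identified, so the default engine fits a
fixed intercept per troop (Poisson GLM with a troop factor); the
``random`` engine fits a variational-Bayes Poisson mixed model and
reports posterior means/SDs, for a side-by-side check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .networks import spearman_screen

#: Default predictor set (columns of the design frame).
DEFAULT_PREDICTORS = (
    "relative_rank",
    "boldness",
    "age",
    "sex_code",
    "proximity_strength",
    "grooming_strength",
)

RESPONSES = ("n_acquired", "n_applied", "n_exploited")

ALPHA = 0.05


class ConstraintError(ValueError):
    pass


@dataclass
class TermEstimate:
    predictor: str
    beta: float
    se: float
    stat: float
    p: float


@dataclass
class ConstraintModelFit:
    """A (possibly minimal) count-model fit with its elimination trace."""

    response: str
    engine: str
    terms: list[TermEstimate]
    random_intercept_sd: float
    loglik: float
    deviance: float
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)
    readd_check: dict[str, float] = field(default_factory=dict)
    readd_inconsistent: list[str] = field(default_factory=list)

    def term_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": self.response,
                "predictor": [t.predictor for t in self.terms],
                "beta": [t.beta for t in self.terms],
                "se": [t.se for t in self.terms],
                "t": [t.stat for t in self.terms],
                "p": [t.p for t in self.terms],
            }
        )


def _design(data: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    for col in predictors:
        if col not in data.columns:
            raise ConstraintError(f"missing predictor column {col!r}")
        vals = data[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            raise ConstraintError(f"predictor {col!r} is constant; model is degenerate")
    return data[predictors].astype(float)


def fit_poisson_counts(
    data: pd.DataFrame,
    response: str,
    predictors: list[str] | tuple[str, ...] = DEFAULT_PREDICTORS,
    troop_col: str = "troop_id",
    engine: str = "fixed",
) -> ConstraintModelFit:
    """Fit the full log-link Poisson count model with a troop intercept.

    ``data`` holds one row per individual with the response count, the
    predictor columns and a troop column.  ``engine='fixed'`` (default)
    fits a separate fixed intercept per troop; ``engine='random'`` fits
    a variational Poisson mixed model with a troop random intercept.
    Wald statistics on the coefficient scale give the reported p-values.
    """
    predictors = list(predictors)
    if response not in data.columns:
        raise ConstraintError(f"missing response column {response!r}")
    y = data[response].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ConstraintError(f"response {response!r} must hold nonnegative integer counts")
    X = _design(data, predictors)
    troops = sorted(data[troop_col].unique())

    if engine == "fixed":
        exog = pd.DataFrame(index=data.index)
        # one intercept column per troop (no global intercept)
        for t in troops:
            exog[f"intercept[{t}]"] = (data[troop_col] == t).astype(float)
        for col in predictors:
            exog[col] = X[col]
        model = sm.GLM(y, exog, family=sm.families.Poisson())
        res = model.fit()
        terms = [
            TermEstimate(
                predictor=name,
                beta=float(res.params[name]),
                se=float(res.bse[name]),
                stat=float(res.tvalues[name]),
                p=float(res.pvalues[name]),
            )
            for name in exog.columns
        ]
        return ConstraintModelFit(
            response=response, engine=engine, terms=terms,
            random_intercept_sd=0.0, loglik=float(res.llf),
            deviance=float(res.deviance),
        )
    if engine == "random":
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        if len(troops) < 2:
            raise ConstraintError("random-intercept engine needs >= 2 troops")
        df = pd.concat([pd.Series(y, index=data.index, name="_y"), X], axis=1)
        df["_troop"] = data[troop_col].to_numpy()
        formula = "_y ~ " + " + ".join(predictors)
        model = PoissonBayesMixedGLM.from_formula(formula, {"troop": "0 + C(_troop)"}, df)
        res = model.fit_vb()
        fe_names = list(res.model.exog_names)
        terms = []
        for i, name in enumerate(fe_names):
            mean = float(res.fe_mean[i])
            sd = float(res.fe_sd[i])
            z = mean / sd if sd > 0 else np.inf
            terms.append(
                TermEstimate(predictor="intercept" if name == "Intercept" else name,
                             beta=mean, se=sd, stat=z,
                             p=float(2 * stats.norm.sf(abs(z))))
            )
        vc_sd = float(np.exp(res.vcp_mean[0]))
        return ConstraintModelFit(
            response=response, engine=engine, terms=terms,
            random_intercept_sd=vc_sd, loglik=np.nan, deviance=np.nan,
        )
    raise ConstraintError(f"unknown engine {engine!r}; expected 'fixed' or 'random'")


def _predictor_terms(fit: ConstraintModelFit, predictors: list[str]) -> list[TermEstimate]:
    return [t for t in fit.terms if t.predictor in predictors]


def backward_eliminate(
    data: pd.DataFrame,
    response: str,
    predictors: list[str] | tuple[str, ...] = DEFAULT_PREDICTORS,
    troop_col: str = "troop_id",
    alpha: float = ALPHA,
    engine: str = "fixed",
) -> ConstraintModelFit:
    """Backward-eliminate non-significant predictors, then re-add check.

    Repeatedly drops the predictor with the largest p >= alpha and
    refits until all retained predictors are significant (troop
    intercepts are never dropped).  Each dropped term is then re-added
    singly to the minimal model to confirm it stays non-significant; a
    re-added term that turns significant is flagged in
    ``readd_inconsistent`` but the minimal model is kept.
    """
    current = list(predictors)
    trace: list[tuple[str, float]] = []
    fit = fit_poisson_counts(data, response, current, troop_col, engine)
    while current:
        cand = max(_predictor_terms(fit, current), key=lambda t: t.p)
        if cand.p < alpha:
            break
        current.remove(cand.predictor)
        trace.append((cand.predictor, cand.p))
        fit = fit_poisson_counts(data, response, current, troop_col, engine)
    readd: dict[str, float] = {}
    inconsistent: list[str] = []
    for dropped, _ in trace:
        refit = fit_poisson_counts(data, response, current + [dropped], troop_col, engine)
        p = next(t.p for t in refit.terms if t.predictor == dropped)
        readd[dropped] = p
        if p < alpha:
            inconsistent.append(dropped)
    fit.elimination_trace = trace
    fit.readd_check = readd
    fit.readd_inconsistent = inconsistent
    return fit


def collinearity_screen(
    predictors: pd.DataFrame, concern_threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Spearman correlations among predictors, flagging pairs
    whose |rho| exceeds the collinearity-concern threshold."""
    table = spearman_screen(predictors)
    table["flagged"] = table["rho"].abs() >= concern_threshold
    return table
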