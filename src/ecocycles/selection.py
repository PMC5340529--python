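"""Viability-selection and density-dependence statistics.

Implements the analysis layer applied to per-individual weight samples and
per-population abundance tables: standardized selection differentials with
Welch tests, nonlinear fitting of the logistic non-breeding survival curve,
a mixed model for density-dependent selection (selection differential vs
non-breeding abundance with population random intercepts), and the lagged
fecundity/survival regressions that document delayed density dependence.

Expected table schemas
----------------------
weights:     population, generation, stage ('before'|'after'), weight_mg
abundances:  population, generation, season ('breeding'|'nonbreeding'),
             boundary ('start'|'end'), count
survival:    population, generation, n_start, survivors
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .params import SuParams

__all__ = [
    "SuFit",
    "MixedFitResult",
    "selection_differential",
    "selection_differentials",
    "welch_t",
    "fit_logistic_survival",
    "fit_selection_density_model",
    "fit_delayed_density_models",
]

logger = logging.getLogger(__name__)


def _as_weights(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"{name} must hold at least 2 weights")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{name} must be finite and > 0")
    return x


def selection_differential(before, after, *, mean: float | None = None,
                           sd: float | None = None) -> float:
    """Standardized linear selection differential S for one population-generation.

    Weights are standardized to mean zero and unit variance against the
    pooled before+after sample of that population-generation (pass ``mean``
    and ``sd`` to standardize against an external pool instead), and
    ``S = mean(after) - mean(before)`` on the standardized scale: negative S
    means survivors of the non-breeding season were smaller than the cohort
    entering it.
    """
    before = _as_weights(before, "before")
    after = _as_weights(after, "after")
    pooled = np.concatenate([before, after])
    if mean is None:
        mean = pooled.mean()
    if sd is None:
        sd = pooled.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((after.mean() - mean) / sd - (before.mean() - mean) / sd)


def selection_differentials(weights: pd.DataFrame) -> pd.DataFrame:
    """Per-population-generation S from a long-format weight table.

    Population-generation groups missing either stage, or with fewer than
    two weights in a stage, are dropped.
    """
    out = []
    for (pop, gen), grp in weights.groupby(["population", "generation"]):
        before = grp.loc[grp["stage"] == "before", "weight_mg"].to_numpy()
        after = grp.loc[grp["stage"] == "after", "weight_mg"].to_numpy()
        if len(before) < 2 or len(after) < 2:
            continue
        out.append(
            {"population": pop, "generation": gen,
             "S": selection_differential(before, after)}
        )
    return pd.DataFrame(out)


def welch_t(before, after):
    """Welch's unequal-variance t-test of mean weight after vs before.

    Returns ``(t, df, p)`` with ``t = (mean_after - mean_before) /
    sqrt(s2_a/n_a + s2_b/n_b)``, Welch-Satterthwaite degrees of freedom and
    a two-sided p-value.
    """
    before = _as_weights(before, "before")
    after = _as_weights(after, "after")
    va, vb = after.var(ddof=1), before.var(ddof=1)
    if va == 0 and vb == 0:
        if after.mean() == before.mean():
            # Identical degenerate groups: no evidence of a difference.
            na, nb = len(after), len(before)
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(after, before, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class SuFit:
    """Result of fitting the logistic non-breeding survival curve."""

    params: SuParams
    se_v: float
    se_w: float
    converged: bool
    n: int

    @property
    def v(self) -> float:
        return self.params.v

    @property
    def w(self) -> float:
        return self.params.w


def fit_logistic_survival(survival: pd.DataFrame) -> SuFit:
    """Nonlinear least-squares fit of ``Su(N) = 1 / (1 + (N/v)**w)``.

    ``survival`` needs columns ``n_start`` (abundance at the non-breeding
    start) and ``survivors``; the observed fraction ``survivors / n_start``
    is regressed on ``n_start``.  Returns point estimates with standard
    errors from the Jacobian-based covariance.
    """
    N = survival["n_start"].to_numpy(dtype=float)
    surv = survival["survivors"].to_numpy(dtype=float)
    if len(N) < 3 or len(np.unique(N)) < 3:
        raise ValueError("need >= 3 distinct abundances to fit the curve")
    if np.any(surv > N):
        raise ValueError("survivors exceed starting abundance")
    if np.any(N <= 0):
        raise ValueError("starting abundance must be > 0")
    frac = surv / N

    def su(n, v, w):
        return 1.0 / (1.0 + (n / v) ** w)

    # Start v near the abundance where survival crosses 0.5, w at 2.
    order = np.argsort(np.abs(frac - 0.5))
    v0 = float(np.clip(N[order[0]], 1.0, None))
    try:
        popt, pcov = optimize.curve_fit(
            su, N, frac, p0=[v0, 2.0],
            bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise RuntimeError(f"logistic survival fit did not converge: {err}")
    se = np.sqrt(np.diag(pcov))
    converged = bool(np.all(np.isfinite(se)))
    return SuFit(
        params=SuParams(v=float(popt[0]), w=float(popt[1])),
        se_v=float(se[0]), se_w=float(se[1]),
        converged=converged, n=len(N),
    )


@dataclass
class MixedFitResult:
    """Coefficients of a random-intercept mixed model (or its OLS fallback)."""

    coef: pd.DataFrame          # index: term; columns: estimate, se, t, p
    r2_marginal: float
    r2_conditional: float
    used_random_intercept: bool
    n_obs: int
    n_groups: int


def _fit_random_intercept(df: pd.DataFrame, response: str,
                          terms: list[str]) -> MixedFitResult:
    """S or log-rate regressed on fixed terms with population intercepts.

    Falls back to ordinary least squares when only one population is
    present.  Inference on the fixed effects uses large-sample Wald
    statistics.  Marginal / conditional R2 follow the standard
    variance-partition definitions for linear mixed models.
    """
    exog = sm.add_constant(df[terms], has_constant="add")
    groups = df["population"]
    n_groups = groups.nunique()
    if n_groups < 2:
        logger.warning(
            "single population: falling back to ordinary least squares"
        )
        fit = sm.OLS(df[response], exog).fit()
        coef = pd.DataFrame(
            {"estimate": fit.params, "se": fit.bse,
             "t": fit.tvalues, "p": fit.pvalues}
        )
        r2 = float(fit.rsquared)
        return MixedFitResult(coef, r2, r2, False, int(fit.nobs), 1)

    model = sm.MixedLM(df[response], exog, groups=groups)
    fit = model.fit(reml=True)
    fe = fit.fe_params
    coef = pd.DataFrame(
        {"estimate": fe, "se": fit.bse_fe.loc[fe.index],
         "t": fit.tvalues.loc[fe.index], "p": fit.pvalues.loc[fe.index]}
    )
    var_fixed = float(np.var(np.asarray(exog @ fe)))
    var_rand = float(fit.cov_re.iloc[0, 0])
    var_resid = float(fit.scale)
    total = var_fixed + var_rand + var_resid
    return MixedFitResult(
        coef=coef,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_rand) / total,
        used_random_intercept=True,
        n_obs=int(fit.nobs),
        n_groups=int(n_groups),
    )


def fit_selection_density_model(records: pd.DataFrame) -> MixedFitResult:
    """Selection differential vs non-breeding abundance, population intercepts.

    ``records`` needs columns ``population``, ``S`` and ``N_nb`` (abundance
    at the start of the non-breeding season).  A significantly negative
    slope is the signature of density-dependent viability selection:
    selection for smaller flies strengthens with crowding.
    """
    required = {"population", "S", "N_nb"}
    if missing := required - set(records.columns):
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) < 10:
        raise ValueError("need at least 10 selection records")
    if np.any(records["N_nb"] < 0):
        raise ValueError("N_nb must be >= 0")
    if np.allclose(records["S"].to_numpy(), records["S"].iloc[0]):
        # No variation in S: slope is exactly zero, skip the solver.
        coef = pd.DataFrame(
            {"estimate": [records["S"].iloc[0], 0.0], "se": [0.0, 0.0],
             "t": [np.nan, np.nan], "p": [np.nan, np.nan]},
            index=["const", "N_nb"],
        )
        return MixedFitResult(coef, 0.0, 0.0, False, len(records),
                              records["population"].nunique())
    return _fit_random_intercept(records, "S", ["N_nb"])


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if sd == 0:
        raise ValueError(f"predictor {col.name!r} has zero variance")
    return (col - col.mean()) / sd


def _log_with_offset(rate: pd.Series) -> pd.Series:
    """Log transform with exact zeros offset by half the smallest positive value."""
    rate = rate.astype(float)
    if np.any(rate < 0):
        raise ValueError("rates must be >= 0")
    if np.any(rate == 0):
        positive = rate[rate > 0]
        if positive.empty:
            raise ValueError("all rates are zero; cannot log-transform")
        rate = rate.replace(0.0, positive.min() / 2.0)
    return np.log(rate)


def _season_starts(abundances: pd.DataFrame) -> pd.DataFrame:
    """Wide per-population-generation table of season start/end counts."""
    required = {"population", "generation", "season", "boundary", "count"}
    if missing := required - set(abundances.columns):
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    wide = abundances.pivot_table(
        index=["population", "generation"],
        columns=["season", "boundary"],
        values="count",
    )
    wide.columns = [f"{s}_{b}" for s, b in wide.columns]
    return wide.reset_index()


def fit_delayed_density_models(abundances: pd.DataFrame) -> dict[str, MixedFitResult]:
    """Lagged density regressions for fecundity and non-breeding survival.

    Fecundity (offspring per parent over the breeding season, logged) is
    regressed on current breeding-start abundance B, the previous
    generation's non-breeding-start abundance NB, and their interaction —
    the carry-over structure.  Survival (survivors per individual over the
    non-breeding season, logged) is regressed on current non-breeding-start
    abundance NB and the season-start abundances going back two generations
    (B1, NB1, B2, NB2).  Predictors are standardized to mean 0, SD 1 before
    fitting and population enters as a random intercept.

    Returns ``{"fecundity": MixedFitResult, "survival": MixedFitResult}``.
    """
    wide = _season_starts(abundances)
    need = {"breeding_start", "breeding_end", "nonbreeding_start", "nonbreeding_end"}
    if missing := need - set(wide.columns):
        raise ValueError(f"abundance table lacks {sorted(missing)} counts")
    wide = wide.sort_values(["population", "generation"])
    grp = wide.groupby("population")
    if grp["generation"].count().max() < 3:
        raise ValueError("need >= 3 generations to build two-generation lags")

    wide["B"] = wide["breeding_start"]
    wide["NB"] = wide["nonbreeding_start"]
    wide["B1"] = grp["breeding_start"].shift(1)
    wide["NB1"] = grp["nonbreeding_start"].shift(1)
    wide["B2"] = grp["breeding_start"].shift(2)
    wide["NB2"] = grp["nonbreeding_start"].shift(2)

    wide["fecundity"] = wide["breeding_end"] / wide["breeding_start"]
    wide["survival"] = wide["nonbreeding_end"] / wide["nonbreeding_start"]

    raw = wide.dropna(subset=["B", "NB1", "fecundity"])
    fec = pd.DataFrame({
        "population": raw["population"],
        "log_fecundity": _log_with_offset(raw["fecundity"]),
        "B": _standardize(raw["B"]),
        # NB in the fecundity model is the previous non-breeding season's start.
        "NB": _standardize(raw["NB1"]),
    })
    fec["BxNB"] = fec["B"] * fec["NB"]
    fec_fit = _fit_random_intercept(fec, "log_fecundity", ["B", "NB", "BxNB"])

    sur = wide.dropna(subset=["NB", "B1", "NB1", "B2", "NB2", "survival"]).copy()
    sur["log_survival"] = _log_with_offset(sur["survival"])
    for c in ("NB", "B1", "NB1", "B2", "NB2"):
        sur[c] = _standardize(sur[c])
    sur_fit = _fit_random_intercept(
        sur, "log_survival", ["NB", "B1", "NB1", "B2", "NB2"]
    )
    return {"fecundity": fec_fit, "survival": sur_fit}
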