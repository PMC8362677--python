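"""Lexical/affective predictors of epidemic-specific search change.

The magnitude of a word's differential-correlation measure (natural log
of the absolute value) is related to its normative lexical and affective
variables — valence, arousal, dominance, familiarity, concreteness and
(log) word frequency — first through zero-order parametric and
non-parametric correlations, then through a forward stepwise multiple
regression with a tolerance cutoff of .6 guarding against
multicollinearity (tolerance of a candidate = 1 − R² of that candidate
regressed on the predictors already in the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["PREDICTORS", "RegressionResult", "log_abs_transform",
           "zero_order_correlations", "stepwise_regression"]

PREDICTORS = ("valence", "arousal", "dominance", "familiarity",
              "concreteness", "log_frequency")


def log_abs_transform(values, eps: float = 1e-8):
    """ln|x| with |x| floored at ``eps``; returns (transformed, n_floored).

    The four differential measures are signed; their magnitudes are
    log-transformed to tame right skew before correlation/regression.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mag = np.abs(values)
    floored = mag < eps
    return np.log(np.maximum(mag, eps)), int(floored.sum())


def zero_order_correlations(outcome, predictors: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlation of the outcome with each predictor.

    Pairwise-complete cases per predictor; constant predictors are flagged
    (``defined = False``) rather than returned as NaN surprises.
    """
    outcome = np.asarray(outcome, dtype=float)
    rows = []
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(outcome)
        row = {"predictor": name, "n": int(ok.sum()), "defined": True}
        if ok.sum() < 10 or np.ptp(x[ok]) == 0:
            row.update(defined=False, pearson_r=np.nan, pearson_p=np.nan,
                       spearman_rho=np.nan, spearman_p=np.nan)
        else:
            pr = stats.pearsonr(x[ok], outcome[ok])
            sr = stats.spearmanr(x[ok], outcome[ok])
            row.update(pearson_r=pr.statistic, pearson_p=pr.pvalue,
                       spearman_rho=sr.statistic, spearman_p=sr.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Final stepwise model: per-predictor stats plus the model summary."""

    coefficients: pd.DataFrame      # predictor, b, ci_low, ci_high, t, p, tolerance
    f_value: float
    df_model: int
    df_resid: int
    r_squared: float
    n_used: int
    n_excluded: int
    steps: list = field(default_factory=list)   # entry/removal log

    @property
    def retained(self) -> list:
        return [p for p in self.coefficients["predictor"] if p != "const"]


def _tolerance(candidate: str, included: list, X: pd.DataFrame) -> float:
    """1 − R² of the candidate regressed on the already-included set."""
    if not included:
        return 1.0
    model = sm.OLS(X[candidate], sm.add_constant(X[included])).fit()
    return float(1.0 - model.rsquared)


def stepwise_regression(outcome, predictors: pd.DataFrame,
                        tolerance_cutoff: float = 0.6,
                        entry_p: float = 0.05,
                        removal_p: float = 0.10) -> RegressionResult:
    """Forward stepwise OLS with removal checks and a tolerance guard.

    At each step the candidate with the smallest entry p-value below
    ``entry_p`` whose tolerance against the current model is at least
    ``tolerance_cutoff`` enters; after every entry, included predictors
    whose p-value rises above ``removal_p`` leave (largest first).  Rows
    with any missing value are dropped and counted.  An empty final model
    (intercept only) is a valid result.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="outcome")
    X = predictors.reset_index(drop=True).astype(float)
    y = y.reset_index(drop=True)
    complete = X.notna().all(axis=1) & y.notna()
    n_excluded = int((~complete).sum())
    X, y = X[complete], y[complete]

    included: list = []
    steps: list = []
    while True:
        best_name, best_p = None, entry_p
        for name in X.columns:
            if name in included:
                continue
            # the entrant, and every predictor already in, must keep
            # tolerance >= cutoff in the augmented model
            trial = included + [name]
            if any(_tolerance(v, [u for u in trial if u != v], X)
                   < tolerance_cutoff for v in trial):
                continue
            fit = sm.OLS(y, sm.add_constant(X[included + [name]])).fit()
            p = float(fit.pvalues[name])
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None:
            break
        included.append(best_name)
        steps.append(("enter", best_name, best_p))
        # removal pass
        while included:
            fit = sm.OLS(y, sm.add_constant(X[included])).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) <= removal_p:
                break
            included.remove(worst)
            steps.append(("remove", worst, float(pvals[worst])))

    fit = sm.OLS(y, sm.add_constant(X[included]) if included
                 else np.ones((len(y), 1))).fit()
    ci = fit.conf_int(alpha=0.05)
    if not included:
        ci = np.asarray(ci)
        coeff = pd.DataFrame({
            "predictor": ["const"], "b": [float(fit.params.iloc[0])],
            "ci_low": [float(ci[0, 0])], "ci_high": [float(ci[0, 1])],
            "t": [float(fit.tvalues.iloc[0])], "p": [float(fit.pvalues.iloc[0])],
            "tolerance": [np.nan],
        })
    else:
        names = ["const"] + included
        tol = {"const": np.nan}
        for name in included:
            tol[name] = _tolerance(name, [p for p in included if p != name], X)
        coeff = pd.DataFrame({
            "predictor": names,
            "b": [float(fit.params[n]) for n in names],
            "ci_low": [float(ci.loc[n, 0]) for n in names],
            "ci_high": [float(ci.loc[n, 1]) for n in names],
            "t": [float(fit.tvalues[n]) for n in names],
            "p": [float(fit.pvalues[n]) for n in names],
            "tolerance": [tol[n] for n in names],
        })
    return RegressionResult(
        coefficients=coeff,
        f_value=float(fit.fvalue) if included else np.nan,
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared) if included else 0.0,
        n_used=int(len(y)),
        n_excluded=n_excluded,
        steps=steps,
    )
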