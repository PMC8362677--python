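"""Moderation of rating change by emotional profile: crossed-intercept LMMs.

Per affective dimension and per covariate (PANAS−, PANAS+ or FCV-19S,
centered), the model for the rating difference (current − normative) of
participant s on word i is

    diff_si = b0 + StimType_{g(i)} + slope_{g(i)} * x_s + u_s + w_i + e_si,

with crossed random intercepts u_s (participant) and w_i (word).  The
omnibus tests use a stratified (containment) df convention that follows
the balanced crossed layout exactly:

* StimType       — word stratum:        F(G−1, W−G)
* covariate      — participant stratum: F(1, P−2)
* interaction    — residual stratum:    F(G−1, (P−1)(W−1) − (G−1))

For a fully balanced design (every participant rates every word once)
the default ``engine="strata"`` computes these tests exactly from the
three orthogonal strata (word means, participant means, double-centered
residuals); this coincides with the GLS/REML solution and its ANOVA
variance-component estimators, and reproduces the printed df table of
the 71-participant x 60-word design: (2, 57), (1, 69), (2, 4128).
``engine="reml"`` fits the same model by REML through statsmodels
MixedLM (crossed variance components) and applies the same df rule to
its Wald statistics; a Satterthwaite-style alternative is deliberately
not the default because only the stratified rule matches the reported
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LMMSpec", "LMMResult", "fit_lmm", "stratified_dfs"]


@dataclass
class LMMSpec:
    dimension: str
    covariate: str                       # e.g. "panas_neg"
    group_col: str = "group"
    participant_col: str = "participant"
    word_col: str = "word"
    outcome_col: str = "diff"
    engine: str = "strata"               # "strata" | "reml"


@dataclass
class LMMResult:
    dimension: str
    covariate: str
    #: rows StimType / covariate / interaction; columns F, df1, df2, p
    anova: pd.DataFrame
    #: participant, word, residual variance components (>= 0, boundary flagged)
    varcomps: dict
    #: per-group intercept shifts and covariate slopes with SEs and 95% CIs
    coefficients: pd.DataFrame
    boundary: bool = False
    converged: bool = True
    notes: list = field(default_factory=list)


def stratified_dfs(n_participants: int, n_words: int, n_groups: int = 3):
    """The containment df triplet for the crossed balanced design."""
    resid = (n_participants - 1) * (n_words - 1) - (n_groups - 1)
    return ((n_groups - 1, n_words - n_groups),
            (1, n_participants - 2),
            (n_groups - 1, resid))


def _check_balanced(data, spec: LMMSpec):
    counts = data.groupby([spec.participant_col, spec.word_col]).size()
    p = data[spec.participant_col].nunique()
    w = data[spec.word_col].nunique()
    if len(counts) != p * w or (counts != 1).any():
        raise ValueError(
            "strata engine requires a balanced design: every participant "
            "rated every word exactly once (use engine='reml' otherwise)"
        )
    return p, w


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """Fit one moderation model and return its omnibus table.

    ``data`` is long format with one row per (participant, word); the
    covariate column is a participant-level score and is centered here
    (the interaction F is invariant to centering; the main effects are
    reported at the covariate mean).  StimulusType uses sum-to-zero
    contrasts, under which per-group slopes are mean slope ± deviations.
    """
    data = data.copy()
    x = data[spec.covariate].astype(float)
    data["_x"] = x - x.mean()
    if spec.engine == "strata":
        return _fit_strata(data, spec)
    if spec.engine == "reml":
        return _fit_reml(data, spec)
    raise ValueError(f"unknown engine {spec.engine!r}")


# ------------------------------------------------------------ strata engine

def _fit_strata(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    p_n, w_n = _check_balanced(data, spec)
    groups = sorted(data[spec.group_col].unique())
    g_n = len(groups)
    (df1_a, df2_a), (df1_b, df2_b), (df1_i, df2_i) = \
        stratified_dfs(p_n, w_n, g_n)

    wide = data.pivot(index=spec.participant_col, columns=spec.word_col,
                      values=spec.outcome_col).sort_index()
    word_group = (data.drop_duplicates(spec.word_col)
                  .set_index(spec.word_col)[spec.group_col])
    word_group = word_group.loc[wide.columns]
    xs = (data.drop_duplicates(spec.participant_col)
          .set_index(spec.participant_col)["_x"]).loc[wide.index].to_numpy()
    Y = wide.to_numpy(dtype=float)                       # P x W

    # ---- word stratum: word means regressed on group --------------------
    word_means = Y.mean(axis=0)
    g_codes = word_group.to_numpy()
    grand = word_means.mean()
    group_means = {g: word_means[g_codes == g].mean() for g in groups}
    ss_group = p_n * sum((g_codes == g).sum() * (group_means[g] - grand) ** 2
                         for g in groups)
    ss_word_err = p_n * sum(
        ((word_means[g_codes == g] - group_means[g]) ** 2).sum()
        for g in groups)
    ms_group = ss_group / df1_a
    ms_word_err = ss_word_err / df2_a
    f_a = ms_group / ms_word_err
    p_a = stats.f.sf(f_a, df1_a, df2_a)

    # ---- participant stratum: participant means on the covariate --------
    part_means = Y.mean(axis=1)
    sxx = float((xs ** 2).sum())                          # xs is centered
    slope = float((xs * part_means).sum() / sxx)
    resid_p = part_means - part_means.mean() - slope * xs
    ss_part_err = w_n * float((resid_p ** 2).sum())
    ss_cov = w_n * slope ** 2 * sxx
    ms_part_err = ss_part_err / df2_b
    f_b = (ss_cov / df1_b) / ms_part_err
    p_b = stats.f.sf(f_b, df1_b, df2_b)

    # ---- residual stratum: double-centered interaction ------------------
    R = Y - part_means[:, None] - word_means[None, :] + grand
    # per-group deviation slopes of R on x within the residual stratum
    ss_int = 0.0
    slopes_g = {}
    for g in groups:
        cols = g_codes == g
        rg = R[:, cols].mean(axis=1)                      # P vector
        bg = float((xs * rg).sum() / sxx)
        slopes_g[g] = bg
        ss_int += cols.sum() * bg ** 2 * sxx
    # fitted interaction surface: b_g * x_s on every cell of group g
    fitted = np.zeros_like(R)
    for g in groups:
        fitted[:, g_codes == g] = np.outer(xs * slopes_g[g],
                                           np.ones((g_codes == g).sum()))
    ss_resid = float(((R - fitted) ** 2).sum())
    ms_resid = ss_resid / df2_i
    f_i = (ss_int / df1_i) / ms_resid
    p_i = stats.f.sf(f_i, df1_i, df2_i)

    anova = pd.DataFrame(
        [("StimType", f_a, df1_a, df2_a, p_a),
         (spec.covariate, f_b, df1_b, df2_b, p_b),
         (f"StimType:{spec.covariate}", f_i, df1_i, df2_i, p_i)],
        columns=["effect", "F", "df1", "df2", "p"],
    )

    # ---- variance components (ANOVA estimators, balanced => REML) -------
    v_e = ms_resid
    v_word = max(0.0, ms_word_err / p_n - v_e / p_n)
    v_part = max(0.0, ms_part_err / w_n - v_e / w_n)
    boundary = (ms_word_err / p_n - v_e / p_n < 0) or \
               (ms_part_err / w_n - v_e / w_n < 0)
    varcomps = {"participant": v_part, "word": v_word, "residual": v_e}

    # ---- per-group coefficients -----------------------------------------
    # group means of word means (intercept shifts at x = mean) and
    # per-group slopes (mean slope + stratum deviation), with SEs from
    # the matching stratum variances
    tcrit_b = stats.t.ppf(0.975, df2_b)
    rows = []
    for g in groups:
        w_g = int((g_codes == g).sum())
        mean_g = group_means[g]
        se_mean = np.sqrt(ms_word_err / p_n / w_g)        # word-stratum SE
        slope_g = slope + slopes_g[g]
        # var(b_g) for the group slope: participant stratum contributes the
        # shared mean slope, residual stratum the deviation
        var_bg = (ms_part_err / w_n + ms_resid * (1 / w_g - 1 / w_n)) / sxx
        se_bg = np.sqrt(var_bg)
        rows.append(dict(group=g, n_words=w_g,
                         intercept=mean_g, intercept_se=se_mean,
                         slope=slope_g, slope_se=se_bg,
                         slope_ci_low=slope_g - tcrit_b * se_bg,
                         slope_ci_high=slope_g + tcrit_b * se_bg))
    rows.append(dict(group="(mean)", n_words=w_n,
                     intercept=grand,
                     intercept_se=np.sqrt(ms_word_err / p_n / w_n),
                     slope=slope, slope_se=np.sqrt(ms_part_err / w_n / sxx),
                     slope_ci_low=slope - tcrit_b * np.sqrt(ms_part_err / w_n / sxx),
                     slope_ci_high=slope + tcrit_b * np.sqrt(ms_part_err / w_n / sxx)))
    coefficients = pd.DataFrame(rows)

    return LMMResult(
        dimension=spec.dimension, covariate=spec.covariate,
        anova=anova, varcomps=varcomps, coefficients=coefficients,
        boundary=boundary, converged=True,
    )


# -------------------------------------------------------------- REML engine

def _fit_reml(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    import statsmodels.formula.api as smf
    from patsy.contrasts import Sum  # referenced by the formula string below

    d = data.rename(columns={spec.outcome_col: "_y",
                             spec.group_col: "_g",
                             spec.participant_col: "_p",
                             spec.word_col: "_w"})
    p_n = d["_p"].nunique()
    w_n = d["_w"].nunique()
    g_n = d["_g"].nunique()
    model = smf.mixedlm(
        "_y ~ C(_g, Sum) * _x", d, groups=np.ones(len(d)),
        vc_formula={"participant": "0 + C(_p)", "word": "0 + C(_w)"},
    )
    fit = model.fit(reml=True)

    names = list(fit.model.exog_names)
    k = len(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k, :k]
    beta = np.asarray(fit.fe_params)

    def wald_f(cols):
        L = np.zeros((len(cols), k))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        v = L @ beta
        V = L @ cov @ L.T
        return float(v @ np.linalg.solve(V, v)) / len(cols)

    idx_g = [i for i, n in enumerate(names) if n.startswith("C(_g, Sum)")
             and ":" not in n]
    idx_x = [i for i, n in enumerate(names) if n == "_x"]
    idx_i = [i for i, n in enumerate(names) if ":" in n]
    dfs = stratified_dfs(p_n, w_n, g_n)
    rows = []
    for label, cols, (df1, df2) in [
            ("StimType", idx_g, dfs[0]),
            (spec.covariate, idx_x, dfs[1]),
            (f"StimType:{spec.covariate}", idx_i, dfs[2])]:
        f = wald_f(cols)
        rows.append((label, f, df1, df2, float(stats.f.sf(f, df1, df2))))
    anova = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])

    vc = dict(zip(fit.model.exog_vc.names, fit.vcomp))
    varcomps = {"participant": float(vc.get("participant", np.nan)),
                "word": float(vc.get("word", np.nan)),
                "residual": float(fit.scale)}
    boundary = any(v < 1e-8 for v in fit.vcomp)
    coefficients = pd.DataFrame({
        "term": names, "estimate": beta,
        "se": np.sqrt(np.diag(cov)),
    })
    return LMMResult(
        dimension=spec.dimension, covariate=spec.covariate,
        anova=anova, varcomps=varcomps, coefficients=coefficients,
        boundary=boundary, converged=bool(fit.converged),
    )
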