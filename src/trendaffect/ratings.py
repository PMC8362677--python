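"""Lockdown impact on affective ratings: reliability and effect sizes.

Participants rated 60 words on valence, arousal and dominance (9-point
self-assessment-manikin scale); the same words carry normative means,
SDs and sample sizes from the Italian affective norms.  This module
quantifies the lockdown-related shift:

* reliability — correlation of current item means with the norms, and
  split-half correlations (Spearman–Brown corrected, many random splits);
* a by-items paired t-test per dimension, with the standardized mean
  change d = t/sqrt(n) and a noncentral-t confidence interval;
* per-word Welch t-tests (current raw ratings vs normative summary
  statistics), each yielding a Cohen's d with sampling variance
  (n1+n2)/(n1*n2) + d^2/(2*(n1+n2)) for meta-analysis;
* a fixed-effect internal meta-analysis combining the per-word d's
  within stimulus group, with a between-group heterogeneity statistic
  Q* ~ chi-square(groups − 1);
* a by-items Welch heteroscedastic ANOVA on the per-word rating
  differences across stimulus groups, with eta^2_p = F*df1/(F*df1+df2)
  and pairwise Welch post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "DIMENSIONS",
    "EffectSizeRecord", "MetaResult", "WelchAnovaResult",
    "reliability", "split_half", "spearman_brown",
    "paired_t_items", "d_ci_noncentral_t",
    "welch_t_from_stats", "welch_t_per_word", "effect_table",
    "internal_meta", "eta_squared_partial", "welch_anova_items",
]

DIMENSIONS = ("valence", "arousal", "dominance")


# ---------------------------------------------------------------- reliability

def reliability(current_means: pd.DataFrame,
                norms_means: pd.DataFrame) -> pd.Series:
    """Pearson r between current and normative item means, per dimension.

    Both frames are item x dimension tables sharing an index of words.
    """
    shared = current_means.index.intersection(norms_means.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared items")
    out = {}
    for dim in current_means.columns:
        x = current_means.loc[shared, dim].to_numpy(dtype=float)
        y = norms_means.loc[shared, dim].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[dim] = np.nan
        else:
            out[dim] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name="reliability_r")


def spearman_brown(r: float) -> float:
    """Prophecy correction of a split-half correlation: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half(ratings: pd.DataFrame, n_randomizations: int = 10_000,
               seed=None) -> pd.DataFrame:
    """Randomized split-half reliability, Spearman–Brown corrected.

    ``ratings`` is long format with columns participant, word, dimension,
    value.  Each randomization splits the participants into two halves
    (sizes differing by one when the count is odd), correlates the two
    half-sample item-mean vectors per dimension and applies the 2r/(1+r)
    correction.  Returns per-dimension median, min and max of the
    corrected correlations.  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    dims = sorted(ratings["dimension"].unique())
    wide = {d: ratings[ratings["dimension"] == d]
            .pivot(index="participant", columns="word", values="value")
            .sort_index() for d in dims}
    n_part = len(wide[dims[0]])
    if n_part < 4:
        raise ValueError("need at least 4 participants to split")
    half = n_part // 2

    # one batch of permutations reused across dimensions so halves match
    perms = np.argsort(rng.random((n_randomizations, n_part)), axis=1)
    out = {}
    for d in dims:
        M = wide[d].to_numpy(dtype=float)          # participants x words
        corrected = np.empty(n_randomizations)
        for i in range(n_randomizations):
            idx = perms[i]
            m1 = M[idx[:half]].mean(axis=0)
            m2 = M[idx[half:]].mean(axis=0)
            r = np.corrcoef(m1, m2)[0, 1]
            corrected[i] = spearman_brown(r)
        out[d] = {"median": float(np.median(corrected)),
                  "min": float(corrected.min()),
                  "max": float(corrected.max())}
    return pd.DataFrame(out).T[["median", "min", "max"]]


# ------------------------------------------------------------- paired t-test

def d_ci_noncentral_t(t_value: float, n: float, level: float = 0.95):
    """CI for the standardized mean change d = t/sqrt(n) by inverting the
    noncentral-t distribution of the observed t (df = n − 1)."""
    from scipy.optimize import brentq

    df = n - 1
    alpha = 1.0 - level

    def cdf(nc):
        v = stats.nct.cdf(t_value, df, nc)
        if np.isnan(v):  # deep-tail underflow in scipy's noncentral t
            return 0.0 if nc > t_value else 1.0
        return float(v)

    nc_low = brentq(lambda nc: cdf(nc) - (1 - alpha / 2),
                    t_value - 80, t_value + 80)
    nc_high = brentq(lambda nc: cdf(nc) - alpha / 2,
                     t_value - 80, t_value + 80)
    return nc_low / np.sqrt(n), nc_high / np.sqrt(n)


def paired_t_items(current_means, norms_means) -> dict:
    """By-items paired t-test of current vs normative item means.

    Returns t, df, p, the mean difference (current − norms) with its CI,
    and the standardized mean change d = t/sqrt(n) with a noncentral-t CI.
    """
    x = np.asarray(current_means, dtype=float)
    y = np.asarray(norms_means, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 items")
    diff = x - y
    n = diff.size
    sd = diff.std(ddof=1)
    mean_diff = float(diff.mean())
    if sd == 0:
        if mean_diff == 0:
            return dict(t=0.0, df=n - 1, p=1.0, mean_diff=0.0,
                        mean_ci=(0.0, 0.0), d=0.0, d_ci=(0.0, 0.0))
        raise FloatingPointError(
            "zero variance of differences with nonzero mean (infinite t)")
    se = sd / np.sqrt(n)
    t_value = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t_value), n - 1)
    tcrit = stats.t.ppf(0.975, n - 1)
    d = t_value / np.sqrt(n)
    d_lo, d_hi = (0.0, 0.0) if t_value == 0 else d_ci_noncentral_t(t_value, n)
    return dict(t=float(t_value), df=n - 1, p=float(p),
                mean_diff=mean_diff,
                mean_ci=(mean_diff - tcrit * se, mean_diff + tcrit * se),
                d=float(d), d_ci=(float(d_lo), float(d_hi)))


# ----------------------------------------------------------- per-word Welch t

@dataclass
class EffectSizeRecord:
    word: str
    dimension: str
    mean_current: float
    mean_norms: float
    mean_diff: float
    welch_t: float
    welch_df: float
    p_two_sided: float
    cohens_d: float
    d_var: float
    d_ci_low: float
    d_ci_high: float
    n_current: int
    n_norms: int


def _d_two_sample(m1, s1, n1, m2, s2, n2):
    """Pooled-SD Cohen's d and its large-sample variance."""
    if s1 == 0 and s2 == 0:
        raise FloatingPointError("both samples have zero variance")
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        # one degenerate sample: fall back to the unpooled SD
        pooled = np.sqrt((s1**2 + s2**2) / 2) or max(s1, s2)
    d = (m1 - m2) / pooled
    var = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
    return float(d), float(var)


def welch_t_from_stats(m1, s1, n1, m2, s2, n2):
    """Welch's t with Satterthwaite df from summary statistics."""
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                     equal_var=False)
    v1, v2 = s1**2 / n1, s2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_t_per_word(word: str, dimension: str,
                     current_ratings,
                     norms_mean: float, norms_sd: float, norms_n: int,
                     ) -> EffectSizeRecord:
    """Welch t-test of one word's current ratings against its norms.

    The normative side enters as summary statistics (mean, SD, n) — the
    norms tables publish summaries, not raw participant ratings.
    """
    x = np.asarray(current_ratings, dtype=float)
    if x.size < 2 or norms_n < 2:
        raise ValueError("need at least 2 ratings on each side")
    m1, s1, n1 = float(x.mean()), float(x.std(ddof=1)), x.size
    t, df, p = welch_t_from_stats(m1, s1, n1, norms_mean, norms_sd, norms_n)
    d, d_var = _d_two_sample(m1, s1, n1, norms_mean, norms_sd, norms_n)
    half = 1.959963984540054 * np.sqrt(d_var)
    return EffectSizeRecord(
        word=word, dimension=dimension,
        mean_current=m1, mean_norms=float(norms_mean),
        mean_diff=m1 - float(norms_mean),
        welch_t=t, welch_df=df, p_two_sided=p,
        cohens_d=d, d_var=d_var,
        d_ci_low=d - half, d_ci_high=d + half,
        n_current=n1, n_norms=int(norms_n),
    )


def effect_table(ratings: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Per-word, per-dimension EffectSizeRecords as a DataFrame.

    ``ratings`` is long (participant, word, dimension, value); ``norms``
    has columns word, dimension, mean, sd, n.
    """
    norms_idx = norms.set_index(["word", "dimension"])
    rows = []
    for (word, dim), grp in ratings.groupby(["word", "dimension"], sort=True):
        nm = norms_idx.loc[(word, dim)]
        rec = welch_t_per_word(word, dim, grp["value"].to_numpy(),
                               float(nm["mean"]), float(nm["sd"]),
                               int(nm["n"]))
        rows.append(vars(rec))
    return pd.DataFrame(rows)


# ------------------------------------------------------------- meta-analysis

@dataclass
class MetaResult:
    group: str
    combined_d: float
    ci_low: float
    ci_high: float
    k: int


def internal_meta(records: pd.DataFrame, groups: dict):
    """Fixed-effect inverse-variance combination of per-word d's by group.

    Returns ``(per_group, q_star, q_df, q_p)``: a DataFrame of combined
    d's with 95% CIs, plus the between-group heterogeneity statistic
    Q* = sum_g w_g (d_g − d_..)^2 with w_g the summed inverse variances,
    referred to chi-square(groups − 1).  Groups with no records are
    excluded (warning left to the caller's logging).
    """
    recs = records.copy()
    recs["group"] = recs["word"].map(groups)
    recs = recs[recs["group"].notna()]
    if not np.isfinite(recs["cohens_d"]).all() or \
       not np.isfinite(recs["d_var"]).all():
        raise ValueError("every record needs a finite d and d variance")

    per_group = []
    for g, grp in recs.groupby("group", sort=True):
        w = 1.0 / grp["d_var"].to_numpy()
        d_comb = float(np.sum(w * grp["cohens_d"].to_numpy()) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        per_group.append(dict(group=g, combined_d=d_comb,
                              ci_low=d_comb - 1.959963984540054 * se,
                              ci_high=d_comb + 1.959963984540054 * se,
                              k=len(grp), _w=float(np.sum(w))))
    table = pd.DataFrame(per_group)
    w_g = table["_w"].to_numpy()
    d_g = table["combined_d"].to_numpy()
    d_all = float(np.sum(w_g * d_g) / np.sum(w_g))
    q_star = float(np.sum(w_g * (d_g - d_all) ** 2))
    q_df = len(table) - 1
    q_p = float(stats.chi2.sf(q_star, q_df)) if q_df > 0 else np.nan
    return table.drop(columns="_w"), q_star, q_df, q_p


# --------------------------------------------------------------- Welch ANOVA

@dataclass
class WelchAnovaResult:
    dimension: str
    f_value: float
    df1: int
    df2: float
    p: float
    eta_sq_partial: float
    posthoc: pd.DataFrame
    descriptives: pd.DataFrame


def eta_squared_partial(f_value: float, df1: float, df2: float) -> float:
    """Partial eta squared recovered from an F statistic and its dfs."""
    return float(f_value * df1 / (f_value * df1 + df2))


def welch_anova_items(diffs: pd.DataFrame, dimension: str = "",
                      posthoc: bool = True) -> WelchAnovaResult:
    """Welch heteroscedastic one-way ANOVA on per-item rating differences.

    ``diffs`` has columns ``mean_diff`` (item-level current − norms) and
    ``group``.  Pairwise Welch t post-hocs include pooled-SD Cohen's d
    with its 95% CI.
    """
    counts = diffs.groupby("group")["mean_diff"].agg(["count", "std"])
    if len(counts) < 2 or (counts["count"] < 2).any():
        raise ValueError("need at least 2 groups with at least 2 items each")
    zero_var = counts.index[counts["std"] == 0].tolist()
    if zero_var:
        raise ValueError(f"zero within-group variance in group(s) {zero_var}")

    aov = pg.welch_anova(data=diffs, dv="mean_diff", between="group")
    f_value = float(aov.loc[0, "F"])
    df1 = int(aov.loc[0, "ddof1"])
    df2 = float(aov.loc[0, "ddof2"])
    p = float(aov.loc[0, "p_unc"])

    ph_rows = []
    if posthoc:
        levels = sorted(diffs["group"].unique())
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                xa = diffs.loc[diffs["group"] == a, "mean_diff"].to_numpy()
                xb = diffs.loc[diffs["group"] == b, "mean_diff"].to_numpy()
                res = stats.ttest_ind(xa, xb, equal_var=False)
                d, d_var = _d_two_sample(xa.mean(), xa.std(ddof=1), xa.size,
                                         xb.mean(), xb.std(ddof=1), xb.size)
                half = 1.959963984540054 * np.sqrt(d_var)
                ph_rows.append(dict(group_a=a, group_b=b,
                                    t=float(res.statistic),
                                    df=float(res.df),
                                    p=float(res.pvalue),
                                    cohens_d=d,
                                    d_ci_low=d - half, d_ci_high=d + half))
    desc = diffs.groupby("group")["mean_diff"].agg(["mean", "std", "count"])
    return WelchAnovaResult(
        dimension=dimension, f_value=f_value, df1=df1, df2=df2, p=p,
        eta_sq_partial=eta_squared_partial(f_value, df1, df2),
        posthoc=pd.DataFrame(ph_rows), descriptives=desc,
    )
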