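"""Differential correlation measures for epidemic-specific trend change.

For each word we ask whether its search-trend association with the
epidemic-term reference trace (COVID-RSV) changed from 2019 to 2020.
Four measures are computed per word:

* ``z_pears`` — Steiger's Z comparing the 2020 Pearson correlation
  r(COVID-RSV_2020, word_2020) with the 2019 one, treating the two
  correlations as non-overlapping but dependent (all four series are
  observed on the same aligned days);
* ``z_spear`` — the same test after rank-transforming every series
  (i.e. comparing Spearman correlations);
* ``r_diff`` — Pearson correlation between the word's differential
  series (2020 − 2019) and the reference differential series;
* ``rho_diff`` — its Spearman counterpart.

Positive values mean the 2020 association exceeds the 2019 one.

The Steiger test uses the pooled ("r-bar") form of the Pearson–Filon
covariance between the two Fisher-z transformed correlations:

    Z = (z_jk − z_hm) * sqrt((n − 3) / (2 − 2*s̄)),

where s̄ = ψ(r̄) / (1 − r̄²)², r̄ = (r_jk + r_hm)/2, and ψ is the
Pearson–Filon fourth-moment term evaluated with r̄ substituted for the
two compared correlations.  This is the conventional implementation of
the dependent non-overlapping comparison; tests validate it against a
simulated null (type-I calibration) and a bootstrap standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rsv import differential_series, rank_transform

__all__ = [
    "DegenerateCorrelationError",
    "DiffCorrRecord",
    "pearson_r",
    "spearman_rho",
    "fisher_z",
    "steiger_z_nonoverlapping",
    "multiverse_record",
    "multiverse_table",
]

#: correlations of exactly |1| are clipped here before Fisher z
CLIP = 0.999999


class DegenerateCorrelationError(ValueError):
    """A correlation is undefined (constant input) or the cross-correlation
    structure is degenerate; the affected word should be flagged, not
    silently propagated as NaN."""


@dataclass
class DiffCorrRecord:
    """All four differential measures (plus components) for one word."""

    word: str
    r2019: float
    r2020: float
    rho2019: float
    rho2020: float
    r_diff: float
    rho_diff: float
    z_pears: float
    z_spear: float
    n_days: int


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError("correlation undefined for constant vector")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x, y) -> float:
    """Rank correlation: product-moment correlation of average ranks."""
    return pearson_r(rank_transform(x), rank_transform(y))


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    if abs(r) >= 1:
        raise ValueError(
            "fisher_z undefined at |r| = 1; clip degenerate correlations "
            f"to +/-{CLIP} first"
        )
    return float(np.arctanh(r))


def _clip(r: float, context: str = "") -> float:
    if abs(r) >= 1:
        warnings.warn(
            f"correlation of exactly {r:+.0f} {context}clipped to +/-{CLIP}",
            stacklevel=3,
        )
        return float(np.sign(r)) * CLIP
    return float(r)


def _psi(r_jk, r_hm, r_jh, r_jm, r_kh, r_km) -> float:
    """Pearson–Filon fourth-moment term for cov(r_jk, r_hm)."""
    return 0.5 * (
        (r_jh - r_jk * r_kh) * (r_km - r_kh * r_hm)
        + (r_jm - r_jh * r_hm) * (r_kh - r_jk * r_jh)
        + (r_jh - r_jm * r_hm) * (r_km - r_jk * r_jm)
        + (r_jm - r_jk * r_km) * (r_kh - r_km * r_hm)
    )


def steiger_z_nonoverlapping(r_jk, r_hm, r_jh, r_jm, r_kh, r_km, n):
    """Steiger's Z for two dependent correlations sharing no variable.

    Compares r_jk (here: the 2020 association, variables j = reference
    trace 2020, k = word trace 2020) against r_hm (2019), given the four
    cross-correlations among {j, k, h, m} and the paired sample size n.
    Positive Z means r_jk exceeds r_hm.

    Returns ``(Z, p)`` with a two-sided normal p-value.
    """
    if n < 10:
        raise ValueError("need n >= 10 paired observations")
    r_jk = _clip(r_jk, "(compared) ")
    r_hm = _clip(r_hm, "(compared) ")
    cross = np.array([r_jh, r_jm, r_kh, r_km], dtype=float)
    if np.any(np.abs(cross) > 1):
        raise ValueError("cross-correlations must lie in [-1, 1]")

    R = np.array([
        [1.0, r_jk, r_jh, r_jm],
        [r_jk, 1.0, r_kh, r_km],
        [r_jh, r_kh, 1.0, r_hm],
        [r_jm, r_km, r_hm, 1.0],
    ])
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -1e-8:
        warnings.warn(
            f"cross-correlation matrix not positive semi-definite "
            f"(min eigenvalue {min_eig:.3g}); Z may be unreliable",
            stacklevel=2,
        )

    rbar = (r_jk + r_hm) / 2.0
    sbar = _psi(rbar, rbar, r_jh, r_jm, r_kh, r_km) / (1.0 - rbar**2) ** 2
    denom = 2.0 - 2.0 * sbar
    if denom <= 0:
        raise DegenerateCorrelationError(
            f"non-positive variance of the Fisher-z difference (s-bar = {sbar:.4f})"
        )
    z = (fisher_z(r_jk) - fisher_z(r_hm)) * np.sqrt((n - 3.0) / denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _steiger_from_series(ref20, word20, ref19, word19, corr):
    """Assemble the six correlations for the 2020-vs-2019 comparison."""
    r_jk = corr(ref20, word20)   # 2020 association
    r_hm = corr(ref19, word19)   # 2019 association
    r_jh = corr(ref20, ref19)
    r_jm = corr(ref20, word19)
    r_kh = corr(word20, ref19)
    r_km = corr(word20, word19)
    z, _p = steiger_z_nonoverlapping(r_jk, r_hm, r_jh, r_jm, r_kh, r_km,
                                     n=len(ref20))
    return r_hm, r_jk, z


def multiverse_record(word_pair, covid_pair) -> DiffCorrRecord:
    """All four differential measures for one word.

    Parameters
    ----------
    word_pair, covid_pair : (RSVSeries, RSVSeries)
        The (2019, 2020) aligned series for the word and for the
        epidemic-term reference trace.
    """
    (w19, w20), (c19, c20) = word_pair, covid_pair
    for a, b in [(w19, w20), (c19, w19), (c20, w20)]:
        if len(a) != len(b):
            raise ValueError("series must be aligned to equal length")

    r2019, r2020, z_pears = _steiger_from_series(
        c20.values, w20.values, c19.values, w19.values, pearson_r)
    rho2019, rho2020, z_spear = _steiger_from_series(
        c20.values, w20.values, c19.values, w19.values, spearman_rho)

    d_word = differential_series(w20, w19)
    d_ref = differential_series(c20, c19)
    r_diff = pearson_r(d_ref.values, d_word.values)
    rho_diff = spearman_rho(d_ref.values, d_word.values)

    return DiffCorrRecord(
        word=w19.term,
        r2019=r2019, r2020=r2020,
        rho2019=rho2019, rho2020=rho2020,
        r_diff=r_diff, rho_diff=rho_diff,
        z_pears=z_pears, z_spear=z_spear,
        n_days=len(w19),
    )


MEASURES = ("r_diff", "rho_diff", "z_pears", "z_spear")

#: deterministic CSV column order for the per-word output table
RECORD_COLUMNS = ("word", "r2019", "r2020", "rho2019", "rho2020",
                  "r_diff", "rho_diff", "z_pears", "z_spear", "n_days")


def multiverse_table(word_pairs, covid_pair):
    """Per-word DiffCorrRecords as a DataFrame, flagged words dropped.

    ``word_pairs`` maps word -> (series_2019, series_2020).  Words whose
    correlations are degenerate (constant series) are listed in the
    returned ``flagged`` dict rather than included.
    """
    import pandas as pd

    rows, flagged = [], {}
    for word in sorted(word_pairs):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = multiverse_record(word_pairs[word], covid_pair)
        except DegenerateCorrelationError as exc:
            flagged[word] = str(exc)
            continue
        rows.append({c: getattr(rec, c) for c in RECORD_COLUMNS})
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df, flagged
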