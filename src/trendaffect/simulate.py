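"""Synthetic data with the statistical structure the analyses assume.

Three generators stand in for the study's raw inputs so every pipeline
stage is testable offline:

* ``simulate_rsv`` — per-term daily search-interest traces for two
  matched calendar windows.  The 2019 window is seasonal baseline plus
  AR(1) noise; the 2020 window adds, per word, a coupling coefficient
  kappa_w times an epidemic pulse (a logistic ramp switching on at the
  first-case date); the epidemic terms themselves are pulse plus noise.
  Every series is max-normalized to 100, as search-interest exports are.
* ``simulate_norms`` — a normative lexicon table (valence / arousal /
  dominance / familiarity / concreteness means, SDs, per-word n, word
  frequency, part of speech) with plausible 9-point-scale ranges.
* ``simulate_ratings`` — participant x word x dimension ratings built
  from the crossed random-intercepts model: normative mean + group
  shift + group-specific covariate slope + participant intercept +
  word intercept + residual, with the three variance components scaled
  to requested variance partitioning coefficients (VPCs), then rounded
  to the 9-point scale and clipped to [1, 9].  Rounding happens after
  all effects are added, which attenuates the realized VPCs slightly;
  the returned dataset reports the clipped fraction so configurations
  can keep distortion negligible.

All generators take a ``numpy.random.Generator`` or integer seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rsv import RSVSeries

__all__ = ["TrendSimConfig", "RatingsSimConfig", "SimulatedRatings",
           "COVID_TERMS", "simulate_rsv", "simulate_norms",
           "simulate_ratings", "logistic_pulse"]

COVID_TERMS = ("coronavirus", "covid", "covid-19", "virus")

#: Table-style defaults for the participant questionnaire scores
#: (mean, sd): negative affect, positive affect, epidemic fear
COVARIATE_DEFAULTS = {
    "panas_neg": (19.99, 7.47),
    "panas_pos": (28.08, 6.68),
    "fcv19s": (13.56, 5.46),
}


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TrendSimConfig:
    n_words: int = 100
    year_baseline: int = 2019
    year_epidemic: int = 2020
    window_start: str = "01-01"
    window_end: str = "04-27"
    onset: str = "02-21"            # first confirmed case, epidemic year
    pulse_rate: float = 0.25        # logistic growth rate (1/days)
    coupling: np.ndarray | None = None   # kappa_w in [-1, 1], per word
    seasonal_amplitude: float = 8.0
    ar_phi: float = 0.5
    noise_sd: float = 4.0
    baseline_level: float = 30.0
    pulse_scale: float = 60.0
    seed: int | None = None

    def words(self):
        return [f"w{i:04d}" for i in range(self.n_words)]


def logistic_pulse(n_days: int, onset_index: int, rate: float) -> np.ndarray:
    """Logistic ramp in [0, 1) switching on around ``onset_index``."""
    t = np.arange(n_days, dtype=float)
    return 1.0 / (1.0 + np.exp(-rate * (t - onset_index)))


def _window_dates(year: int, config: TrendSimConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-{config.window_start}",
                         f"{year}-{config.window_end}", freq="D")


def _ar1(rng, n, phi, sd):
    innov = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = innov[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def _normalize(values: np.ndarray) -> np.ndarray:
    """Clip below zero and rescale so the window maximum is 100."""
    v = np.clip(values, 0.0, None)
    m = v.max()
    return np.clip(v * (100.0 / m), 0.0, 100.0) if m > 0 else v


def simulate_rsv(config: TrendSimConfig | None = None, seed=None):
    """Generate (2019, 2020) RSV series for words and epidemic terms.

    Returns ``(series, covid_terms)`` where ``series`` maps
    ``(term, year_window)`` to :class:`RSVSeries`.  Word w couples to the
    epidemic pulse only in the epidemic-year window, with strength
    ``coupling[w] * pulse_scale``; negative coupling suppresses the
    baseline after onset (searches migrating away from a topic).
    """
    config = config or TrendSimConfig()
    rng = _rng(config.seed if seed is None else seed)
    kappa = (np.zeros(config.n_words) if config.coupling is None
             else np.asarray(config.coupling, dtype=float))
    if kappa.shape != (config.n_words,):
        raise ValueError("coupling must have one coefficient per word")
    if np.any(np.abs(kappa) > 1):
        raise ValueError("coupling coefficients must lie in [-1, 1]")

    out = {}
    dates = {y: _window_dates(y, config)
             for y in (config.year_baseline, config.year_epidemic)}
    n_epi = len(dates[config.year_epidemic])
    onset_idx = int((pd.Timestamp(f"{config.year_epidemic}-{config.onset}")
                     - dates[config.year_epidemic][0]).days)
    pulse = logistic_pulse(n_epi, onset_idx, config.pulse_rate)

    for term in COVID_TERMS:
        for year in (config.year_baseline, config.year_epidemic):
            n = len(dates[year])
            base = 3.0 + np.abs(_ar1(rng, n, config.ar_phi, config.noise_sd))
            vals = base.copy()
            if year == config.year_epidemic:
                vals = vals + config.pulse_scale * pulse \
                    + rng.normal(0, config.noise_sd / 2, size=n)
            out[(term, str(year))] = RSVSeries(term, str(year), dates[year],
                                               _normalize(vals))

    day_of_year = {y: (dates[y] - pd.Timestamp(f"{y}-01-01")).days.to_numpy()
                   for y in dates}
    for w, word in enumerate(config.words()):
        phase = rng.uniform(0, 2 * np.pi)
        amp = config.seasonal_amplitude * rng.uniform(0.3, 1.0)
        for year in (config.year_baseline, config.year_epidemic):
            n = len(dates[year])
            seasonal = amp * np.sin(2 * np.pi * day_of_year[year] / 365.0
                                    + phase)
            vals = config.baseline_level + seasonal \
                + _ar1(rng, n, config.ar_phi, config.noise_sd)
            if year == config.year_epidemic and kappa[w] != 0.0:
                vals = vals + kappa[w] * config.pulse_scale * pulse
            out[(word, str(year))] = RSVSeries(word, str(year), dates[year],
                                               _normalize(vals))
    return out, list(COVID_TERMS)


# -------------------------------------------------------------------- norms

def simulate_norms(n_words: int, seed=None,
                   pos_choices=("noun", "verb", "adjective"),
                   pos_probs=(0.6, 0.25, 0.15)) -> pd.DataFrame:
    """Synthetic normative lexicon table (means/SDs/n per word).

    Affective means are drawn wide enough to span the published normative
    ranges; word frequency is log-normal; per-word normative sample sizes
    sit in the low thirties, as in the norms.
    """
    rng = _rng(seed)
    words = [f"w{i:04d}" for i in range(n_words)]
    df = pd.DataFrame({
        "word": words,
        "valence": np.clip(rng.normal(5.2, 1.9, n_words), 1.2, 8.8),
        "arousal": np.clip(rng.normal(5.6, 1.1, n_words), 1.5, 8.5),
        "dominance": np.clip(rng.normal(5.1, 1.0, n_words), 1.5, 8.5),
        "familiarity": np.clip(rng.normal(6.0, 1.2, n_words), 1.0, 9.0),
        "concreteness": np.clip(rng.normal(5.0, 1.6, n_words), 1.0, 9.0),
        "frequency": np.exp(rng.normal(2.5, 1.4, n_words)),
        "pos": rng.choice(pos_choices, size=n_words, p=pos_probs),
    })
    for dim in ("valence", "arousal", "dominance"):
        df[f"{dim}_sd"] = rng.uniform(1.0, 2.3, n_words)
        df[f"{dim}_n"] = rng.integers(30, 40, n_words)
    return df


# ------------------------------------------------------------------ ratings

@dataclass
class RatingsSimConfig:
    n_participants: int = 71
    group_sizes: dict = field(default_factory=lambda: {
        "REL+": 20, "REL-": 20, "UNREL": 20})
    vpc_participant: float = 0.10
    vpc_word: float = 0.15
    vpc_residual: float = 0.75
    total_sd: float = 1.5           # rating units; keeps rounding/clipping mild
    #: per-dimension, per-group mean shift versus the normative means
    #: (defaults: the observed lockdown shifts by stimulus group)
    group_shifts: dict = field(default_factory=lambda: {
        "valence":   {"REL+": -0.76, "REL-": -0.72, "UNREL": -0.40},
        "arousal":   {"REL+": -0.18, "REL-": -0.01, "UNREL": -0.46},
        "dominance": {"REL+": -0.56, "REL-": -0.85, "UNREL": -0.50},
    })
    #: covariate whose per-group slopes enter the generator
    slope_covariate: str = "panas_neg"
    #: per-dimension, per-group slope on the centered covariate
    slopes: dict = field(default_factory=lambda: {
        "valence": {"REL+": 0.0, "REL-": 0.0, "UNREL": 0.0},
        "arousal": {"REL+": 0.0, "REL-": 0.0, "UNREL": 0.0},
        "dominance": {"REL+": 0.0, "REL-": 0.0, "UNREL": 0.0},
    })
    covariates: dict = field(default_factory=lambda: dict(COVARIATE_DEFAULTS))
    round_to_scale: bool = True
    seed: int | None = None


@dataclass
class SimulatedRatings:
    ratings: pd.DataFrame       # participant, word, dimension, value
    participants: pd.DataFrame  # id + questionnaire scores
    words: pd.DataFrame         # word, group
    clipped_fraction: float
    config: RatingsSimConfig


def simulate_ratings(config: RatingsSimConfig | None = None,
                     norms: pd.DataFrame | None = None,
                     seed=None) -> SimulatedRatings:
    """Generate a ratings dataset from the crossed-intercepts model.

    ``norms`` must carry one row per word with per-dimension means
    (columns valence/arousal/dominance); when omitted, a norms table of
    the right size is generated first from the same stream.
    """
    config = config or RatingsSimConfig()
    rng = _rng(config.seed if seed is None else seed)
    n_words = sum(config.group_sizes.values())
    if norms is None:
        norms = simulate_norms(n_words, seed=rng)
    if len(norms) < n_words:
        raise ValueError("norms table smaller than the requested design")
    norms = norms.iloc[:n_words]

    words = norms["word"].tolist()
    group_of = {}
    cursor = 0
    for g, size in config.group_sizes.items():
        for w in words[cursor:cursor + size]:
            group_of[w] = g
        cursor += size

    p_ids = [f"p{i:03d}" for i in range(config.n_participants)]
    participants = pd.DataFrame({"participant": p_ids})
    for name, (mu, sd) in config.covariates.items():
        participants[name] = rng.normal(mu, sd, config.n_participants)

    var_total = config.total_sd ** 2
    sd_u = np.sqrt(config.vpc_participant * var_total)
    sd_w = np.sqrt(config.vpc_word * var_total)
    sd_e = np.sqrt(config.vpc_residual * var_total)
    u = rng.normal(0, sd_u, config.n_participants)
    x = participants[config.slope_covariate].to_numpy()
    x_c = x - x.mean()

    frames = []
    n_clipped = 0
    n_cells = 0
    for dim in ("valence", "arousal", "dominance"):
        base = norms.set_index("word")[dim]
        w_eff = rng.normal(0, sd_w, n_words)
        eps = rng.normal(0, sd_e, (config.n_participants, n_words))
        shift = np.array([config.group_shifts[dim][group_of[w]]
                          for w in words])
        slope = np.array([config.slopes[dim][group_of[w]] for w in words])
        mat = (base.to_numpy()[None, :] + shift[None, :]
               + np.outer(x_c, slope)
               + u[:, None] + w_eff[None, :] + eps)
        if config.round_to_scale:
            mat = np.rint(mat)
        clipped = (mat < 1) | (mat > 9)
        n_clipped += int(clipped.sum())
        n_cells += mat.size
        mat = np.clip(mat, 1.0, 9.0)
        frames.append(pd.DataFrame({
            "participant": np.repeat(p_ids, n_words),
            "word": np.tile(words, config.n_participants),
            "dimension": dim,
            "value": mat.ravel(),
        }))
    ratings = pd.concat(frames, ignore_index=True)
    word_table = pd.DataFrame({"word": words,
                               "group": [group_of[w] for w in words]})
    return SimulatedRatings(
        ratings=ratings,
        participants=participants,
        words=word_table,
        clipped_fraction=n_clipped / n_cells,
        config=config,
    )
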