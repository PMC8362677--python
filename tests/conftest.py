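import io

import numpy as np
import pandas as pd
import pytest

from trendaffect.rsv import RSVSeries
from trendaffect.simulate import (RatingsSimConfig, TrendSimConfig,
                                  simulate_norms, simulate_ratings,
                                  simulate_rsv)


@pytest.fixture
def rng():
    return np.random.default_rng(20200221)


def make_series(term, year, values, start=None):
    values = np.asarray(values, dtype=float)
    start = start or f"{year}-01-01"
    dates = pd.date_range(start, periods=len(values), freq="D")
    return RSVSeries(term, str(year), dates, values)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def small_trend_sim():
    """60 words, 10 coupled each way, moderate noise; plus epidemic terms."""
    kappa = np.zeros(60)
    kappa[:10] = 0.9
    kappa[10:20] = -0.9
    cfg = TrendSimConfig(n_words=60, coupling=kappa, seed=99)
    series, covid_terms = simulate_rsv(cfg)
    return cfg, series, covid_terms


@pytest.fixture(scope="session")
def central_norms():
    """Norms with means kept away from the scale bounds so that clipping
    of simulated ratings is negligible."""
    norms = simulate_norms(60, seed=5)
    for dim in ("valence", "arousal", "dominance"):
        norms[dim] = np.clip(norms[dim], 4.0, 6.0)
    return norms


@pytest.fixture(scope="session")
def ratings_sim(central_norms):
    cfg = RatingsSimConfig(seed=77)
    return simulate_ratings(cfg, central_norms)


def ratings_to_lmm_frame(sim, norms, dimension):
    """Join one dimension's ratings to norms differences and profiles."""
    sub = sim.ratings[sim.ratings["dimension"] == dimension].copy()
    sub["diff"] = sub["value"] - sub["word"].map(
        norms.set_index("word")[dimension])
    sub["group"] = sub["word"].map(dict(zip(sim.words["word"],
                                            sim.words["group"])))
    return sub.merge(sim.participants, on="participant")


@pytest.fixture
def lmm_frame_factory():
    return ratings_to_lmm_frame


def rsv_csv_text(rows):
    buf = io.StringIO()
    pd.DataFrame(rows, columns=["term", "year_window", "date", "value"]
                 ).to_csv(buf, index=False)
    buf.seek(0)
    return buf
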