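"""Stimulus-group selection from the differential-correlation multiverse.

Three word groups are formed from the per-word measures
(r_diff, rho_diff, z_pears, z_spear):

* REL+ — words consistently in the *top* 2.5% tail,
* REL− — words consistently in the *bottom* 2.5% tail,
* UNREL — words with the smallest absolute extremity across measures.

"Consistently" is a two-stage rule: stage 1 admits words in the tail on
at least 3 of the 4 measures; if the group is still short, stage 2
admits words in the tail on at least 2 of 4, ordered by extremity, until
the group size (20) is reached.  Selection is restricted to nouns and
verbs and is fully deterministic: residual ties break lexicographically.

Extremity ordering is the average percentile rank of a word across the
four measures (descending for the top tail, ascending for the bottom);
the UNREL criterion is the smallest average absolute distance of those
percentile ranks from the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diffcorr import MEASURES

__all__ = ["SelectionConfig", "StimulusSet", "ShortfallError",
           "select_extreme", "select_unrelated", "select_stimuli"]


@dataclass
class SelectionConfig:
    group_size: int = 20
    tail_fraction: float = 0.025
    primary_min_measures: int = 3
    fallback_min_measures: int = 2
    allowed_pos: frozenset = frozenset({"noun", "verb"})
    #: compute tail thresholds over admissible-POS words only (True) or
    #: over all words, filtering afterwards (False)
    pos_filter_first: bool = True

    def __post_init__(self) -> None:
        self.allowed_pos = frozenset(self.allowed_pos)
        if not (0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        if not (self.fallback_min_measures < self.primary_min_measures <= 4):
            raise ValueError(
                "need fallback_min_measures < primary_min_measures <= 4"
            )


@dataclass
class StimulusSet:
    rel_plus: list
    rel_minus: list
    unrel: list
    audit: pd.DataFrame = field(repr=False, default=None)

    def all_words(self) -> list:
        return list(self.rel_plus) + list(self.rel_minus) + list(self.unrel)

    def group_of(self) -> dict:
        out = {}
        for g, words in [("REL+", self.rel_plus), ("REL-", self.rel_minus),
                         ("UNREL", self.unrel)]:
            out.update({w: g for w in words})
        return out


class ShortfallError(RuntimeError):
    """Fewer admissible words than the requested group size; carries the
    partial selection so callers can report rather than silently pad."""

    def __init__(self, message, selected, audit):
        super().__init__(message)
        self.selected = selected
        self.audit = audit


def _prepare(records: pd.DataFrame, config: SelectionConfig, pos: dict):
    df = records.set_index("word")[list(MEASURES)].copy()
    df["pos"] = df.index.map(lambda w: pos.get(w, "unknown"))
    if config.pos_filter_first:
        df = df[df["pos"].isin(config.allowed_pos)]
    return df


def _percentile_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """Per-measure percentile rank in (0, 1), midranked ties."""
    n = len(df)
    out = pd.DataFrame(index=df.index)
    for m in MEASURES:
        out[m] = (rankdata(df[m].to_numpy(), method="average") - 0.5) / n
    return out


def _tail_members(df: pd.DataFrame, tail: str, frac: float) -> pd.DataFrame:
    """Boolean table: word x measure, True if in the requested tail.

    Thresholds are empirical quantiles with linear interpolation;
    membership is inclusive at the boundary.
    """
    flags = pd.DataFrame(index=df.index)
    for m in MEASURES:
        vals = df[m].to_numpy()
        if tail == "top":
            thr = np.quantile(vals, 1.0 - frac)
            flags[m] = df[m] >= thr
        elif tail == "bottom":
            thr = np.quantile(vals, frac)
            flags[m] = df[m] <= thr
        else:
            raise ValueError("tail must be 'top' or 'bottom'")
    return flags


def select_extreme(records: pd.DataFrame, tail: str,
                   config: SelectionConfig | None = None,
                   pos: dict | None = None,
                   exclude=()):
    """Two-stage tail-consistency selection of one extreme group.

    Returns ``(words, audit)``; ``audit`` is a DataFrame indexed by word
    with the number of tail measures, the admitting stage and the
    extremity score.  Raises :class:`ShortfallError` when too few words
    qualify (no silent padding).
    """
    config = config or SelectionConfig()
    pos = pos or {}
    df = _prepare(records, config, pos)
    df = df.drop(index=[w for w in exclude if w in df.index])
    if df.empty:
        raise ShortfallError(
            f"no admissible words for the {tail} tail after POS/exclusion "
            "filtering", [], pd.DataFrame())
    if not config.pos_filter_first:
        admissible = df["pos"].isin(config.allowed_pos)
    else:
        admissible = pd.Series(True, index=df.index)

    flags = _tail_members(df, tail, config.tail_fraction)
    n_tail = flags.sum(axis=1)
    pr = _percentile_ranks(df).mean(axis=1)
    extremity = pr if tail == "top" else 1.0 - pr  # larger = more extreme

    audit = pd.DataFrame({
        "n_tail_measures": n_tail,
        "extremity": extremity,
        "stage": 0,
    })

    def ordered(mask):
        cand = audit[mask & admissible].copy()
        cand = cand.sort_values(
            ["extremity"], ascending=False, kind="mergesort"
        )
        # lexicographic tie-break on residual extremity ties
        cand["_w"] = cand.index
        cand = cand.sort_values(["extremity", "_w"],
                                ascending=[False, True], kind="mergesort")
        return list(cand.index)

    selected = []
    stage1 = ordered(n_tail >= config.primary_min_measures)
    for w in stage1[: config.group_size]:
        selected.append(w)
        audit.loc[w, "stage"] = 1
    if len(selected) < config.group_size:
        pool = ordered((n_tail >= config.fallback_min_measures)
                       & ~audit.index.isin(selected))
        for w in pool:
            if len(selected) >= config.group_size:
                break
            selected.append(w)
            audit.loc[w, "stage"] = 2
    if len(selected) < config.group_size:
        raise ShortfallError(
            f"only {len(selected)} of {config.group_size} requested words "
            f"qualify for the {tail} tail",
            selected, audit,
        )
    return selected, audit


def select_unrelated(records: pd.DataFrame,
                     config: SelectionConfig | None = None,
                     pos: dict | None = None,
                     exclude=()):
    """Words with the smallest absolute extremity across the four measures.

    Extremity here is the average over measures of |percentile rank − .5|
    (distance from the median), so a word must be unremarkable on *all*
    measures to qualify.  Words in ``exclude`` (the REL± sets) never enter.
    """
    config = config or SelectionConfig()
    pos = pos or {}
    df = _prepare(records, config, pos)
    df = df.drop(index=[w for w in exclude if w in df.index])
    if not config.pos_filter_first:
        df = df[df["pos"].isin(config.allowed_pos)]
    pr = _percentile_ranks(df)
    abs_extremity = (pr - 0.5).abs().mean(axis=1)
    audit = pd.DataFrame({"abs_extremity": abs_extremity, "stage": 1})
    audit["_w"] = audit.index
    audit = audit.sort_values(["abs_extremity", "_w"],
                              ascending=[True, True], kind="mergesort")
    selected = list(audit.index[: config.group_size])
    if len(selected) < config.group_size:
        raise ShortfallError(
            f"only {len(selected)} of {config.group_size} requested "
            "unrelated words available",
            selected, audit,
        )
    return selected, audit.loc[selected].drop(columns="_w")


def select_stimuli(records: pd.DataFrame,
                   config: SelectionConfig | None = None,
                   pos: dict | None = None) -> StimulusSet:
    """Full three-group selection (REL+, REL−, UNREL), pairwise disjoint."""
    config = config or SelectionConfig()
    rel_plus, audit_p = select_extreme(records, "top", config, pos)
    rel_minus, audit_m = select_extreme(records, "bottom", config, pos,
                                        exclude=rel_plus)
    unrel, audit_u = select_unrelated(records, config, pos,
                                      exclude=rel_plus + rel_minus)
    audit_p = audit_p.loc[rel_plus].assign(group="REL+")
    audit_m = audit_m.loc[rel_minus].assign(group="REL-")
    audit_u = audit_u.assign(group="UNREL")
    audit = pd.concat([audit_p, audit_m, audit_u])
    return StimulusSet(rel_plus, rel_minus, unrel, audit)
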