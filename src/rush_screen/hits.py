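"""Dual-concentration hit calling.

A screen run at a low and a 10-fold higher concentration is summarized per
compound as (z_low, z_high). Candidate activators are the union of the top-K
most-negative Z-scores at either dose, kept if they also score beyond a
threshold at the other dose ("working at both concentrations"); a rescue
rule additionally admits the single best compound at either dose even if it
fails the other-dose threshold (the screen that motivated this pipeline kept
its best low-dose activator, lycorine, exactly this way). Inhibitors mirror
the rule with signs flipped. A well that fails the nuclear-count viability
gate at either dose marks the compound toxic and bars it from both lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HitParams",
    "compound_table",
    "call_activators",
    "call_inhibitors",
    "classify_all",
]


@dataclass(frozen=True)
class HitParams:
    """Hit-calling knobs: shortlist width ``K`` (top-K at either dose),
    other-dose Z threshold ``z_other``, the rank-1 rescue rule, how "both
    concentrations" is operationalized (``threshold`` or ``topk``
    intersection)."""

    K: int = 20
    z_other: float = 1.0
    rescue: bool = True
    both_mode: str = "threshold"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.z_other < 0:
            raise ValueError("z_other must be >= 0")
        if self.both_mode not in ("threshold", "topk"):
            raise ValueError(f"unknown both_mode {self.both_mode!r}")


def compound_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long per-well score table to one row per compound.

    Expects compound wells with ``dose_tier`` in {low, high}; every compound
    must have a score at both doses. Columns out: compound_id, z_low,
    z_high, viable_low, viable_high.
    """
    comp = scores[scores["role"] == "compound"] if "role" in scores else scores
    required = {"compound_id", "dose_tier", "zscore", "viable"}
    missing_cols = required - set(comp.columns)
    if missing_cols:
        raise ValueError(f"score table lacks columns: {sorted(missing_cols)}")

    wide = comp.pivot_table(
        index="compound_id",
        columns="dose_tier",
        values=["zscore", "viable"],
        aggfunc="first",
    )
    for tier in ("low", "high"):
        if ("zscore", tier) not in wide.columns:
            wide[("zscore", tier)] = np.nan
            wide[("viable", tier)] = np.nan
    incomplete = wide.index[
        wide[("zscore", "low")].isna() | wide[("zscore", "high")].isna()
    ].tolist()
    if incomplete:
        raise ValueError(f"compounds missing a dose tier: {incomplete}")
    out = pd.DataFrame(
        dict(
            compound_id=wide.index,
            z_low=wide[("zscore", "low")].to_numpy(float),
            z_high=wide[("zscore", "high")].to_numpy(float),
            viable_low=wide[("viable", "low")].astype(bool).to_numpy(),
            viable_high=wide[("viable", "high")].astype(bool).to_numpy(),
        )
    ).reset_index(drop=True)
    return out.sort_values("compound_id", ignore_index=True)


def _as_compound_table(results: pd.DataFrame) -> pd.DataFrame:
    if "dose_tier" in results.columns:
        return compound_table(results)
    return results.copy()


def _rank(z: pd.Series, ids: pd.Series, sign: int) -> pd.Series:
    """Rank within a direction: rank 1 = strongest (most negative z for
    activators, sign=-1; most positive for inhibitors, sign=+1). Ties break
    lexicographically on compound_id, so ranking is deterministic."""
    key = sign * z.to_numpy(float)
    order = np.lexsort((ids.to_numpy(), -key))  # key descending, ties by id
    ranks = np.empty(len(key), dtype=int)
    ranks[order] = np.arange(1, len(key) + 1)
    return pd.Series(ranks, index=z.index)


def _call_direction(results: pd.DataFrame, params: HitParams, sign: int) -> pd.DataFrame:
    table = _as_compound_table(results)
    eligible = table[table["viable_low"] & table["viable_high"]].copy()
    if eligible.empty:
        return eligible.assign(rank_low=[], rank_high=[], rescue_flag=[])

    eligible["rank_low"] = _rank(eligible["z_low"], eligible["compound_id"], sign)
    eligible["rank_high"] = _rank(eligible["z_high"], eligible["compound_id"], sign)

    top_low = eligible["rank_low"] <= params.K
    top_high = eligible["rank_high"] <= params.K

    def beyond(z: pd.Series) -> pd.Series:
        # "active at the other dose": past the threshold in this direction
        return sign * z >= params.z_other

    if params.both_mode == "topk":
        selected = top_low & top_high
    else:
        # a candidate must be beyond the threshold at the dose(s) OTHER than
        # the one(s) that put it in the top-K
        selected = (top_low | top_high) & (
            (~top_low | beyond(eligible["z_high"]))
            & (~top_high | beyond(eligible["z_low"]))
        )

    rescue_flag = pd.Series(False, index=eligible.index)
    if params.rescue:
        # the single best compound at either dose is kept even if it fails
        # the other-dose requirement, provided it is actually active (in
        # this direction) at its best dose
        best = ((eligible["rank_low"] == 1) & (sign * eligible["z_low"] > 0)) | (
            (eligible["rank_high"] == 1) & (sign * eligible["z_high"] > 0)
        )
        rescue_flag = best & ~selected
        selected = selected | best
    eligible["rescue_flag"] = rescue_flag

    shortlist = eligible[selected].copy()
    return shortlist.sort_values(
        ["rank_low", "rank_high", "compound_id"], ignore_index=True
    )


def call_activators(
    results: pd.DataFrame,
    K: int = 20,
    z_other: float = 1.0,
    rescue: bool = True,
    both_mode: str = "threshold",
) -> pd.DataFrame:
    """Shortlist candidate secretion activators (most NEGATIVE Z-scores).

    Eligible compounds are viable at both doses. The candidate set is the
    union of the top-``K`` at either dose; a candidate is shortlisted when
    its Z-score at the other dose is <= -``z_other``. With ``rescue``, the
    rank-1 compound at either dose enters the shortlist regardless, flagged
    ``rescue_flag``.
    """
    params = HitParams(K=K, z_other=z_other, rescue=rescue, both_mode=both_mode)
    return _call_direction(results, params, sign=-1)


def call_inhibitors(
    results: pd.DataFrame,
    K: int = 20,
    z_other: float = 1.0,
    rescue: bool = False,
    both_mode: str = "threshold",
) -> pd.DataFrame:
    """Shortlist candidate secretion inhibitors: the mirror of
    :func:`call_activators` with signs flipped (rank by most POSITIVE
    Z-score; other-dose requirement z >= +``z_other``). The rescue rule is
    off by default in this direction."""
    params = HitParams(K=K, z_other=z_other, rescue=rescue, both_mode=both_mode)
    return _call_direction(results, params, sign=+1)


def classify_all(results: pd.DataFrame, params: HitParams | None = None) -> pd.DataFrame:
    """Merge both directions and toxicity into one final per-compound table.

    Precedence: toxic (viability failure at either dose — a dead well's low
    GFP is artifactual) > activator > inhibitor > inactive. Ranks are the
    within-direction ranks of the compound's own class (absent otherwise).
    A compound appearing in both shortlists is impossible with a positive
    threshold and raises.
    """
    params = params or HitParams()
    table = _as_compound_table(results)
    activators = _call_direction(table, params, sign=-1)
    inh_params = HitParams(
        K=params.K, z_other=params.z_other, rescue=False, both_mode=params.both_mode
    )
    inhibitors = _call_direction(table, inh_params, sign=+1)

    both = set(activators["compound_id"]) & set(inhibitors["compound_id"])
    if both:
        raise AssertionError(
            f"compound(s) shortlisted in both directions (sign contradiction): {sorted(both)}"
        )

    act = activators.set_index("compound_id")
    inh = inhibitors.set_index("compound_id")
    out = table.copy()
    classification = []
    rank_low = []
    rank_high = []
    rescue = []
    for row in out.itertuples(index=False):
        cid = row.compound_id
        if not (row.viable_low and row.viable_high):
            classification.append("toxic")
            rank_low.append(pd.NA)
            rank_high.append(pd.NA)
            rescue.append(False)
        elif cid in act.index:
            classification.append("activator")
            rank_low.append(int(act.at[cid, "rank_low"]))
            rank_high.append(int(act.at[cid, "rank_high"]))
            rescue.append(bool(act.at[cid, "rescue_flag"]))
        elif cid in inh.index:
            classification.append("inhibitor")
            rank_low.append(int(inh.at[cid, "rank_low"]))
            rank_high.append(int(inh.at[cid, "rank_high"]))
            rescue.append(bool(inh.at[cid, "rescue_flag"]))
        else:
            classification.append("inactive")
            rank_low.append(pd.NA)
            rank_high.append(pd.NA)
            rescue.append(False)
    out["classification"] = classification
    out["rank_low"] = pd.array(rank_low, dtype="Int64")
    out["rank_high"] = pd.array(rank_high, dtype="Int64")
    out["rescue_flag"] = rescue
    return out
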