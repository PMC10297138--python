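"""Plate-level normalization, Z-scoring against negative controls, and the
nuclear-count viability gate.

Sign convention follows the screen's readout: retained cytoplasmic GFP is
the raw signal, so a NEGATIVE Z-score means less retained GFP than the
biotin-only controls (candidate secretion ACTIVATOR) and a POSITIVE Z-score
means blocked release (candidate INHIBITOR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ControlStats",
    "DegenerateScaleError",
    "NEGATIVE_ROLES",
    "POSITIVE_ROLES",
    "control_stats",
    "normalize_and_zscore",
    "viability_gate",
    "score_plate",
    "score_screen",
]

#: Plate-map roles counted as negative controls (unperturbed secretion:
#: biotin-only / DMSO / untreated) and as positive controls (full retention:
#: brefeldin-A-like block or no biotin).
NEGATIVE_ROLES = frozenset({"neg_control", "untreated"})
POSITIVE_ROLES = frozenset({"pos_control", "no_biotin"})

#: Consistency factor making the median absolute deviation an unbiased
#: estimator of the standard deviation under normality.
MAD_TO_SD = 1.4826


class DegenerateScaleError(ValueError):
    """Raised when the negative-control scale is zero and Z-scores are
    undefined."""


@dataclass(frozen=True)
class ControlStats:
    """Robust location/scale of a plate's controls: median and
    1.4826*MAD of the negative-control well GFP, and the median
    positive-control (full-retention) well GFP."""

    neg_mean: float
    neg_sd: float
    pos_mean: float
    n_neg: int
    n_pos: int


def _merged(wells: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    df = wells.merge(
        platemap[["plate_id", "well_id", "role", "compound_id", "dose_tier"]],
        on=["plate_id", "well_id"],
        how="left",
        validate="one_to_one",
    )
    if df["role"].isna().any():
        missing = df.loc[df["role"].isna(), "well_id"].tolist()
        raise ValueError(f"wells absent from plate map: {missing}")
    return df


def control_stats(wells: pd.DataFrame, platemap: pd.DataFrame) -> ControlStats:
    """Robust control statistics of one plate.

    ``neg_mean`` / ``pos_mean`` are medians of the negative / positive
    control ``well_gfp``; ``neg_sd`` is 1.4826 * MAD of the negative
    controls. Requires at least two negative-control wells with cells.
    """
    df = _merged(wells, platemap)
    plates = df["plate_id"].unique()
    if len(plates) != 1:
        raise ValueError(f"control_stats expects one plate, got {sorted(plates)}")
    plate = plates[0]

    neg = df[df["role"].isin(NEGATIVE_ROLES) & (df["n_cells"] > 0)]["well_gfp"].dropna()
    pos = df[df["role"].isin(POSITIVE_ROLES) & (df["n_cells"] > 0)]["well_gfp"].dropna()
    if len(neg) < 2:
        raise ValueError(
            f"plate {plate}: need >= 2 negative-control wells with cells, found {len(neg)}"
        )
    if len(pos) < 1:
        raise ValueError(f"plate {plate}: no positive-control well with cells")
    neg_mean = float(neg.median())
    neg_sd = float(MAD_TO_SD * np.median(np.abs(neg - neg_mean)))
    return ControlStats(
        neg_mean=neg_mean,
        neg_sd=neg_sd,
        pos_mean=float(pos.median()),
        n_neg=len(neg),
        n_pos=len(pos),
    )


def normalize_and_zscore(wells: pd.DataFrame, stats: ControlStats) -> pd.DataFrame:
    """Add ``normalized_activity`` and ``zscore`` columns to a wells table.

    ``normalized_activity = (raw - neg_mean) / (pos_mean - neg_mean)``
    (0 = secretion like the biotin-only controls, 1 = full retention);
    ``zscore = (raw - neg_mean) / neg_sd``. A zero negative-control scale
    raises :class:`DegenerateScaleError`; coincident control means leave the
    normalized activity undefined (NaN) but Z-scores are still produced.
    """
    if stats.neg_sd == 0:
        raise DegenerateScaleError(
            "negative-control MAD is zero: Z-scores are undefined on this plate"
        )
    out = wells.copy()
    raw = out["well_gfp"].astype(float)
    out["zscore"] = (raw - stats.neg_mean) / stats.neg_sd
    span = stats.pos_mean - stats.neg_mean
    if span == 0:
        out["normalized_activity"] = np.nan
        out["normalization_degenerate"] = True
    else:
        out["normalized_activity"] = (raw - stats.neg_mean) / span
        out["normalization_degenerate"] = False
    return out


def viability_gate(
    wells: pd.DataFrame, platemap: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Flag wells whose nuclear count falls below ``min_fraction`` of the
    plate's negative-control median count (cytotoxicity proxy).

    Returns the wells table with ``viability_ratio`` and ``viable`` columns.
    """
    df = _merged(wells, platemap)
    out = wells.copy()
    ratios = np.empty(len(out))
    viable = np.empty(len(out), dtype=bool)
    for plate, grp in df.groupby("plate_id"):
        ref = grp[grp["role"].isin(NEGATIVE_ROLES)]["n_cells"]
        ref_median = float(ref.median()) if len(ref) else 0.0
        if ref_median <= 0:
            raise ValueError(
                f"plate {plate}: negative-control median cell count is zero"
            )
        idx = df["plate_id"] == plate
        ratios[idx.to_numpy()] = grp["n_cells"] / ref_median
    viable = ratios >= min_fraction
    out["viability_ratio"] = ratios
    out["viable"] = viable
    return out


def score_plate(
    wells: pd.DataFrame,
    platemap: pd.DataFrame,
    min_viability: float = 0.5,
) -> pd.DataFrame:
    """Score one plate: control stats -> normalization + Z-score ->
    viability gate. Returns one row per well with role/compound annotations.
    Non-viable wells keep their scores; exclusion happens at hit calling.
    """
    stats = control_stats(wells, platemap)
    scored = normalize_and_zscore(wells, stats)
    scored = viability_gate(scored, platemap, min_fraction=min_viability)
    out = _merged(scored, platemap)
    out = out.rename(columns={"well_gfp": "raw"})
    cols = [
        "plate_id", "well_id", "role", "compound_id", "dose_tier",
        "n_cells", "raw", "normalized_activity", "zscore",
        "viability_ratio", "viable",
    ]
    return out[cols]


def score_screen(
    wells: pd.DataFrame,
    platemap: pd.DataFrame,
    min_viability: float = 0.5,
) -> pd.DataFrame:
    """Score every plate of a screen independently and concatenate. Each
    plate is normalized against its own controls."""
    frames = []
    for plate, grp in wells.groupby("plate_id", sort=True):
        pm = platemap[platemap["plate_id"] == plate]
        frames.append(score_plate(grp.reset_index(drop=True), pm, min_viability))
    if not frames:
        raise ValueError("no plates to score")
    return pd.concat(frames, ignore_index=True)
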