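"""Crystal-violet microtiter biofilm-assay scoring.

Each well contributes one OD595/OD600 ratio (crystal-violet stain
normalised by culture density); ratios are aggregated per strain and a
strain whose aggregate ratio strictly exceeds 5 is called a biofilm
former.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AssayConfig", "score_strain", "score_plate", "classify_former"]


@dataclass(frozen=True)
class AssayConfig:
    """former_threshold: aggregate ratio above which (strictly) a strain is
    a biofilm former. blank_od595 is subtracted from each well's OD595
    before the ratio (default 0, i.e. no blank correction)."""

    former_threshold: float = 5.0
    aggregation: str = "mean"
    blank_od595: float = 0.0

    def __post_init__(self) -> None:
        if self.former_threshold <= 0:
            raise ValueError("former_threshold must be positive")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")


def _ratios(wells: pd.DataFrame, cfg: AssayConfig) -> np.ndarray:
    od595 = wells["od595"].to_numpy(dtype=float) - cfg.blank_od595
    od600 = wells["od600"].to_numpy(dtype=float)
    bad = od600 <= 0
    if bad.any():
        for _, row in wells[bad].iterrows():
            logger.warning("dropping well (strain %s, replicate %s): "
                           "nonpositive OD600", row.get("strain_id"),
                           row.get("replicate"))
    return od595[~bad] / od600[~bad]


def score_strain(wells: pd.DataFrame,
                 cfg: AssayConfig = AssayConfig()) -> dict:
    """Aggregate one strain's wells into a mean (or median) ratio.

    Wells with nonpositive OD600 are dropped with a log entry; at least
    one valid well is required. The standard deviation is NaN for n = 1.
    """
    r = _ratios(wells, cfg)
    if len(r) == 0:
        raise ValueError("no valid wells for strain")
    agg = float(np.mean(r) if cfg.aggregation == "mean" else np.median(r))
    return {
        "strain_id": wells["strain_id"].iloc[0],
        "mean_ratio": agg,
        "sd_ratio": float(np.std(r, ddof=1)) if len(r) > 1 else float("nan"),
        "n": int(len(r)),
    }


def classify_former(mean_ratio: float,
                    cfg: AssayConfig = AssayConfig()) -> bool:
    """Biofilm former iff the aggregate ratio strictly exceeds the threshold."""
    if mean_ratio < 0:
        raise ValueError("mean_ratio must be nonnegative")
    return mean_ratio > cfg.former_threshold


def score_plate(plate: pd.DataFrame,
                cfg: AssayConfig = AssayConfig()) -> pd.DataFrame:
    """Score every strain on a plate; one row per strain with the call."""
    rows = []
    for _, wells in plate.groupby("strain_id", sort=True):
        row = score_strain(wells, cfg)
        row["is_former"] = classify_former(row["mean_ratio"], cfg)
        rows.append(row)
    return pd.DataFrame(rows)
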