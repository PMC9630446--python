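"""Missense-mutation proximity scores.

For each mutation event the score counts the other events within a +/-7-residue
window and divides by the distance to the nearest other event.  Computed once
per protein in local coordinates (``prox_ratio_each``) and once with every
family member's events projected onto shared alignment columns
(``prox_ratio_all``); the sum of the two ratios is the parallel cluster score
``pclust_score`` used as a modeling covariate and for stratifying activities.

Conventions (configurable where noted):
- the window count excludes the index event itself; distinct substitutions at
  the same position count as neighbours at distance 0;
- nearest distances are clamped below at 1 so co-positional events score
  maximal clustering instead of dividing by zero;
- an event with no other event in its coordinate system, or none inside the
  window, has ratio 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import CoordinateMap, ValidationError, VariantTable

DEFAULT_WINDOW = 7

SCORE_COLUMNS = [
    "window_count_each", "nearest_dist_each", "prox_ratio_each",
    "window_count_all", "nearest_dist_all", "prox_ratio_all",
    "pclust_score",
]


def window_count(events: list[int], index: int, w: int = DEFAULT_WINDOW) -> int:
    """Number of other events within +/-``w`` residues of ``events[index]``."""
    if w < 1:
        raise ValueError("window must be >= 1")
    pos = events[index]
    return sum(1 for j, p in enumerate(events) if j != index and abs(p - pos) <= w)


def nearest_distance(events: list[int], index: int) -> int | None:
    """Distance to the nearest other event, clamped at 1; None for a singleton."""
    pos = events[index]
    dists = [abs(p - pos) for j, p in enumerate(events) if j != index]
    if not dists:
        return None
    return max(1, min(dists))


def prox_ratio(events: list[int], w: int = DEFAULT_WINDOW) -> list[float]:
    """Per-event window count divided by nearest distance (0 if count is 0)."""
    counts, dists, ratios = _prox_arrays(np.asarray(events, dtype=float), w)
    return list(ratios)


def _prox_arrays(pos: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized counts / clamped nearest distances / ratios for one event pool."""
    n = len(pos)
    if n == 0:
        z = np.zeros(0)
        return z, z, z
    if n == 1:
        return np.zeros(1), np.full(1, np.nan), np.zeros(1)
    d = np.abs(pos[:, None] - pos[None, :])
    np.fill_diagonal(d, np.inf)
    counts = (d <= w).sum(axis=1).astype(float)
    nearest = np.maximum(d.min(axis=1), 1.0)
    ratios = np.where(counts > 0, counts / nearest, 0.0)
    return counts, nearest, ratios


def prox_ratio_each(table: VariantTable, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Within-protein proximity scores, computed independently per member."""
    df = table.df
    out = pd.DataFrame(index=df.index,
                       columns=["window_count_each", "nearest_dist_each",
                                "prox_ratio_each"], dtype=float)
    for _, idx in df.groupby("protein_id").groups.items():
        pos = df.loc[idx, "position"].to_numpy(dtype=float)
        counts, nearest, ratios = _prox_arrays(pos, w)
        out.loc[idx, "window_count_each"] = counts
        out.loc[idx, "nearest_dist_each"] = nearest
        out.loc[idx, "prox_ratio_each"] = ratios
    return out


def prox_ratio_all(table: VariantTable, cmap: CoordinateMap,
                   w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Aggregate proximity scores with all members projected onto alignment columns."""
    df = table.df
    cols = np.empty(len(df), dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            cols[i] = cmap.column_from_full(str(row.protein_id), int(row.position))
        except (KeyError, ValidationError) as exc:
            raise ValidationError(
                f"variant {row.protein_id}:{row.position}{row.mut_aa} "
                f"cannot be projected onto the alignment: {exc}") from None
    counts, nearest, ratios = _prox_arrays(cols, w)
    return pd.DataFrame({"window_count_all": counts, "nearest_dist_all": nearest,
                         "prox_ratio_all": ratios}, index=df.index)


def pclust_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Attach the parallel cluster score: exact sum of the two ratios."""
    out = scores.copy()
    out["pclust_score"] = out["prox_ratio_each"] + out["prox_ratio_all"]
    return out


def compute_cluster_scores(table: VariantTable, cmap: CoordinateMap,
                           w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """All cluster-score columns for a variant table (row-aligned to the table)."""
    each = prox_ratio_each(table, w)
    allp = prox_ratio_all(table, cmap, w)
    return pclust_score(pd.concat([each, allp], axis=1))


@dataclass
class Stratification:
    """Variants split at a cluster-score threshold, with group activity summaries."""

    threshold: float
    low_activities: np.ndarray
    high_activities: np.ndarray
    mean_low: float
    mean_high: float
    mean_difference: float  # mean(low) - mean(high)


def stratify_by_pclust(scores: pd.Series | np.ndarray,
                       activities: pd.Series | np.ndarray,
                       threshold: float = 1.5) -> Stratification:
    """Split activities into low/high cluster-score groups (ties go to low)."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(activities, dtype=float)
    if s.shape != a.shape:
        raise ValueError("scores and activities must be aligned")
    low, high = a[s <= threshold], a[s > threshold]
    if len(low) == 0 or len(high) == 0:
        warnings.warn(f"one stratification group is empty at threshold {threshold}; "
                      "no group comparison possible", stacklevel=2)
    mean_low = float(low.mean()) if len(low) else float("nan")
    mean_high = float(high.mean()) if len(high) else float("nan")
    return Stratification(threshold, low, high, mean_low, mean_high,
                          mean_low - mean_high)
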