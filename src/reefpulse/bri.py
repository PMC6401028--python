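"""Bleaching Response Index (BRI).

Colonies (here, scored coral points) fall into seven ordered severity
categories: normal, pale, 0-20%, 20-50%, 50-80%, 80-100% bleached, and
recently dead.  The index is the weighted mean of the category proportions,

    BRI = (0*c1 + 1*c2 + ... + 6*c7) / 6,

which ranges from 0 (all normal) to 1 (all recently dead).  A variant with
weights 0..7 over the same seven categories (divisor 6) is available via
``weights="zero_to_seven"`` for comparison with sources that print that
form; it can exceed 1.  Proportions are fractions by default; pass
``percent=True`` to report the index x100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import BLEACH_STATES, SurveyDataset

N_CATEGORIES = 7
_WEIGHTS = {
    "zero_to_six": np.arange(7, dtype=float),
    "zero_to_seven": np.arange(1, 8, dtype=float),
}
_DIVISOR = 6.0


@dataclass(frozen=True)
class BleachTally:
    """Proportions of scored points in each severity category.

    ``c`` holds the seven proportions in severity order (sum 1); ``n`` is the
    number of scored points; ``scope`` identifies (site, depth, year, taxon).
    """

    c: np.ndarray
    n: int
    scope: dict

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.shape != (N_CATEGORIES,):
            raise ValueError(f"need {N_CATEGORIES} category proportions, got {c.shape}")
        if (c < -1e-12).any():
            raise ValueError("negative proportions")
        if abs(c.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {c.sum()}, not 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def tally_bleach_states(ds: SurveyDataset, **scope) -> BleachTally:
    """Tally severity proportions over scored coral points in a scope.

    ``scope`` filters by record columns (e.g. ``site_id=..., year=...,
    taxon=...``); omit ``taxon`` to pool all corals.  Raises if the scope
    contains no scored points.
    """
    sub = ds.subset(**scope) if scope else ds
    scored = sub.records[sub.records["bleach_state"].notna()]
    if scored.empty:
        raise ValueError(f"no bleach-state annotations in scope {scope}")
    counts = scored["bleach_state"].value_counts()
    c = np.array([counts.get(s, 0) for s in BLEACH_STATES], dtype=float)
    n = int(c.sum())
    return BleachTally(c / n, n, dict(scope))


def compute_bri(
    tally: BleachTally, weights: str = "zero_to_six", percent: bool = False
) -> float:
    """Weighted-mean severity index of a tally (0 = all normal)."""
    w = _WEIGHTS[weights]
    bri = float(np.dot(w, tally.c) / _DIVISOR)
    return bri * 100.0 if percent else bri


def pool_tallies(tallies: list[BleachTally], scope: dict | None = None) -> BleachTally:
    """Point-count-weighted pooling of tallies (e.g. per-taxon -> site level)."""
    if not tallies:
        raise ValueError("no tallies to pool")
    n = sum(t.n for t in tallies)
    c = sum(t.c * t.n for t in tallies) / n
    return BleachTally(c, n, scope or {"pooled": True})


def delta_bri(bri_earlier: float, bri_later: float) -> float:
    """Year-to-year change, earlier event minus later (positive = decline in
    bleaching response between events)."""
    return bri_earlier - bri_later


def bri_table(
    ds: SurveyDataset,
    by_taxon: bool = True,
    weights: str = "zero_to_six",
) -> pd.DataFrame:
    """BRI per (site, depth band, year[, taxon]) as a tidy table."""
    scored = ds.records[ds.records["bleach_state"].notna()]
    if scored.empty:
        raise ValueError("dataset has no scored coral points")
    keys = ["site_id", "depth_band", "year"] + (["taxon"] if by_taxon else [])
    rows = []
    for key_vals, grp in scored.groupby(keys):
        counts = grp["bleach_state"].value_counts()
        c = np.array([counts.get(s, 0) for s in BLEACH_STATES], dtype=float)
        t = BleachTally(c / c.sum(), int(c.sum()), dict(zip(keys, key_vals)))
        rows.append({**t.scope, "n": t.n, "bri": compute_bri(t, weights=weights)})
    return pd.DataFrame(rows)
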