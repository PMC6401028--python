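"""Monte Carlo sampling-sufficiency analysis for photo-quadrat surveys.

How many images must be scored before cover estimates stabilize?  For each
candidate image count n, cover of all live coral and of the most common
coral taxa is recomputed over many random without-replacement draws of n
images; the coefficient of variation (sample sd / mean) of those estimates,
as a function of n, is the sufficiency curve.  At n equal to the full image
set every draw is identical and the CV is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import CORAL_LIVE, SurveyDataset


@dataclass
class SufficiencyCurve:
    """CV of resampled cover estimates per tracked category and image count."""

    cv: pd.DataFrame          # rows n_images, columns categories; NaN when mean 0
    n_reps: int
    seed: int | None
    categories: list[str]

    def to_long(self) -> pd.DataFrame:
        out = self.cv.stack(future_stack=True).rename("cv").reset_index()
        out.columns = ["n", "category", "cv"]
        return out[["category", "n", "cv"]]


def _image_counts(ds: SurveyDataset, top_k: int):
    """Per-image counts of live coral and of the top_k live taxa (determined
    on the full image set, before any resampling)."""
    rec = ds.records
    img_key = ["site_id", "depth_band", "year", "transect", "image"]
    images = rec.groupby(img_key, sort=True)
    n_points = images.size().to_numpy()

    live = rec[rec["label"] == CORAL_LIVE]
    top = live["taxon"].value_counts().index[:top_k].tolist()
    cats = ["live_coral"] + top
    mat = np.zeros((len(n_points), len(cats)))
    live_counts = live.groupby(img_key, sort=True).size()
    idx = pd.Index(images.size().index)
    mat[:, 0] = live_counts.reindex(idx, fill_value=0).to_numpy()
    for j, taxon in enumerate(top, start=1):
        tc = live[live["taxon"] == taxon].groupby(img_key, sort=True).size()
        mat[:, j] = tc.reindex(idx, fill_value=0).to_numpy()
    return mat, n_points, cats


def cover_cv_curve(
    ds: SurveyDataset,
    n_range: range | None = None,
    n_reps: int = 1000,
    top_k: int = 4,
    seed: int | None = 0,
    with_replacement: bool = False,
) -> SufficiencyCurve:
    """Sufficiency curve: CV of cover estimates vs. number of images drawn.

    ``n_range`` defaults to 1..(images available); requested counts beyond
    the available images are truncated.  Categories whose resampled mean is
    zero get a null CV (not infinity).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    counts, n_points, cats = _image_counts(ds, top_k)
    n_images = len(n_points)
    if n_range is None:
        n_range = range(1, n_images + 1)
    ns = [n for n in n_range if 1 <= n <= n_images]
    if not ns:
        raise ValueError("n_range contains no feasible image counts")

    rng = np.random.default_rng(seed)
    rows = {}
    for n in ns:
        if with_replacement:
            draws = rng.integers(0, n_images, size=(n_reps, n))
        else:
            # first n columns of a random permutation per replicate
            draws = np.argsort(rng.random((n_reps, n_images)), axis=1)[:, :n]
        cover = counts[draws].sum(axis=1) / n_points[draws].sum(axis=1)[:, None]
        mean = cover.mean(axis=0)
        sd = cover.std(axis=0, ddof=1)
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
        rows[n] = cv
    cv_df = pd.DataFrame.from_dict(rows, orient="index", columns=cats)
    cv_df.index.name = "n"
    return SufficiencyCurve(cv_df, n_reps, seed, cats)


def minimal_images(curve: SufficiencyCurve, cv_threshold: float = 0.25) -> int | None:
    """Smallest image count at which every tracked category's CV is below the
    threshold (null CVs — absent categories — are ignored); None when the
    curve never qualifies."""
    for n, row in curve.cv.iterrows():
        vals = row.dropna()
        if (vals < cv_threshold).all():
            return int(n)
    return None
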