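import numpy as np
import pandas as pd
import pytest

from reefpulse.survey import COLUMNS, SurveyDataset


def make_records(points, site="S1", atoll="tarawa", depth="deep_10_12m",
                 year=2010, transect="T1"):
    """Build point records from (image, point, label, taxon, bleach_state) tuples."""
    rows = [
        (site, atoll, depth, year, transect, img, pt, label, taxon, state)
        for (img, pt, label, taxon, state) in points
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def uniform_image(img, label="sand", taxon=None, state=None, n=50):
    return [(img, p, label, taxon, state) for p in range(1, n + 1)]


@pytest.fixture
def small_survey():
    """Two images x 50 points: half live acropora (normal), half sand."""
    pts = []
    for img in (1, 2):
        for p in range(1, 51):
            if p <= 25:
                pts.append((img, p, "coral", "acropora", "normal"))
            else:
                pts.append((img, p, "sand", None, None))
    return SurveyDataset(make_records(pts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
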