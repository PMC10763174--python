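"""Shared fixtures: tiny hand-built studies and generated interchange files."""

import numpy as np
import pandas as pd
import pytest

from delphistats import Classification, classify
from delphistats.data import RATING_COLUMNS
from delphistats.datasets import load_summaries


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """Three panellists rating one item in round 1 (scores 2, 2, 3)."""
    return pd.DataFrame(
        {
            "panellist_id": ["p1", "p2", "p3"],
            "round": [1, 1, 1],
            "item_id": ["A", "A", "A"],
            "dimension": ["appropriateness"] * 3,
            "rating": [2, 2, 3],
        }
    )


@pytest.fixture
def study_shape_csv(tmp_path):
    """A deterministic file with the published design shape.

    24 panellists x 20 items in round 1; the first 19 panellists re-rate
    those plus 13 derived items in round 2.  Scores are an arbitrary
    deterministic pattern (the shape, not the statistics, matters here).
    """
    rows = []
    items_r1 = [f"S{i:02d}" for i in range(1, 21)]
    items_r2 = items_r1 + [f"M{i:02d}" for i in range(1, 14)]
    for p in range(1, 25):
        for j, item in enumerate(items_r1):
            rows.append((f"P{p:02d}", 1, item, (p + j) % 9 + 1))
    for p in range(1, 20):
        for j, item in enumerate(items_r2):
            rows.append((f"P{p:02d}", 2, item, (p * 2 + j) % 9 + 1))
    df = pd.DataFrame(rows, columns=["panellist_id", "round", "item_id", "rating"])
    path = tmp_path / "shape.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def published():
    """Published summary rows split by round/variant, with parsed classes."""
    df = load_summaries()
    recomputed = {
        (r.item_id, int(r.round)): classify(median=r.median, di=r.di)
        for r in df.itertuples(index=False)
    }
    printed = {
        (r.item_id, int(r.round)): Classification.from_label(r.label)
        for r in df.itertuples(index=False)
    }
    return {"frame": df, "recomputed": recomputed, "printed": printed}


def oracle_percentile(scores, q):
    """Independent sort-and-interpolate percentile at position (n-1)q + 1."""
    s = sorted(float(x) for x in scores)
    pos = (len(s) - 1) * q
    lo = int(np.floor(pos))
    frac = pos - lo
    if frac == 0:
        return s[lo]
    return s[lo] + frac * (s[lo + 1] - s[lo])


def oracle_summary(scores, q_low=0.30, q_high=0.70):
    """Independent direct-formula summary used as the brute-force oracle."""
    import statistics

    p_lo = oracle_percentile(scores, q_low)
    p_hi = oracle_percentile(scores, q_high)
    ipr = p_hi - p_lo
    iprcp = (p_lo + p_hi) / 2.0
    ai = abs(5.0 - iprcp)
    ipras = 2.35 + 1.5 * ai
    return {
        "median": statistics.median(scores),
        "p_low": p_lo,
        "p_high": p_hi,
        "ipr": ipr,
        "ipras": ipras,
        "di": ipr / ipras,
        "bins": (
            sum(1 for x in scores if x <= 3),
            sum(1 for x in scores if 4 <= x <= 6),
            sum(1 for x in scores if x >= 7),
        ),
    }
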