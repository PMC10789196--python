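"""Polarity metrics for IC scalp topographies: skewness, dominance, mismatch.

A topography is *positive-dominant* when its peak-magnitude electrode value is
positive.  The distributional proxy is the sample skewness of the values
across electrodes: positive skewness indicates a positive-dominant map.  A
*mismatch* is a disagreement between the sign of the skewness and the
dominance sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PolarityRecord", "topo_skewness", "topo_dominance", "polarity_table"]


@dataclass(frozen=True)
class PolarityRecord:
    skewness: float
    dominance: int
    mismatch: bool


def topo_skewness(topography) -> float:
    """Sample skewness ``m3 / m2**1.5`` (no bias correction) across electrodes.

    The bias correction would be a positive monotone rescaling and cannot
    change the sign, which is all the polarity analysis uses.
    """
    t = np.asarray(topography, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 electrodes for a skewness")
    if np.ptp(t) == 0:
        raise ValueError("constant topography has undefined skewness")
    return float(stats.skew(t, bias=True))


def topo_dominance(topography) -> int:
    """Sign (+1/-1) of the peak-magnitude entry; exact ties break toward +1."""
    t = np.asarray(topography, dtype=float)
    if not np.any(t != 0):
        raise ValueError("all-zero topography has no dominance")
    return -1 if -t.min() > t.max() else 1


def polarity_table(topographies) -> tuple[pd.DataFrame, dict]:
    """Per-IC polarity records and summary percentages.

    ``topographies`` is (n_electrodes, n_ics) — one column per IC — or an
    iterable of 1-D maps.  Returns a DataFrame with columns ``skewness``,
    ``dominance``, ``mismatch`` and a summary dict with ``pct_positive``,
    ``pct_negative`` and ``pct_mismatch`` (dominance is binary, so the first
    two sum to 100).
    """
    if isinstance(topographies, np.ndarray) and topographies.ndim == 2:
        maps = [topographies[:, k] for k in range(topographies.shape[1])]
    else:
        maps = [np.asarray(t, dtype=float) for t in topographies]
    if len(maps) == 0:
        raise ValueError("need at least one topography")
    rows = []
    for t in maps:
        sk = topo_skewness(t)
        dom = topo_dominance(t)
        rows.append((sk, dom, int(np.sign(sk)) != dom))
    df = pd.DataFrame(rows, columns=["skewness", "dominance", "mismatch"])
    n = len(df)
    summary = {
        "n_ics": n,
        "pct_positive": 100.0 * float((df["dominance"] == 1).sum()) / n,
        "pct_negative": 100.0 * float((df["dominance"] == -1).sum()) / n,
        "pct_mismatch": 100.0 * float(df["mismatch"].sum()) / n,
    }
    return df, summary
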