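"""Small shared helpers: percentage rounding and logging setup."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("methkit")


def round_percentages(counts) -> np.ndarray:
    """Integer percentages by largest-remainder allocation.

    Guarantees the rounded shares sum to exactly 100 (for a non-empty,
    non-degenerate count vector), so a partition reported as percentages
    stays a partition.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if counts.size == 0:
        return np.zeros(0, dtype=int)
    if total <= 0:
        return np.zeros(counts.size, dtype=int)
    exact = 100.0 * counts / total
    floors = np.floor(exact).astype(int)
    short = 100 - floors.sum()
    # distribute the shortfall to the largest fractional remainders
    order = np.argsort(-(exact - floors), kind="stable")
    floors[order[:short]] += 1
    return floors
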