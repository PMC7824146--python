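"""Independent oracles used by the test suite.

``PARAGRAPH_RULES`` transcribes each food group's published scoring rule as
a standalone literal function — deliberately *not* routed through the
package's shape machinery — so the scoring engine can be checked against an
independent code path. ``spearman_oracle`` is a from-first-principles rank
correlation: average-rank the data by hand, then take the Pearson
correlation of the ranks.
"""

from __future__ import annotations

import numpy as np


def _whole_grains(x: float) -> float:
    # 125 g/day or higher scores 10; below 100 g scores 0; linear between.
    if x >= 125:
        return 10.0
    if x < 100:
        return 0.0
    return 10.0 * (x - 100) / (125 - 100)


def _vegetables(x: float) -> float:
    if x >= 300:
        return 10.0
    if x < 200:
        return 0.0
    return 10.0 * (x - 200) / (300 - 200)


def _fruits(x: float) -> float:
    if x >= 200:
        return 10.0
    if x < 100:
        return 0.0
    return 10.0 * (x - 100) / (200 - 100)


def _dairy(x: float) -> float:
    # optimum 250-500 scores 10; above 500 scores 0; ratio 0->250.
    if x > 500:
        return 0.0
    if x >= 250:
        return 10.0
    return 10.0 * x / 250


def _red_meat(x: float) -> float:
    if x <= 14:
        return 10.0
    if x > 28:
        return 0.0
    return 10.0 * ((28 - 14) - (x - 14)) / (28 - 14)


def _fish(x: float) -> float:
    if x > 100:
        return 0.0
    if x >= 28:
        return 10.0
    return 10.0 * x / 28


def _eggs(x: float) -> float:
    if x <= 13:
        return 10.0
    if x > 25:
        return 0.0
    return 10.0 * ((25 - 13) - (x - 13)) / (25 - 13)


def _poultry(x: float) -> float:
    if x <= 29:
        return 10.0
    if x > 58:
        return 0.0
    return 10.0 * ((58 - 29) - (x - 29)) / (58 - 29)


def _legumes(x: float) -> float:
    if x >= 75:
        return 10.0
    return 10.0 * x / 75


def _nuts(x: float) -> float:
    if x > 75:
        return 0.0
    if x >= 50:
        return 10.0
    return 10.0 * x / 50


def _unsat_oils(x: float) -> float:
    # below 20 scores 0; 20-40 proportional; 40-80 scores 10; above 80 scores 0.
    if x > 80:
        return 0.0
    if x >= 40:
        return 10.0
    if x < 20:
        return 0.0
    return 10.0 * (x - 20) / (40 - 20)


def _sat_oils(x: float) -> float:
    return 10.0 if x <= 11.8 else 0.0


def _added_sugars(x: float) -> float:
    return 10.0 if x <= 31 else 0.0


PARAGRAPH_RULES = {
    "whole_grains": _whole_grains,
    "vegetables": _vegetables,
    "fruits": _fruits,
    "dairy": _dairy,
    "red_meat": _red_meat,
    "fish": _fish,
    "eggs": _eggs,
    "poultry": _poultry,
    "legumes": _legumes,
    "nuts": _nuts,
    "unsat_oils": _unsat_oils,
    "sat_oils": _sat_oils,
    "added_sugars": _added_sugars,
}


def average_ranks(values) -> np.ndarray:
    """Ranks 1..n with tied values assigned the mean of their positions."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Rank both variables (average ties), then Pearson on the ranks."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
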