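"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's groupby/scipy code paths: class
sizes come from O(n²) pairwise tuple comparison, h(g) from a direct count
of patients whose own class size is at most g, and the rank correlation
from hand-computed average ranks fed to a plain Pearson formula.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def pairwise_class_sizes(keys: list[tuple]) -> list[int]:
    """Size of each record's equivalence class, by pairwise comparison."""
    return [sum(1 for other in keys if other == k) for k in keys]


def pairwise_histogram(keys: list[tuple]) -> dict[int, int]:
    """Class-size histogram {size: number of classes} from pairwise sizes.

    A class of size s contributes s records that each report size s, so
    |bin(s)| = (#records of size s) / s.
    """
    records_per_size = Counter(pairwise_class_sizes(keys))
    return {s: c // s for s, c in records_per_size.items()}


def direct_h(keys: list[tuple], g: int) -> int:
    """Patients whose own class size is ≤ g, counted record by record."""
    sizes = pairwise_class_sizes(keys)
    return sum(1 for s in sizes if s <= g)


def _average_ranks(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks

def rank_correlation(x, y) -> float:
    """Spearman rho via hand-rolled average ranks + Pearson on the ranks."""
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
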