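"""Independent reference implementations used only to check the package.

These deliberately take the slow, direct route (full enumeration, textbook
formulas) and never share code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration: sum the
    point probabilities of every table (with the observed margins) whose
    probability does not exceed the observed table's."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    k_min = max(0, col1 - (n_total - row1))
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n_total, row1, col1)
    p_obs = pmf[a - k_min]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def bh_step_up(p_values) -> np.ndarray:
    """Direct transcription of the BH step-up definition (no vector tricks)."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(min(p[order[j - 1]] * m / j for j in range(pos, m + 1)), 1.0)
    return np.array(q)


def min_set_cover_size(sets: list[set]) -> int:
    """Exhaustive minimum set cover over a small family of peptide sets."""
    universe = set().union(*sets)
    for k in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), k):
            if set().union(*(sets[i] for i in combo)) == universe:
                return k
    raise AssertionError("no cover exists")


def pearson_direct(x, y) -> float:
    """Textbook Pearson correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den


def average_linkage_merges(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Brute-force average-linkage agglomeration: at each step merge the pair
    of clusters with the smallest average pairwise distance."""
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dd = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, i, j)
        dd, i, j = best
        merges.append((clusters[i], clusters[j], dd))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
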