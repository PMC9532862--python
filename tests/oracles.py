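"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic, full enumeration, and rotation scans.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def nb_split_weights(t: int, n_a: int, n_b: int, phi: float) -> list[Fraction]:
    """Exact conditional split weights w(a) for a = 0..t.

    phi = 0: binomial split, w(a) = C(t, a) * n_a^a * n_b^(t-a).
    phi > 0 with integer r_g = n_g / phi: NB split,
    w(a) = C(a + r_a - 1, a) * C(t - a + r_b - 1, t - a).
    """
    if phi == 0:
        return [Fraction(math.comb(t, a) * n_a ** a * n_b ** (t - a))
                for a in range(t + 1)]
    r_a = Fraction(n_a) / Fraction(phi).limit_denominator(10 ** 6)
    r_b = Fraction(n_b) / Fraction(phi).limit_denominator(10 ** 6)
    assert r_a.denominator == 1 and r_b.denominator == 1, \
        "oracle needs integer NB sizes"
    ra, rb = int(r_a), int(r_b)
    return [Fraction(math.comb(a + ra - 1, a)
                     * math.comb(t - a + rb - 1, t - a))
            for a in range(t + 1)]


def nb_split_pvalue(a_obs: int, t: int, n_a: int, n_b: int,
                    phi: float) -> float:
    """Exact two-sided conditional p: mass of splits with weight <= observed."""
    w = nb_split_weights(t, n_a, n_b, phi)
    total = sum(w)
    tail = sum(wi for wi in w if wi <= w[a_obs])
    return float(Fraction(tail, total))


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws (N <= ~14)."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def midrank(values) -> np.ndarray:
    """Average ranks with midranks for ties (1-based), textbook definition."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_via_ranks(x, y) -> float:
    """Rank-then-Pearson Spearman oracle."""
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pearson_textbook(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum()
                 / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def circular_sites_by_rotation(mirna: str, target: str):
    """All circular seed sites via brute-force rotation scans.

    Scans every rotation linearly, keeps sites whose full classification
    window is internal to the rotation, and maps them back to original
    coordinates; duplicates collapse by construction.
    """
    from cernet.targets import SITE_SPAN, find_seed_sites

    L = len(target)
    seen = {}
    for r in range(L):
        rot = target[r:] + target[:r]
        for s in find_seed_sites(mirna, rot, "linear"):
            start0 = s.position - 1
            anchor = start0 + 1 if s.site_type in ("8mer", "7mer-m8") \
                else start0
            if anchor - 1 < 0 or anchor + 6 > L - 1:
                continue  # flank checks were truncated in this rotation
            orig_start = (start0 + r) % L
            spans = orig_start + SITE_SPAN[s.site_type] > L
            orig_anchor = (anchor + r) % L
            seen[orig_anchor] = (orig_start + 1, s.site_type, spans)
    return set(seen.values())
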