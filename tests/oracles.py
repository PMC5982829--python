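"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and where possible the libraries)
they validate: plain-Python rank computation, step-up enumeration, full
hypergeometric enumeration, per-base loops and all-vs-all scans.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple


def midranks(values: Sequence[float]) -> List[float]:
    """Average ranks (1-based) with midranks for ties, by explicit grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Brute-force Spearman rho: Pearson correlation of midranks."""
    return pearson(midranks(x), midranks(y))


def bh_step_up(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up written directly from its definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        adjusted[i] = min(
            min(m * p_values[j] / (list(order).index(j) + 1) for j in order[rank_pos - 1:]),
            1.0,
        )
    return adjusted


def hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins r1, r2 (rows) and c1 (column)."""
    n = r1 + r2
    return (
        math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive enumeration over the support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom_pmf(k, r1, r2, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def window_pairs_bruteforce(
    anchors, partners, window_bp: int, dedupe_unordered: bool = False
) -> set:
    """All-vs-all scan: (anchor_id, partner_id) whose span intersects the flank."""
    out = set()
    for a in anchors:
        for p in partners:
            if p.chrom != a.chrom or p.gene_id == a.gene_id:
                continue
            if p.start < a.end + window_bp and p.end > a.start - window_bp:
                key = (a.gene_id, p.gene_id)
                if dedupe_unordered:
                    key = tuple(sorted(key))
                out.add(key)
    return out


def conservation_per_base(
    support: Sequence[Tuple[int, int]],
    track_intervals: Sequence[Tuple[int, int, float]],
) -> Tuple[float, int]:
    """(mean score, n bases) by looping over every base of the support."""
    scores: Dict[int, float] = {}
    for s, e, v in track_intervals:
        for pos in range(s, e):
            scores[pos] = v
    total = 0.0
    n = 0
    for s, e in support:
        for pos in range(s, e):
            total += scores.get(pos, 0.0)
            n += 1
    return (total / n if n else float("nan")), n


def confusion_bruteforce(truth_pairs, labels: Dict[tuple, str]) -> Dict[str, Dict[str, int]]:
    out: Dict[str, Dict[str, int]] = {}
    for p in truth_pairs:
        lbl = labels.get((p.anchor_id, p.partner_id), "untested")
        out.setdefault(p.pair_class, {})
        out[p.pair_class][lbl] = out[p.pair_class].get(lbl, 0) + 1
    return out
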