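"""Independent reference implementations used only to check the package.

Each oracle is written from the definition of the quantity it checks, using
plain dict/loop arithmetic, and shares no code path with the implementation
under test.
"""

from __future__ import annotations

import math
from collections import Counter


def trigrams(surface: str) -> list[str]:
    padded = f"#{surface.casefold()}#"
    return [padded[i : i + 3] for i in range(len(padded) - 2)]


def tfidf_cosine_table(aliases: list[str]) -> tuple[dict[str, float], list[dict[str, float]]]:
    """Smoothed log IDF over the alias collection and L2-normalized row vectors."""
    n = len(aliases)
    df: Counter = Counter()
    rows_tf = []
    for alias in aliases:
        counts = Counter(trigrams(alias))
        rows_tf.append(counts)
        df.update(counts.keys())
    idf = {g: math.log((1 + n) / (1 + df[g])) + 1.0 for g in df}
    rows = []
    for counts in rows_tf:
        vec = {g: tf * idf[g] for g, tf in counts.items()}
        norm = math.sqrt(sum(v * v for v in vec.values()))
        rows.append({g: v / norm for g, v in vec.items()} if norm else {})
    return idf, rows


def brute_force_link(surface: str, aliases: list[str]) -> tuple[int, float]:
    """(best alias row index, cosine similarity) by exhaustive search."""
    idf, rows = tfidf_cosine_table(aliases)
    counts = Counter(g for g in trigrams(surface) if g in idf)
    qvec = {g: tf * idf[g] for g, tf in counts.items()}
    qnorm = math.sqrt(sum(v * v for v in qvec.values()))
    best_idx, best_sim = -1, 0.0
    for idx, row in enumerate(rows):
        dot = sum(qvec.get(g, 0.0) * w for g, w in row.items())
        sim = dot / qnorm if qnorm else 0.0
        if sim > best_sim:
            best_idx, best_sim = idx, sim
    return best_idx, best_sim


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact pmf summation with integer binomials."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def bh_stepup(p_values: list[float]) -> list[float]:
    """Naive BH: sort ascending, adj_(i) = min_{j>=i} p_(j)*m/j capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def unweighted_ks_es(ranking: list[str], members: set[str]) -> float:
    """Classical (weight-0) running-sum statistic: max |deviation|, signed."""
    n_hit = sum(1 for g in ranking if g in members)
    n_miss = len(ranking) - n_hit
    running = 0.0
    best = 0.0
    for gene in ranking:
        running += 1.0 / n_hit if gene in members else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
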