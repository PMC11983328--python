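"""Scoring and significance testing of co-occurrence associations.

The association score for a pair (x, y) is

    S_xy = C_xy^a * (C_xy * C_** / (C_x* * C_*y))^(1 - a)

where C_xy is the number of sentences co-mentioning x and y, C_x* and C_*y the
per-entity margins, C_** the total number of mixed-type sentences, and
``a`` (default 0.6) a trade-off weight between the raw count and the
background-corrected ratio.  At a=1 the score is the raw count; at a=0 it is
the pure lift term.  The correction demotes pairs whose co-mentions are
explained by one heavily studied entity.

Significance is an upper-tail hypergeometric test (N=C_**, K=C_x*, n=C_*y,
k=C_xy): the probability of observing k or more co-mention sentences if the
margins were assorted at random, followed by Benjamini-Hochberg adjustment
within the type-pair family of observed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cooccur import CooccurrenceTable, PairKey
from .vocab import EntityType

__all__ = [
    "ScoringParams",
    "AssociationRecord",
    "association_score",
    "hypergeom_pvalue",
    "bh_adjust",
    "score_table",
    "records_to_frame",
    "write_association_tsv",
    "read_association_tsv",
]


@dataclass(frozen=True)
class ScoringParams:
    """Weighting factor ``a`` in [0, 1] balancing raw count vs background correction."""

    a: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")


@dataclass(frozen=True)
class AssociationRecord:
    """One scored, significance-tested entity pair."""

    pair: PairKey
    count: int
    score: float
    p_value: float
    p_adj: float
    name_x: str | None = None
    name_y: str | None = None


def association_score(
    c_xy: int, c_x_star: int, c_star_y: int, c_star_star: int, a: float = 0.6
) -> float:
    """Background-corrected co-occurrence score S_xy; 0 when C_xy is 0."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must be in [0, 1], got {a}")
    if min(c_xy, c_x_star, c_star_y, c_star_star) < 0:
        raise ValueError("counts must be non-negative")
    if c_xy == 0:
        return 0.0
    if c_x_star < c_xy or c_star_y < c_xy or c_star_star < max(c_x_star, c_star_y):
        raise ValueError(
            f"count invariants violated: C_xy={c_xy}, C_x*={c_x_star}, "
            f"C_*y={c_star_y}, C_**={c_star_star}"
        )
    lift = c_xy * c_star_star / (c_x_star * c_star_y)
    return float(c_xy**a * lift ** (1.0 - a))


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n); symmetric in (K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric inputs k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="fdr_bh")[1]]


def score_table(
    table: CooccurrenceTable,
    params: ScoringParams = ScoringParams(),
    names: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """Score and significance-test every observed pair (C_xy >= 1) of a table.

    The BH family is the set of observed pairs of this type pair.  Records are
    sorted by score descending, ties by count descending then (cui_x, cui_y).
    """
    pairs = sorted(table.c_xy)
    if not pairs:
        return []
    ks = np.array([table.c_xy[p] for p in pairs])
    Ks = np.array([table.c_x[x] for x, _ in pairs])
    ns = np.array([table.c_y[y] for _, y in pairs])
    N = table.c_total
    scores = [
        association_score(int(k), int(K), int(n), N, a=params.a)
        for k, K, n in zip(ks, Ks, ns)
    ]
    pvals = np.clip(hypergeom.sf(ks - 1, N, Ks, ns), 0.0, 1.0)
    padj = bh_adjust(pvals)
    names = names or {}
    records = [
        AssociationRecord(
            pair=table.pair_key(x, y),
            count=int(k),
            score=s,
            p_value=float(p),
            p_adj=float(q),
            name_x=names.get(x),
            name_y=names.get(y),
        )
        for (x, y), k, s, p, q in zip(pairs, ks, scores, pvals, padj)
    ]
    records.sort(key=lambda r: (-r.score, -r.count, r.pair.cui_x, r.pair.cui_y))
    return records


# --------------------------------------------------------------------------
# association-table I/O

_COLUMNS = [
    "type_x",
    "type_y",
    "cui_x",
    "name_x",
    "cui_y",
    "name_y",
    "count",
    "score",
    "p_value",
    "p_adj",
]


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    rows = [
        {
            "type_x": r.pair.type_x.value,
            "type_y": r.pair.type_y.value,
            "cui_x": r.pair.cui_x,
            "name_x": r.name_x if r.name_x is not None else r.pair.cui_x,
            "cui_y": r.pair.cui_y,
            "name_y": r.name_y if r.name_y is not None else r.pair.cui_y,
            "count": r.count,
            "score": r.score,
            "p_value": r.p_value,
            "p_adj": r.p_adj,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_association_tsv(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Persist records at full float precision (reports may round, storage does not)."""
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_association_tsv(path: str | Path) -> list[AssociationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"cui_x": str, "cui_y": str})
    return [
        AssociationRecord(
            pair=PairKey(
                EntityType(row.type_x), EntityType(row.type_y), row.cui_x, row.cui_y
            ),
            count=int(row.count),
            score=float(row.score),
            p_value=float(row.p_value),
            p_adj=float(row.p_adj),
            name_x=str(row.name_x),
            name_y=str(row.name_y),
        )
        for row in frame.itertuples(index=False)
    ]
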