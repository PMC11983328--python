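"""Validation of ranked disease-gene lists against clinically validated targets.

Two complementary checks are provided.

Fisher's exact test asks whether clinically validated targets are
over-represented among text-mined disease genes, on a 2x2 contingency table
against a protein-coding-gene universe.  The one-sided (greater) p-value is
the upper hypergeometric tail, numerically identical to the co-occurrence
significance test.  Two odds-ratio estimates are reported: the sample
(cross-product) odds ratio a*d/(b*c), and the conditional maximum-likelihood
odds ratio -- the value of the noncentral-hypergeometric odds parameter whose
conditional expectation of cell ``a`` equals the observed ``a``, obtained by
root-finding on the log-odds scale.

GSEA-preranked asks whether a target group concentrates near the top of a
ranked gene list.  The enrichment score (ES) is the maximal deviation of a
weighted running sum: each hit increments by |metric|^w normalized over hits,
each miss decrements by 1/N_miss.  Significance comes from gene-label
permutations; the normalized enrichment score (NES) divides ES by the mean of
same-sign permutation ES values, nominal p is the same-sign permutation tail,
and the FDR q compares the pooled permutation NES distribution with the
observed NES values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher

from .assoc import hypergeom_pvalue

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "build_target_contingency",
    "fisher_exact",
    "conditional_mle_odds_ratio",
    "GeneSet",
    "GseaResult",
    "gsea_preranked",
    "read_gmt",
    "read_targets_tsv",
]


# --------------------------------------------------------------------------
# Fisher's exact test


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; ``a`` = genes both in the disease list and the target set."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")


@dataclass(frozen=True)
class FisherResult:
    sample_or: float  # a*d/(b*c); inf on a zero off-diagonal, nan if undefined
    cmle_or: float
    p_one_sided: float
    sample_or_defined: bool


def build_target_contingency(
    disease_genes: Iterable[str], clinical_targets: Iterable[str], universe_size: int
) -> ContingencyTable2x2:
    """2x2 table of disease-list membership vs clinical-target membership."""
    disease = set(disease_genes)
    targets = set(clinical_targets)
    if universe_size < len(disease | targets):
        raise ValueError(
            f"universe_size {universe_size} smaller than |disease ∪ targets| "
            f"{len(disease | targets)}"
        )
    a = len(disease & targets)
    b = len(disease) - a
    c = len(targets) - a
    d = universe_size - len(disease) - c
    return ContingencyTable2x2(a, b, c, d)


def conditional_mle_odds_ratio(table: ContingencyTable2x2, tol: float = 1e-8) -> float:
    """Conditional MLE of the odds ratio given all four table margins.

    Solves E_psi[A] = a for the Fisher noncentral hypergeometric cell count A;
    for this one-parameter exponential family the mean-matching root is the
    conditional likelihood maximizer.  Boundary tables return 0 or inf.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    M = a + b + c + d
    n1 = a + b  # first-margin total (disease list size)
    n2 = a + c  # second-margin total (target set size)
    a_min = max(0, n1 + n2 - M)
    a_max = min(n1, n2)
    if a_min == a_max:  # degenerate support: any odds fits
        return 1.0
    if a == a_max:
        return math.inf
    if a == a_min:
        return 0.0

    def mean_gap(log_odds: float) -> float:
        return float(nchypergeom_fisher.mean(M, n1, n2, math.exp(log_odds))) - a

    lo, hi = -1.0, 1.0
    while mean_gap(lo) > 0:
        lo *= 2
        if lo < -500:
            return 0.0
    while mean_gap(hi) < 0:
        hi *= 2
        if hi > 500:
            return math.inf
    root = brentq(mean_gap, lo, hi, xtol=tol)
    return math.exp(root)


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """One-sided (greater) Fisher's exact test with both odds-ratio estimates."""
    a, b, c, d = table.a, table.b, table.c, table.d
    p = hypergeom_pvalue(k=a, K=a + b, n=a + c, N=a + b + c + d)
    if b * c > 0:
        sample_or = a * d / (b * c)
        defined = True
    else:
        sample_or = math.inf if a * d > 0 else math.nan
        defined = False
    return FisherResult(
        sample_or=sample_or,
        cmle_or=conditional_mle_odds_ratio(table),
        p_one_sided=p,
        sample_or_defined=defined,
    )


# --------------------------------------------------------------------------
# GSEA preranked


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name or not self.genes:
            raise ValueError("gene set needs a name and at least one gene")


@dataclass(frozen=True)
class GseaResult:
    name: str
    size: int  # genes of the set present in the ranked list
    es: float
    nes: float
    p_value: float
    fdr: float
    evaluable: bool


def _validate_ranking(ranked: Sequence[tuple[str, float]]) -> tuple[list[str], np.ndarray]:
    if len(ranked) < 2:
        raise ValueError("ranked list needs at least two genes")
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in ranked list")
    metrics = np.asarray([m for _, m in ranked], dtype=float)
    if np.any(np.diff(metrics) > 1e-12):
        raise ValueError("ranking metric must be non-increasing")
    return genes, metrics


def _enrichment_scores(hit_pos: np.ndarray, absw: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed ES for one or many hit-position vectors.

    *hit_pos*: (..., m) arrays of sorted 0-based hit ranks.  The running sum
    only changes value at hits; its extrema therefore occur immediately before
    or after a hit, which is all this evaluates.
    """
    hit_pos = np.atleast_2d(hit_pos)
    m = hit_pos.shape[-1]
    w = absw[hit_pos]
    denom = w.sum(axis=-1, keepdims=True)
    uniform = 1.0 / m
    w_norm = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), uniform)
    miss_step = 1.0 / (n_genes - m)
    idx = np.arange(m)
    after = np.cumsum(w_norm, axis=-1) - (hit_pos - idx) * miss_step
    before = after - w_norm
    candidates = np.concatenate([before, after], axis=-1)
    choice = np.argmax(np.abs(candidates), axis=-1)
    return np.take_along_axis(candidates, choice[..., None], axis=-1)[..., 0]


def gsea_preranked(
    ranked: Sequence[tuple[str, float]],
    gene_sets: Sequence[GeneSet],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 17,
) -> list[GseaResult]:
    """Preranked gene-set enrichment over a non-increasing (gene, metric) list.

    Fully deterministic for a given *seed*: each set's permutations are drawn
    from an independent stream spawned from the seed, so adding or reordering
    sets does not perturb the others.  A set with no overlap is returned as
    not evaluable; a set covering the whole list is an error (no misses).
    """
    genes, metrics = _validate_ranking(ranked)
    n = len(genes)
    absw = np.abs(metrics) ** weight_exponent
    position = {g: i for i, g in enumerate(genes)}

    # observed ES per set
    observed: list[tuple[GeneSet, np.ndarray | None]] = []
    for gs in gene_sets:
        hits = np.array(sorted(position[g] for g in gs.genes if g in position), dtype=int)
        if hits.size == n:
            raise ValueError(f"gene set {gs.name!r} covers the entire ranked list")
        observed.append((gs, hits if hits.size else None))

    rng_streams = np.random.SeedSequence(seed).spawn(len(gene_sets))
    es_obs: list[float] = []
    nes_obs: list[float] = []
    p_nominal: list[float] = []
    nes_perm_pool: list[np.ndarray] = []
    evaluable: list[bool] = []
    sizes: list[int] = []

    for (gs, hits), stream in zip(observed, rng_streams):
        if hits is None:
            es_obs.append(math.nan)
            nes_obs.append(math.nan)
            p_nominal.append(math.nan)
            evaluable.append(False)
            sizes.append(0)
            continue
        m = hits.size
        es = float(_enrichment_scores(hits, absw, n)[0])
        rng = np.random.default_rng(stream)
        rand = rng.random((n_perm, n))
        perm_hits = np.sort(np.argpartition(rand, m - 1, axis=1)[:, :m], axis=1)
        es_p = _enrichment_scores(perm_hits, absw, n)
        pos_mean = es_p[es_p > 0].mean() if np.any(es_p > 0) else math.nan
        neg_mean = -es_p[es_p < 0].mean() if np.any(es_p < 0) else math.nan
        if es >= 0:
            same = es_p[es_p >= 0]
            p = float(np.mean(same >= es)) if same.size else 1.0
            nes = es / pos_mean if pos_mean and not math.isnan(pos_mean) else math.nan
        else:
            same = es_p[es_p < 0]
            p = float(np.mean(same <= es)) if same.size else 1.0
            nes = es / neg_mean if neg_mean and not math.isnan(neg_mean) else math.nan
        with np.errstate(invalid="ignore"):
            nes_p = np.where(es_p >= 0, es_p / pos_mean, es_p / neg_mean)
        es_obs.append(es)
        nes_obs.append(float(nes))
        p_nominal.append(p)
        nes_perm_pool.append(nes_p[np.isfinite(nes_p)])
        evaluable.append(True)
        sizes.append(m)

    pool = np.concatenate(nes_perm_pool) if nes_perm_pool else np.array([])
    nes_valid = np.array([v for v, ok in zip(nes_obs, evaluable) if ok])
    results: list[GseaResult] = []
    for gs, es, nes, p, ok, m in zip(
        gene_sets, es_obs, nes_obs, p_nominal, evaluable, sizes
    ):
        if not ok or math.isnan(nes):
            results.append(GseaResult(gs.name, m, es, math.nan, p, math.nan, ok))
            continue
        if nes >= 0:
            null_frac = np.mean(pool >= nes) if pool.size else 0.0
            obs_frac = np.mean(nes_valid >= nes)
        else:
            null_frac = np.mean(pool <= nes) if pool.size else 0.0
            obs_frac = np.mean(nes_valid <= nes)
        fdr = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 0.0
        results.append(GseaResult(gs.name, m, es, nes, p, fdr, True))
    return results


# --------------------------------------------------------------------------
# inputs

VALID_PHASES = ("phase1", "phase2", "phase3", "approved")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, then genes, tab-separated)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description, >=1 gene")
            sets.append(GeneSet(name=fields[0], genes=frozenset(g for g in fields[2:] if g)))
    return sets


def read_targets_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a clinical-target list (columns: gene, phase) into phase -> gene sets."""
    groups: dict[str, set[str]] = {p: set() for p in VALID_PHASES}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "phase"]:
            raise ValueError(f"target TSV must start with columns gene, phase; got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gene, phase = line.rstrip("\n").split("\t")[:2]
            if phase not in VALID_PHASES:
                raise ValueError(f"line {lineno}: unknown phase {phase!r}")
            groups[phase].add(gene)
    return groups
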