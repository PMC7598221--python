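"""Gene-set enrichment: permutation GSEA and hypergeometric over-representation.

The enrichment score walks the ranked gene list, adding |r_j|^p (normalized
over the set's hits) at set members and subtracting 1/(N - N_H) at misses;
the ES is the running-sum extremum of largest magnitude.  Significance comes
from phenotype (sample-label) permutations, which respect inter-gene
correlation; the gene-permutation fallback is used when a contrast group is
too small to permute meaningfully.  NES normalizes the ES by the mean
magnitude of same-sign permutation scores.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg, moderated_t_stats
from .types import Contrast, ExpressionStudy

log = logging.getLogger("lncmod")

#: smallest group size for which phenotype permutation is used
MIN_PHENOTYPE_GROUP = 7


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def gene_sets_from_gmt(gmt: Mapping[str, tuple[str, Sequence[str]]]) -> list[GeneSet]:
    return [GeneSet(name, desc, tuple(dict.fromkeys(members)))
            for name, (desc, members) in gmt.items()]


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------
def _rank_order(gene_ids: Sequence[str], scores: np.ndarray) -> np.ndarray:
    """Descending-score order; ties broken by gene id for determinism."""
    ids = np.asarray(gene_ids)
    return np.lexsort((ids, -scores))


def enrichment_score(
    gene_ids: Sequence[str],
    scores: Sequence[float],
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov-Smirnov-like enrichment score.

    Genes are ranked by descending score; the running sum gains
    ``|r|^p / sum_hits |r|^p`` at each set member and loses ``1/(N - N_H)``
    at each non-member.  Returns ``(ES, running_sum, leading_edge)`` where
    the leading edge holds the members at or before the extremum for a
    positive ES and strictly after it for a negative ES.  ``weight_p = 0``
    reduces to the classical two-sample KS statistic between the hit and
    miss positions.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    order = _rank_order(gene_ids, scores)
    ranked_ids = [gene_ids[i] for i in order]
    r = scores[order]
    members = set(gene_set)
    hit = np.array([g in members for g in ranked_ids])
    n = hit.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranking; "
                         "miss decrement undefined")
    w = np.abs(r) ** weight_p
    denom = w[hit].sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal weights
        inc_hit = np.full(n, 1.0 / n_hit)
    else:
        inc_hit = w / denom
    steps = np.where(hit, inc_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_star = int(np.argmax(np.abs(running)))
    es = float(running[i_star])
    if es >= 0:
        leading = [g for j, g in enumerate(ranked_ids) if hit[j] and j <= i_star]
    else:
        leading = [g for j, g in enumerate(ranked_ids) if hit[j] and j > i_star]
    return es, running, leading


def _es_batch(scores: np.ndarray, order: np.ndarray, masks: np.ndarray,
              weight_p: float) -> np.ndarray:
    """ES for many sets at once on one ranking.

    ``masks`` is a (n_sets, n_genes) boolean matrix of membership in input
    gene order; the running sums for all sets are built as one cumsum.
    """
    r = scores[order]
    n = r.size
    hits = masks[:, order]                       # (S, n), ranked order
    n_hit = hits.sum(axis=1)
    w = np.abs(r) ** weight_p                    # (n,)
    denom = hits @ w                             # (S,)
    safe = denom > 0
    inc = np.where(hits, w[None, :], 0.0)
    inc[safe] /= denom[safe, None]
    # all-zero hit weights: fall back to equal weights
    if not safe.all():
        eq = hits[~safe] / np.maximum(n_hit[~safe, None], 1)
        inc[~safe] = eq
    miss = (~hits) / (n - n_hit)[:, None]
    running = np.cumsum(inc - miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(masks.shape[0]), idx]


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------
def _contrast_scores(xa: np.ndarray, xb: np.ndarray, metric: str) -> np.ndarray:
    if metric == "moderated_t":
        return np.asarray(moderated_t_stats(xa, xb)["t_mod"], dtype=float)
    if metric == "snr":  # signal-to-noise ratio with a small variance floor
        sa = xa.std(axis=1, ddof=1)
        sb = xb.std(axis=1, ddof=1)
        return (xa.mean(axis=1) - xb.mean(axis=1)) / (sa + sb + 1e-8)
    raise ValueError(f"unknown ranking metric {metric!r}")


def _phenotype_permutations(n_a: int, n_b: int, n_perm: int,
                            rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays (into the pooled sample axis) selecting permuted group a."""
    n = n_a + n_b
    n_distinct = math.comb(n, n_a)
    if n_distinct < 20:
        log.warning("only %d distinct label permutations; enumerating exactly",
                    n_distinct)
        return [np.array(c) for c in combinations(range(n), n_a)]
    return [rng.permutation(n)[:n_a] for _ in range(n_perm)]


def gsea_significance(
    study: ExpressionStudy,
    contrast: Contrast,
    gene_sets: Sequence[GeneSet],
    metric: str = "moderated_t",
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Permutation GSEA for one contrast over a gene-set collection.

    Phenotype labels are permuted when both groups have at least
    ``MIN_PHENOTYPE_GROUP`` samples; otherwise the ranking scores are
    permuted across genes (logged fallback).  Per set: NES = ES divided by
    the mean |permuted ES| of the same sign, a one-sided permutation p
    within that sign, and BH FDR computed separately in the positive and
    negative NES pools.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids_a, ids_b = contrast.resolve(study.samples)
    pooled = study.matrix[ids_a + ids_b].to_numpy(float)
    n_a, n_b = len(ids_a), len(ids_b)
    gene_ids = study.gene_ids
    obs_scores = _contrast_scores(pooled[:, :n_a], pooled[:, n_a:], metric)

    universe = set(gene_ids)
    kept_sets = []
    for gs in gene_sets:
        inter = [g for g in gs.members if g in universe]
        if 0 < len(inter) < len(gene_ids):
            kept_sets.append((gs, inter))
        else:
            log.warning("gene set %s skipped (intersection %d of %d genes)",
                        gs.name, len(inter), len(gene_ids))

    # observed ES + leading edges
    observed = {}
    for gs, inter in kept_sets:
        es, _, leading = enrichment_score(gene_ids, obs_scores, inter, weight_p)
        observed[gs.name] = (es, leading)

    # permutation scores
    phenotype = min(n_a, n_b) >= MIN_PHENOTYPE_GROUP
    if not phenotype:
        log.warning("group sizes %d/%d below %d: falling back to gene "
                    "permutation", n_a, n_b, MIN_PHENOTYPE_GROUP)
    if phenotype:
        perms = _phenotype_permutations(n_a, n_b, n_perm, rng)
        perm_scores = []
        all_idx = np.arange(n_a + n_b)
        for sel in perms:
            rest = np.setdiff1d(all_idx, sel, assume_unique=False)
            perm_scores.append(
                _contrast_scores(pooled[:, sel], pooled[:, rest], metric))
    else:
        perm_scores = [obs_scores[rng.permutation(len(gene_ids))]
                       for _ in range(n_perm)]

    masks = np.stack([
        np.array([g in set(inter) for g in gene_ids])
        for _, inter in kept_sets])
    ids_arr = np.asarray(gene_ids)
    perm_es_mat = np.empty((len(perm_scores), len(kept_sets)))
    for b, sc in enumerate(perm_scores):
        order = np.lexsort((ids_arr, -sc))
        perm_es_mat[b] = _es_batch(sc, order, masks, weight_p)

    rows = []
    for j, (gs, inter) in enumerate(kept_sets):
        es, leading = observed[gs.name]
        pes = perm_es_mat[:, j]
        same = pes[pes >= 0] if es >= 0 else pes[pes < 0]
        if same.size == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
        rows.append({"name": gs.name, "size": len(inter), "ES": es,
                     "NES": nes, "p_perm": p,
                     "leading_edge": ",".join(leading)})
    out = pd.DataFrame(rows).set_index("name")
    out["q"] = np.nan
    for mask in (out["ES"] >= 0, out["ES"] < 0):
        if mask.any():
            out.loc[mask, "q"] = benjamini_hochberg(out.loc[mask, "p_perm"])
    return out


# ---------------------------------------------------------------------------
# hypergeometric over-representation
# ---------------------------------------------------------------------------
def hypergeometric_enrichment(
    module_genes: Iterable[str],
    term_table: pd.DataFrame,
    universe: Iterable[str],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of terms in a module.

    For each term with K annotated genes in a universe of N, observing k of
    them among the module's n draws has p = P[X >= k].  Returns the full
    table sorted by ascending p with a ``significant`` flag at the raw
    ``p_cutoff`` (no FDR, per the guilt-by-association convention used for
    module annotation); a BH column ``q`` is emitted for transparency.
    """
    universe_set = set(universe)
    module = [g for g in dict.fromkeys(module_genes) if g in universe_set]
    if not module:
        raise ValueError("module has no genes inside the universe")
    module_set = set(module)
    n_draws = len(module)
    n_pop = len(universe_set)

    anno = term_table[term_table["gene_id"].isin(universe_set)]
    rows = []
    for term, grp in anno.groupby("term", sort=False):
        term_genes = set(grp["gene_id"])
        k = len(term_genes & module_set)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_pop, big_k, n_draws))
        rows.append({"term": term, "k": k, "K": big_k, "n": n_draws,
                     "N": n_pop, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p", "q", "significant"]
        ).set_index("term")
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = benjamini_hochberg(out["p"])
    out["significant"] = out["p"] < p_cutoff
    return out.sort_values("p", kind="stable")
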