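"""lncRNA-PCG coexpression modules by non-negative matrix factorization.

The pipeline mirrors the guilt-by-association network construction used for
lncRNA functional annotation: take the differentially expressed lncRNAs and
PCGs of a contrast, build their pairwise correlation matrix, map it to a
nonnegative matrix (positive clipping by default, so that modules collect
similarly regulated genes rather than conflating correlation with
anti-correlation), factorize A ~ W H by multiplicative updates minimizing
the Frobenius reconstruction error, and read module membership off the
column-normalized symmetrized factor.  Each module's representative core is
the 4 lncRNAs and 13 PCGs with the highest membership; unknown lncRNAs
inherit the GO annotation enriched among their module's PCGs.

The factorization rank can be fixed or selected by consensus clustering:
for each candidate k the argmax module assignment is computed over random
restarts, co-assignment frequencies form a consensus matrix, and the k with
the highest cophenetic correlation of that consensus wins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .enrichment import hypergeometric_enrichment
from .types import ExpressionStudy

log = logging.getLogger("lncmod")

CORE_N_LNCRNA = 4
CORE_N_PCG = 13


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------
@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene correlation matrix over the DE transcripts."""

    gene_ids: list[str]
    C: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.gene_ids, columns=self.gene_ids)


def build_correlation_matrix(
    study: ExpressionStudy,
    de_gene_ids: Sequence[str],
    method: str = "pearson",
    sample_ids: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise correlation among DE genes across the analysis samples.

    Zero-variance genes are dropped with a warning; exact symmetry is
    enforced by averaging C with its transpose and the diagonal is unity.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    ids = list(de_gene_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 DE genes for a correlation matrix")
    cols = list(sample_ids) if sample_ids is not None else study.sample_ids
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for a correlation matrix")
    x = study.matrix.loc[ids, cols].to_numpy(float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(ids, keep) if not k]
        log.warning("dropping %d zero-variance genes: %s...",
                    len(dropped), dropped[:3])
        ids = [g for g, k in zip(ids, keep) if k]
        x = x[keep]
    if len(ids) < 2:
        raise ValueError("fewer than 2 genes left after variance filtering")
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    c = np.corrcoef(x)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(gene_ids=ids, C=c, method=method)


def nonnegative_transform(C: CorrelationMatrix | np.ndarray,
                          mode: str = "positive_clip") -> np.ndarray:
    """Map a correlation matrix to a nonnegative matrix for factorization.

    positive_clip: A = max(C, 0) — anti-correlated pairs contribute nothing;
    abs: A = |C|; shift: A = (C + 1) / 2.  The diagonal is retained.
    """
    c = C.C if isinstance(C, CorrelationMatrix) else np.asarray(C, dtype=float)
    if mode == "positive_clip":
        return np.maximum(c, 0.0)
    if mode == "abs":
        return np.abs(c)
    if mode == "shift":
        return (c + 1.0) / 2.0
    raise ValueError(f"unknown transform mode {mode!r}")


# ---------------------------------------------------------------------------
# NMF by multiplicative updates
# ---------------------------------------------------------------------------
@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    objective: float                       # ||A - WH||_F^2 of the best restart
    objective_trace: np.ndarray            # per-iteration objective, best restart
    n_iter: int


_EPS = 1e-12


def _nmf_once(a: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = a.shape
    scale = np.sqrt(a.mean() / k) if a.mean() > 0 else 1.0
    w = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    h = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS
    trace: list[float] = []
    prev = None
    for it in range(max_iter):
        h *= (w.T @ a) / (w.T @ w @ h + _EPS)
        w *= (a @ h.T) / (w @ (h @ h.T) + _EPS)
        obj = float(np.linalg.norm(a - w @ h) ** 2)
        trace.append(obj)
        if prev is not None and prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return w, h, trace


def nmf_factorize(
    A: np.ndarray,
    k: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = 0,
) -> NMFResult:
    """Best-of-restarts NMF minimizing the Frobenius reconstruction error.

    Multiplicative updates keep the objective non-increasing per iteration;
    convergence is declared when the relative objective change drops below
    ``tol``.  Deterministic given ``seed``.
    """
    a = np.asarray(A, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("A must be a square matrix")
    if np.any(a < 0):
        raise ValueError("A must be nonnegative")
    if not 1 <= k < a.shape[0]:
        raise ValueError(f"rank k={k} must satisfy 1 <= k < dim={a.shape[0]}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        w, h, trace = _nmf_once(a, k, rng, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (w, h, trace)
    w, h, trace = best  # type: ignore[misc]
    return NMFResult(W=w, H=h, objective=trace[-1],
                     objective_trace=np.asarray(trace), n_iter=len(trace))


def membership_matrix(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Column-normalized membership from the symmetrized factor (W + H^T)/2.

    For a symmetric input W and H are near-transposes; averaging removes the
    residual asymmetry, and each module column is scaled to unit Euclidean
    norm so memberships are comparable across modules.
    """
    m = (W + H.T) / 2.0
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    return m / norms


# ---------------------------------------------------------------------------
# rank selection by consensus cophenetic correlation
# ---------------------------------------------------------------------------
@dataclass
class RankSelection:
    k_star: int
    cophenetic: dict[int, float]
    low_confidence: bool
    table: pd.DataFrame


def _consensus_cophenetic(a: np.ndarray, k: int, n_restarts: int,
                          max_iter: int,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Cophenetic correlation of the restart-consensus plus best objective."""
    n = a.shape[0]
    consensus = np.zeros((n, n))
    best_obj = np.inf
    for _ in range(n_restarts):
        w, h, trace = _nmf_once(a, k, rng, max_iter, tol=1e-5)
        best_obj = min(best_obj, trace[-1])
        assign = np.argmax(membership_matrix(w, h), axis=1)
        consensus += (assign[:, None] == assign[None, :]).astype(float)
    consensus /= n_restarts
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0, best_obj  # degenerate: all pairwise consensus identical
    z = linkage(condensed, method="average")
    coph, _ = cophenet(z, condensed)
    return (float(coph) if np.isfinite(coph) else 1.0), best_obj


def select_rank(
    A: np.ndarray,
    k_range: Iterable[int] = range(2, 11),
    n_restarts: int = 20,
    max_iter: int = 500,
    seed: int | None = 0,
) -> RankSelection:
    """Pick the factorization rank maximizing consensus cophenetic correlation.

    On a cleanly blocked matrix the consensus can be perfectly stable for
    several ranks at once (merging two blocks the same way on every restart
    also yields cophenetic 1), so near-ties — within 0.01 of the maximum —
    are broken by the reconstruction-error gain: the candidate whose
    objective improves most over the next-smaller rank wins.  A flat or low
    profile (max cophenetic < 0.9) flags the selection as low confidence —
    the matrix carries no stable block structure.
    """
    a = np.asarray(A, dtype=float)
    ks = sorted(k for k in k_range if 1 <= k < a.shape[0])
    if not ks:
        raise ValueError("no admissible ranks in k_range")
    rng = np.random.default_rng(seed)
    coph: dict[int, float] = {}
    obj: dict[int, float] = {}
    for k in ks:
        coph[k], obj[k] = _consensus_cophenetic(a, k, n_restarts, max_iter,
                                                rng)
    # objective baseline one rank below the smallest candidate
    k0 = ks[0] - 1
    if k0 >= 1:
        _, _, trace = _nmf_once(a, k0, rng, max_iter, tol=1e-5)
        obj[k0] = trace[-1]
    else:
        obj[k0] = float(np.linalg.norm(a) ** 2)
    prev = {k: (ks[i - 1] if i else k0) for i, k in enumerate(ks)}
    gain = {k: obj[prev[k]] / max(obj[k], _EPS) for k in ks}
    max_coph = max(coph.values())
    candidates = [k for k in ks if coph[k] >= max_coph - 0.01]
    k_star = max(candidates, key=lambda k: (gain[k], -k))
    low_confidence = coph[k_star] < 0.9
    if low_confidence:
        log.warning("rank selection low confidence: max cophenetic %.3f at k=%d",
                    coph[k_star], k_star)
    table = pd.DataFrame({"k": ks, "cophenetic": [coph[k] for k in ks],
                          "objective": [obj[k] for k in ks],
                          "error_gain": [gain[k] for k in ks]})
    return RankSelection(k_star=k_star, cophenetic=coph,
                         low_confidence=low_confidence, table=table)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------
@dataclass
class CoexprModule:
    """An NMF coexpression module with its representative core."""

    module_id: str
    members: list[str]
    membership: dict[str, float]
    core_lncrnas: list[str]
    core_pcgs: list[str]
    enriched_terms: pd.DataFrame | None = None

    @property
    def core(self) -> list[str]:
        return self.core_lncrnas + self.core_pcgs


def assign_modules(
    W: np.ndarray,
    H: np.ndarray,
    gene_ids: Sequence[str],
    biotypes: Sequence[str],
) -> list[CoexprModule]:
    """Assign each gene to its argmax-membership module and pick the cores.

    Ties in membership are broken by lexicographic gene id (and, for the
    argmax across modules, by the first module index), keeping the build
    deterministic.  Cores are the top ``CORE_N_LNCRNA`` lncRNAs and
    ``CORE_N_PCG`` PCGs by membership within each module.
    """
    m = membership_matrix(W, H)
    k = m.shape[1]
    if len(gene_ids) != m.shape[0]:
        raise ValueError("gene_ids length does not match factor dimension")
    assign = np.argmax(m, axis=1)  # first module wins ties
    modules: list[CoexprModule] = []
    for j in range(k):
        mid = f"M{j + 1:02d}"
        idx = [i for i in range(len(gene_ids)) if assign[i] == j]
        # sort members by descending membership, ties by gene id
        idx.sort(key=lambda i: (-m[i, j], gene_ids[i]))
        members = [gene_ids[i] for i in idx]
        weights = {gene_ids[i]: float(m[i, j]) for i in idx}
        lncs = [gene_ids[i] for i in idx if biotypes[i] == "lncRNA"]
        pcgs = [gene_ids[i] for i in idx if biotypes[i] == "PCG"]
        modules.append(CoexprModule(
            module_id=mid,
            members=members,
            membership=weights,
            core_lncrnas=lncs[:CORE_N_LNCRNA],
            core_pcgs=pcgs[:CORE_N_PCG],
        ))
    return modules


def annotate_modules(
    modules: list[CoexprModule],
    term_table: pd.DataFrame,
    universe: Iterable[str],
    p_cutoff: float = 0.01,
) -> list[CoexprModule]:
    """Attach hypergeometric term enrichment of each module's PCG members.

    Annotation maps PCGs only (the guilt-by-association step annotates
    lncRNAs through their coexpressed PCGs); the universe is the set of DE
    PCGs entering the network.  Modules without PCGs get an empty table.
    """
    universe = list(universe)
    for mod in modules:
        pcg_universe = set(universe)
        pcgs = [g for g in mod.members if g in pcg_universe]
        if not pcgs:
            log.warning("module %s has no annotated PCG members", mod.module_id)
            mod.enriched_terms = pd.DataFrame(
                columns=["k", "K", "n", "N", "p", "q", "significant"])
            continue
        mod.enriched_terms = hypergeometric_enrichment(
            pcgs, term_table, universe, p_cutoff=p_cutoff)
    return modules


# ---------------------------------------------------------------------------
# end-to-end pipelines
# ---------------------------------------------------------------------------
@dataclass
class CoexpressionNetwork:
    """Full module-extraction result for one contrast."""

    correlation: CorrelationMatrix
    transform_mode: str
    k: int
    nmf: NMFResult
    modules: list[CoexprModule]
    rank_selection: RankSelection | None = None
    focus_cooccupancy: dict[str, list[str]] = field(default_factory=dict)

    def module_of(self) -> dict[str, str]:
        out = {}
        for mod in self.modules:
            for g in mod.members:
                out[g] = mod.module_id
        return out

    def core_edge_list(self, min_abs_r: float = 0.0) -> pd.DataFrame:
        """Edge list (gene1, gene2, correlation) among each module's core."""
        cdf = self.correlation.to_frame()
        rows = []
        for mod in self.modules:
            core = [g for g in mod.core if g in cdf.index]
            for i, g1 in enumerate(core):
                for g2 in core[i + 1:]:
                    r = float(cdf.loc[g1, g2])
                    if abs(r) >= min_abs_r:
                        rows.append({"module": mod.module_id, "gene1": g1,
                                     "gene2": g2, "correlation": r})
        return pd.DataFrame(rows, columns=["module", "gene1", "gene2",
                                           "correlation"])

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        module_of = self.module_of()
        for gid in self.correlation.gene_ids:
            g.add_node(gid, module=module_of.get(gid, ""))
        for _, row in self.core_edge_list().iterrows():
            g.add_edge(row["gene1"], row["gene2"],
                       weight=float(row["correlation"]))
        nx.write_graphml(g, path)


def extract_modules(
    study: ExpressionStudy,
    de_gene_ids: Sequence[str],
    k: int | str = "auto",
    transform: str = "positive_clip",
    method: str = "pearson",
    sample_ids: Sequence[str] | None = None,
    n_restarts: int = 30,
    max_iter: int = 2000,
    seed: int | None = 0,
    term_table: pd.DataFrame | None = None,
) -> CoexpressionNetwork:
    """Correlation matrix -> nonnegative transform -> NMF -> modules.

    ``k="auto"`` selects the rank by consensus cophenetic correlation over
    2..min(10, dim - 1).  When a term table is supplied the modules are
    annotated against the network's PCG universe.
    """
    corr = build_correlation_matrix(study, de_gene_ids, method=method,
                                    sample_ids=sample_ids)
    a = nonnegative_transform(corr, mode=transform)
    selection = None
    if k == "auto":
        k_max = min(10, a.shape[0] - 1)
        selection = select_rank(a, k_range=range(2, k_max + 1), seed=seed)
        k_use = selection.k_star
    else:
        k_use = int(k)
    nmf = nmf_factorize(a, k_use, n_restarts=n_restarts, max_iter=max_iter,
                        seed=seed)
    biotypes = [study.biotype_of(g) for g in corr.gene_ids]
    modules = assign_modules(nmf.W, nmf.H, corr.gene_ids, biotypes)
    if term_table is not None:
        pcg_universe = [g for g, b in zip(corr.gene_ids, biotypes) if b == "PCG"]
        annotate_modules(modules, term_table, pcg_universe)
    return CoexpressionNetwork(correlation=corr, transform_mode=transform,
                               k=k_use, nmf=nmf, modules=modules,
                               rank_selection=selection)


def lncrna_centered_network(
    study: ExpressionStudy,
    focus_lncrnas: Sequence[str],
    de_gene_ids: Sequence[str],
    n_partners: int = 50,
    k: int | str = "auto",
    transform: str = "positive_clip",
    method: str = "pearson",
    sample_ids: Sequence[str] | None = None,
    seed: int | None = 0,
    term_table: pd.DataFrame | None = None,
) -> CoexpressionNetwork:
    """Coexpression modules built around designated focus lncRNAs.

    Each focus contributes its ``n_partners`` most strongly correlated DE
    PCGs (by |r|; all of them when fewer are available); the module pipeline
    then runs on the foci plus the partner union, and only modules holding
    at least one focus are returned.  ``focus_cooccupancy`` maps each
    retained module to the foci it contains — foci landing in one module
    are candidates for shared regulation.
    """
    foci = list(focus_lncrnas)
    missing = [f for f in foci if f not in study.matrix.index]
    if missing:
        raise KeyError(f"focus lncRNA(s) not expressed in study: {missing}")
    cols = list(sample_ids) if sample_ids is not None else study.sample_ids
    pcg_pool = [g for g in de_gene_ids
                if g in study.matrix.index and study.biotype_of(g) == "PCG"
                and g not in foci]
    x_f = study.matrix.loc[foci, cols].to_numpy(float)
    x_p = study.matrix.loc[pcg_pool, cols].to_numpy(float)
    partners: list[str] = []
    if pcg_pool:
        if method == "spearman":
            x_f = np.apply_along_axis(stats.rankdata, 1, x_f)
            x_p = np.apply_along_axis(stats.rankdata, 1, x_p)
        zf = (x_f - x_f.mean(axis=1, keepdims=True))
        zp = (x_p - x_p.mean(axis=1, keepdims=True))
        zf /= np.maximum(np.linalg.norm(zf, axis=1, keepdims=True), _EPS)
        zp /= np.maximum(np.linalg.norm(zp, axis=1, keepdims=True), _EPS)
        r = zf @ zp.T  # foci x pool
        for i in range(len(foci)):
            order = np.argsort(-np.abs(r[i]), kind="stable")
            take = order[:min(n_partners, len(pcg_pool))]
            partners += [pcg_pool[j] for j in take]
    genes = list(dict.fromkeys(foci + partners))
    net = extract_modules(study, genes, k=k, transform=transform,
                          method=method, sample_ids=cols, seed=seed,
                          term_table=term_table)
    keep = [m for m in net.modules if any(f in m.members for f in foci)]
    net.modules = keep
    net.focus_cooccupancy = {
        m.module_id: [f for f in foci if f in m.members] for m in keep}
    return net
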