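"""Probe handling and differential expression.

The moderated t-statistic shrinks per-gene residual variances toward a common
prior via an empirical-Bayes scaled-inverse-chi-square model: with per-gene
residual variance s2_g on d_g degrees of freedom, the posterior variance is

    s2_post = (d0 * s2_0 + d_g * s2_g) / (d0 + d_g),

and t_mod = logFC / sqrt(s2_post * (1/n_a + 1/n_b)) is referred to a t
distribution with d0 + d_g degrees of freedom.  The hyperparameters
(d0, s2_0) are fitted by the method of moments on log variances using the
digamma/trigamma closed forms; when the trigamma equation has no positive
solution the prior df is infinite and variances pool completely.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .types import Contrast, ExpressionStudy

log = logging.getLogger("lncmod")


# ---------------------------------------------------------------------------
# probe filtering / collapsing
# ---------------------------------------------------------------------------
def detection_filter(
    study: ExpressionStudy,
    min_signal: float | None = None,
    min_fraction: float = 0.1,
) -> ExpressionStudy:
    """Keep genes detected (value > min_signal) in >= min_fraction of samples.

    ``min_signal`` defaults to the 10th percentile of the whole matrix —
    an arbitrary, configurable stand-in for an array detection call.
    """
    if min_signal is None:
        min_signal = float(np.quantile(study.matrix.to_numpy(), 0.10))
    frac = (study.matrix.to_numpy() > min_signal).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("detection filter removed every gene")
    kept = [g for g, k in zip(study.gene_ids, keep) if k]
    log.info("detection filter (signal > %.4g in >= %.0f%% of samples): "
             "kept %d / %d genes", min_signal, 100 * min_fraction,
             len(kept), study.n_genes)
    return study.subset_genes(kept)


def collapse_duplicates(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse probe rows sharing a gene id to their per-sample median.

    Rows with a unique id pass through unchanged; input order is preserved
    by first occurrence.
    """
    m = study.matrix
    if not m.index.has_duplicates:
        return study
    order = list(dict.fromkeys(m.index))
    collapsed = m.groupby(level=0, sort=False).median().loc[order]
    genes = study.genes[~study.genes.index.duplicated(keep="first")].loc[order]
    log.info("collapsed %d probes to %d unique genes", m.shape[0], len(order))
    return ExpressionStudy(collapsed, genes, study.samples).validate()


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameters
# ---------------------------------------------------------------------------
def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s2_0) from per-gene variances.

    Works on z_g = log s2_g: under the model, z_g - digamma(d/2) + log(d/2)
    has mean log s2_0 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(d/2).  No positive solution -> d0 = inf
    (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if e.size < 2:
        return np.inf, float(s2[ok].mean())
    evar = float(e.var(ddof=1))
    rhs = evar - polygamma(1, df / 2.0)
    if rhs <= 0:
        # complete pooling: all true variances coincide, so the arithmetic
        # mean is the natural (unbiased) common-variance estimate and keeps
        # constant inputs a fixed point of the shrinkage
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(rhs)
    s2_0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s2_0


def moderated_t_stats(
    xa: np.ndarray,
    xb: np.ndarray,
    d0: float | None = None,
    s2_0: float | None = None,
) -> dict[str, np.ndarray | float]:
    """Vectorized moderated two-sample t over genes (rows).

    ``d0``/``s2_0`` may be forced (d0 = 0 reduces to the ordinary pooled t);
    by default they are fitted from the data.
    """
    na, nb = xa.shape[1], xb.shape[1]
    d_g = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    logfc = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g
    if d0 is None:
        if xa.shape[0] == 1:
            log.warning("single gene: falling back to ordinary t (d0 = 0)")
            d0, s2_0 = 0.0, 0.0
        else:
            d0, s2_0 = fit_variance_prior(s2, d_g)
    elif s2_0 is None:
        s2_0 = 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s2_0)
    else:
        s2_post = (d0 * s2_0 + d_g * s2) / (d0 + d_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    df_total = d0 + d_g
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return {"logFC": logfc, "s2_g": s2, "d_g": float(d_g), "s2_post": s2_post,
            "d0": float(d0), "s2_0": float(s2_0), "t_mod": t, "p": p}


def moderated_t_contrast(
    study: ExpressionStudy,
    contrast: Contrast,
    d0: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t for one contrast (group_a minus group_b).

    Returns one row per gene with columns logFC, s2_g, d_g, s2_post, d0,
    s2_0, t_mod, p, q (BH-adjusted) and the boolean ``significant`` call at
    the contrast's strict |logFC| and FDR thresholds.
    """
    ids_a, ids_b = contrast.resolve(study.samples)
    xa = study.matrix[ids_a].to_numpy(float)
    xb = study.matrix[ids_b].to_numpy(float)
    if np.all(((xa - xa.mean(axis=1, keepdims=True)) == 0)) and \
       np.all(((xb - xb.mean(axis=1, keepdims=True)) == 0)):
        raise ValueError("zero residual variance in every gene")
    st = moderated_t_stats(xa, xb, d0=d0)
    q = benjamini_hochberg(st["p"])
    out = pd.DataFrame(
        {
            "logFC": st["logFC"],
            "s2_g": st["s2_g"],
            "d_g": st["d_g"],
            "s2_post": st["s2_post"],
            "d0": st["d0"],
            "s2_0": st["s2_0"],
            "t_mod": st["t_mod"],
            "p": st["p"],
            "q": q,
        },
        index=pd.Index(study.gene_ids, name="gene_id"),
    )
    out["significant"] = (np.abs(out["logFC"]) > contrast.lfc_threshold) & \
                         (out["q"] < contrast.fdr_threshold)
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DECallSummary:
    """Up/down/non-significant gene lists split by biotype, with counts."""

    up: dict[str, list[str]]
    down: dict[str, list[str]]
    ns: dict[str, list[str]]

    def counts(self) -> pd.DataFrame:
        biotypes = sorted(set(self.up) | set(self.down) | set(self.ns))
        return pd.DataFrame(
            {
                "up": [len(self.up.get(b, [])) for b in biotypes],
                "down": [len(self.down.get(b, [])) for b in biotypes],
                "ns": [len(self.ns.get(b, [])) for b in biotypes],
            },
            index=biotypes,
        )

    @property
    def significant(self) -> list[str]:
        out: list[str] = []
        for d in (self.up, self.down):
            for genes in d.values():
                out += genes
        return out


def call_significant(
    results: pd.DataFrame,
    study: ExpressionStudy,
    contrast: Contrast,
) -> DECallSummary:
    """Partition DE results into up / down / ns per biotype.

    Strict inequalities at both thresholds: a gene at exactly |logFC| =
    threshold is not significant.
    """
    thr, fdr = contrast.lfc_threshold, contrast.fdr_threshold
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    ns: dict[str, list[str]] = {}
    for gid, row in results.iterrows():
        bt = study.biotype_of(gid)
        if row["q"] < fdr and row["logFC"] > thr:
            up.setdefault(bt, []).append(gid)
        elif row["q"] < fdr and row["logFC"] < -thr:
            down.setdefault(bt, []).append(gid)
        else:
            ns.setdefault(bt, []).append(gid)
    summary = DECallSummary(up=up, down=down, ns=ns)
    log.info("contrast %s: %s", contrast.name,
             summary.counts().to_dict(orient="index"))
    return summary


# ---------------------------------------------------------------------------
# one-way ANOVA across diagnostic groups + group clustering
# ---------------------------------------------------------------------------
@dataclass
class AnovaProfile:
    """Per-gene one-way ANOVA across diagnostic groups.

    ``table`` has columns F, p, q; ``group_means`` and ``logfc_vs_ctr`` are
    genes x groups matrices (the latter relative to the control mean, zero
    for the control column by construction).
    """

    table: pd.DataFrame
    group_means: pd.DataFrame
    logfc_vs_ctr: pd.DataFrame
    groups: list[str]


def anova_profile(study: ExpressionStudy, min_group_size: int = 2) -> AnovaProfile:
    """Classical one-way F per gene across the diagnostic groups.

    Groups with fewer than ``min_group_size`` samples are excluded with a
    warning.  BH adjustment runs across genes; fold changes are expressed
    against the control-group mean.
    """
    sample_groups = study.samples["group"]
    groups = [g for g in dict.fromkeys(sample_groups)
              if (sample_groups == g).sum() >= min_group_size]
    dropped = set(sample_groups) - set(groups)
    if dropped:
        log.warning("ANOVA: excluding undersized groups %s", sorted(dropped))
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 samples each")

    x = study.matrix.to_numpy(float)
    cols = {g: [i for i, s in enumerate(study.sample_ids)
                if sample_groups[s] == g] for g in groups}
    n_tot = sum(len(c) for c in cols.values())
    k = len(groups)
    means = np.column_stack([x[:, cols[g]].mean(axis=1) for g in groups])
    ns = np.array([len(cols[g]) for g in groups], dtype=float)
    grand = (means * ns).sum(axis=1) / n_tot
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(x.shape[0])
    for j, g in enumerate(groups):
        ssw += ((x[:, cols[g]] - means[:, j][:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(np.isnan(p), 1.0, p)
    q = benjamini_hochberg(p)

    idx = pd.Index(study.gene_ids, name="gene_id")
    group_means = pd.DataFrame(means, index=idx, columns=groups)
    if "CTR" in groups:
        logfc = group_means.sub(group_means["CTR"], axis=0)
    else:
        log.warning("no control group present; logfc_vs_ctr left as NaN")
        logfc = group_means * np.nan
    table = pd.DataFrame({"F": f, "p": p, "q": q}, index=idx)
    return AnovaProfile(table=table, group_means=group_means,
                        logfc_vs_ctr=logfc, groups=groups)


@dataclass
class GroupClusters:
    """Hierarchical clustering of group expression profiles."""

    linkage: np.ndarray
    labels: dict[str, int]
    groups: list[str]
    significant_genes: list[str]


def cluster_groups(
    anova: AnovaProfile,
    n_clusters: int = 3,
    fdr_threshold: float = 0.05,
) -> GroupClusters:
    """Cluster diagnostic groups on their ANOVA-significant fold-change profiles.

    Average-linkage hierarchical clustering (Euclidean distance) of the
    group-mean logFC-vs-control vectors restricted to genes with ANOVA
    q < ``fdr_threshold``, cut into ``n_clusters`` flat clusters.
    """
    sig = list(anova.table.index[anova.table["q"] < fdr_threshold])
    if len(sig) < 2:
        raise ValueError(
            f"need >= 2 ANOVA-significant genes to cluster, got {len(sig)}")
    profiles = anova.logfc_vs_ctr.loc[sig].T  # groups x genes
    z = linkage(profiles.to_numpy(), method="average", metric="euclidean")
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    labels = dict(zip(anova.groups, (int(c) for c in flat)))
    return GroupClusters(linkage=z, labels=labels, groups=list(anova.groups),
                         significant_genes=sig)
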