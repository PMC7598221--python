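"""Cis-pair correlation and the imprinted-locus ratio-discordance classifier.

Sense/antisense and locus-neighbour transcript pairs (WT1/WT1-AS,
LEF1/LEF1-AS1, H19/IGF2, H19/miR-675) are expected to be transcriptionally
coregulated; a breakdown of that coregulation in the H19/IGF2 imprinted
region marks higher-risk disease.  Discordance is called per sample on the
linear-scale expression ratio 2^(x - y): a sample whose ratio departs from
the healthy-control reference ratio by more than 10-fold in either
direction is discordant, and discordant patients are compared with
concordant ones by log-rank tests on OS and PFS.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import logrank_test, records_from_study
from .types import ExpressionStudy

log = logging.getLogger("lncmod")


def cis_pair_correlation(
    study: ExpressionStudy,
    pairs: Sequence[tuple[str, str]],
    subgroups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Spearman correlation of each transcript pair within each subgroup.

    ``subgroups`` maps a label (e.g. "all", "ctr_lower_risk") to sample ids.
    Subgroups with fewer than 4 samples yield NaN with a warning.
    """
    rows = []
    for gx, gy in pairs:
        for gid in (gx, gy):
            if gid not in study.matrix.index:
                raise KeyError(f"gene {gid!r} not expressed in study")
        for label, ids in subgroups.items():
            ids = list(ids)
            if len(ids) < 4:
                log.warning("cis pair %s/%s in %s: only %d samples",
                            gx, gy, label, len(ids))
                rows.append({"gene_x": gx, "gene_y": gy, "subgroup": label,
                             "n": len(ids), "r": np.nan, "p": np.nan})
                continue
            x = study.matrix.loc[gx, ids].astype(float)
            y = study.matrix.loc[gy, ids].astype(float)
            r, p = stats.spearmanr(x, y)
            rows.append({"gene_x": gx, "gene_y": gy, "subgroup": label,
                         "n": len(ids), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def classify_concordance(
    study: ExpressionStudy,
    gene_x: str,
    gene_y: str,
    reference_ids: Sequence[str],
    fold_threshold: float = 10.0,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Label samples concordant/discordant on the x/y expression ratio.

    The reference ratio is the median over the reference samples (healthy
    controls by convention) of the linear ratio 2^(x - y).  A sample is
    discordant iff its ratio changes by strictly more than ``fold_threshold``
    in either direction (fold > 10 or fold < 0.1); exactly 10-fold stays
    concordant.  Labels are invariant to swapping the pair and to adding a
    constant to both genes' log2 values.
    """
    for gid in (gene_x, gene_y):
        if gid not in study.matrix.index:
            raise KeyError(f"gene {gid!r} not expressed in study")
    refs = list(reference_ids)
    if not refs:
        raise ValueError("reference sample set is empty")
    ids = list(sample_ids) if sample_ids is not None else study.sample_ids
    log_ratio = study.matrix.loc[gene_x] - study.matrix.loc[gene_y]
    ref_ratio = float(2.0 ** np.median(log_ratio[refs].astype(float)))
    rows = []
    for sid in ids:
        ratio = float(2.0 ** log_ratio[sid])
        fold = ratio / ref_ratio
        label = ("discordant"
                 if fold > fold_threshold or fold < 1.0 / fold_threshold
                 else "concordant")
        rows.append({"sample_id": sid, "gene_x": gene_x, "gene_y": gene_y,
                     "ratio": ratio, "ref_ratio": ref_ratio,
                     "fold_change_of_ratio": fold, "label": label})
    return pd.DataFrame(rows).set_index("sample_id")


def discordance_survival_test(
    study: ExpressionStudy,
    calls: pd.DataFrame,
    endpoints: Sequence[str] = ("os", "pfs"),
) -> dict[str, tuple[float, float]]:
    """Log-rank comparison of concordant vs discordant patients per endpoint.

    Returns ``{endpoint: (chi2, p)}``; a single-class labelling yields
    ``(nan, nan)`` with a warning.
    """
    patients = [s for s in calls.index
                if s in study.samples.index
                and study.samples.at[s, "group"] != "CTR"]
    conc = [s for s in patients if calls.at[s, "label"] == "concordant"]
    disc = [s for s in patients if calls.at[s, "label"] == "discordant"]
    out: dict[str, tuple[float, float]] = {}
    for ep in endpoints:
        if not conc or not disc:
            log.warning("discordance survival (%s): single-class labelling", ep)
            out[ep] = (np.nan, np.nan)
            continue
        ra = records_from_study(study, [], ep, sample_ids=conc)
        rb = records_from_study(study, [], ep, sample_ids=disc)
        if not ra or not rb:
            log.warning("discordance survival (%s): no usable records", ep)
            out[ep] = (np.nan, np.nan)
            continue
        out[ep] = logrank_test(ra, rb)
    return out
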