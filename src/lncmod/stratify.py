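"""Cohort stratification rules shared by the prognosis analyses.

Three stratifiers, each returning a partition (disjoint and exhaustive) of its
eligible input set:

* 18-month overall-survival split (short vs long survivors),
* IPSS-R lower- vs higher-risk grouping (intermediate risk excluded),
* somatic-mutation carrier vs wild type at a 5% VAF cut-off.
"""
from __future__ import annotations

import logging

from .types import ExpressionStudy

log = logging.getLogger("lncmod")


def stratify_by_survival(
    study: ExpressionStudy,
    cutoff_months: float = 18.0,
) -> tuple[list[str], list[str], list[str]]:
    """Split patients into short vs long overall survivors at a cut-off.

    short: deceased (os_event) with os_months <= cutoff — death at exactly
    the cut-off counts as short.  long: os_months > cutoff regardless of
    event status.  Patients censored at or before the cut-off cannot be
    classified and are excluded, as are samples with missing follow-up and
    all healthy controls.

    Returns ``(short_ids, long_ids, excluded_ids)``, a partition of all
    study samples in input order.
    """
    s = study.samples
    if not (s["group"] != "CTR").any():
        raise ValueError("no MDS/AML-MRC samples to stratify")
    short, long_, excluded = [], [], []
    for sid, row in s.iterrows():
        t, ev = row["os_months"], row["os_event"]
        if row["group"] == "CTR" or t != t:  # NaN check
            excluded.append(sid)
        elif t > cutoff_months:
            long_.append(sid)
        elif ev is True or ev == 1:
            short.append(sid)
        else:  # censored at or before the cut-off: outcome unknown
            excluded.append(sid)
    log.info(
        "survival stratification at %.4g months: %d short, %d long, %d excluded",
        cutoff_months, len(short), len(long_), len(excluded),
    )
    return short, long_, excluded


_LOWER = {"very_low", "low"}
_HIGHER = {"high", "very_high"}


def stratify_by_ipssr(
    study: ExpressionStudy,
) -> tuple[list[str], list[str], list[str]]:
    """Group MDS patients into IPSS-R lower vs higher risk.

    lower = {very_low, low}; higher = {high, very_high}; intermediate-risk
    MDS, AML-MRC, controls and samples without a category are excluded.
    Empty strata are allowed (logged, not an error).
    """
    s = study.samples
    lower, higher, excluded = [], [], []
    for sid, row in s.iterrows():
        cat = row["ipssr_category"]
        if row["group"] == "CTR" or row["group"] == "AML-MRC" or not isinstance(cat, str):
            excluded.append(sid)
        elif cat in _LOWER:
            lower.append(sid)
        elif cat in _HIGHER:
            higher.append(sid)
        else:
            excluded.append(sid)
    if not lower or not higher:
        log.warning("IPSS-R stratification produced an empty stratum "
                    "(%d lower, %d higher)", len(lower), len(higher))
    return lower, higher, excluded


def mutation_carrier_sets(
    study: ExpressionStudy,
    gene_symbol: str,
    vaf_cutoff: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split screened samples into carriers vs wild type for one gene.

    A sample is a carrier iff any recorded variant in ``gene_symbol`` has
    VAF strictly above ``vaf_cutoff`` (a variant at exactly the cut-off is
    wild type).  Unscreened samples (no mutation data) are excluded from
    both sets.
    """
    mutated, wildtype = [], []
    for sid, muts in study.samples["mutations"].items():
        if muts is None:
            continue
        if muts.get(gene_symbol, 0.0) > vaf_cutoff:
            mutated.append(sid)
        else:
            wildtype.append(sid)
    return mutated, wildtype
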