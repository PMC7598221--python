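"""Core domain containers for the lncRNA/PCG expression-study pipeline.

An :class:`ExpressionStudy` bundles a genes x samples log2 expression matrix
with a gene annotation table (biotype, optional sense/antisense locus partner)
and a sample metadata table (WHO diagnostic group, IPSS-R risk, karyotype,
somatic mutation VAFs, survival endpoints, blood counts).  Every downstream
stage — differential expression, enrichment, coexpression networks, survival
models — consumes this one container.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("lncmod")

#: WHO diagnostic groups, ordered from healthy controls to overt leukemia.
GROUPS = (
    "CTR",
    "MDS-SLD",
    "MDS-MLD",
    "MDS-RS",
    "MDS-del5q",
    "MDS-EB1",
    "MDS-EB2",
    "AML-MRC",
)
MDS_GROUPS = tuple(g for g in GROUPS if g.startswith("MDS"))
#: every non-control group (MDS subtypes plus AML-MRC)
PATIENT_GROUPS = tuple(g for g in GROUPS if g != "CTR")

BIOTYPES = ("lncRNA", "PCG", "miRNA")

IPSSR_CATEGORIES = ("very_low", "low", "intermediate", "high", "very_high")
KARYOTYPES = ("normal", "isolated_del5q", "other")

#: IPSS-R score cut points -> category (upper bounds, inclusive)
_IPSSR_BOUNDS = ((1.5, "very_low"), (3.0, "low"), (4.5, "intermediate"), (6.0, "high"))


def ipssr_category_from_score(score: float) -> str:
    """Map a numeric IPSS-R score to its risk category (very_low .. very_high)."""
    for bound, cat in _IPSSR_BOUNDS:
        if score <= bound:
            return cat
    return "very_high"


class StudyValidationError(ValueError):
    """Raised when an expression study violates a structural invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene/probe annotation: identifier, biotype, optional locus partner."""

    gene_id: str
    biotype: str
    partner_id: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise StudyValidationError(
                f"unknown biotype {self.biotype!r} for {self.gene_id}"
            )


Selector = Callable[[pd.DataFrame], pd.Series] | Sequence[str]


def _resolve_selector(selector: Selector, samples: pd.DataFrame) -> list[str]:
    """Resolve a sample selector to an ordered list of sample ids.

    A selector is either a callable ``samples -> boolean mask``, a collection
    of group names, or a collection of explicit sample ids.
    """
    if callable(selector):
        mask = selector(samples)
        return list(samples.index[np.asarray(mask, dtype=bool)])
    items = list(selector)
    if all(it in GROUPS for it in items):
        return list(samples.index[samples["group"].isin(items)])
    missing = [it for it in items if it not in samples.index]
    if missing:
        raise KeyError(f"selector entries are neither groups nor sample ids: {missing}")
    return items


@dataclass(frozen=True)
class Contrast:
    """A two-group differential-expression contrast (group_a minus group_b).

    ``group_a``/``group_b`` are selectors: collections of WHO group names,
    explicit sample-id lists, or callables returning boolean masks over the
    sample metadata table.  Significance thresholds default to the standard
    |logFC| > 1, FDR < 0.05 setting; mutation contrasts typically refine the
    fold-change cut to 0.3.
    """

    name: str
    group_a: Selector
    group_b: Selector
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.lfc_threshold > 0:
            raise ValueError("lfc_threshold must be > 0")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")

    def resolve(self, samples: pd.DataFrame) -> tuple[list[str], list[str]]:
        """Return the (ids_a, ids_b) sample lists; disjoint, each of size >= 2."""
        ids_a = _resolve_selector(self.group_a, samples)
        ids_b = _resolve_selector(self.group_b, samples)
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise StudyValidationError(
                f"contrast {self.name!r}: groups overlap on {sorted(overlap)[:5]}"
            )
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise StudyValidationError(
                f"contrast {self.name!r}: both groups need >= 2 samples "
                f"(got {len(ids_a)} vs {len(ids_b)})"
            )
        return ids_a, ids_b

    def swapped(self) -> "Contrast":
        return replace(self, name=self.name + "_swapped",
                       group_a=self.group_b, group_b=self.group_a)


#: metadata columns expected in the sample table (beyond the index)
SAMPLE_COLUMNS = (
    "group",
    "ipssr_score",
    "ipssr_category",
    "karyotype",
    "mutations",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "age",
    "blast_pct",
    "hemoglobin",
    "neutrophils",
    "platelets",
)


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus gene annotation and sample metadata.

    Attributes
    ----------
    matrix : DataFrame, genes x samples, log2 intensities.
    genes : DataFrame indexed by gene_id with columns ``biotype`` and
        ``partner_id`` (empty string / NaN when absent).
    samples : DataFrame indexed by sample_id with the clinical columns of
        :data:`SAMPLE_COLUMNS`; ``mutations`` holds ``dict[symbol, VAF]``
        for screened samples and ``None`` for unscreened ones.

    Input row/column order is preserved throughout; nothing is sorted.
    """

    matrix: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame

    # -- basic geometry ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def biotype_of(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "biotype"])

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return list(self.genes.index[self.genes["biotype"] == biotype])

    # -- subsetting --------------------------------------------------------
    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionStudy":
        ids = list(gene_ids)
        return ExpressionStudy(self.matrix.loc[ids], self.genes.loc[ids],
                               self.samples)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionStudy":
        ids = list(sample_ids)
        return ExpressionStudy(self.matrix[ids], self.genes,
                               self.samples.loc[ids])

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.copy(), self.genes.copy(),
                               self.samples.copy())

    # -- validation --------------------------------------------------------
    def validate(self, allow_duplicate_genes: bool = False) -> "ExpressionStudy":
        """Check structural invariants; return self for chaining.

        Raises :class:`StudyValidationError` on the first violation.  With
        ``allow_duplicate_genes`` the matrix may still contain probe-level
        rows sharing a gene id (pre probe-collapse).
        """
        m, g, s = self.matrix, self.genes, self.samples
        if not allow_duplicate_genes and m.index.has_duplicates:
            dup = m.index[m.index.duplicated()][0]
            raise StudyValidationError(f"duplicate gene id {dup!r}")
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise StudyValidationError(f"duplicate sample id {dup!r}")
        if list(m.index) != list(g.index):
            raise StudyValidationError("matrix rows and gene annotation disagree")
        extra = [c for c in m.columns if c not in s.index]
        if extra:
            raise StudyValidationError(
                f"sample {extra[0]!r} present in matrix but absent from metadata"
            )
        if list(m.columns) != list(s.index):
            raise StudyValidationError("matrix columns and sample metadata disagree")
        vals = m.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise StudyValidationError("expression matrix is not numeric")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise StudyValidationError(
                f"non-finite expression at gene {m.index[i]!r}, "
                f"sample {m.columns[j]!r}"
            )
        bad = set(g["biotype"]) - set(BIOTYPES)
        if bad:
            raise StudyValidationError(f"unknown biotypes {sorted(bad)}")
        if "partner_id" in g.columns:
            partners = g["partner_id"].dropna()
            partners = partners[partners != ""]
            unknown = [p for p in partners if p not in g.index]
            if unknown:
                raise StudyValidationError(
                    f"partner_id {unknown[0]!r} refers to no gene in the study"
                )
        bad_group = set(s["group"]) - set(GROUPS)
        if bad_group:
            raise StudyValidationError(f"unknown sample groups {sorted(bad_group)}")
        # controls must be free of somatic mutations above the VAF cut
        for sid in s.index[s["group"] == "CTR"]:
            muts = s.at[sid, "mutations"]
            if isinstance(muts, dict) and any(v > 0.05 for v in muts.values()):
                raise StudyValidationError(
                    f"control sample {sid!r} carries a mutation with VAF > 0.05"
                )
        # score/category consistency when both present
        both = s.dropna(subset=["ipssr_score"])
        for sid, row in both.iterrows():
            cat = row.get("ipssr_category")
            if isinstance(cat, str) and cat:
                expected = ipssr_category_from_score(float(row["ipssr_score"]))
                if cat != expected:
                    raise StudyValidationError(
                        f"sample {sid!r}: ipssr_category {cat!r} inconsistent "
                        f"with score {row['ipssr_score']} (expected {expected!r})"
                    )
        return self


@dataclass
class SurvivalRecord:
    """Time-to-event record for one patient with a covariate mapping."""

    sample_id: str
    time: float
    event: bool
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.sample_id}: survival time must be > 0")
        bad = [k for k, v in self.covariates.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"{self.sample_id}: non-finite covariates {bad}")
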