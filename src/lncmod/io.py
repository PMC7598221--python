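"""Readers and writers for the plain-text formats used across the pipeline.

Formats
-------
expression matrix : TSV; first column ``gene_id``, one column per sample,
    log2 values.
gene annotation : TSV with columns ``gene_id``, ``biotype``, ``partner_id``
    (empty allowed).
sample metadata : TSV with the clinical fields; the ``mutations`` column
    encodes screened samples as a semicolon list ``GENE:VAF;GENE:VAF`` (the
    literal ``none`` meaning screened with no variant calls) and unscreened
    samples as an empty cell.
gene sets : GMT (tab separated: name, description, member gene ids).
gene -> term annotation : two-column TSV ``gene_id<TAB>term``.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import SAMPLE_COLUMNS, ExpressionStudy, StudyValidationError

log = logging.getLogger("lncmod")

_UNSCREENED = ""
_NO_VARIANTS = "none"


# ---------------------------------------------------------------------------
# mutation encoding
# ---------------------------------------------------------------------------
def parse_mutations(cell: object) -> dict[str, float] | None:
    """Decode a mutation cell; ``None`` means the sample was not screened."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == _UNSCREENED:
        return None
    if text.lower() == _NO_VARIANTS:
        return {}
    out: dict[str, float] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            symbol, vaf = item.split(":")
            out[symbol.strip()] = float(vaf)
        except ValueError as exc:
            raise StudyValidationError(f"malformed mutation entry {item!r}") from exc
    return out


def format_mutations(muts: Mapping[str, float] | None) -> str:
    if muts is None:
        return _UNSCREENED
    if not muts:
        return _NO_VARIANTS
    return ";".join(f"{k}:{v:.4g}" for k, v in muts.items())


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------
def _read_matrix(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise StudyValidationError(
            f"{path}: first matrix column must be 'gene_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise StudyValidationError(
                f"{path}: non-numeric expression value {raw.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        cols[col] = converted
    return pd.DataFrame(cols, index=raw.index)


_NUMERIC_SAMPLE_COLS = (
    "ipssr_score", "os_months", "pfs_months", "age", "blast_pct",
    "hemoglobin", "neutrophils", "platelets",
)
_BOOL_SAMPLE_COLS = ("os_event", "pfs_event")


def read_expression_study(
    matrix_path: str | Path,
    gene_anno_path: str | Path,
    sample_meta_path: str | Path,
    allow_duplicate_genes: bool = False,
) -> ExpressionStudy:
    """Read the three study TSVs and return a validated :class:`ExpressionStudy`.

    Missing clinical fields stay missing (NaN / None); nothing is imputed.
    Duplicate ids, samples absent from the metadata, and non-numeric
    expression cells are hard errors that name the offending row/column.
    """
    matrix = _read_matrix(Path(matrix_path))
    genes = pd.read_csv(gene_anno_path, sep="\t", dtype=str).set_index("gene_id")
    if "partner_id" not in genes.columns:
        genes["partner_id"] = ""
    genes["partner_id"] = genes["partner_id"].fillna("")

    samples = pd.read_csv(sample_meta_path, sep="\t", dtype=str).set_index("sample_id")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            samples[col] = np.nan
    for col in _NUMERIC_SAMPLE_COLS:
        samples[col] = pd.to_numeric(samples[col], errors="raise")
    for col in _BOOL_SAMPLE_COLS:
        vals = samples[col].replace({"True": 1, "False": 0, "true": 1,
                                     "false": 0})
        vals = pd.to_numeric(vals, errors="raise")
        samples[col] = vals.map(lambda v: bool(v) if pd.notna(v) else np.nan)
    samples["mutations"] = samples["mutations"].map(parse_mutations)
    for col in ("ipssr_category", "karyotype"):
        samples[col] = samples[col].where(samples[col].notna(), None)

    study = ExpressionStudy(matrix=matrix, genes=genes, samples=samples)
    return study.validate(allow_duplicate_genes=allow_duplicate_genes)


def write_expression_study(
    study: ExpressionStudy,
    outdir: str | Path,
    prefix: str = "study",
) -> dict[str, Path]:
    """Write matrix/genes/samples TSVs; returns the paths keyed by role.

    Expression values are written with enough digits that a write -> read
    round trip reproduces the matrix to better than 1e-9.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}_matrix.tsv",
        "genes": outdir / f"{prefix}_genes.tsv",
        "samples": outdir / f"{prefix}_samples.tsv",
    }
    m = study.matrix.copy()
    m.index.name = "gene_id"
    m.to_csv(paths["matrix"], sep="\t", float_format="%.12g")

    g = study.genes.copy()
    g.index.name = "gene_id"
    g.to_csv(paths["genes"], sep="\t")

    s = study.samples.copy()
    s["mutations"] = s["mutations"].map(format_mutations)
    for col in _BOOL_SAMPLE_COLS:
        s[col] = s[col].map(lambda v: int(v) if v is True or v is False else v)
    s.index.name = "sample_id"
    s.to_csv(paths["samples"], sep="\t", float_format="%.12g")
    return paths


# ---------------------------------------------------------------------------
# gene sets (GMT) and term annotation
# ---------------------------------------------------------------------------
def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file -> ``{name: (description, [member gene ids])}``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise StudyValidationError(f"malformed GMT line: {line[:60]!r}")
        name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if not members:
            raise StudyValidationError(f"gene set {name!r} has no members")
        if name in sets:
            raise StudyValidationError(f"duplicate gene set {name!r}")
        sets[name] = (desc, members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


def read_term_table(path: str | Path) -> pd.DataFrame:
    """Read the two-column ``gene_id<TAB>term`` annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "term"}
    if not need <= set(df.columns):
        raise StudyValidationError(
            f"{path}: term table needs columns {sorted(need)}, got {list(df.columns)}"
        )
    return df[["gene_id", "term"]]


def write_term_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[["gene_id", "term"]].to_csv(path, sep="\t", index=False)
    return path
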