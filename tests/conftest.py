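"""Shared fixtures: handmade micro-studies and small simulated cohorts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lncmod as lm
from lncmod.types import ExpressionStudy, SurvivalRecord


def make_study(matrix: dict[str, list[float]], biotypes: dict[str, str],
               groups: dict[str, str], **sample_cols) -> ExpressionStudy:
    """Build a small validated study from plain dicts.

    ``matrix`` maps gene_id -> per-sample values; sample ids default to
    A, B, C...; extra sample columns may be passed as dicts keyed by
    sample id.
    """
    genes = list(matrix)
    n = len(next(iter(matrix.values())))
    sample_ids = sample_cols.pop("sample_ids",
                                 [chr(ord("A") + i) for i in range(n)])
    m = pd.DataFrame({s: [matrix[g][j] for g in genes]
                      for j, s in enumerate(sample_ids)},
                     index=pd.Index(genes, name="gene_id"), dtype=float)
    g = pd.DataFrame({"biotype": [biotypes.get(x, "PCG") for x in genes],
                      "partner_id": ""},
                     index=pd.Index(genes, name="gene_id"))
    s = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    s["group"] = [groups.get(x, "MDS-MLD") for x in sample_ids]
    defaults = {"ipssr_score": np.nan, "ipssr_category": None,
                "karyotype": None, "mutations": None,
                "os_months": np.nan, "os_event": np.nan,
                "pfs_months": np.nan, "pfs_event": np.nan,
                "age": np.nan, "blast_pct": np.nan, "hemoglobin": np.nan,
                "neutrophils": np.nan, "platelets": np.nan}
    for col, default in defaults.items():
        vals = sample_cols.get(col, {})
        s[col] = [vals.get(x, default) for x in sample_ids]
    return ExpressionStudy(m, g, s).validate()


def make_records(times, events, **covariates) -> list[SurvivalRecord]:
    n = len(times)
    return [
        SurvivalRecord(f"S{i}", float(times[i]), bool(events[i]),
                       {k: float(v[i]) for k, v in covariates.items()})
        for i in range(n)
    ]


def null_two_group_config(seed: int, n_genes: int = 200,
                          n_per_group: int = 10) -> lm.SimulationConfig:
    """Pure-noise two-group study: no planted effects of any kind."""
    half = n_genes // 2
    return lm.SimulationConfig(
        n_lnc=half, n_pcg=n_genes - half,
        n_samples_per_group={"CTR": n_per_group, "MDS-EB2": n_per_group},
        group_severity={"CTR": 0.0, "MDS-EB2": 1.0},
        n_modules=0, de_fraction=0.0, de_logfc=0.0,
        include_locus_genes=False, mutation_carriers={},
        n_unscreened_patients=0, n_unscreened_controls=0, seed=seed)


def module_recovery_config(seed: int, noise_sd: float = 0.3,
                           n_modules: int = 3) -> lm.SimulationConfig:
    """Planted-module factor model: 15 lncRNA + 40 PCG per module, 60 samples."""
    return lm.SimulationConfig(
        n_lnc=15 * n_modules, n_pcg=40 * n_modules,
        n_samples_per_group={"CTR": 20, "MDS-EB2": 40},
        group_severity={"CTR": 0.0, "MDS-EB2": 1.0},
        n_modules=n_modules, module_size_lnc=15, module_size_pcg=40,
        module_loading=1.0, module_factor_sd=1.0, noise_sd=noise_sd,
        de_fraction=0.0, de_logfc=0.0, include_locus_genes=False,
        mutation_carriers={}, n_unscreened_patients=0,
        n_unscreened_controls=0, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """A small full-featured simulated cohort shared across read-only tests."""
    cfg = lm.SimulationConfig(n_lnc=200, n_pcg=200, seed=11)
    study, truth, term_table, gmt = lm.simulate_full(cfg)
    return study, truth, term_table, gmt


@pytest.fixture()
def two_group_null_study():
    study, truth = lm.simulate_study(null_two_group_config(seed=5))
    return study, truth
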