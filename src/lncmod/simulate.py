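"""Synthetic expression studies with known ground truth.

The generator emulates the design of a CD34+ bone-marrow microarray study of
myelodysplastic syndrome: ~10^4 lncRNA and ~10^4 protein-coding features over
a cohort of healthy controls, six WHO MDS subtypes and AML-MRC.  Expression
follows a planted linear model on the log2 scale,

    x_gs = mu_g + sum_c delta_gc * severity(group_s)
               + sum_m lambda_gm * f_ms + eps_gs,

with module factors f_ms ~ Normal(0, module_factor_sd) and residual noise
eps ~ Normal(0, noise_sd).  Planted structure — differential genes, lncRNA/PCG
coexpression modules, mutation carriers with expression shifts, hazard-driving
marker genes, and locus genes (H19/IGF2/miR-675, WT1/WT1-AS, LEF1/LEF1-AS1,
TCL6/TCL1A/TCL1B) — is recorded in a :class:`GroundTruth` object so every
downstream stage has a recovery-based test.

Disease severity scales the planted group effects: controls sit at 0, early
MDS (single-lineage dysplasia) close to 0, the intermediate subtypes at ~0.5
and MDS-EB2/AML-MRC at 1, producing the gradual healthy -> advanced expression
shift with three natural sample clusters.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import (
    GROUPS,
    PATIENT_GROUPS,
    Contrast,
    ExpressionStudy,
    ipssr_category_from_score,
)

log = logging.getLogger("lncmod")

#: default cohort layout (discovery-cohort sizes: 54 MDS + 14 AML-MRC + 9 CTR)
DEFAULT_COHORT: dict[str, int] = {
    "CTR": 9,
    "MDS-SLD": 6,
    "MDS-MLD": 12,
    "MDS-RS": 8,
    "MDS-del5q": 8,
    "MDS-EB1": 10,
    "MDS-EB2": 10,
    "AML-MRC": 14,
}

#: independent validation-cohort layout (79 MDS + 14 AML-MRC + 13 CTR)
TESTING_COHORT: dict[str, int] = {
    "CTR": 13,
    "MDS-SLD": 8,
    "MDS-MLD": 18,
    "MDS-RS": 12,
    "MDS-del5q": 11,
    "MDS-EB1": 15,
    "MDS-EB2": 15,
    "AML-MRC": 14,
}

#: disease severity per group, scaling every planted group effect
DEFAULT_SEVERITY: dict[str, float] = {
    "CTR": 0.0,
    "MDS-SLD": 0.15,
    "MDS-MLD": 0.5,
    "MDS-RS": 0.5,
    "MDS-del5q": 0.5,
    "MDS-EB1": 0.6,
    "MDS-EB2": 1.0,
    "AML-MRC": 1.0,
}

#: planted somatic-mutation carrier counts among screened patients
DEFAULT_MUTATION_CARRIERS: dict[str, int] = {
    "SF3B1": 14,
    "TET2": 10,
    "TP53": 10,
    "DNMT3A": 9,
    "RUNX1": 9,
}

#: named locus genes: gene_id -> (biotype, partner_id)
LOCUS_GENES: dict[str, tuple[str, str]] = {
    "H19": ("lncRNA", "IGF2"),
    "IGF2": ("PCG", "H19"),
    "MIR675": ("miRNA", "H19"),
    "WT1": ("PCG", "WT1-AS"),
    "WT1-AS": ("lncRNA", "WT1"),
    "LEF1": ("PCG", "LEF1-AS1"),
    "LEF1-AS1": ("lncRNA", "LEF1"),
    "TCL6": ("lncRNA", ""),
    "TCL1A": ("PCG", "TCL6"),
    "TCL1B": ("PCG", "TCL6"),
}

#: shared cis latent factors: factor name -> member gene ids
CIS_FACTORS: dict[str, tuple[str, ...]] = {
    "cis_WT1": ("WT1", "WT1-AS"),
    "cis_LEF1": ("LEF1", "LEF1-AS1"),
    "cis_TCL": ("TCL6", "TCL1A", "TCL1B"),
    "cis_H19": ("H19", "IGF2", "MIR675"),
}

#: severity-scaled log2 shifts of prognosis-related locus genes
LOCUS_SEVERITY_EFFECTS: dict[str, float] = {
    "WT1": 0.8,
    "WT1-AS": 0.8,
    "LEF1": -0.8,
    "LEF1-AS1": -0.8,
    "TCL6": -0.8,
    "TCL1A": -0.3,
    "TCL1B": -0.3,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults reproduce the emulated design."""

    n_lnc: int = 10_000
    n_pcg: int = 10_000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT))
    group_severity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY))
    n_modules: int = 4
    module_size_lnc: int = 15
    module_size_pcg: int = 40
    module_factor_sd: float = 1.0
    module_loading: float = 1.0
    de_fraction: float = 0.01
    de_logfc: float = 1.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    # survival
    survival_beta: Mapping[str, float] = field(
        default_factory=lambda: {"H19": 0.7, "blast_pct": 0.5, "TP53_mut": 0.7})
    baseline_hazard: float = 0.03        # events per month
    censor_rate: float = 0.3
    pfs_rate_multiplier: float = 1.6     # progression-or-death vs death-only rate
    # mutations
    mutation_carriers: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_CARRIERS))
    mutation_n_affected: int = 30
    mutation_logfc: float = 0.6
    n_unscreened_patients: int = 4
    n_unscreened_controls: int = 1
    # locus genes
    include_locus_genes: bool = True
    cis_loading: float = 1.5
    locus_disruption_logfc: float = 2.0
    # annotation
    n_terms: int = 200
    term_enrichment: float = 0.8
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")
        if self.n_modules * self.module_size_lnc > self.n_lnc:
            raise ValueError("module lncRNA demand exceeds n_lnc")
        if self.n_modules * self.module_size_pcg > self.n_pcg:
            raise ValueError("module PCG demand exceeds n_pcg")
        for name, val in (("module_factor_sd", self.module_factor_sd),
                          ("noise_sd", self.noise_sd),
                          ("baseline_hazard", self.baseline_hazard)):
            if not val > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        unknown = set(self.n_samples_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        n_screened_patients = (
            sum(n for g, n in self.n_samples_per_group.items() if g != "CTR")
            - self.n_unscreened_patients)
        if self.mutation_carriers and max(self.mutation_carriers.values(), default=0) \
                > max(n_screened_patients, 0):
            raise ValueError("more planted carriers than screened patients")
        return self


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    config: SimulationConfig
    de_effects: dict[str, float]            # gene -> signed log2 shift at severity 1
    module_members: dict[str, list[str]]    # module id -> member genes
    module_of: dict[str, str]               # gene -> module id
    carriers: dict[str, list[str]]          # mutation symbol -> carrier sample ids
    mutation_effect_genes: dict[str, dict[str, float]]
    marker_genes: dict[str, float]          # hazard covariate -> log-hazard beta
    contrast: Contrast | None               # the primary MDS-vs-control contrast
    matched_terms: dict[str, str] = field(default_factory=dict)

    @property
    def de_up(self) -> list[str]:
        return [g for g, e in self.de_effects.items() if e > 0]

    @property
    def de_down(self) -> list[str]:
        return [g for g, e in self.de_effects.items() if e < 0]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# expression + clinical metadata
# ---------------------------------------------------------------------------
def simulate_study(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Draw a study from the planted linear model; reproducible given the seed."""
    config.validate()
    rng = _rng(config, 0)

    # -- genes -------------------------------------------------------------
    lnc_ids = [f"LNC{i:05d}" for i in range(1, config.n_lnc + 1)]
    pcg_ids = [f"PCG{i:05d}" for i in range(1, config.n_pcg + 1)]
    gene_ids = lnc_ids + pcg_ids
    biotype = ["lncRNA"] * config.n_lnc + ["PCG"] * config.n_pcg
    partner = [""] * len(gene_ids)
    if config.include_locus_genes:
        for gid, (bt, pt) in LOCUS_GENES.items():
            gene_ids.append(gid)
            biotype.append(bt)
            partner.append(pt)
    genes = pd.DataFrame({"biotype": biotype, "partner_id": partner},
                         index=pd.Index(gene_ids, name="gene_id"))
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # -- samples -----------------------------------------------------------
    group_of: list[str] = []
    for g in GROUPS:  # canonical group order; sizes from config
        group_of += [g] * int(config.n_samples_per_group.get(g, 0))
    n_samples = len(group_of)
    if n_samples == 0:
        raise ValueError("empty cohort")
    sample_ids = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    severity = np.array([config.group_severity.get(g, 0.0) for g in group_of])

    # -- planted group effects ----------------------------------------------
    effects = np.zeros(n_genes)
    de_effects: dict[str, float] = {}
    n_de_lnc = int(round(config.de_fraction * config.n_lnc))
    n_de_pcg = int(round(config.de_fraction * config.n_pcg))
    de_lnc = rng.choice(config.n_lnc, size=n_de_lnc, replace=False)
    de_pcg = config.n_lnc + rng.choice(config.n_pcg, size=n_de_pcg, replace=False)
    for idx in np.concatenate([de_lnc, de_pcg]).astype(int):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[idx] = sign * config.de_logfc
        de_effects[gene_ids[idx]] = effects[idx]

    # -- planted coexpression modules ---------------------------------------
    # members are drawn from non-DE genes then given their own group effect so
    # they pass the DE filter feeding the coexpression network
    free_lnc = [i for i in range(config.n_lnc) if effects[i] == 0]
    free_pcg = [i for i in range(config.n_lnc, config.n_lnc + config.n_pcg)
                if effects[i] == 0]
    pick_lnc = rng.choice(len(free_lnc),
                          size=config.n_modules * config.module_size_lnc,
                          replace=False)
    pick_pcg = rng.choice(len(free_pcg),
                          size=config.n_modules * config.module_size_pcg,
                          replace=False)
    module_members: dict[str, list[str]] = {}
    module_of: dict[str, str] = {}
    loadings = np.zeros((n_genes, config.n_modules))
    for m in range(config.n_modules):
        mid = f"M{m + 1:02d}"
        lidx = [free_lnc[j] for j in
                pick_lnc[m * config.module_size_lnc:(m + 1) * config.module_size_lnc]]
        pidx = [free_pcg[j] for j in
                pick_pcg[m * config.module_size_pcg:(m + 1) * config.module_size_pcg]]
        members = [gene_ids[i] for i in lidx + pidx]
        module_members[mid] = members
        for i in lidx + pidx:
            module_of[gene_ids[i]] = mid
            loadings[i, m] = config.module_loading
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[i] = sign * config.de_logfc
            de_effects[gene_ids[i]] = effects[i]

    # -- locus gene effects --------------------------------------------------
    if config.include_locus_genes:
        for gid, eff in LOCUS_SEVERITY_EFFECTS.items():
            effects[gene_pos[gid]] += eff
            de_effects[gid] = de_effects.get(gid, 0.0) + eff
        # imprinting-locus disruption: H19 up, IGF2/miR-675 down with severity
        d = config.locus_disruption_logfc
        for gid, eff in (("H19", d), ("IGF2", -d), ("MIR675", -d)):
            effects[gene_pos[gid]] += eff
            de_effects[gid] = de_effects.get(gid, 0.0) + eff

    # -- assemble the matrix --------------------------------------------------
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    x = mu[:, None] + effects[:, None] * severity[None, :]
    if config.n_modules:
        factors = rng.normal(0.0, config.module_factor_sd,
                             size=(config.n_modules, n_samples))
        x += loadings @ factors
    if config.include_locus_genes:
        for members in CIS_FACTORS.values():
            f = rng.normal(0.0, 1.0, size=n_samples)
            for gid in members:
                x[gene_pos[gid]] += config.cis_loading * f
    x += rng.normal(0.0, config.noise_sd, size=x.shape)
    matrix = pd.DataFrame(x, index=genes.index,
                          columns=pd.Index(sample_ids, name="sample_id"))

    # -- clinical metadata -----------------------------------------------------
    samples = _simulate_clinical(config, rng, sample_ids, group_of, severity)

    # -- mutations --------------------------------------------------------------
    carriers, effect_genes = _simulate_mutations(
        config, rng, samples, gene_ids, x)
    matrix.iloc[:, :] = x  # mutation shifts were applied in place

    patient_groups = [g for g in PATIENT_GROUPS
                      if config.n_samples_per_group.get(g, 0) >= 2]
    has_ctr = config.n_samples_per_group.get("CTR", 0) >= 2
    contrast = None
    if patient_groups and has_ctr:
        contrast = Contrast("MDS_vs_CTR", tuple(patient_groups), ("CTR",))

    truth = GroundTruth(
        config=config,
        de_effects=de_effects,
        module_members=module_members,
        module_of=module_of,
        carriers=carriers,
        mutation_effect_genes=effect_genes,
        marker_genes=dict(config.survival_beta),
        contrast=contrast,
    )
    study = ExpressionStudy(matrix=matrix, genes=genes, samples=samples)
    return study.validate(), truth


def _simulate_clinical(config, rng, sample_ids, group_of, severity) -> pd.DataFrame:
    n = len(sample_ids)
    blast_base = {"CTR": 1.0, "MDS-SLD": 2.0, "MDS-MLD": 2.5, "MDS-RS": 2.5,
                  "MDS-del5q": 2.5, "MDS-EB1": 7.0, "MDS-EB2": 14.0,
                  "AML-MRC": 25.0}
    rows = []
    for i, (sid, grp) in enumerate(zip(sample_ids, group_of)):
        sev = severity[i]
        if grp == "CTR":
            score, cat = np.nan, None
        else:
            score = float(np.clip(rng.normal(1.5 + 5.5 * sev, 1.0), 0.0, 10.0))
            cat = ipssr_category_from_score(score)
        if grp == "MDS-del5q":
            karyo = "isolated_del5q"
        else:
            karyo = "normal" if rng.random() < 0.7 else "other"
        rows.append({
            "sample_id": sid,
            "group": grp,
            "ipssr_score": score,
            "ipssr_category": cat,
            "karyotype": karyo,
            "mutations": None,  # filled by the mutation stage
            "os_months": np.nan,
            "os_event": np.nan,
            "pfs_months": np.nan,
            "pfs_event": np.nan,
            "age": float(rng.normal(70.0, 8.0)),
            "blast_pct": float(np.clip(
                blast_base[grp] + rng.normal(0.0, 1.5), 0.0, 30.0)),
            "hemoglobin": float(rng.normal(125.0 - 30.0 * sev, 12.0)),
            "neutrophils": float(np.exp(rng.normal(0.7 - 0.5 * sev, 0.4))),
            "platelets": float(np.clip(rng.normal(220.0 - 80.0 * sev, 60.0),
                                       5.0, None)),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_mutations(config, rng, samples, gene_ids, x):
    """Assign screening status, carriers and carrier expression shifts."""
    patients = [s for s in samples.index if samples.at[s, "group"] != "CTR"]
    controls = [s for s in samples.index if samples.at[s, "group"] == "CTR"]
    unscreened = set()
    if patients and config.n_unscreened_patients:
        k = min(config.n_unscreened_patients, len(patients))
        unscreened |= set(rng.choice(patients, size=k, replace=False))
    if controls and config.n_unscreened_controls:
        k = min(config.n_unscreened_controls, len(controls))
        unscreened |= set(rng.choice(controls, size=k, replace=False))
    muts: dict[str, dict[str, float] | None] = {
        s: (None if s in unscreened else {}) for s in samples.index}

    screened_patients = [s for s in patients if s not in unscreened]
    sample_pos = {s: j for j, s in enumerate(samples.index)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    generic = [g for g in gene_ids if g not in LOCUS_GENES]
    carriers: dict[str, list[str]] = {}
    effect_genes: dict[str, dict[str, float]] = {}
    for symbol, count in config.mutation_carriers.items():
        if count == 0 or not screened_patients:
            carriers[symbol] = []
            effect_genes[symbol] = {}
            continue
        chosen = list(rng.choice(screened_patients, size=count, replace=False))
        carriers[symbol] = chosen
        for s in chosen:
            muts[s][symbol] = float(rng.uniform(0.1, 0.5))
        affected = rng.choice(len(generic), size=min(config.mutation_n_affected,
                                                     len(generic)), replace=False)
        eff = {}
        cols = [sample_pos[s] for s in chosen]
        for j in affected:
            gid = generic[j]
            e = config.mutation_logfc * (1.0 if rng.random() < 0.5 else -1.0)
            eff[gid] = e
            x[gene_pos[gid], cols] += e
        effect_genes[symbol] = eff
    samples["mutations"] = pd.Series(muts)
    return carriers, effect_genes


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------
def _hazard_covariate(study: ExpressionStudy, name: str,
                      patient_ids: list[str]) -> np.ndarray:
    """Resolve a hazard covariate to a standardized vector over patients."""
    if name in study.matrix.index:
        v = study.matrix.loc[name, patient_ids].to_numpy(float)
    elif name.endswith("_mut"):
        symbol = name[:-4]
        v = np.array([
            1.0 if (isinstance(m, dict) and m.get(symbol, 0.0) > 0.05) else 0.0
            for m in study.samples.loc[patient_ids, "mutations"]])
        return v  # indicator enters the hazard unstandardized
    elif name in study.samples.columns:
        v = study.samples.loc[patient_ids, name].to_numpy(float)
    else:
        raise KeyError(f"unknown hazard marker {name!r}")
    sd = v.std()
    if sd == 0:
        raise ValueError(f"marker {name!r} is constant; cannot standardize")
    return (v - v.mean()) / sd


def simulate_survival(
    study: ExpressionStudy,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionStudy:
    """Fill OS/PFS columns from an exponential proportional-hazards model.

    Event times are exponential with rate
    ``baseline_hazard * exp(sum_g beta_g z_gs)`` where ``z`` is the
    standardized marker expression (mutation indicators enter as 0/1).
    Censoring is an independent exponential time whose rate is solved so the
    expected censored fraction matches ``censor_rate``; controls get no
    survival data.
    """
    if rng is None:
        rng = _rng(config, 1)
    study = study.copy()
    patients = [s for s in study.sample_ids
                if study.samples.at[s, "group"] != "CTR"]
    if not patients:
        return study
    lp = np.zeros(len(patients))
    for name, beta in config.survival_beta.items():
        lp += beta * _hazard_covariate(study, name, patients)
    rate = config.baseline_hazard * np.exp(lp)
    t_death = rng.exponential(1.0 / rate)
    t_prog = rng.exponential(1.0 / (rate * (config.pfs_rate_multiplier - 1.0))) \
        if config.pfs_rate_multiplier > 1.0 else np.full_like(t_death, np.inf)
    t_pfs = np.minimum(t_death, t_prog)

    if config.censor_rate > 0:
        def excess(log_lc: float) -> float:
            lc = math.exp(log_lc)
            return float(np.mean(lc / (lc + rate))) - config.censor_rate
        log_lc = brentq(excess, -20.0, 20.0)
        t_cens = rng.exponential(math.exp(-log_lc), size=len(patients))
    else:
        t_cens = np.full(len(patients), np.inf)

    os_months = np.minimum(t_death, t_cens)
    os_event = t_death <= t_cens
    pfs_months = np.minimum(t_pfs, t_cens)
    pfs_event = t_pfs <= t_cens
    # guard against zero times (exponential draws are > 0 but keep a floor)
    os_months = np.maximum(os_months, 1e-6)
    pfs_months = np.maximum(pfs_months, 1e-6)

    for col in ("os_event", "pfs_event"):
        study.samples[col] = study.samples[col].astype(object)
    study.samples.loc[patients, "os_months"] = os_months
    study.samples.loc[patients, "os_event"] = list(map(bool, os_event))
    study.samples.loc[patients, "pfs_months"] = pfs_months
    study.samples.loc[patients, "pfs_event"] = list(map(bool, pfs_event))
    return study


# ---------------------------------------------------------------------------
# annotation (terms + gene sets)
# ---------------------------------------------------------------------------
def simulate_annotation(
    truth: GroundTruth,
    config: SimulationConfig,
    gene_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[str, list[str]]]]:
    """Build a gene -> term table plus GMT gene sets with planted enrichment.

    Each planted module gets one matched term covering ``term_enrichment`` of
    its members (all of them at 1.0); the remaining ``n_terms`` background
    terms draw members uniformly from the whole gene universe.  Two extra
    GMT sets collect the planted up- and down-regulated genes so permutation
    GSEA has a recoverable signal.  Updates ``truth.matched_terms`` in place.
    """
    if rng is None:
        rng = _rng(config, 2)
    rows: list[tuple[str, str]] = []
    gmt: dict[str, tuple[str, list[str]]] = {}
    for mid, members in truth.module_members.items():
        term = f"TERM_{mid}"
        k = max(1, int(round(config.term_enrichment * len(members))))
        if k >= len(members):
            chosen = list(members)
        else:
            chosen = list(rng.choice(members, size=k, replace=False))
        truth.matched_terms[mid] = term
        rows += [(g, term) for g in chosen]
        gmt[term] = (f"matched term for planted module {mid}", chosen)
    for t in range(1, config.n_terms + 1):
        term = f"TERM{t:04d}"
        size = int(rng.integers(10, 50))
        members = list(rng.choice(gene_ids, size=min(size, len(gene_ids)),
                                  replace=False))
        rows += [(g, term) for g in members]
        gmt[term] = ("background term", members)
    if truth.de_up:
        gmt["SET_PLANTED_UP"] = ("planted up-regulated genes", truth.de_up)
    if truth.de_down:
        gmt["SET_PLANTED_DOWN"] = ("planted down-regulated genes", truth.de_down)
    table = pd.DataFrame(rows, columns=["gene_id", "term"])
    return table, gmt


def simulate_full(config: SimulationConfig):
    """Convenience: study with survival plus annotation in one call.

    Returns ``(study, truth, term_table, gmt)``.
    """
    study, truth = simulate_study(config)
    study = simulate_survival(study, config)
    table, gmt = simulate_annotation(truth, config, study.gene_ids)
    return study, truth, table, gmt
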