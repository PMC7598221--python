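"""Survival estimation and prognosis modelling.

Kaplan-Meier product-limit curves, two-group log-rank tests, expression
dichotomization, univariate forest statistics, a Spearman covariate
correlation matrix, and multivariate Cox proportional-hazards regression
with backward variable elimination.  The Cox partial likelihood handles
tied event times with the Efron correction and is maximized by
Newton-Raphson on the analytic score and information.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stratify import mutation_carrier_sets
from .types import ExpressionStudy, SurvivalRecord

log = logging.getLogger("lncmod")


class CoxConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized."""


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------
def extract_covariate(study: ExpressionStudy, name: str) -> pd.Series:
    """Resolve a covariate name to per-sample values.

    Gene ids map to log2 expression rows; ``SYMBOL_mut`` maps to a 0/1
    mutation-carrier indicator (NaN for unscreened samples); anything else
    must be a clinical metadata column.
    """
    if name in study.matrix.index:
        return study.matrix.loc[name].astype(float)
    if name.endswith("_mut"):
        symbol = name[:-4]
        mutated, wildtype = mutation_carrier_sets(study, symbol)
        vals = pd.Series(np.nan, index=study.samples.index, name=name)
        vals[mutated] = 1.0
        vals[wildtype] = 0.0
        return vals
    if name in study.samples.columns:
        return study.samples[name].astype(float)
    raise KeyError(f"unknown covariate {name!r}")


def records_from_study(
    study: ExpressionStudy,
    variables: Sequence[str],
    endpoint: str = "os",
    sample_ids: Sequence[str] | None = None,
    standardize: bool = False,
) -> list[SurvivalRecord]:
    """Build complete-case survival records for an endpoint.

    Patients (non-control samples) with the endpoint and every covariate
    observed are included; the number dropped for missingness is logged,
    never imputed.  ``standardize`` z-scores continuous covariates across
    the included patients (binary indicators are left as 0/1).
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    pool = list(sample_ids) if sample_ids is not None else [
        s for s in study.sample_ids if study.samples.at[s, "group"] != "CTR"]
    covs = {v: extract_covariate(study, v) for v in variables}
    records: list[SurvivalRecord] = []
    dropped = 0
    kept_rows: list[tuple[str, float, bool, dict[str, float]]] = []
    for sid in pool:
        t = study.samples.at[sid, tcol]
        ev = study.samples.at[sid, ecol]
        row = {v: covs[v].get(sid, np.nan) for v in variables}
        if not np.isfinite(t) or ev is np.nan or ev != ev or \
                any(not np.isfinite(x) for x in row.values()):
            dropped += 1
            continue
        kept_rows.append((sid, float(t), bool(ev), row))
    if dropped:
        log.info("complete-case filter (%s): dropped %d of %d patients",
                 endpoint, dropped, len(pool))
    if standardize and kept_rows:
        for v in variables:
            vals = np.array([r[3][v] for r in kept_rows])
            uniq = np.unique(vals)
            if uniq.size <= 2:
                continue  # keep indicators interpretable
            sd = vals.std()
            if sd > 0:
                for r in kept_rows:
                    r[3][v] = (r[3][v] - vals.mean()) / sd
    for sid, t, ev, row in kept_rows:
        records.append(SurvivalRecord(sample_id=sid, time=t, event=ev,
                                      covariates=dict(row)))
    return records


def _records_to_arrays(records: Sequence[SurvivalRecord],
                       variables: Sequence[str] | None):
    if not records:
        raise ValueError("no survival records")
    if variables is None:
        variables = list(records[0].covariates)
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=bool)
    x = np.array([[r.covariates[v] for v in variables] for r in records],
                 dtype=float) if variables else np.zeros((len(records), 0))
    return time, event, x, list(variables)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------
def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival curve S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    One row per distinct event time with the risk-set size, event count and
    the survival estimate; censoring shrinks the risk set without a step.
    """
    time, event, _, _ = _records_to_arrays(records, [])
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = len(time)
    i = 0
    at_risk = n
    while i < n:
        t = time[i]
        d = 0
        c = 0
        while i < n and time[i] == t:
            if event[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append({"time": t, "n_at_risk": at_risk, "n_events": d,
                         "survival": s})
        at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival"])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------
def logrank_test(
    records_a: Sequence[SurvivalRecord],
    records_b: Sequence[SurvivalRecord],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi2 on 1 df, p).

    Sums observed-minus-expected group-a events over the pooled event times
    with the hypergeometric variance.  No events at all -> p = 1 with a
    warning (zero variance).
    """
    if not records_a or not records_b:
        raise ValueError("both groups must be non-empty")
    ta, ea, _, _ = _records_to_arrays(records_a, [])
    tb, eb, _, _ = _records_to_arrays(records_b, [])
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    if not events.any():
        log.warning("log-rank: no events in either group; p = 1")
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_b = int((at_risk & group).sum())
        d = int((events & (times == t)).sum())
        d_b = int((events & (times == t) & group).sum())
        o_minus_e += d_b - d * n_b / n
        if n > 1:
            var += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    if var == 0:
        log.warning("log-rank: zero variance; p = 1")
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# expression dichotomization
# ---------------------------------------------------------------------------
def dichotomize_expression(
    study: ExpressionStudy,
    gene_id: str,
    rule: str = "median",
    sample_ids: Sequence[str] | None = None,
    endpoint: str = "os",
) -> tuple[list[str], list[str], float]:
    """Split samples into low vs high expressors of one gene.

    ``median`` (default): cut at the median, values equal to the cut point
    go to the low group.  ``maxstat``: the cut point between the 10% and
    90% expression quantiles minimizing the log-rank p for ``endpoint``.
    Returns ``(low_ids, high_ids, cutpoint)``.
    """
    ids = list(sample_ids) if sample_ids is not None else [
        s for s in study.sample_ids if study.samples.at[s, "group"] != "CTR"]
    vals = study.matrix.loc[gene_id, ids].astype(float)
    if vals.nunique() == 1:
        raise ValueError(f"{gene_id}: constant expression; cannot dichotomize")
    if rule == "median":
        cut = float(vals.median())
    elif rule == "maxstat":
        lo, hi = vals.quantile(0.10), vals.quantile(0.90)
        candidates = sorted(v for v in vals.unique() if lo <= v <= hi)
        best = (np.inf, float(vals.median()))
        for c in candidates:
            low = [s for s in ids if vals[s] <= c]
            high = [s for s in ids if vals[s] > c]
            if len(low) < 2 or len(high) < 2:
                continue
            ra = records_from_study(study, [], endpoint, sample_ids=low)
            rb = records_from_study(study, [], endpoint, sample_ids=high)
            if not ra or not rb:
                continue
            _, p = logrank_test(ra, rb)
            if p < best[0]:
                best = (p, float(c))
        cut = best[1]
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    low = [s for s in ids if vals[s] <= cut]
    high = [s for s in ids if vals[s] > cut]
    return low, high, cut


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------
@dataclass
class CoxModel:
    """Fitted proportional-hazards model; may be empty after selection."""

    variables: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    log_partial_likelihood: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95_low(self) -> np.ndarray:
        return np.exp(self.beta - 1.96 * self.se)

    @property
    def ci95_high(self) -> np.ndarray:
        return np.exp(self.beta + 1.96 * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self, sort_by_p: bool = False) -> pd.DataFrame:
        out = pd.DataFrame({
            "beta": self.beta, "HR": self.hr,
            "ci95_low": self.ci95_low, "ci95_high": self.ci95_high,
            "p": self.wald_p,
        }, index=pd.Index(self.variables, name="variable"))
        if sort_by_p:
            out = out.sort_values("p", ascending=False, kind="stable")
        return out

    @property
    def is_empty(self) -> bool:
        return len(self.variables) == 0


def _efron_loglik(beta, time, event, x):
    """Log partial likelihood, score and information with Efron ties.

    Vectorized over tied-event blocks: samples are sorted by descending
    time so risk-set sums are cumulative sums; within each block of d tied
    events the Efron weights l/d, l = 0..d-1, discount the tied set.
    """
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    t, ev, xs = time[order], event[order], x[order]
    eta = xs @ beta
    eta -= eta.max()  # guard exp overflow; constant shifts cancel
    theta = np.exp(eta)
    wx = theta[:, None] * xs
    wxx = theta[:, None, None] * (xs[:, :, None] * xs[:, None, :])
    cum0 = np.cumsum(theta)
    cum1 = np.cumsum(wx, axis=0)
    cum2 = np.cumsum(wxx, axis=0)

    # block boundaries: distinct times, descending
    change = np.nonzero(np.diff(t))[0]
    ends = np.append(change, n - 1)  # last index of each time block
    starts = np.append(0, change + 1)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for s_i, e_i in zip(starts, ends):
        block = slice(s_i, e_i + 1)
        ev_block = ev[block]
        d = int(ev_block.sum())
        if d == 0:
            continue
        idx_ev = np.arange(s_i, e_i + 1)[ev_block]
        s0r, s1r, s2r = cum0[e_i], cum1[e_i], cum2[e_i]
        th_d = theta[idx_ev]
        s0d = th_d.sum()
        s1d = wx[idx_ev].sum(axis=0)
        s2d = wxx[idx_ev].sum(axis=0)
        loglik += float(eta[idx_ev].sum())
        score += xs[idx_ev].sum(axis=0)
        frac = np.arange(d) / d
        phi = s0r - frac * s0d                       # (d,)
        num1 = s1r[None, :] - frac[:, None] * s1d    # (d, p)
        num2 = s2r[None, :, :] - frac[:, None, None] * s2d
        loglik -= float(np.log(phi).sum())
        score -= (num1 / phi[:, None]).sum(axis=0)
        mean1 = num1 / phi[:, None]
        info += (num2 / phi[:, None, None]).sum(axis=0)
        info -= np.einsum("li,lj->ij", mean1, mean1)
    return loglik, score, info


def cox_fit(
    records: Sequence[SurvivalRecord],
    variables: Sequence[str] | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxModel:
    """Newton-Raphson maximization of the Efron-tie partial likelihood.

    Convergence when the largest score component falls below ``tol``.
    Monotone likelihood (separation) or non-convergence raises
    :class:`CoxConvergenceError` naming the worst-behaved variable.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    time, event, x, variables = _records_to_arrays(records, variables)
    n_events = int(event.sum())
    if n_events < len(variables) + 1:
        raise ValueError(
            f"need >= {len(variables) + 1} events for {len(variables)} "
            f"variables, got {n_events}")
    if not variables:
        ll, _, _ = _efron_loglik(np.zeros(0), time, event, x)
        return CoxModel([], np.zeros(0), np.zeros(0), len(records),
                        n_events, ll)
    # center covariates for numerical stability (beta is unaffected)
    x = x - x.mean(axis=0)
    beta = np.zeros(len(variables))
    ll, score, info = _efron_loglik(beta, time, event, x)
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            worst = variables[int(np.argmax(np.abs(score)))]
            raise CoxConvergenceError(
                f"singular information matrix (variable {worst!r})") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_loglik(new_beta, time, event, x)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_loglik(new_beta, time, event, x)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > 50:
            worst = variables[int(np.argmax(np.abs(beta)))]
            raise CoxConvergenceError(
                f"monotone likelihood: variable {worst!r} separates the data")
    else:
        worst = variables[int(np.argmax(np.abs(score)))]
        raise CoxConvergenceError(
            f"no convergence in {max_iter} iterations (variable {worst!r})")
    # monotone likelihood: an effectively infinite coefficient converges to a
    # numerically flat region (huge beta on the per-SD scale, exploding SE)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    per_sd = np.abs(beta) * sd
    if np.any(per_sd > 20):
        worst = variables[int(np.argmax(per_sd))]
        raise CoxConvergenceError(
            f"monotone likelihood: variable {worst!r} separates the data")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxModel(list(variables), beta, se, len(records), n_events, float(ll))


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------
def backward_select(
    records: Sequence[SurvivalRecord],
    variables: Sequence[str],
    alpha_stay: float = 0.05,
) -> tuple[CoxModel, list[tuple[str, float]]]:
    """Backward variable elimination on Wald p-values.

    Iteratively drops the variable with the largest p > ``alpha_stay`` and
    refits until every remaining variable satisfies p <= ``alpha_stay``.
    Ties on the worst p are broken by dropping the later input position.
    Returns the final model (possibly empty, with a warning) and the
    ordered removal trace ``[(variable, p_at_removal), ...]``.
    """
    remaining = list(variables)
    trace: list[tuple[str, float]] = []
    while remaining:
        model = cox_fit(records, remaining)
        p = model.wald_p
        worst_p = np.nanmax(p)
        if worst_p <= alpha_stay:
            return model, trace
        # later input position wins ties
        worst_idx = max(
            (i for i in range(len(remaining)) if p[i] == worst_p),
            key=lambda i: variables.index(remaining[i]) if remaining[i]
            in variables else i)
        trace.append((remaining[worst_idx], float(worst_p)))
        remaining.pop(worst_idx)
    log.warning("backward selection removed every variable")
    empty = cox_fit(records, [])
    return empty, trace


def lower_risk_subanalysis(
    study: ExpressionStudy,
    variables: Sequence[str],
    endpoints: Sequence[str] = ("os", "pfs"),
    score_threshold: float = 4.5,
    alpha_stay: float = 0.05,
    standardize: bool = True,
) -> dict[str, tuple[CoxModel, list[tuple[str, float]]]]:
    """Backward-selected Cox models restricted to IPSS-R score < threshold.

    Re-runs the prognosis model on lower/intermediate-risk patients only.
    An empty selection is an error; fewer than 10 eligible patients is a
    warning.
    """
    s = study.samples
    eligible = [sid for sid in study.sample_ids
                if s.at[sid, "group"] != "CTR"
                and np.isfinite(s.at[sid, "ipssr_score"])
                and s.at[sid, "ipssr_score"] < score_threshold]
    if not eligible:
        raise ValueError(
            f"no patients with IPSS-R score < {score_threshold}")
    if len(eligible) < 10:
        log.warning("lower-risk sub-analysis on only %d patients", len(eligible))
    out = {}
    for ep in endpoints:
        records = records_from_study(study, variables, ep,
                                     sample_ids=eligible,
                                     standardize=standardize)
        out[ep] = backward_select(records, list(variables),
                                  alpha_stay=alpha_stay)
    return out


# ---------------------------------------------------------------------------
# univariate forest + Spearman matrix
# ---------------------------------------------------------------------------
def _stars(p: float) -> str:
    for cut, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < cut:
            return mark
    return "n.s."


def univariate_forest(
    study: ExpressionStudy,
    variables: Sequence[str],
    endpoint: str = "os",
) -> pd.DataFrame:
    """Per-variable univariate survival statistics, input order preserved.

    Each variable enters a one-covariate Cox fit per unit for the HR and
    95% CI; the p-value is the log-rank test on the median-dichotomized
    variable (binary indicators are compared directly), starred at the
    0.05 / 0.01 / 0.001 / 0.0001 levels.
    """
    rows = []
    for var in variables:
        records = records_from_study(study, [var], endpoint)
        row = {"variable": var, "HR": np.nan, "ci95_low": np.nan,
               "ci95_high": np.nan, "logrank_p": np.nan, "stars": "n.s.",
               "n": len(records)}
        try:
            model = cox_fit(records, [var])
            row.update(HR=float(model.hr[0]), ci95_low=float(model.ci95_low[0]),
                       ci95_high=float(model.ci95_high[0]))
        except (CoxConvergenceError, ValueError) as exc:
            log.warning("univariate Cox failed for %s: %s", var, exc)
        vals = np.array([r.covariates[var] for r in records])
        if len(records) >= 4 and np.unique(vals).size > 1:
            cut = np.median(vals) if np.unique(vals).size > 2 else 0.5
            low = [r for r in records if r.covariates[var] <= cut]
            high = [r for r in records if r.covariates[var] > cut]
            if low and high:
                _, p = logrank_test(low, high)
                row.update(logrank_p=p, stars=_stars(p))
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def spearman_matrix(
    study: ExpressionStudy,
    variables: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between covariates.

    Returns ``(r, p)`` DataFrames; cells with fewer than 4 pairwise complete
    observations stay NaN with a warning.  Average ranks with the
    t-approximation p-value on n - 2 degrees of freedom.
    """
    ids = list(sample_ids) if sample_ids is not None else [
        s for s in study.sample_ids if study.samples.at[s, "group"] != "CTR"]
    data = pd.DataFrame({v: extract_covariate(study, v).reindex(ids)
                         for v in variables})
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, vi in enumerate(variables):
        for j in range(i + 1, k):
            vj = variables[j]
            sub = data[[vi, vj]].dropna()
            if len(sub) < 4:
                log.warning("Spearman %s vs %s: only %d complete pairs",
                            vi, vj, len(sub))
                rho, pval = np.nan, np.nan
            else:
                rho, pval = stats.spearmanr(sub[vi], sub[vj])
            r.loc[vi, vj] = r.loc[vj, vi] = rho
            p.loc[vi, vj] = p.loc[vj, vi] = pval
    return r, p
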