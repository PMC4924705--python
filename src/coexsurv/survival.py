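"""Prognostic screening: Cox regression, log-rank tests, two-cohort
validation and permutation group enrichment.

The Cox proportional-hazards model is fit by Newton-Raphson maximization of
the Breslow partial likelihood

    l(b) = sum_{i: event} [ eta_i - log sum_{j: t_j >= t_i} exp(eta_j) ],
    eta = X b,

with Wald standard errors from the observed information at the maximum.
The log-rank statistic compares observed vs expected events between a
high-expression and a low-expression group split at the median.  Genes
significant in a discovery cohort are validated in a second cohort by
requiring significance there too with a concordant hazard-ratio sign, and
the concentration of survival-associated genes inside a module group is
assessed by a label-permutation test against a hypergeometric-style null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coexsurv.io import ClinicalTable, ExpressionMatrix, ValidationError

__all__ = [
    "CoxResult",
    "ScreenResult",
    "fit_cox",
    "cox_screen",
    "median_split_logrank",
    "reproducible_screen",
    "permutation_group_enrichment",
    "screen_stage_groups",
    "encode_covariates",
]

MAX_ABS_BETA = 20.0


@dataclass
class CoxResult:
    """Per-gene Cox fit summary (coefficient of the expression covariate)."""

    gene: str
    beta: float
    hr: float
    se: float
    z: float
    p_value: float
    n_used: int
    n_events: int
    converged: bool
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "beta": self.beta,
            "hr": self.hr,
            "se": self.se,
            "z": self.z,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "n_events": self.n_events,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


@dataclass
class ScreenResult:
    """Per-stage-group outcome of the two-cohort survival screen."""

    stage: str
    group_genes: list[str]
    discovery_significant: list[str]
    validated: list[str]
    enrichment_p: float
    discovery: pd.DataFrame = field(repr=False, default=None)
    validation: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery


def _breslow_quantities(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood, score and observed information (Breslow ties)."""
    order = np.argsort(time, kind="stable")
    Xs, ts, ev = X[order], time[order], event[order]
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios
    w = np.exp(eta)
    # suffix sums: risk set of an event at t is everyone with t_j >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    outer = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum((w[:, None, None] * outer)[::-1], axis=0)[::-1]
    # map each position to the first index of its tie group
    first = np.searchsorted(ts, ts, side="left")
    ev_idx = np.where(ev == 1)[0]
    j = first[ev_idx]
    s0 = S0[j]
    mu = S1[j] / s0[:, None]
    ll = float(eta[ev_idx].sum() - np.log(s0).sum())
    grad = Xs[ev_idx].sum(axis=0) - mu.sum(axis=0)
    info = (S2[j] / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mu, mu)
    return ll, grad, info


def _grid_search_beta(X, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force 1-d maximizer of the Breslow log partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    best_b, best_ll = 0.0, -np.inf
    for b in grid:
        ll, _, _ = _breslow_quantities(np.array([b]), X, time, event)
        if ll > best_ll:
            best_b, best_ll = float(b), ll
    return best_b


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    gene: str = "x",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Cox PH fit of survival on an expression vector (plus optional covariates).

    The reported statistics are for the expression coefficient (first
    column); covariates are adjusted for but not reported.  Ties are handled
    with the Breslow approximation; convergence is declared when the score
    norm falls below ``tol``.  A constant expression vector gives the
    degenerate result beta = 0, p = 1; fits wandering beyond |beta| > 20
    (separation) are flagged non-converged.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(time).all() and np.isfinite(x).all()):
        raise ValidationError("non-finite time or expression values")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValidationError("no events in cohort; Cox model is unidentifiable")
    if np.ptp(x) == 0:
        return CoxResult(gene, 0.0, 1.0, np.inf, 0.0, 1.0, len(x), n_events, True, degenerate=True)
    cols = [x[:, None]]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        cols.append(covariates)
    X = np.hstack(cols)
    # center + scale for numerical stability; back-transform beta/se after
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xn = (X - mean) / scale
    p = Xn.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _breslow_quantities(beta, Xn, time, event)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        step_ll = -np.inf
        for _ in range(30):
            cand = beta + delta
            step_ll, step_grad, step_info = _breslow_quantities(cand, Xn, time, event)
            if step_ll >= ll - 1e-12:
                break
            delta = delta / 2.0
        beta, ll, grad, info = cand, step_ll, step_grad, step_info
        if np.abs(beta[0] / scale[0]) > MAX_ABS_BETA:
            break
    else:
        converged = bool(np.linalg.norm(grad) < tol)
    beta_raw = beta / scale
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se_raw = np.sqrt(np.abs(np.diag(cov))) / scale
    b0, se0 = float(beta_raw[0]), float(se_raw[0])
    if abs(b0) > MAX_ABS_BETA or not np.isfinite(se0):
        return CoxResult(gene, b0, float(np.exp(np.clip(b0, -500, 500))), se0, np.nan, np.nan, len(x), n_events, False)
    z = b0 / se0 if se0 > 0 else 0.0
    pv = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(gene, b0, float(np.exp(b0)), se0, float(z), pv, len(x), n_events, converged)


def encode_covariates(clinical: ClinicalTable, names: Sequence[str]) -> np.ndarray | None:
    """Reference-level indicator encoding for categorical covariates; age as-is."""
    if not names:
        return None
    cols = []
    t = clinical.table
    for name in names:
        if name not in t.columns:
            raise ValidationError(f"covariate {name!r} absent from clinical table")
        col = t[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols) if cols else None


def cox_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: Iterable[str] | None = None,
    adjust: Sequence[str] = (),
) -> pd.DataFrame:
    """Univariate (optionally covariate-adjusted) Cox fit per gene.

    Expression columns are matched to clinical rows by sample id; samples
    missing from either side are dropped.
    """
    shared = [s for s in expr.sample_ids if s in clinical.table.index]
    if len(shared) < 2:
        raise ValidationError("fewer than 2 samples shared between expression and clinical tables")
    clin = clinical.aligned_to(shared)
    sub = expr.data[shared]
    covs = encode_covariates(clin, adjust)
    gene_list = list(genes) if genes is not None else list(sub.index)
    rows = []
    for g in gene_list:
        if g not in sub.index:
            continue
        res = fit_cox(clin.time, clin.event, sub.loc[g].to_numpy(), covariates=covs, gene=g)
        rows.append(res.as_dict())
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Log-rank


def median_split_logrank(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Two-group log-rank test after splitting at the median expression.

    High group: x > median; low group: x <= median (values equal to the
    median go low, for determinism on discrete data).  Returns
    ``(labels, chi_square, p)`` where labels is 1 for high, 0 for low.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    high = (x > med).astype(int)
    if high.sum() == 0 or high.sum() == len(x):
        raise ValidationError("median split produced an empty group (constant expression?)")
    chi2 = logrank_chi2(time, event, high)
    p = float(stats.chi2.sf(chi2, df=1))
    return high, float(chi2), p


def logrank_chi2(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Standard two-group log-rank chi-square (1 df).

    At each distinct event time the observed events in group 1 are compared
    to the expectation under equal hazards, with the usual hypergeometric
    variance; the statistic is (sum O - sum E)^2 / sum V.
    """
    event_times = np.unique(time[event == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return float((O - E) ** 2 / V)


# ---------------------------------------------------------------------------
# Two-cohort validation and permutation enrichment


def reproducible_screen(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
    sign_only: bool = False,
) -> list[str]:
    """Genes significant in discovery and concordant in validation.

    Keeps genes with p < alpha in discovery, present in the validation
    screen with the same sign of beta, and (unless ``sign_only``) p < alpha
    in validation as well.  Genes absent from validation are dropped.
    """
    hits = discovery.index[discovery["p_value"] < alpha]
    kept = []
    for g in hits:
        if g not in validation.index:
            continue
        if np.sign(discovery.loc[g, "beta"]) != np.sign(validation.loc[g, "beta"]):
            continue
        if not sign_only and not validation.loc[g, "p_value"] < alpha:
            continue
        kept.append(g)
    return kept


def permutation_group_enrichment(
    group_genes: Iterable[str],
    significant_genes: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for over-representation of significant genes.

    The observed statistic is the overlap between the module group and the
    significant set; the null redraws ``|group|`` genes from the universe
    without replacement ``n_perm`` times.  The estimator is
    ``(1 + #{overlap >= observed}) / (1 + n_perm)``, never exactly zero.
    """
    rng = np.random.default_rng(rng)
    group = set(group_genes)
    sig = set(significant_genes)
    uni = sorted(set(universe))
    if not group:
        raise ValidationError("empty module group")
    if not group <= set(uni) or not sig <= set(uni):
        raise ValidationError("group and significant genes must lie inside the universe")
    if len(group) > len(uni):
        raise ValidationError("group larger than universe")
    observed = len(group & sig)
    k = len(group)
    sig_mask = np.array([g in sig for g in uni])
    # vectorized draws without replacement: k smallest of a uniform row
    u = rng.random((n_perm, len(uni)))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    overlaps = sig_mask[idx].sum(axis=1)
    return float((1 + int((overlaps >= observed).sum())) / (1 + n_perm))


def screen_stage_groups(
    stage_gene_sets: dict[str, list[str]],
    discovery_expr: ExpressionMatrix,
    discovery_clinical: ClinicalTable,
    validation_expr: ExpressionMatrix,
    validation_clinical: ClinicalTable,
    alpha: float = 0.05,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    adjust: Sequence[str] = (),
    universe: Iterable[str] | None = None,
) -> dict[str, ScreenResult]:
    """Two-cohort survival screen per stage group with enrichment testing.

    For each stage group: univariate Cox screen in the discovery cohort,
    validation of the discovery hits in the second cohort (significance +
    sign concordance), and a permutation test of whether the group is
    enriched for genes significant in discovery.  The permutation universe
    defaults to the union of all screened genes.
    """
    rng = np.random.default_rng(rng)
    all_genes = sorted({g for genes in stage_gene_sets.values() for g in genes})
    screenable = [g for g in all_genes if g in discovery_expr.data.index]
    disc_all = cox_screen(discovery_expr, discovery_clinical, genes=screenable, adjust=adjust)
    sig_all = set(disc_all.index[disc_all["p_value"] < alpha])
    uni = sorted(universe) if universe is not None else list(disc_all.index)
    results: dict[str, ScreenResult] = {}
    for stage, genes in stage_gene_sets.items():
        genes_here = [g for g in genes if g in disc_all.index]
        disc = disc_all.loc[genes_here]
        hits = list(disc.index[disc["p_value"] < alpha])
        val = cox_screen(validation_expr, validation_clinical, genes=hits, adjust=adjust) if hits else pd.DataFrame(columns=disc.columns)
        validated = reproducible_screen(disc, val, alpha=alpha) if hits else []
        p_enrich = permutation_group_enrichment(
            genes_here, sig_all & set(uni), uni, n_perm=n_perm, rng=rng
        )
        results[stage] = ScreenResult(
            stage=stage,
            group_genes=genes_here,
            discovery_significant=hits,
            validated=validated,
            enrichment_p=p_enrich,
            discovery=disc,
            validation=val,
        )
    return results
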