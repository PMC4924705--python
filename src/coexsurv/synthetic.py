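"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the study's data sources:

* a developmental time series (default 9 time points) of protein and mRNA
  abundance with planted co-expressed modules peaking in early / middle /
  late blocks of the time axis;
* a STRING-style interaction set enriched within the planted modules;
* proportional-hazards survival cohorts where chosen genes carry log-hazard
  effects, with independent exponential censoring;
* a compound x cell-line log10(IC50) panel with planted gene-drug
  sensitivity effects.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from coexsurv.io import ClinicalTable, ExpressionMatrix, InteractionSet, ValidationError
from coexsurv.network import ModulePartition
from coexsurv.stages import STAGES, default_stage_blocks

__all__ = [
    "DevelopmentSimSpec",
    "SurvivalSimSpec",
    "DrugSimSpec",
    "simulate_development",
    "simulate_ppi",
    "simulate_survival_cohort",
    "simulate_drug_response",
]


# ---------------------------------------------------------------------------
# Developmental time series


@dataclass
class DevelopmentSimSpec:
    """Design of the synthetic protein/mRNA developmental time series.

    ``module_defs`` lists (size, peak_stage, rho) triples: each planted
    module's genes share a stage-peaked template plus independent Gaussian
    noise, giving expected within-module Pearson correlation ``rho``.
    ``mrna_agreement`` in [0, 1] controls how faithfully each gene's mRNA
    profile tracks its protein profile (1 = identical).
    """

    n_genes: int
    module_defs: list[tuple[int, str, float]]
    n_timepoints: int = 9
    background_gene_count: int | None = None
    noise_sd: float = 1.0
    mrna_agreement: float = 0.8
    template_jitter: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(size for size, _, _ in self.module_defs)
        if self.background_gene_count is None:
            self.background_gene_count = self.n_genes - total
        if total + self.background_gene_count != self.n_genes:
            raise ValidationError(
                f"module sizes ({total}) + background ({self.background_gene_count}) "
                f"!= n_genes ({self.n_genes})"
            )
        if self.background_gene_count < 0:
            raise ValidationError("background_gene_count must be >= 0")
        for size, stage, rho in self.module_defs:
            if size < 1:
                raise ValidationError("module size must be >= 1")
            if stage not in STAGES:
                raise ValidationError(f"peak stage must be in {STAGES}, got {stage!r}")
            if not 0 <= rho <= 1:
                raise ValidationError("within-module correlation must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 <= self.mrna_agreement <= 1:
            raise ValidationError("mrna_agreement must be in [0, 1]")


def _stage_template(stage: str, n_timepoints: int) -> np.ndarray:
    """Unit-variance template: high in the stage's block, low elsewhere."""
    blocks = default_stage_blocks(n_timepoints)
    t = np.full(n_timepoints, -0.5)
    t[blocks[STAGES.index(stage)]] = 1.0
    t = t - t.mean()
    return t / t.std()


def _wiggle_basis(n_timepoints: int) -> np.ndarray:
    """Orthonormal directions orthogonal to all stage templates (and constants).

    Every such direction has zero mean within each stage block, so adding it
    to a template leaves the block means — and hence the stage peak —
    exactly unchanged while decorrelating modules from each other.
    """
    base = np.array([_stage_template(s, n_timepoints) for s in STAGES])
    a = np.vstack([np.ones(n_timepoints), base])
    _, _, vt = np.linalg.svd(a)
    return vt[a.shape[0] :]


def _module_template(stage: str, module_index: int, n_timepoints: int, jitter: float) -> np.ndarray:
    """Stage template plus a module-identity wiggle, unit variance.

    The wiggle makes two modules that peak in the same stage statistically
    distinguishable (template correlation 1/(1+jitter^2)) without moving
    the peak.  Wiggle directions cycle through a fixed orthonormal basis,
    negated on the second pass.
    """
    template = _stage_template(stage, n_timepoints)
    if jitter <= 0:
        return template
    basis = _wiggle_basis(n_timepoints)
    k = module_index % len(basis)
    sign = 1.0 if (module_index // len(basis)) % 2 == 0 else -1.0
    w = sign * basis[k] * np.sqrt(n_timepoints)  # unit variance across time
    t = template + jitter * w
    t = t - t.mean()
    return t / t.std()


def simulate_development(
    spec: DevelopmentSimSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ModulePartition]:
    """Protein and mRNA matrices with planted stage-peaked modules.

    Gene profile = amplitude * template + N(0, noise_sd^2) per time point,
    with the amplitude set so the expected within-module correlation equals
    the module's rho (rho = 1 is the noiseless limit).  The mRNA profile
    adds independent noise scaled so corr(protein, mRNA) ~= mrna_agreement.
    """
    rng = np.random.default_rng(spec.seed)
    nt = spec.n_timepoints
    profiles = []
    gene_ids = []
    assignment: dict[str, int] = {}
    stages: dict[int, str] = {}
    for m, (size, stage, rho) in enumerate(spec.module_defs, start=1):
        template = _module_template(stage, m - 1, nt, spec.template_jitter)
        if rho >= 1.0:
            amp, sd = spec.noise_sd, 0.0
        else:
            amp = spec.noise_sd * np.sqrt(rho / (1.0 - rho))
            sd = spec.noise_sd
        for g in range(size):
            gid = f"M{m}_G{g + 1}"
            gene_ids.append(gid)
            assignment[gid] = m
            profiles.append(amp * template + rng.normal(0.0, sd, nt))
        stages[m] = stage
    for g in range(spec.background_gene_count):
        gid = f"BG_G{g + 1}"
        gene_ids.append(gid)
        assignment[gid] = 0
        profiles.append(rng.normal(0.0, spec.noise_sd, nt))
    prot = np.array(profiles)
    cols = [f"T{t + 1}" for t in range(nt)]
    protein = ExpressionMatrix(
        pd.DataFrame(prot, index=gene_ids, columns=cols), axis_kind="timepoints"
    )
    # mRNA layer: protein profile + independent noise sized per gene so that
    # corr(protein, mRNA) ~= mrna_agreement
    if spec.mrna_agreement >= 1.0:
        mrna_vals = prot.copy()
    else:
        gene_sd = prot.std(axis=1, ddof=0)
        gene_sd = np.where(gene_sd == 0, spec.noise_sd, gene_sd)
        a = max(spec.mrna_agreement, 1e-6)
        extra = gene_sd * np.sqrt(1.0 / a**2 - 1.0)
        mrna_vals = prot + rng.normal(0.0, 1.0, prot.shape) * extra[:, None]
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_vals, index=gene_ids, columns=cols), axis_kind="timepoints"
    )
    truth = ModulePartition(assignment, stages=stages)
    return protein, mrna, truth


# ---------------------------------------------------------------------------
# Interaction network


def simulate_ppi(
    truth: ModulePartition,
    p_within: float = 0.3,
    p_between: float = 0.01,
    seed: int | None = None,
    include_background: bool = False,
) -> InteractionSet:
    """Stochastic-block interaction set enriched within planted modules.

    Each within-module pair becomes an edge with probability ``p_within``,
    every other pair (involving assigned genes; background genes only if
    ``include_background``) with ``p_between``.  Scores are drawn above the
    STRING filter thresholds so every simulated edge survives reading.
    """
    if not 0 <= p_between < p_within <= 1:
        raise ValidationError("require 0 <= p_between < p_within <= 1")
    rng = np.random.default_rng(seed)
    genes = (
        sorted(truth.assignment) if include_background else truth.assigned_genes()
    )
    label = {g: truth.assignment[g] for g in genes}
    records = []
    for a, b in combinations(genes, 2):
        same = label[a] == label[b] and label[a] != 0
        p = p_within if same else p_between
        if p > 0 and rng.random() < p:
            records.append(
                (
                    *(sorted((a, b))),
                    int(rng.integers(201, 1000)),
                    int(rng.integers(401, 1000)),
                )
            )
    edges = pd.DataFrame(records, columns=["gene_a", "gene_b", "experimental", "combined"])
    return InteractionSet(edges)


# ---------------------------------------------------------------------------
# Survival cohorts


@dataclass
class SurvivalSimSpec:
    """Proportional-hazards cohort design.

    Event times are exponential with rate ``baseline_rate * exp(linear
    predictor)``; censoring is an independent exponential with rate
    ``censor_rate`` (0 = no censoring).  ``gene_betas`` maps gene ids to
    log-hazard coefficients per unit expression; ``covariate_effects``
    optionally adds age/gender/race terms.
    """

    n_samples: int
    gene_betas: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.01
    censor_rate: float = 0.005
    covariate_effects: dict[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValidationError("censor_rate must be >= 0")


def simulate_survival_cohort(
    spec: SurvivalSimSpec,
    expression: ExpressionMatrix | None = None,
    extra_genes: int = 0,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Patient expression matrix plus (time, event) clinical table.

    If no expression matrix is supplied, gene expression is standard normal
    per patient for the genes named in ``gene_betas`` plus ``extra_genes``
    null genes.  The proportional-hazards structure holds by construction.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"P{i + 1}" for i in range(spec.n_samples)]
    if expression is None:
        genes = sorted(spec.gene_betas) + [f"NULL_G{i + 1}" for i in range(extra_genes)]
        if not genes:
            raise ValidationError("no genes: supply gene_betas, extra_genes or an expression matrix")
        x = rng.standard_normal((len(genes), spec.n_samples))
        expression = ExpressionMatrix(
            pd.DataFrame(x, index=genes, columns=samples), axis_kind="patients"
        )
    else:
        samples = expression.sample_ids
        missing = [g for g in spec.gene_betas if g not in expression.data.index]
        if missing:
            raise ValidationError(f"gene_betas reference absent genes: {missing}")
    lp = np.zeros(len(samples))
    for g, beta in spec.gene_betas.items():
        lp += beta * expression.data.loc[g].to_numpy()
    covariates = {}
    if spec.covariate_effects:
        age = rng.normal(60.0, 10.0, len(samples))
        gender = rng.choice(["female", "male"], len(samples))
        race = rng.choice(["white", "black", "asian"], len(samples))
        covariates = {"age": age, "gender": gender, "race": race}
        effects = spec.covariate_effects
        lp += effects.get("age", 0.0) * (age - age.mean())
        lp += effects.get("gender", 0.0) * (gender == "male")
        lp += effects.get("race", 0.0) * (race != "white")
    rate = spec.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        t_censor = rng.exponential(1.0 / spec.censor_rate, len(samples))
    else:
        t_censor = np.full(len(samples), np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    table = pd.DataFrame({"time": time, "event": event, **covariates}, index=samples)
    return expression, ClinicalTable(table)


# ---------------------------------------------------------------------------
# Drug-response panel


@dataclass
class DrugSimSpec:
    """NCI-60-style drug response design.

    ``planted_pairs`` maps (gene, drug) to an effect size delta: the gene's
    expression is shifted by -delta in cell lines falling in the sensitive
    IC50 tail and +delta in the resistant tail.  ``n_cell_lines`` must be
    >= 25 so the >=10 sensitive / >=10 resistant filter can succeed.
    """

    n_drugs: int
    n_genes: int = 10
    n_cell_lines: int = 60
    planted_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    ic50_noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cell_lines < 25:
            raise ValidationError("n_cell_lines must be >= 25")
        if self.n_drugs < 1 or self.n_genes < 1:
            raise ValidationError("need >= 1 drug and >= 1 gene")
        for (g, d), delta in self.planted_pairs.items():
            if not np.isfinite(delta):
                raise ValidationError(f"non-finite effect for pair ({g}, {d})")


def simulate_drug_response(
    spec: DrugSimSpec,
) -> tuple["DrugResponseMatrix", ExpressionMatrix, dict[tuple[str, str], float]]:
    """Drug response matrix, cell-line expression, and the planted truth.

    log10(IC50) per drug is standard-normal noise across cell lines (times
    ``ic50_noise_sd``).  For planted pairs, the sensitive tail is the set of
    lines below mu - SD of the drug's vector and the resistant tail above
    mu + SD, matching the downstream classification rule.
    """
    from coexsurv.chemo import DrugResponseMatrix

    rng = np.random.default_rng(spec.seed)
    lines = [f"CL{i + 1}" for i in range(spec.n_cell_lines)]
    drugs = [f"D{i + 1}" for i in range(spec.n_drugs)]
    genes = sorted({g for g, _ in spec.planted_pairs} | {f"G{i + 1}" for i in range(spec.n_genes)})
    ic50 = rng.standard_normal((spec.n_drugs, spec.n_cell_lines)) * spec.ic50_noise_sd
    response = pd.DataFrame(ic50, index=drugs, columns=lines)
    expr = pd.DataFrame(
        rng.standard_normal((len(genes), spec.n_cell_lines)), index=genes, columns=lines
    )
    for (gene, drug), delta in spec.planted_pairs.items():
        if drug not in response.index:
            raise ValidationError(f"planted pair references unknown drug {drug!r}")
        v = response.loc[drug]
        mu, sd = v.mean(), v.std(ddof=1)
        expr.loc[gene, v < mu - sd] -= delta
        expr.loc[gene, v > mu + sd] += delta
    return (
        DrugResponseMatrix(response),
        ExpressionMatrix(expr, axis_kind="cell_lines"),
        dict(spec.planted_pairs),
    )
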