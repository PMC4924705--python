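"""End-to-end orchestration of the analysis from a single YAML config.

Stage order mirrors the study workflow: (1) protein-vs-mRNA co-expression
over the interaction network, (2) weighted co-expression module discovery
with the PPI membership filter, (3) module activity scoring and stage
grouping, (4) two-cohort Cox survival screen with permutation group
enrichment, (5) gene-drug chemoresponse association.  Inputs are either
read from files (``inputs:`` section) or generated by the synthetic module
(``simulate:`` section) with planted ground truth.  Every output is a TSV
with a provenance header (package version + config hash); runs are pure
functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import coexsurv
from coexsurv import chemo as chemo_mod
from coexsurv import io as io_mod
from coexsurv import network as net_mod
from coexsurv import ppi_coexpression as ppi_mod
from coexsurv import stages as stages_mod
from coexsurv import survival as surv_mod
from coexsurv import synthetic as sim_mod

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "default_synthetic_config"]


DEFAULT_PARAMS = {
    "power": 10,
    "min_module_size": 5,
    "cut_height": None,
    "n_groups": 3,
    "alpha": 0.05,
    "n_perm": 10000,
    "min_sensitive": 10,
    "min_resistant": 10,
    "adjust": [],
}


def default_synthetic_config(seed: int = 0) -> dict:
    """Bundled synthetic configuration exercising every stage end to end.

    Six planted co-expression modules (two per developmental stage) over a
    9-point time axis; the early-stage module genes carry the planted
    survival effects, so the early group should show the smallest
    enrichment p; a 25-drug panel carries three planted gene-drug effects.
    """
    return {
        "seed": seed,
        "simulate": {
            "development": {
                "n_genes": 260,
                "module_defs": [
                    [45, "early", 0.9],
                    [40, "early", 0.9],
                    [40, "middle", 0.9],
                    [35, "middle", 0.9],
                    [40, "late", 0.9],
                    [30, "late", 0.9],
                ],
                "noise_sd": 1.0,
                "mrna_agreement": 0.6,
            },
            "ppi": {"p_within": 0.35, "p_between": 0.01},
            "survival": {
                "prognostic": {"stage": "early", "n_genes": 12, "beta": 1.0},
                "discovery": {"n_samples": 120, "baseline_rate": 0.01, "censor_rate": 0.003},
                "validation": {"n_samples": 300, "baseline_rate": 0.01, "censor_rate": 0.003},
            },
            "drugs": {
                "n_drugs": 25,
                "n_genes": 30,
                "planted": [["G1", "D1", 3.0], ["G2", "D2", 3.0], ["G3", "D3", 3.0]],
            },
        },
        "params": dict(DEFAULT_PARAMS, n_perm=2000),
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header(config_hash: str) -> str:
    return f"coexsurv {coexsurv.__version__} config={config_hash}"


def _write_df(df: pd.DataFrame, path: Path, config_hash: str, index_label=None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {_header(config_hash)}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index_label=index_label)


def run_pipeline(config: dict, outdir: str | Path) -> dict[str, Any]:
    """Execute the full analysis; returns (and writes) the run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    params = dict(DEFAULT_PARAMS, **config.get("params", {}))
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {"config_hash": chash, "seed": seed, "version": coexsurv.__version__}

    data = _gather_inputs(config, seed)

    # 1. protein vs mRNA co-expression over the interaction network
    stage = "coexpress"
    try:
        ec = ppi_mod.edge_correlations(data["protein"], data["mrna"], data["interactions"])
        cmp_ = ppi_mod.compare_pcc_paired(ec.r_protein, ec.r_mrna)
        _write_df(ec.to_frame(), outdir / "edge_correlations.tsv", chash)
        summary["coexpression"] = {
            "n_edges": cmp_.n_pairs,
            "mean_r_protein": round(cmp_.mean_protein, 6),
            "mean_r_mrna": round(cmp_.mean_mrna, 6),
            "t_statistic": round(cmp_.t_statistic, 6),
            "p_value": float(f"{cmp_.p_value:.6g}"),
        }
        logger.info("coexpress: %d edges, mean r protein %.3f vs mRNA %.3f",
                    cmp_.n_pairs, cmp_.mean_protein, cmp_.mean_mrna)

        # 2. module discovery + PPI filter
        stage = "modules"
        raw_part = net_mod.detect_modules(
            data["protein"],
            power=params["power"],
            min_module_size=params["min_module_size"],
            cut_height=params["cut_height"],
        )
        part = net_mod.filter_modules_by_ppi(raw_part, data["interactions"])
        io_mod.write_modules(part, outdir / "modules.gmt")
        assign_df = pd.DataFrame(
            {"module": pd.Series(part.assignment).sort_index()}
        )
        _write_df(assign_df, outdir / "module_assignment.tsv", chash, index_label="gene")
        summary["modules"] = {
            "n_modules_raw": len(raw_part.labels),
            "n_modules": len(part.labels),
            "sizes": {int(k): int(v) for k, v in sorted(part.module_sizes.items())},
            "n_unassigned": sum(1 for m in part.assignment.values() if m == 0),
        }
        logger.info("modules: %d raw -> %d after PPI filter", len(raw_part.labels), len(part.labels))

        # 3. module activity + stage grouping
        stage = "stages"
        activity = stages_mod.module_activity(data["protein"], part)
        groups = stages_mod.group_modules(activity, n_groups=params["n_groups"])
        _write_df(activity.table, outdir / "module_activity.tsv", chash, index_label="module")
        stage_df = pd.DataFrame(
            {"stage": pd.Series(groups.assignment).sort_index()}
        )
        _write_df(stage_df, outdir / "module_stages.tsv", chash, index_label="module")
        summary["stages"] = {int(m): s for m, s in sorted(groups.assignment.items())}

        # 4. two-cohort survival screen + permutation enrichment
        stage = "survival"
        stage_gene_sets = {
            s: sorted(g for m in groups.modules_in(s) for g in part.members(m))
            for s in stages_mod.STAGES
        }
        stage_gene_sets = {s: gs for s, gs in stage_gene_sets.items() if gs}
        screen = surv_mod.screen_stage_groups(
            stage_gene_sets,
            data["discovery_expr"],
            data["discovery_clinical"],
            data["validation_expr"],
            data["validation_clinical"],
            alpha=params["alpha"],
            n_perm=params["n_perm"],
            rng=np.random.default_rng(seed + 1),
            adjust=tuple(params["adjust"]),
        )
        cox_frames = []
        for s, res in screen.items():
            df = res.discovery.copy()
            df.insert(0, "stage_group", s)
            cox_frames.append(df)
        _write_df(pd.concat(cox_frames), outdir / "cox_discovery.tsv", chash, index_label="gene")
        summary["survival"] = {
            s: {
                "n_genes": len(r.group_genes),
                "n_discovery_significant": len(r.discovery_significant),
                "n_validated": len(r.validated),
                "validated": r.validated,
                "enrichment_p": r.enrichment_p,
            }
            for s, r in screen.items()
        }
        with open(outdir / "validated_genes.txt", "w") as fh:
            fh.write(f"# {_header(chash)}\n")
            for s, r in screen.items():
                for g in r.validated:
                    fh.write(f"{g}\t{s}\n")

        # 5. chemoresponse association
        stage = "chemo"
        normalized = chemo_mod.normalize_response(data["response"])
        labels = chemo_mod.classify_all(normalized)
        kept = chemo_mod.filter_compounds(
            labels, params["min_sensitive"], params["min_resistant"]
        )
        assoc = chemo_mod.gene_drug_association(
            data["cellline_expr"], labels, compounds=kept, alpha=params["alpha"]
        )
        _write_df(labels.counts(), outdir / "compound_labels.tsv", chash, index_label="compound")
        _write_df(assoc, outdir / "gene_drug_association.tsv", chash)
        summary["chemo"] = {
            "n_compounds": len(data["response"].compounds),
            "n_compounds_retained": len(kept),
            "n_tests": int(assoc["p_value"].notna().sum()),
            "n_significant": int(assoc["significant"].sum()),
        }
    except Exception as exc:  # noqa: BLE001 - report the failing stage, keep partials
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "summary.yaml", "w") as fh:
        fh.write(f"# {_header(chash)}\n")
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary


def _gather_inputs(config: dict, seed: int) -> dict[str, Any]:
    """Load all inputs from files or generate them synthetically."""
    if "inputs" in config:
        inp = config["inputs"]
        protein = io_mod.read_expression_matrix(inp["protein"], "timepoints")
        data = {
            "protein": protein,
            "mrna": io_mod.read_expression_matrix(inp["mrna"], "timepoints"),
            "interactions": io_mod.read_interactions(
                inp["interactions"], universe=set(protein.gene_ids)
            ),
            "discovery_expr": io_mod.read_expression_matrix(inp["discovery_expr"], "patients"),
            "discovery_clinical": io_mod.read_clinical_table(inp["discovery_clinical"]),
            "validation_expr": io_mod.read_expression_matrix(inp["validation_expr"], "patients"),
            "validation_clinical": io_mod.read_clinical_table(inp["validation_clinical"]),
            "response": chemo_mod.DrugResponseMatrix(
                pd.read_csv(inp["response"], sep="\t", index_col=0, comment="#")
            ),
            "cellline_expr": io_mod.read_expression_matrix(inp["cellline_expr"], "cell_lines"),
        }
        return data
    sim = config["simulate"]
    dev = sim["development"]
    dev_spec = sim_mod.DevelopmentSimSpec(
        n_genes=dev["n_genes"],
        module_defs=[(int(s), str(st), float(r)) for s, st, r in dev["module_defs"]],
        noise_sd=dev.get("noise_sd", 1.0),
        mrna_agreement=dev.get("mrna_agreement", 0.8),
        n_timepoints=dev.get("n_timepoints", 9),
        seed=seed,
    )
    protein, mrna, truth = sim_mod.simulate_development(dev_spec)
    ppi_cfg = sim.get("ppi", {})
    interactions = sim_mod.simulate_ppi(
        truth,
        p_within=ppi_cfg.get("p_within", 0.35),
        p_between=ppi_cfg.get("p_between", 0.01),
        seed=seed + 10,
    )
    surv_cfg = sim["survival"]
    prog = surv_cfg.get("prognostic", {})
    stage_wanted = prog.get("stage", "early")
    prognostic_genes: list[str] = []
    for m, s in sorted((truth.stages or {}).items()):
        if s == stage_wanted:
            prognostic_genes.extend(truth.members(m))
    prognostic_genes = prognostic_genes[: prog.get("n_genes", 5)]
    betas = {g: float(prog.get("beta", 0.8)) for g in prognostic_genes}
    cohorts = {}
    for i, name in enumerate(("discovery", "validation")):
        ccfg = surv_cfg[name]
        cspec = sim_mod.SurvivalSimSpec(
            n_samples=ccfg["n_samples"],
            gene_betas=betas,
            baseline_rate=ccfg.get("baseline_rate", 0.01),
            censor_rate=ccfg.get("censor_rate", 0.005),
            seed=seed + 20 + i,
        )
        rng = np.random.default_rng(seed + 30 + i)
        samples = [f"{name[:1].upper()}{j + 1}" for j in range(ccfg["n_samples"])]
        expr = io_mod.ExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((len(truth.assigned_genes()), len(samples))),
                index=truth.assigned_genes(),
                columns=samples,
            ),
            axis_kind="patients",
        )
        cohorts[name] = sim_mod.simulate_survival_cohort(cspec, expression=expr)
    drug_cfg = sim.get("drugs", {})
    planted = {
        (str(g), str(d)): float(delta)
        for g, d, delta in drug_cfg.get("planted", [])
    }
    dspec = sim_mod.DrugSimSpec(
        n_drugs=drug_cfg.get("n_drugs", 20),
        n_genes=drug_cfg.get("n_genes", 20),
        n_cell_lines=drug_cfg.get("n_cell_lines", 60),
        planted_pairs=planted,
        seed=seed + 40,
    )
    response, cellline_expr, _ = sim_mod.simulate_drug_response(dspec)
    return {
        "protein": protein,
        "mrna": mrna,
        "interactions": interactions,
        "truth": truth,
        "discovery_expr": cohorts["discovery"][0],
        "discovery_clinical": cohorts["discovery"][1],
        "validation_expr": cohorts["validation"][0],
        "validation_clinical": cohorts["validation"][1],
        "response": response,
        "cellline_expr": cellline_expr,
    }
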