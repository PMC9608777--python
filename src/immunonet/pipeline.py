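"""End-to-end pipeline: simulate -> modules -> preservation -> DE ->
dTFI -> subnetwork/centrality -> deconvolution -> PLS-DA prediction.

The stage order mirrors the analysis workflow the package implements:
co-expression modules are built on the reference cohort, preservation
is assessed against the validation cohort, differential expression and
differential TF involvement are computed within the disease-associated
preserved module, the rule-filtered subnetwork is ranked by Laplacian
centrality, cell proportions are imputed by deconvolution and
median-split, and PLS-DA models of the splits are calibrated on cohort
1 and validated on cohort 2 against negative-control gene lists drawn
from non-preserved modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import deconv as dc
from . import transition as mt
from . import plsda as pls
from . import simulate as sim
from . import subnetwork as sn
from .stats import moderated_t_test
from .io import write_expression, write_truth, write_annotations

logger = logging.getLogger("immunonet")

__all__ = ["Thresholds", "PipelineConfig", "run_pipeline", "write_report", "render_report"]

SCHEMA_VERSION = 1


@dataclass
class Thresholds:
    module_trait_p: float = 0.05
    de_fdr: float = 0.1
    dtfi_fdr: float = 0.1
    zsummary_min: float = 10.0
    mwu_p: float = 0.05
    vip_min: float = 1.0
    roc_p: float = 0.05

    def validate(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    """All stage parameters, thresholds and seeds in one round-trippable object."""

    simulate: dict = field(default_factory=dict)      # CohortSpec overrides
    thresholds: Thresholds = field(default_factory=Thresholds)
    module_min_size: int = 20
    merge_threshold: float = 0.25
    candidate_betas: list = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    preservation_permutations: int = 200
    dtfi_permutations: int = 200
    blend_alpha: float = 0.5
    deconv_method: str = "nnls"
    mixture_noise_sd: float = 0.5
    plsda_components: int = 2
    roc_permutations: int = 2000
    n_negative_control_genes: int = 50
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            tk = {f.name for f in dataclasses.fields(Thresholds)}
            bad = set(d["thresholds"]) - tk
            if bad:
                raise ValueError(f"unknown threshold keys: {sorted(bad)}")
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "simulate" in d and d["simulate"]:
            spec_keys = {f.name for f in dataclasses.fields(sim.CohortSpec)}
            bad = set(d["simulate"]) - spec_keys
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        cfg = cls(**d)
        cfg.thresholds.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def cohort_spec(self) -> sim.CohortSpec:
        over = dict(self.simulate)
        over.setdefault("seed", self.seed)
        spec = sim.CohortSpec(**over)
        if "module_size_range" in over:
            spec.module_size_range = tuple(over["module_size_range"])
        for k in ("dirichlet_alpha_cases", "dirichlet_alpha_controls"):
            setattr(spec, k, tuple(getattr(spec, k)))
        return spec


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage on synthetic data; returns the report dict.

    With ``outdir`` set, stage outputs (expression/phenotype/motif/
    signature/truth/labels/DE/dTFI/subnetwork/proportions tables and
    the JSON + text report) are written as they are produced.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": asdict(th),
        "seed": config.seed,
        "stages": {},
    }

    # ---- simulate ---------------------------------------------------------
    _stage("simulate")
    spec = config.cohort_spec()
    truth = sim.generate_truth(spec)
    coh1, coh2, motif, signature = sim.generate_cohort_pair(spec, truth)
    annotations = sim.generate_annotations(truth, seed=spec.seed)
    tf_list = sorted(truth.tf_motif_targets)
    if out is not None:
        write_expression(coh1.expr, out / "cohort1_expression.tsv")
        write_expression(coh2.expr, out / "cohort2_expression.tsv")
        coh1.phenotype.to_csv(out / "cohort1_phenotype.csv", index=False)
        coh2.phenotype.to_csv(out / "cohort2_phenotype.csv", index=False)
        motif.to_csv(out / "motif_prior.tsv", sep="\t", index=False)
        signature.to_csv(out / "signature.tsv", sep="\t", index_label="gene")
        write_truth(truth, out / "truth.json")
        write_annotations(annotations, out / "annotations.tsv")
    report["stages"]["simulate"] = {
        "n_genes": spec.n_genes,
        "n_tfs": spec.n_tfs,
        "samples_per_cohort": spec.n_cases + spec.n_controls,
    }

    gene_rows = [g for g in coh1.expr.index if g not in set(tf_list)]
    expr1 = coh1.expr.loc[gene_rows]
    expr2 = coh2.expr.loc[gene_rows]
    groups1 = coh1.group_labels
    groups2 = coh2.group_labels

    # ---- co-expression modules -------------------------------------------
    _stage("modules")
    beta, fit_table = cx.pick_soft_threshold(
        expr1, config.candidate_betas, config.r2_target
    )
    network = cx.build_network(expr1, beta)
    modules = cx.detect_modules(
        network, expr1, min_size=config.module_min_size,
        merge_threshold=config.merge_threshold,
    )
    traits = pd.DataFrame(
        {"disease": (groups1 == "case").astype(float)}, index=expr1.columns
    )
    assoc = cx.module_trait_association(modules.eigengenes, traits, alpha=th.module_trait_p)
    if out is not None:
        modules.labels.rename("module").to_csv(out / "module_labels.tsv", sep="\t")
        modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        assoc.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    report["stages"]["modules"] = {
        "beta": int(beta),
        "n_modules": len(modules.modules),
        "sizes": {m: int((modules.labels == m).sum()) for m in modules.modules},
        "grey": int((modules.labels == "grey").sum()),
    }

    # ---- preservation -----------------------------------------------------
    _stage("preserve")
    pres = cx.preservation_zsummary(
        expr1, expr2, modules.labels[modules.labels != "grey"],
        n_permutations=config.preservation_permutations,
        seed=config.seed, beta=beta,
    )
    preserved = pres.preserved(th.zsummary_min)
    if out is not None:
        pres.table.to_csv(out / "preservation.tsv", sep="\t")
    report["stages"]["preserve"] = {
        "z_summary": {m: float(v) for m, v in pres.table["z_summary"].items()},
        "preserved": preserved,
    }

    # disease modules: significant trait association + preserved
    sig_assoc = assoc[(assoc["trait"] == "disease") & assoc["significant"]]
    disease_mods = [m for m in sig_assoc["module"] if m in preserved]
    rho = {m: float(sig_assoc.set_index("module").loc[m, "spearman_rho"]) for m in disease_mods}
    up_mods = [m for m in disease_mods if rho[m] > 0]
    report["stages"]["modules"]["disease_modules"] = {m: rho[m] for m in disease_mods}

    # ---- differential expression -----------------------------------------
    _stage("de")
    de = moderated_t_test(expr1, groups1)
    if out is not None:
        de.table.to_csv(out / "de_cohort1.tsv", sep="\t", index_label="gene")
    report["stages"]["de"] = {
        "n_significant": int((de.table["q"] < th.de_fdr).sum()),
        "prior_df": de.prior_df,
    }

    # ---- dTFI -------------------------------------------------------------
    _stage("dtfi")
    focus = up_mods[0] if up_mods else (disease_mods[0] if disease_mods else modules.modules[0])
    focus_genes = modules.genes_in(focus)
    subset = coh1.expr.loc[focus_genes + tf_list]
    dtfi = mt.dtfi_significance(
        subset, groups1, tf_list, motif,
        n_permutations=config.dtfi_permutations, seed=config.seed,
        fdr_threshold=th.dtfi_fdr, blend_alpha=config.blend_alpha,
    )
    if out is not None:
        dtfi.table.to_csv(out / "dtfi.tsv", sep="\t")
    report["stages"]["dtfi"] = {
        "module": focus,
        "significant_tfs": dtfi.significant(th.dtfi_fdr),
        "top_dtfi": dtfi.top(),
    }

    # ---- subnetwork + centrality ------------------------------------------
    _stage("subnet")
    case_mask = groups1 == "case"
    net_ctrl = mt.infer_state_network(
        subset.loc[:, ~case_mask], tf_list, motif, config.blend_alpha, "baseline"
    )
    net_case = mt.infer_state_network(
        subset.loc[:, case_mask], tf_list, motif, config.blend_alpha, "perturbed"
    )
    graph = sn.build_subnetwork(
        dtfi.table, de.table, net_case.weights, net_ctrl.weights,
        annotations, dtfi_fdr=th.dtfi_fdr, de_fdr=th.de_fdr,
    )
    report["stages"]["subnet"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }
    if graph.number_of_edges() > 0:
        cent = sn.laplacian_centrality(graph)
        regulators = sn.rank_regulators(cent, graph, dtfi_z=dtfi.table["z"])
        if out is not None:
            cent.to_csv(out / "centrality.tsv", sep="\t")
            edges = pd.DataFrame(
                [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
                columns=["tf", "gene", "delta_weight"],
            )
            edges.to_csv(out / "subnetwork_edges.tsv", sep="\t", index=False)
            try:
                import networkx as nx
                nx.write_graphml(graph, out / "subnetwork.graphml")
            except Exception:  # pragma: no cover - graphml is a convenience export
                pass
        report["stages"]["subnet"]["regulators"] = regulators
        top_tf = regulators[0]
        target_genes = sorted(graph.successors(top_tf))
    else:
        regulators, top_tf, target_genes = [], None, []
        report["stages"]["subnet"]["regulators"] = []

    # ---- deconvolution ----------------------------------------------------
    _stage("deconv")
    mixtures = sim.generate_mixtures(
        signature, truth.true_proportions, config.mixture_noise_sd, seed=config.seed
    )
    props = dc.deconvolve(mixtures, signature, method=config.deconv_method)
    pheno = pd.concat([coh1.phenotype, coh2.phenotype]).set_index("sample_id")
    groups_all = pheno.loc[props.fractions.index, "group"].to_numpy()
    cohorts_all = pheno.loc[props.fractions.index, "cohort"].to_numpy()
    comparisons = {}
    splits = {}
    for cohort in (1, 2):
        mask = cohorts_all == cohort
        sub = dc.CellProportions(
            fractions=props.fractions[mask],
            diagnostics=props.diagnostics[mask],
            method=props.method,
        )
        comparisons[cohort] = dc.compare_groups(sub, groups_all[mask])
        splits[cohort] = {
            cell: dc.median_split(sub.fractions[cell])
            for cell in ("CD14_monocyte", "CD4_T")
        }
    if out is not None:
        props.fractions.join(props.diagnostics).to_csv(out / "proportions.csv")
    report["stages"]["deconv"] = {
        "mwu_p": {
            str(c): {cell: float(t.loc[cell, "p"]) for cell in t.index}
            for c, t in comparisons.items()
        },
        "directions": {
            str(c): {cell: int(t.loc[cell, "direction"]) for cell in t.index}
            for c, t in comparisons.items()
        },
    }

    # ---- PLS-DA -----------------------------------------------------------
    _stage("plsda")
    # negative controls: random gene lists from the two least-preserved
    # modules (lowest Z-summary)
    rng = np.random.default_rng(config.seed)
    by_z = pres.table["z_summary"].sort_values().index.tolist()
    neg_lists = {}
    for i, mod in enumerate(by_z[:2]):
        pool = modules.genes_in(mod)
        k = min(config.n_negative_control_genes, len(pool))
        neg_lists[f"control_{i + 1}"] = sorted(
            rng.choice(pool, size=k, replace=False)
        )

    plsda_report = {}
    if target_genes:
        gene_lists = {"signal": target_genes, **neg_lists}
        for cell, positive in (("CD14_monocyte", "high"), ("CD4_T", "high")):
            y1 = splits[1][cell].loc[coh1.phenotype["sample_id"]]
            y2 = splits[2][cell].loc[coh2.phenotype["sample_id"]]
            entry = {}
            scores2 = {}
            for name, genes in gene_lists.items():
                x1 = coh1.expr.loc[genes].T
                x2 = coh2.expr.loc[genes].T
                model = pls.fit_plsda(x1, y1, n_components=config.plsda_components)
                calib = model.calibrate_check(x1, y1)
                s2 = model.decision_scores(x2)
                _, auc = pls.roc_auc(s2.to_numpy(), (y2 == positive).astype(int).to_numpy())
                scores2[name] = s2.to_numpy()
                vips = model.vip_scores()
                entry[name] = {
                    "calibration_pass": calib.passed,
                    "misclassifications": calib.misclassifications,
                    "accuracy": calib.accuracy,
                    "validation_auc": float(auc),
                    "n_vip_selected": int(vips["selected"].sum()),
                }
            ybin = (y2 == positive).astype(int).to_numpy()
            for name in neg_lists:
                vt = pls.venkatraman_test(
                    scores2["signal"], scores2[name], ybin,
                    n_permutations=config.roc_permutations, seed=config.seed,
                )
                entry[name]["venkatraman_p_vs_signal"] = vt["p_value"]
            plsda_report[cell] = entry
    report["stages"]["plsda"] = plsda_report

    if out is not None:
        write_report(report, out)
    return report


def write_report(report: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def render_report(report: dict) -> str:
    """Deterministic human-readable summary of a report dict."""
    s = report["stages"]
    lines = [
        f"immunonet pipeline report (schema v{report['schema_version']}, seed {report['seed']})",
        "",
        f"modules: {s['modules']['n_modules']} detected (beta={s['modules']['beta']}), "
        f"{s['modules']['grey']} grey genes",
        "z_summary: "
        + ", ".join(
            f"{m}={v:.1f}" for m, v in sorted(s["preserve"]["z_summary"].items())
        ),
        f"preserved: {', '.join(s['preserve']['preserved']) or 'none'}",
        f"disease modules: "
        + (
            ", ".join(
                f"{m} (rho={r:+.2f})"
                for m, r in sorted(s["modules"].get("disease_modules", {}).items())
            )
            or "none"
        ),
        f"DE genes at FDR {report['thresholds']['de_fdr']}: {s['de']['n_significant']}",
        f"dTFI ({s['dtfi']['module']}): significant = "
        + (", ".join(s["dtfi"]["significant_tfs"]) or "none")
        + f"; top = {s['dtfi']['top_dtfi']}",
        f"subnetwork: {s['subnet']['n_nodes']} nodes, {s['subnet']['n_edges']} edges; "
        f"regulators: {', '.join(s['subnet'].get('regulators', [])[:5]) or 'none'}",
    ]
    for cohort, tests in sorted(s["deconv"]["mwu_p"].items()):
        lines.append(
            f"deconv cohort {cohort} MWU p: "
            + ", ".join(f"{c}={p:.3g}" for c, p in sorted(tests.items()))
        )
    for cell, entry in sorted(s.get("plsda", {}).items()):
        parts = [f"{name}: AUC={v['validation_auc']:.3f}" for name, v in sorted(entry.items())]
        lines.append(f"plsda [{cell}] " + "; ".join(parts))
    return "\n".join(lines) + "\n"
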