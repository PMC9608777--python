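"""Synthetic two-cohort case-control PBMC data with planted ground truth.

The generator emulates the structure of a reference + validation pair of
case-control expression cohorts profiled on different platforms:

* an additive latent-factor model plants gene co-expression modules,
  a subset disease-associated (group-shifted eigengene) and preserved in
  the second cohort, another subset whose co-expression is scrambled in
  the second cohort (non-preserved negative controls);
* TF transcripts with motif priors; one (or more) planted differential
  TF whose coupling to a block of disease-module targets exists only in
  the case state, so differential targeting is recoverable from
  expression alone;
* cell-type mixtures drawn from a marker-gene signature matrix with
  monocyte-enriched / CD4-depleted cases;
* a gene-wise affine platform distortion applied to cohort 2 only.

Every output is deterministic given the spec's seed, and the planted
truth is exported alongside the data so recovery tests can assert
against it without ever feeding it back into inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "CohortSpec",
    "GroundTruth",
    "ExpressionCohort",
    "generate_truth",
    "generate_cohort_pair",
    "generate_mixtures",
    "generate_signature",
    "generate_annotations",
]

CELL_TYPES = ("CD4_T", "CD8_T", "B_cell", "NK_cell", "CD14_monocyte")

# per-stage independent random streams derived from the spec seed
_STREAM_TRUTH = 1
_STREAM_EXPR = 2
_STREAM_PLATFORM = 3
_STREAM_SIGNATURE = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class CohortSpec:
    """Generator parameters; defaults define the study conditions.

    Counts are per cohort (each cohort has ``n_cases`` + ``n_controls``
    samples).  ``factor_effect`` is the case-minus-control shift of the
    disease-module latent factors in factor-SD units; ``targeting_shift``
    is the case-only coupling strength between the planted differential
    TF and its shifted target block.  Dirichlet concentration vectors
    follow the order of :data:`CELL_TYPES`.
    """

    n_cases: int = 30
    n_controls: int = 30
    n_genes: int = 300
    n_modules: int = 6
    module_size_range: tuple[int, int] = (25, 40)
    factor_effect: float = 3.0
    noise_sd: float = 0.5
    platform_scale_sd: float = 0.15
    platform_offset_sd: float = 0.3
    n_tfs: int = 12
    targeting_shift: float = 1.5
    dirichlet_alpha_cases: tuple[float, ...] = (60.0, 48.0, 40.0, 24.0, 88.0)
    dirichlet_alpha_controls: tuple[float, ...] = (100.0, 48.0, 40.0, 24.0, 48.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_modules", "n_tfs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1 (got {getattr(self, name)})")
        lo, hi = self.module_size_range
        if lo < 3 or hi < lo:
            raise ValueError(
                f"module_size_range must satisfy 3 <= lo <= hi (got {self.module_size_range})"
            )
        if self.n_modules * hi < self.n_modules * lo:
            raise ValueError("module_size_range inverted")
        for name in ("dirichlet_alpha_cases", "dirichlet_alpha_controls"):
            alpha = np.asarray(getattr(self, name), dtype=float)
            if alpha.ndim != 1 or len(alpha) != len(CELL_TYPES):
                raise ValueError(f"{name} must have one entry per cell type")
            if np.any(alpha <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("noise_sd", "platform_scale_sd", "platform_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """Planted structure exported alongside the synthetic data."""

    module_assignment: dict[str, str]
    disease_modules: dict[str, int]          # label -> +1 over / -1 under
    preserved_modules: list[str]
    differential_tfs: list[str]
    de_genes: dict[str, float]               # gene -> planted effect (SD units)
    true_proportions: pd.DataFrame           # sample x cell type fractions
    seed: int
    loadings: dict[str, float] = field(default_factory=dict)
    gene_means: dict[str, float] = field(default_factory=dict)
    tf_motif_targets: dict[str, list[str]] = field(default_factory=dict)
    tf_coupled_targets: dict[str, list[str]] = field(default_factory=dict)
    shifted_targets: dict[str, list[str]] = field(default_factory=dict)
    sample_table: pd.DataFrame | None = None  # sample_id, group, cohort

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_proportions"] = self.true_proportions.to_dict(orient="index")
        d["sample_table"] = (
            self.sample_table.to_dict(orient="records")
            if self.sample_table is not None
            else None
        )
        return d


@dataclass
class ExpressionCohort:
    """Gene x sample log-expression with phenotype labels for one cohort."""

    expr: pd.DataFrame
    phenotype: pd.DataFrame                  # sample_id, group, cohort
    cohort: int
    latent_factors: pd.DataFrame | None = None

    @property
    def group_labels(self) -> np.ndarray:
        return self.phenotype.set_index("sample_id").loc[
            self.expr.columns, "group"
        ].to_numpy()


def _sample_ids(cohort: int, n_cases: int, n_controls: int) -> tuple[list[str], list[str]]:
    ids = [f"c{cohort}_case{i:03d}" for i in range(n_cases)] + [
        f"c{cohort}_ctrl{i:03d}" for i in range(n_controls)
    ]
    groups = ["case"] * n_cases + ["control"] * n_controls
    return ids, groups


def generate_truth(spec: CohortSpec) -> GroundTruth:
    """Draw the planted ground truth (module map, TF targets, proportions)."""
    spec.validate()
    rng = _rng(spec.seed, _STREAM_TRUTH)

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    tfs = [f"TF{i:02d}" for i in range(spec.n_tfs)]
    labels = [f"M{i + 1}" for i in range(spec.n_modules)]

    lo, hi = spec.module_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_modules)
    if sizes.sum() > spec.n_genes:
        raise ValueError(
            f"n_genes={spec.n_genes} too small for module_size_range "
            f"{spec.module_size_range} x n_modules={spec.n_modules}"
        )
    order = rng.permutation(spec.n_genes)
    assignment = {g: "grey" for g in genes}
    pos = 0
    for lab, size in zip(labels, sizes):
        for idx in order[pos : pos + size]:
            assignment[genes[idx]] = lab
        pos += size

    if spec.n_modules >= 2:
        disease = {labels[0]: +1, labels[1]: -1}
    else:
        disease = {labels[0]: +1}
    n_nonpreserved = 2 if spec.n_modules >= 4 else 0
    preserved = labels[: spec.n_modules - n_nonpreserved]

    loadings = {g: float(rng.uniform(0.8, 1.2)) for g in genes}
    gene_means = {g: float(rng.normal(7.0, 1.0)) for g in genes + tfs}

    total_sd = {
        g: float(np.sqrt(loadings[g] ** 2 + spec.noise_sd**2))
        if assignment[g] != "grey"
        else max(spec.noise_sd, 1e-12)
        for g in genes
    }
    de_genes = {
        g: disease[assignment[g]] * loadings[g] * spec.factor_effect / total_sd[g]
        for g in genes
        if assignment[g] in disease
    }

    # Motif priors, baseline couplings, and the planted targeting change.
    # The differential TF acquires, in the case state only, the target
    # blocks that belong to two "donor" TFs at baseline: re-expressing
    # its perturbed targeting profile in terms of baseline profiles then
    # requires those donors' columns, i.e. off-diagonal transition mass.
    diff_tfs = [tfs[0]]
    donors = tfs[1:4] if len(tfs) >= 4 else tfs[1:2]
    plus_module = next(lab for lab, sgn in disease.items() if sgn > 0)
    plus_genes = [g for g in genes if assignment[g] == plus_module]
    motif_targets: dict[str, list[str]] = {}
    coupled: dict[str, list[str]] = {}
    shifted: dict[str, list[str]] = {}
    # motif target sets are stratified across modules (and the grey
    # pool) so every TF has stable prior structure inside any module's
    # gene subset; a TF whose column were pure noise within a module
    # would look maximally unstable there for trivial reasons
    pools = {lab: [g for g in genes if assignment[g] == lab] for lab in labels}
    pools["grey"] = [g for g in genes if assignment[g] == "grey"]
    donor_pool = list(plus_genes)
    rng.shuffle(donor_pool)
    donor_blocks = {}
    block_size = max(4, min(8, len(donor_pool) // max(len(donors), 1)))
    for i, d in enumerate(donors):
        donor_blocks[d] = sorted(donor_pool[i * block_size : (i + 1) * block_size])
    for t in tfs:
        targets = []
        for pool in pools.values():
            if pool:
                k = min(len(pool), max(3, round(0.12 * len(pool))))
                targets.extend(rng.choice(pool, size=k, replace=False))
        targets = sorted(set(targets))
        if t in donors:
            # donor TFs drive disjoint blocks inside the over-expressed
            # disease module; in the case state the differential TF
            # takes those blocks over (source switch, equal strength)
            coupled[t] = donor_blocks[t]
            targets = sorted(set(targets) | set(donor_blocks[t]))
        else:
            coupled[t] = list(
                rng.choice(targets, size=min(8, len(targets)), replace=False)
            )
        motif_targets[t] = targets
    for t in diff_tfs:
        # novel targeting: the gained block is absent from this TF's
        # motif prior, so only the perturbed state's expression evidence
        # carries it
        block = sorted(set(g for d in donors for g in coupled[d]))
        shifted[t] = block
        motif_targets[t] = sorted(set(motif_targets[t]) - set(block))

    # per-sample cell-type fractions for both cohorts
    rows, idx = [], []
    for cohort in (1, 2):
        ids, groups = _sample_ids(cohort, spec.n_cases, spec.n_controls)
        for sid, grp in zip(ids, groups):
            alpha = (
                spec.dirichlet_alpha_cases
                if grp == "case"
                else spec.dirichlet_alpha_controls
            )
            rows.append(rng.dirichlet(alpha))
            idx.append(sid)
    props = pd.DataFrame(rows, index=idx, columns=list(CELL_TYPES))

    sample_table = pd.DataFrame(
        [
            {"sample_id": sid, "group": grp, "cohort": cohort}
            for cohort in (1, 2)
            for sid, grp in zip(*_sample_ids(cohort, spec.n_cases, spec.n_controls))
        ]
    )

    return GroundTruth(
        module_assignment=assignment,
        disease_modules=disease,
        preserved_modules=preserved,
        differential_tfs=diff_tfs,
        de_genes=de_genes,
        true_proportions=props,
        seed=spec.seed,
        loadings=loadings,
        gene_means=gene_means,
        tf_motif_targets=motif_targets,
        tf_coupled_targets=coupled,
        shifted_targets=shifted,
        sample_table=sample_table,
    )


def _check_consistency(spec: CohortSpec, truth: GroundTruth) -> None:
    if len([g for g in truth.module_assignment if not g.startswith("TF")]) != spec.n_genes:
        raise ValueError("truth/spec mismatch: gene count differs")
    if len(truth.tf_motif_targets) != spec.n_tfs:
        raise ValueError("truth/spec mismatch: TF count differs")
    if truth.seed != spec.seed:
        raise ValueError("truth/spec mismatch: seed differs")


def generate_cohort_pair(
    spec: CohortSpec, truth: GroundTruth
) -> tuple[ExpressionCohort, ExpressionCohort, pd.DataFrame, pd.DataFrame]:
    """Simulate both cohorts plus the motif prior and signature matrix.

    Returns ``(cohort1, cohort2, motif_prior, signature)``.  Cohort 1 is
    platform-undistorted; cohort 2 receives a gene-wise affine
    scale/offset.  Non-preserved-module genes are re-assigned to random
    factors in cohort 2, destroying their cohort-1 co-expression.
    """
    spec.validate()
    _check_consistency(spec, truth)
    rng = _rng(spec.seed, _STREAM_EXPR)
    rng_platform = _rng(spec.seed, _STREAM_PLATFORM)

    genes = sorted(g for g in truth.module_assignment)
    tfs = sorted(truth.tf_motif_targets)
    labels = sorted({m for m in truth.module_assignment.values() if m != "grey"})
    coupling_kappa = 0.5

    nonpreserved = [m for m in labels if m not in truth.preserved_modules]
    cohorts = []
    for cohort in (1, 2):
        ids, groups = _sample_ids(cohort, spec.n_cases, spec.n_controls)
        n = len(ids)
        case_mask = np.array([g == "case" for g in groups])

        # fresh cohort-2-only factors host the scrambled genes of
        # non-preserved modules (no disease shift: their cohort-1
        # co-expression and disease association simply do not replicate)
        fresh = [f"S{i + 1}" for i in range(len(labels))] if cohort == 2 else []
        factors = pd.DataFrame(
            rng.standard_normal((len(labels) + len(fresh), n)),
            index=labels + fresh,
            columns=ids,
        )
        for lab, sign in truth.disease_modules.items():
            factors.loc[lab, case_mask] += sign * spec.factor_effect

        tf_activity = pd.DataFrame(
            rng.standard_normal((len(tfs), n)), index=tfs, columns=ids
        )

        assignment = dict(truth.module_assignment)
        scramble_rng = _rng(spec.seed, 10 + cohort)
        if cohort == 2 and nonpreserved:
            for g in genes:
                if assignment[g] in nonpreserved:
                    assignment[g] = str(scramble_rng.choice(fresh))

        x = np.empty((len(genes), n))
        for i, g in enumerate(genes):
            lab = assignment[g]
            lam = truth.loadings[g]
            if cohort == 2 and truth.module_assignment[g] in nonpreserved:
                lam = float(scramble_rng.uniform(0.8, 1.2))
            base = truth.gene_means[g]
            if lab == "grey":
                row = base + spec.noise_sd * rng.standard_normal(n)
            else:
                row = (
                    base
                    + lam * factors.loc[lab].to_numpy()
                    + spec.noise_sd * rng.standard_normal(n)
                )
            x[i] = row
        expr = pd.DataFrame(x, index=genes, columns=ids)

        # TF->target couplings.  Ordinary TFs couple to their targets in
        # both states.  Donor TFs drive their disease-module blocks in
        # the control state only; in the case state the differential TF
        # drives those same blocks at equal strength (a source switch:
        # correlation moves between TFs, total variance is state-
        # balanced).
        donor_genes = {
            g for t in truth.differential_tfs for g in truth.shifted_targets.get(t, [])
        }
        donors = [
            t
            for t in tfs
            if t not in truth.differential_tfs
            and set(truth.tf_coupled_targets.get(t, [])) <= donor_genes
            and truth.tf_coupled_targets.get(t)
        ]
        for t in tfs:
            act = tf_activity.loc[t].to_numpy()
            if t in truth.differential_tfs:
                for g in truth.shifted_targets.get(t, []):
                    expr.loc[g, case_mask] += spec.targeting_shift * act[case_mask]
            elif t in donors:
                for g in truth.tf_coupled_targets[t]:
                    expr.loc[g, ~case_mask] += spec.targeting_shift * act[~case_mask]
            else:
                for g in truth.tf_coupled_targets.get(t, []):
                    expr.loc[g] += coupling_kappa * act

        tf_expr = tf_activity.add(
            pd.Series({t: truth.gene_means[t] for t in tfs}), axis=0
        )
        expr = pd.concat([expr, tf_expr])

        if cohort == 2:
            scale = 1.0 + spec.platform_scale_sd * rng_platform.standard_normal(
                len(expr)
            )
            scale = np.clip(scale, 0.2, None)
            offset = spec.platform_offset_sd * rng_platform.standard_normal(len(expr))
            expr = expr.mul(scale, axis=0).add(offset, axis=0)

        phenotype = pd.DataFrame(
            {"sample_id": ids, "group": groups, "cohort": cohort}
        )
        cohorts.append(
            ExpressionCohort(
                expr=expr, phenotype=phenotype, cohort=cohort, latent_factors=factors
            )
        )

    motif_rows = [
        {"tf": t, "gene": g, "weight": 1}
        for t in tfs
        for g in sorted(truth.tf_motif_targets[t])
    ]
    motif_prior = pd.DataFrame(motif_rows)
    signature = generate_signature(seed=spec.seed)
    return cohorts[0], cohorts[1], motif_prior, signature


def generate_signature(
    n_markers_per_type: int = 12, seed: int = 0
) -> pd.DataFrame:
    """Marker-gene x cell-type reference signature (nonnegative).

    Each cell type gets ``n_markers_per_type`` distinguishing markers
    with high expression in that type and low background elsewhere.
    """
    rng = _rng(seed, _STREAM_SIGNATURE)
    rows, idx = [], []
    for c, cell in enumerate(CELL_TYPES):
        for j in range(n_markers_per_type):
            base = rng.uniform(0.2, 1.5, size=len(CELL_TYPES))
            base[c] = rng.uniform(8.0, 14.0)
            rows.append(base)
            idx.append(f"MK_{cell}_{j:02d}")
    return pd.DataFrame(rows, index=idx, columns=list(CELL_TYPES))


_FATE_PROCESSES = (
    "apoptotic process", "cell death", "cell cycle arrest",
    "regulation of cell proliferation", "autophagy", "cell differentiation",
    "phagocytosis, engulfment", "cell division",
)
_OTHER_PROCESSES = (
    "RNA metabolic process", "transmembrane transport", "signal transduction",
    "lipid biosynthetic process", "protein folding", "chromatin organization",
)


def generate_annotations(
    truth: GroundTruth, seed: int = 0, fate_fraction: float = 0.85
) -> dict[str, list[str]]:
    """Gene -> process-name annotations for subnetwork keyword filtering.

    Most disease-module genes get a cell-fate process (apoptosis, cell
    cycle, proliferation, ...); every gene also gets one generic
    process, and a small fraction of background genes carry a fate
    annotation too, so the keyword filter is exercised both ways.
    """
    rng = _rng(seed, 5)
    out: dict[str, list[str]] = {}
    disease = set(truth.disease_modules)
    for g in sorted(truth.module_assignment):
        procs = [str(rng.choice(_OTHER_PROCESSES))]
        in_disease = truth.module_assignment[g] in disease
        if (in_disease and rng.random() < fate_fraction) or (
            not in_disease and rng.random() < 0.05
        ):
            procs.append(str(rng.choice(_FATE_PROCESSES)))
        out[g] = procs
    return out


def generate_mixtures(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk marker-gene expression: signature @ proportions.T + noise, clipped at 0."""
    if list(signature.columns) != list(proportions.columns):
        raise ValueError("signature columns must match proportion cell types")
    p = proportions.to_numpy(dtype=float)
    if np.any(p < 0):
        raise ValueError("negative cell fractions")
    rng = _rng(seed, 99)
    mix = signature.to_numpy() @ p.T
    if noise_sd > 0:
        mix = mix + noise_sd * rng.standard_normal(mix.shape)
    mix = np.clip(mix, 0.0, None)
    return pd.DataFrame(mix, index=signature.index, columns=proportions.index)
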