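"""End-to-end orchestration: simulate/ingest -> discover -> signature ->
train -> predict -> survival -> associate, driven by a flat config.

Every run writes its artifacts plus a JSON manifest (inputs, parameters,
package version, SHA-256 of each output) sufficient to re-execute it; the
same config and seed reproduce byte-identical outputs (numeric formatting is
fixed at 6 decimals). A stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, bccp, discovery, io, signature, survival, synthetic
from .io import PIPELINE_VERSION

log = logging.getLogger("lnc6")


@dataclass
class PipelineConfig:
    """Flat parameter set for every stage, loadable from a YAML mapping."""

    seed: int = 0
    out_dir: str = "lnc6_run"
    # optional ingest paths; when None the synthetic generator is used
    lnc_expression: str | None = None
    mrna_expression: str | None = None
    # cohort
    n_samples: int = 300
    n_lnc_genes: int = 4000
    n_mrna_genes: int = 4000
    k_subtypes: int = 6
    subtype_proportions: list[float] | None = None
    n_marker_genes_per_subtype: int = 500
    effect_size: float = 4.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 1.0
    # survival generation
    baseline_hazard_per_subtype: list[float] = field(
        default_factory=lambda: [0.05, 0.03, 0.01, 0.03, 0.01, 0.06]
    )
    treatment_hazard_ratio_per_subtype: list[float] = field(
        default_factory=lambda: [1.0, 0.4, 1.0, 1.0, 1.0, 1.0]
    )
    censoring_rate: float = 0.01
    max_followup: float = 120.0
    # discovery
    distance: str = "correlation"
    linkage: str = "ward"
    n_top: int = 1000
    # signature
    p_threshold: float = 0.001
    max_genes: int = 200
    # bccp
    prior_in: float = 0.5
    # survival analysis
    endpoint: str = "OS"
    adjust: str = "BH"
    # association
    alpha: float = 0.05
    n_permutations: int = 1000
    n_cell_lines: int = 40
    n_drugs: int = 20
    coupled_drug_indices: list[int] = field(default_factory=lambda: [1, 2, 3])
    coupling_slope: float = -6.0
    auc_noise_sd: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def validate_config(config: PipelineConfig) -> list[str]:
    """Range/consistency checks; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    c = config
    for name in ("n_samples", "n_lnc_genes", "n_mrna_genes", "k_subtypes",
                 "n_marker_genes_per_subtype", "n_top", "max_genes",
                 "n_cell_lines", "n_drugs", "n_permutations"):
        if getattr(c, name) <= 0:
            problems.append(f"{name} must be positive")
    if c.noise_sd <= 0:
        problems.append("noise_sd must be > 0")
    if c.batch_shift_sd < 0:
        problems.append("batch_shift_sd must be >= 0")
    if c.subtype_proportions is not None:
        props = np.asarray(c.subtype_proportions, dtype=float)
        if len(props) != c.k_subtypes:
            problems.append(
                f"subtype_proportions has length {len(props)}, expected k_subtypes={c.k_subtypes}"
            )
        elif abs(props.sum() - 1.0) > 1e-9:
            problems.append(f"subtype_proportions sum to {props.sum():.6f}, not 1")
    for name in ("baseline_hazard_per_subtype", "treatment_hazard_ratio_per_subtype"):
        vec = getattr(c, name)
        if len(vec) != c.k_subtypes:
            problems.append(f"{name} has length {len(vec)}, expected k_subtypes={c.k_subtypes}")
        if any(v <= 0 for v in vec):
            problems.append(f"{name} entries must be > 0")
    if c.censoring_rate < 0:
        problems.append("censoring_rate must be >= 0")
    if c.max_followup <= 0:
        problems.append("max_followup must be > 0")
    if c.distance not in discovery.DISTANCES:
        problems.append(f"distance must be one of {discovery.DISTANCES}")
    if c.linkage not in discovery.LINKAGES:
        problems.append(f"linkage must be one of {discovery.LINKAGES}")
    if not 0 < c.p_threshold <= 1:
        problems.append("p_threshold must be in (0, 1]")
    if not 0 < c.prior_in < 1:
        problems.append("prior_in must be in (0, 1)")
    if not 0 < c.alpha < 1:
        problems.append("alpha must be in (0, 1)")
    if c.endpoint not in ("OS", "RFS"):
        problems.append("endpoint must be OS or RFS")
    if c.adjust not in ("BH", "bonferroni"):
        problems.append("adjust must be BH or bonferroni")
    if any(not 1 <= i <= c.n_drugs for i in c.coupled_drug_indices):
        problems.append("coupled_drug_indices out of 1..n_drugs")
    if c.n_marker_genes_per_subtype * c.k_subtypes > min(c.n_lnc_genes, c.n_mrna_genes):
        problems.append("marker genes exceed the size of a feature space")
    for name in ("lnc_expression", "mrna_expression"):
        path = getattr(c, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name} path does not exist: {path}")
    if (c.lnc_expression is None) != (c.mrna_expression is None):
        problems.append("provide both expression paths or neither")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager logging stage timing and renaming partial outputs."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
            return False
        raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage on a synthetic (or ingested) cohort.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    seed = config.seed

    with _Stage("simulate"):
        if config.lnc_expression is not None:
            lnc = io.read_expression(config.lnc_expression, "lncRNA", "ingested")
            mrna = io.read_expression(config.mrna_expression, "mRNA", "ingested")
            true_labels = None
        else:
            cohort_cfg = synthetic.CohortConfig(
                n_samples=config.n_samples,
                n_lnc_genes=config.n_lnc_genes,
                n_mrna_genes=config.n_mrna_genes,
                k_subtypes=config.k_subtypes,
                subtype_proportions=config.subtype_proportions,
                n_marker_genes_per_subtype=config.n_marker_genes_per_subtype,
                effect_size=config.effect_size,
                noise_sd=config.noise_sd,
                batch_shift_sd=config.batch_shift_sd,
                seed=seed,
            )
            lnc, mrna, true_labels = synthetic.generate_training_cohort(cohort_cfg)
        io.write_expression(lnc, out / "lnc_train.tsv")
        io.write_expression(mrna, out / "mrna_train.tsv")
        outputs["lnc_train"] = out / "lnc_train.tsv"
        outputs["mrna_train"] = out / "mrna_train.tsv"

    with _Stage("discover"):
        # median-center genes so baselines do not drive sample correlations
        lnc_centered = io.median_center_genes(lnc)
        genes = discovery.select_variable_genes(lnc_centered, min(config.n_top, lnc.n_genes))
        clustering = discovery.hierarchical_cluster(
            lnc_centered, genes, k=config.k_subtypes,
            distance=config.distance, linkage=config.linkage,
        )
        labels = clustering.labels
        label_frame = pd.DataFrame({"sample_id": lnc.sample_ids, "label": labels})
        if true_labels is not None:
            label_frame["true_label"] = true_labels
        io.write_annotations(label_frame, out / "labels.csv", "stage=discover")
        outputs["labels"] = out / "labels.csv"

    with _Stage("signature"):
        signatures = signature.build_all_signatures(
            mrna, labels, p_threshold=config.p_threshold, max_genes=config.max_genes
        )
        io.write_signatures_gmt(signatures, out / "signatures.gmt")
        io.write_signature_stats(signatures, out / "signature_stats.csv")
        outputs["signatures"] = out / "signatures.gmt"
        outputs["signature_stats"] = out / "signature_stats.csv"

    with _Stage("train"):
        mrna_z = io.zscore_genes(mrna)
        models = bccp.train_multiclass(mrna_z, labels, signatures, priors=config.prior_in)
        bccp.models_to_json(models, out / "model.json")
        outputs["model"] = out / "model.json"

    with _Stage("predict"):
        test = synthetic.apply_batch_shift(mrna, config.batch_shift_sd, seed + 1)
        test_z = io.zscore_genes(test)
        assignments = bccp.predict(models, test_z)
        assign_frame = bccp.assignments_to_frame(assignments)
        with open(out / "assignments.csv", "w") as fh:
            fh.write(f"# lnc6 v{PIPELINE_VERSION} assignments cohort=test\n")
            assign_frame.to_csv(fh, index=False, float_format="%.6f")
        outputs["assignments"] = out / "assignments.csv"

    with _Stage("survival"):
        surv_labels = true_labels if true_labels is not None else labels
        arms = synthetic.generate_arms(len(surv_labels), seed + 2)
        surv_cfg = synthetic.SurvivalConfig(
            baseline_hazard_per_subtype=config.baseline_hazard_per_subtype,
            treatment_hazard_ratio_per_subtype=config.treatment_hazard_ratio_per_subtype,
            censoring_rate=config.censoring_rate,
            max_followup=config.max_followup,
        )
        surv_frame = synthetic.generate_survival(
            surv_labels, arms, surv_cfg, seed + 3,
            sample_ids=lnc.sample_ids, endpoint=config.endpoint,
        )
        io.write_annotations(surv_frame, out / "survival.csv", f"endpoint={config.endpoint}")
        outputs["survival"] = out / "survival.csv"
        records = survival.records_from_frame(surv_frame, endpoint=config.endpoint)
        assigned = {a.sample_id: a.hard_label for a in assignments}
        by_subtype = {
            s: [r for r in records if assigned.get(r.sample_id) == s]
            for s in range(1, config.k_subtypes + 1)
        }
        groups = {s: recs for s, recs in by_subtype.items() if recs}
        stat, df, p_global = survival.logrank_global(list(groups.values()))
        pairwise = survival.pairwise_logrank(groups, adjust=config.adjust)
        benefit_rows = []
        for s in sorted(groups):
            try:
                _, _, (b_stat, _, b_p) = survival.treatment_benefit(records, assigned, s)
                benefit_rows.append({"subtype": s, "chi_square": b_stat, "p": b_p})
            except ValueError:
                benefit_rows.append({"subtype": s, "chi_square": np.nan, "p": np.nan})
        with open(out / "survival_tests.csv", "w") as fh:
            fh.write(f"# lnc6 v{PIPELINE_VERSION} global chi2={stat:.6f} df={df} p={p_global:.6g}\n")
            pairwise.to_csv(fh, index=False, float_format="%.6f")
        with open(out / "treatment_benefit.csv", "w") as fh:
            fh.write(f"# lnc6 v{PIPELINE_VERSION} within-subtype arm comparison\n")
            pd.DataFrame(benefit_rows).to_csv(fh, index=False, float_format="%.6f")
        outputs["survival_tests"] = out / "survival_tests.csv"
        outputs["treatment_benefit"] = out / "treatment_benefit.csv"

    with _Stage("associate"):
        # cross-tabulation of predicted vs generating (or discovered) labels
        alt = dict(zip(lnc.sample_ids, (true_labels if true_labels is not None else labels)))
        table = association.cross_tabulate(assigned, alt)
        with open(out / "crosstab.csv", "w") as fh:
            fh.write(f"# lnc6 v{PIPELINE_VERSION} predicted (rows) vs generating (cols)\n")
            table.to_frame().to_csv(fh)
        outputs["crosstab"] = out / "crosstab.csv"

        # drug screen: lncRNA-space model scores a synthetic cell-line panel,
        # its last-subtype probability drives two independent drug panels
        lnc_sigs = signature.build_all_signatures(
            lnc, labels, p_threshold=config.p_threshold, max_genes=config.max_genes
        )
        lnc_models = bccp.train_multiclass(
            io.zscore_genes(lnc), labels, lnc_sigs, priors=config.prior_in
        )
        if true_labels is not None:
            line_cfg = dataclasses.replace(cohort_cfg, n_samples=config.n_cell_lines,
                                           seed=seed + 4)
            line_lnc, _, _ = synthetic.generate_training_cohort(line_cfg)
            target_model = [lnc_models[-1]]
            line_probs_arr = [
                a.probabilities[0] for a in bccp.predict(target_model, io.zscore_genes(line_lnc))
            ]
            line_probs = dict(zip(line_lnc.sample_ids, map(float, line_probs_arr)))
            panel_cfg = synthetic.DrugPanelConfig(
                n_cell_lines=config.n_cell_lines,
                n_drugs=config.n_drugs,
                coupled_drug_indices=tuple(config.coupled_drug_indices),
                coupling_slope=config.coupling_slope,
                auc_noise_sd=config.auc_noise_sd,
            )
            prob_vec = np.array([line_probs[s] for s in line_lnc.sample_ids])
            screens = []
            for tag, pseed in (("panelA", seed + 5), ("panelB", seed + 6)):
                panel = synthetic.generate_drug_panel(prob_vec, panel_cfg, pseed)
                panel.columns = line_lnc.sample_ids
                screens.append(
                    association.spearman_screen(line_probs, panel, config.alpha, tag)
                )
            hits = association.concordant_hits(screens, alpha=config.alpha, sign="negative")
            with open(out / "drug_screen.csv", "w") as fh:
                fh.write(
                    f"# lnc6 v{PIPELINE_VERSION} concordant_negative_hits={';'.join(hits)}\n"
                )
                association.drug_screen_frame(screens).to_csv(
                    fh, index=False, float_format="%.6f"
                )
            outputs["drug_screen"] = out / "drug_screen.csv"

        # GSEA: lncRNAs up-regulated in the best-prognosis subtype, against a
        # responder-vs-non-responder ranking (responders ~ that subtype)
        resp_subtype = min(config.k_subtypes, 5)
        responders = (labels == resp_subtype).astype(int) + 1  # 1 = non, 2 = resp
        stats = signature.ovr_t_test(lnc, responders, 2)
        ranking = {g.gene_id: g.t_statistic for g in stats}
        gene_set = lnc_sigs[resp_subtype - 1].gene_ids()
        if gene_set:
            gsea = association.preranked_gsea(
                ranking, gene_set, weight=1.0,
                n_permutations=config.n_permutations, seed=seed + 7,
                set_name=f"subtype_{resp_subtype}_up_lncRNA",
            )
            pd.DataFrame([dataclasses.asdict(gsea)]).to_csv(
                out / "gsea.csv", index=False, float_format="%.6f"
            )
            outputs["gsea"] = out / "gsea.csv"

    manifest = {
        "version": PIPELINE_VERSION,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
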