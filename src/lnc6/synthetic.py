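"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generators emulate a multi-cohort tumor-subtyping study: a training
cohort with K latent expression subtypes visible in two feature spaces
(lncRNA and mRNA), test cohorts measured on other platforms (modeled as
per-gene additive batch shifts), censored survival with subtype-specific
hazards and a within-subtype treatment effect, and a cell-line drug panel
whose dose-response AUC is linearly coupled to one subtype's membership
probability.

Modeling choices, in brief: expression noise is Gaussian on the log2 scale
(the pipeline consumes normalized log-scale matrices only — no count-level
simulation); each subtype's markers are up-regulated by a constant shift in
that subtype, marker sets disjoint across subtypes; event and censoring
times are independent exponentials truncated at an administrative follow-up
horizon; the treatment arm is Bernoulli(0.5) independent of subtype, so
roughly half of each subtype is treated. All randomness flows through
explicit integer seeds — no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

_DEFAULT_K = 6


@dataclass
class CohortConfig:
    """Parameters of the synthetic expression cohort.

    ``effect_size`` is the log2-units mean up-shift of a subtype's marker
    genes within that subtype; ``noise_sd`` the within-subtype per-gene SD
    (log2 units). Defaults give 6 balanced subtypes of 300 tumors with 500
    disjoint markers per subtype in each feature space and a 4-sigma marker
    effect.
    """

    n_samples: int = 300
    n_lnc_genes: int = 4000
    n_mrna_genes: int = 4000
    k_subtypes: int = _DEFAULT_K
    subtype_proportions: np.ndarray | None = None
    n_marker_genes_per_subtype: int = 500
    effect_size: float = 4.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_proportions is None:
            self.subtype_proportions = np.full(self.k_subtypes, 1.0 / self.k_subtypes)
        self.subtype_proportions = np.asarray(self.subtype_proportions, dtype=float)
        for name in ("n_samples", "n_lnc_genes", "n_mrna_genes", "k_subtypes",
                     "n_marker_genes_per_subtype"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if len(self.subtype_proportions) != self.k_subtypes:
            raise ValueError("subtype_proportions length must equal k_subtypes")
        if abs(self.subtype_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        needed = self.n_marker_genes_per_subtype * self.k_subtypes
        if needed > self.n_lnc_genes or needed > self.n_mrna_genes:
            raise ValueError(
                f"{needed} marker genes required but feature spaces have "
                f"{self.n_lnc_genes} / {self.n_mrna_genes} genes"
            )


@dataclass
class SurvivalConfig:
    """Exponential event/censoring model, hazards in events per month."""

    baseline_hazard_per_subtype: np.ndarray = field(
        default_factory=lambda: np.array([0.05, 0.03, 0.01, 0.03, 0.01, 0.06])
    )
    treatment_hazard_ratio_per_subtype: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.4, 1.0, 1.0, 1.0, 1.0])
    )
    censoring_rate: float = 0.01
    max_followup: float = 120.0

    def __post_init__(self) -> None:
        self.baseline_hazard_per_subtype = np.asarray(
            self.baseline_hazard_per_subtype, dtype=float
        )
        self.treatment_hazard_ratio_per_subtype = np.asarray(
            self.treatment_hazard_ratio_per_subtype, dtype=float
        )
        if (self.baseline_hazard_per_subtype <= 0).any():
            raise ValueError("baseline hazards must be > 0")
        if (self.treatment_hazard_ratio_per_subtype <= 0).any():
            raise ValueError("treatment hazard ratios must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")


@dataclass
class DrugPanelConfig:
    """Cell-line drug panel; coupled drugs get AUC declining in probability."""

    n_cell_lines: int = 40
    n_drugs: int = 20
    coupled_drug_indices: tuple[int, ...] = (1, 2, 3)  # 1-based drug indices
    coupling_slope: float = -6.0
    auc_noise_sd: float = 1.0
    auc_intercept: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0 or self.n_drugs <= 0:
            raise ValueError("panel dimensions must be positive")
        bad = [i for i in self.coupled_drug_indices if not 1 <= i <= self.n_drugs]
        if bad:
            raise ValueError(f"coupled drug indices out of range: {bad}")
        if self.auc_noise_sd < 0:
            raise ValueError("auc_noise_sd must be >= 0")


def marker_genes(config: CohortConfig, feature_space: str) -> dict[int, list[str]]:
    """Planted marker gene IDs per subtype (ground truth for oracle checks)."""
    prefix = "LNC" if feature_space == "lncRNA" else "MRNA"
    m = config.n_marker_genes_per_subtype
    return {
        s: [f"{prefix}{(s - 1) * m + i:05d}" for i in range(m)]
        for s in range(1, config.k_subtypes + 1)
    }


def _generate_space(
    config: CohortConfig,
    labels: np.ndarray,
    n_genes: int,
    prefix: str,
    feature_space: str,
    rng: np.random.Generator,
    sample_ids: list[str],
) -> ExpressionMatrix:
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, config.n_samples)
    )
    m = config.n_marker_genes_per_subtype
    for s in range(1, config.k_subtypes + 1):
        rows = slice((s - 1) * m, s * m)
        values[rows, labels == s] += config.effect_size
    gene_ids = [f"{prefix}{i:05d}" for i in range(n_genes)]
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        feature_space=feature_space,
        cohort_tag="synthetic-train",
    )


def generate_training_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, np.ndarray]:
    """Draw a training cohort: paired lncRNA and mRNA matrices + true labels.

    Both matrices share sample IDs and subtype structure; the returned
    labels (1..K) are ground truth for oracle use only — the pipeline itself
    re-derives labels by clustering.
    """
    rng = np.random.default_rng(config.seed)
    labels = (
        rng.choice(config.k_subtypes, size=config.n_samples, p=config.subtype_proportions)
        + 1
    )
    sample_ids = [f"S{j:04d}" for j in range(config.n_samples)]
    lnc = _generate_space(
        config, labels, config.n_lnc_genes, "LNC", "lncRNA", rng, sample_ids
    )
    mrna = _generate_space(
        config, labels, config.n_mrna_genes, "MRNA", "mRNA", rng, sample_ids
    )
    return lnc, mrna, labels


def apply_batch_shift(
    matrix: ExpressionMatrix, batch_shift_sd: float, seed: int
) -> ExpressionMatrix:
    """Platform/batch effect: one N(0, sd^2) additive offset per gene.

    The offset is shared by all samples of the cohort, emulating a test
    cohort measured on a different platform. IDs are preserved;
    ``batch_shift_sd=0`` returns values identical to the input.
    """
    if batch_shift_sd < 0:
        raise ValueError("batch_shift_sd must be >= 0")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, batch_shift_sd, size=matrix.n_genes) if batch_shift_sd > 0 \
        else np.zeros(matrix.n_genes)
    return replace(
        matrix,
        values=matrix.values + offsets[:, None],
        cohort_tag=f"{matrix.cohort_tag}+batch",
    )


def generate_arms(n_samples: int, seed: int) -> np.ndarray:
    """Treatment arm per sample: Bernoulli(0.5), independent of subtype."""
    rng = np.random.default_rng(seed)
    return np.where(rng.random(n_samples) < 0.5, "treated", "untreated")


def generate_survival(
    labels: np.ndarray,
    arms: np.ndarray,
    config: SurvivalConfig,
    seed: int,
    sample_ids: list[str] | None = None,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Censored survival records for one endpoint.

    Event times are exponential with rate
    ``baseline_hazard[label] * (treatment_hazard_ratio[label] if treated)``;
    censoring is an independent exponential at ``censoring_rate``, truncated
    at ``max_followup`` months. Returns a DataFrame with columns
    ``sample_id, label, arm, time, event, endpoint``.
    """
    labels = np.asarray(labels)
    arms = np.asarray(arms)
    if labels.shape != arms.shape:
        raise ValueError("labels and arms must align")
    k = len(config.baseline_hazard_per_subtype)
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(
            f"label outside 1..{k}: labels must index the hazard vectors"
        )
    rng = np.random.default_rng(seed)
    base = config.baseline_hazard_per_subtype[labels - 1]
    hr = np.where(
        arms == "treated", config.treatment_hazard_ratio_per_subtype[labels - 1], 1.0
    )
    rate = base * hr
    event_t = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        censor_t = rng.exponential(1.0 / config.censoring_rate, size=len(labels))
    else:
        censor_t = np.full(len(labels), np.inf)
    cutoff = np.minimum(censor_t, config.max_followup)
    time = np.minimum(event_t, cutoff)
    event = (event_t <= cutoff).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{j:04d}" for j in range(len(labels))]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "arm": arms,
            "time": time,
            "event": event,
            "endpoint": endpoint,
        }
    )


def generate_drug_panel(
    cell_line_probabilities: np.ndarray,
    config: DrugPanelConfig,
    seed: int,
) -> pd.DataFrame:
    """Drug-by-cell-line AUC table coupled to a subtype membership score.

    Coupled drugs follow ``AUC = intercept + slope * probability + noise``
    (slope negative: lines with high subtype probability are more
    sensitive); uncoupled drugs are intercept + noise. Two independent
    pharmacogenomic panels are obtained by calling twice with distinct
    seeds.
    """
    probs = np.asarray(cell_line_probabilities, dtype=float)
    if probs.shape[0] != config.n_cell_lines:
        raise ValueError("one probability per cell line required")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.auc_noise_sd, size=(config.n_drugs, config.n_cell_lines))
    auc = np.full((config.n_drugs, config.n_cell_lines), config.auc_intercept) + noise
    for d in config.coupled_drug_indices:
        auc[d - 1, :] += config.coupling_slope * probs
    drug_ids = [f"DRUG{d:03d}" for d in range(1, config.n_drugs + 1)]
    line_ids = [f"CL{j:03d}" for j in range(config.n_cell_lines)]
    return pd.DataFrame(auc, index=drug_ids, columns=line_ids)
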