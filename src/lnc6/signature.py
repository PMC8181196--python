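"""Subtype-specific gene signatures from one-vs-rest two-class t-tests.

Each subtype is contrasted against all remaining samples pooled. Per gene we
report the pooled-variance (Student) two-sample t statistic, its two-sided
p-value at n-2 degrees of freedom, and the log ratio — the difference of
group means on the log2 scale, i.e. the log2 fold change. A subtype's
signature keeps the genes passing the p-value gate that are up-regulated in
the subtype, ranked by descending log ratio, truncated to a gene budget
(default: p < 0.001, top 200).

The same machinery serves both feature spaces: mRNA signatures drive the
cross-cohort predictor, lncRNA signatures drive the trial-cohort variant.
No multiple-testing correction is applied at this stage — selection is by a
raw per-gene threshold, with miscalibration guarded by the test suite's
null-cohort calibration checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class GeneStat:
    """One gene's one-vs-rest contrast: t, log2 mean difference, p."""

    gene_id: str
    t_statistic: float
    log_ratio: float
    p_value: float


@dataclass
class SubtypeSignature:
    """Ordered up-regulated gene list for one subtype."""

    subtype: int
    genes: list[GeneStat]
    p_threshold: float
    max_genes: int

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)


def pooled_t_from_moments(
    sum_in: np.ndarray,
    sumsq_in: np.ndarray,
    n_in: int,
    sum_out: np.ndarray,
    sumsq_out: np.ndarray,
    n_out: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t-test from per-group moments.

    Returns ``(t, log_ratio, p)`` arrays. Degrees of freedom are
    ``n_in + n_out - 2``. Degenerate genes (zero pooled variance) get
    ``t = 0, p = 1`` when the means agree and ``t = ±inf, p = 0`` otherwise.

    Exposed separately so that leave-one-out cross-validation can re-derive
    fold statistics from updated moments through the exact same formula.
    """
    if n_in < 2 or n_out < 2:
        raise ValueError(f"both groups need >=2 samples (got {n_in} and {n_out})")
    mean_in = sum_in / n_in
    mean_out = sum_out / n_out
    ss_in = np.maximum(sumsq_in - n_in * mean_in**2, 0.0)
    ss_out = np.maximum(sumsq_out - n_out * mean_out**2, 0.0)
    df = n_in + n_out - 2
    pooled_var = (ss_in + ss_out) / df
    se = np.sqrt(pooled_var * (1.0 / n_in + 1.0 / n_out))
    diff = mean_in - mean_out
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0.0
    t = np.where(zero_se & (diff == 0.0), 0.0, t)
    t = np.where(zero_se & (diff > 0.0), np.inf, t)
    t = np.where(zero_se & (diff < 0.0), -np.inf, t)
    finite_t = np.where(np.isinf(t), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * sstats.t.sf(np.abs(finite_t), df))
    return t, diff, p


def ovr_t_test(
    matrix: ExpressionMatrix, labels: np.ndarray, subtype: int
) -> list[GeneStat]:
    """Per-gene pooled-variance t-test of one subtype vs all other samples.

    ``labels`` holds one subtype index per sample (aligned with
    ``matrix.sample_ids``); ``subtype`` picks the in-group. Results are in
    the matrix's gene order.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise ValueError("labels length does not match number of samples")
    mask = labels == subtype
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    x_in = matrix.values[:, mask]
    x_out = matrix.values[:, ~mask]
    t, lr, p = pooled_t_from_moments(
        x_in.sum(axis=1), (x_in**2).sum(axis=1), n_in,
        x_out.sum(axis=1), (x_out**2).sum(axis=1), n_out,
    )
    return [
        GeneStat(g, float(t[i]), float(lr[i]), float(p[i]))
        for i, g in enumerate(matrix.gene_ids)
    ]


def build_signature(
    stats: list[GeneStat],
    subtype: int = 0,
    p_threshold: float = 0.001,
    max_genes: int = 200,
    rank_by: str = "signed",
) -> SubtypeSignature:
    """Filter and rank one subtype's gene statistics into a signature.

    Keeps genes with ``p_value < p_threshold`` and ``log_ratio > 0``
    (up-regulated in the subtype), sorts by descending log ratio with
    lexicographic gene-ID tie-break, and truncates to ``max_genes``.
    ``rank_by="abs"`` ranks by absolute log ratio instead and drops the
    up-regulation requirement.
    """
    if not stats:
        raise ValueError("empty statistics list")
    if rank_by not in ("signed", "abs"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if rank_by == "signed":
        passing = [g for g in stats if g.p_value < p_threshold and g.log_ratio > 0]
        passing.sort(key=lambda g: (-g.log_ratio, g.gene_id))
    else:
        passing = [g for g in stats if g.p_value < p_threshold and g.log_ratio != 0]
        passing.sort(key=lambda g: (-abs(g.log_ratio), g.gene_id))
    if not passing:
        warnings.warn(
            f"no genes pass p<{p_threshold} with positive log ratio for subtype "
            f"{subtype}; signature is empty",
            stacklevel=2,
        )
    return SubtypeSignature(
        subtype=subtype,
        genes=passing[:max_genes],
        p_threshold=p_threshold,
        max_genes=max_genes,
    )


def build_all_signatures(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    p_threshold: float = 0.001,
    max_genes: int = 200,
    rank_by: str = "signed",
) -> list[SubtypeSignature]:
    """One signature per subtype index present in ``labels`` (ascending order).

    A gene may appear in several subtypes' signatures; no exclusivity is
    enforced.
    """
    labels = np.asarray(labels)
    subtypes = sorted(int(s) for s in np.unique(labels))
    return [
        build_signature(
            ovr_t_test(matrix, labels, s),
            subtype=s,
            p_threshold=p_threshold,
            max_genes=max_genes,
            rank_by=rank_by,
        )
        for s in subtypes
    ]
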