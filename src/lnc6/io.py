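"""Reading, writing and normalization of the pipeline's file formats.

Expression travels as tab-separated text (first column gene IDs, first row
sample IDs). Gene signatures are written both as GMT-style set files and as a
detailed per-gene statistics CSV. Sample annotations (subtype label, treatment
arm, survival) share one CSV layout. Writers emit a leading ``#`` comment line
with the package version and the writer's parameters so every artifact is
self-describing.

Normalization here is deliberately minimal: per-gene median centering (for
signature heatmap-style contrasts) and per-gene z-scoring (the cross-cohort
harmonization contract required before compound-covariate scoring). Gene
matching between cohorts is by exact identifier string.
"""

from __future__ import annotations

import csv
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .signature import GeneStat, SubtypeSignature

PIPELINE_VERSION = "0.1.0"

# Load-time missing-data policy (fixed; the upstream cohorts are assumed
# complete, real-world gaps are handled conservatively and logged):
MAX_MISSING_FRACTION = 0.20  # rows with more missing are dropped


def _comment(params: str) -> str:
    return f"# lnc6 v{PIPELINE_VERSION} {params}"


def read_expression(
    path: str | Path,
    feature_space: str = "lncRNA",
    cohort_tag: str = "",
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV into an :class:`ExpressionMatrix`.

    Duplicate gene IDs are collapsed by per-gene mean. Rows with more than
    20% missing cells are dropped; remaining missing cells are imputed by the
    per-gene mean of the observed cells.

    Raises
    ------
    ValueError
        On an empty file, or a non-numeric cell (the error names the
        offending gene row and sample column).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty or header-only expression file")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {frame.iat[i, j]!r} at gene "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    # collapse duplicated gene IDs by mean
    numeric = numeric.groupby(level=0, sort=False).mean()
    # drop heavily missing rows, impute the rest by per-gene mean
    missing_frac = numeric.isna().mean(axis=1)
    numeric = numeric.loc[missing_frac <= MAX_MISSING_FRACTION]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path}: no gene rows left after missingness filter")
    row_means = numeric.mean(axis=1)
    numeric = numeric.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return ExpressionMatrix.from_frame(numeric, feature_space=feature_space, cohort_tag=cohort_tag)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            _comment(
                f"expression feature_space={matrix.feature_space} cohort={matrix.cohort_tag}"
            )
            + "\n"
        )
        matrix.to_frame().to_csv(fh, sep="\t", float_format="%.6f")


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (row medians become 0)."""
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    med = np.median(matrix.values, axis=1, keepdims=True)
    return replace(matrix, values=matrix.values - med)


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to mean 0, sample SD (n-1 denominator) 1.

    Constant rows cannot be standardized; they are set to all zeros and their
    gene IDs recorded in ``constant_genes`` on the returned matrix.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(const[:, None], 1.0, sd)
    z = (matrix.values - mean) / safe_sd
    z[const, :] = 0.0
    flagged = tuple(g for g, c in zip(matrix.gene_ids, const) if c)
    return replace(matrix, values=z, constant_genes=flagged)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, lexicographic order."""
    if a.feature_space != b.feature_space:
        raise ValueError(
            f"feature spaces differ: {a.feature_space} vs {b.feature_space}"
        )
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("no genes in common between the two matrices")
    return a.subset_genes(shared), b.subset_genes(shared)


# ---------------------------------------------------------------------------
# sample annotations (labels / arms / survival)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["sample_id", "label", "arm", "time", "event", "endpoint"]


def write_annotations(frame: pd.DataFrame, path: str | Path, params: str = "") -> None:
    """Write a sample-annotation CSV (subset of the canonical columns ok)."""
    cols = [c for c in ANNOTATION_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(_comment(f"annotations {params}".rstrip()) + "\n")
        frame[cols + extra].to_csv(fh, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# signatures (GMT + stats CSV)
# ---------------------------------------------------------------------------


def write_signatures_gmt(signatures: list[SubtypeSignature], path: str | Path) -> None:
    """GMT-style text: one line per set — name, description, tab-joined genes."""
    with open(path, "w") as fh:
        for sig in signatures:
            name = f"subtype_{sig.subtype}_up"
            desc = f"p<{sig.p_threshold};top{sig.max_genes}"
            genes = "\t".join(g.gene_id for g in sig.genes)
            fh.write(f"{name}\t{desc}\t{genes}\n" if genes else f"{name}\t{desc}\n")


def read_gene_sets_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_signature_stats(signatures: list[SubtypeSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment("signature per-gene statistics") + "\n")
        writer = csv.writer(fh)
        writer.writerow(["subtype", "rank", "gene_id", "t_statistic", "log_ratio", "p_value"])
        for sig in signatures:
            for rank, g in enumerate(sig.genes, start=1):
                writer.writerow(
                    [sig.subtype, rank, g.gene_id, f"{g.t_statistic:.6f}",
                     f"{g.log_ratio:.6f}", f"{g.p_value:.6g}"]
                )


def read_signature_stats(path: str | Path) -> list[SubtypeSignature]:
    """Rebuild signatures from a stats CSV written by :func:`write_signature_stats`.

    Threshold metadata is not stored per row; the reconstructed signatures
    carry the observed gene lists with ``p_threshold``/``max_genes`` set to
    permissive bounds.
    """
    frame = pd.read_csv(path, comment="#")
    sigs = []
    for subtype, grp in frame.groupby("subtype", sort=True):
        grp = grp.sort_values("rank")
        genes = [
            GeneStat(row.gene_id, float(row.t_statistic), float(row.log_ratio), float(row.p_value))
            for row in grp.itertuples()
        ]
        sigs.append(
            SubtypeSignature(subtype=int(subtype), genes=genes, p_threshold=1.0,
                             max_genes=len(genes))
        )
    return sigs
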