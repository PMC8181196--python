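"""Core in-memory container for log2 expression data.

The pipeline passes gene-by-sample matrices between every stage; this module
defines the single container they all share. Values are log2-scale expression
(normalized upstream), rows are genes, columns are samples. A matrix carries a
``feature_space`` tag (``"lncRNA"`` or ``"mRNA"``) so that signature/model
stages can refuse to mix spaces, plus a free-text ``cohort_tag`` identifying
the cohort the samples came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FEATURE_SPACES = ("lncRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Float array of shape ``(len(gene_ids), len(sample_ids))`` with no
        missing values (load-time imputation happens in :mod:`lnc6.io`).
    feature_space
        ``"lncRNA"`` or ``"mRNA"``.
    cohort_tag
        Free-text cohort/platform label.
    constant_genes
        Gene IDs whose row was constant at the last z-scoring (set by
        :func:`lnc6.io.zscore_genes`; empty otherwise).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_space: str = "lncRNA"
    cohort_tag: str = ""
    constant_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_space not in FEATURE_SPACES:
            raise ValueError(
                f"feature_space must be one of {FEATURE_SPACES}, got {self.feature_space!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN; impute at load time")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` (kept in the given order)."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        rows = [idx[g] for g in genes]
        return replace(self, gene_ids=list(genes), values=self.values[rows, :])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return replace(self, sample_ids=list(samples), values=self.values[:, cols])

    def sample_profile(self, sample_id: str) -> dict[str, float]:
        """Single-sample profile as a gene_id -> value mapping."""
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids, self.values[:, j]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        feature_space: str = "lncRNA",
        cohort_tag: str = "",
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            feature_space=feature_space,
            cohort_tag=cohort_tag,
        )
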