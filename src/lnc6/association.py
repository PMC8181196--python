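"""Downstream associations of the subtypes.

Three independent analyses share this module:

* cross-tabulation of the subtype assignment against an alternative
  classification of the same samples (the contingency counts behind a
  chord diagram);
* a Spearman correlation screen of drug-sensitivity AUC against a subtype's
  predicted membership probability across cell lines, with a concordance
  filter over independent pharmacogenomic panels (significant correlation
  of the required sign in every panel);
* pre-ranked gene set enrichment analysis: the weighted Kolmogorov-Smirnov
  running-sum enrichment score of a gene set in a ranked list, with a
  gene-label permutation p-value. Set membership is permuted over genes
  (pre-ranked mode) rather than phenotypes — appropriate for small-cohort
  responder contrasts where phenotype permutation is underpowered.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

EXACT_PERMUTATION_MAX_N = 9  # n! enumeration is cheap up to here


@dataclass
class OverlapTable:
    """Contingency counts between two labelings of the same samples."""

    rows: list
    cols: list
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.rows, columns=self.cols)


@dataclass(frozen=True)
class DrugCorrelation:
    drug_id: str
    rho: float
    p: float
    n: int
    dataset_tag: str = ""


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    n_permutations: int


def cross_tabulate(assign_a: dict[str, object], assign_b: dict[str, object]) -> OverlapTable:
    """counts[i][j] = samples labeled i in A and j in B, over shared samples."""
    shared = sorted(set(assign_a) & set(assign_b))
    if not shared:
        raise ValueError("no samples shared between the two labelings")
    rows = sorted({assign_a[s] for s in shared}, key=str)
    cols = sorted({assign_b[s] for s in shared}, key=str)
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    ri = {r: i for i, r in enumerate(rows)}
    cj = {c: j for j, c in enumerate(cols)}
    for s in shared:
        counts[ri[assign_a[s]], cj[assign_b[s]]] += 1
    return OverlapTable(rows=rows, cols=cols, counts=counts)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def _spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided p: t approximation for n >= 10, exact permutation below."""
    n = len(x)
    if n >= 10:
        if abs(rho) >= 1.0:
            return 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        return float(2.0 * t_dist.sf(abs(t), n - 2))
    # exact permutation null: enumerate all orderings of one rank vector
    rxc = tuple(rankdata(x) - rankdata(x).mean())
    ryc = tuple(rankdata(y) - rankdata(y).mean())
    denom = math.sqrt(sum(a * a for a in rxc) * sum(b * b for b in ryc))
    threshold = abs(rho) * denom - 1e-12
    hits = total = 0
    for perm in itertools.permutations(rxc):
        total += 1
        if abs(sum(a * b for a, b in zip(perm, ryc))) >= threshold:
            hits += 1
    return hits / total


def spearman_screen(
    probabilities: dict[str, float],
    auc_table: pd.DataFrame,
    alpha: float = 0.05,
    dataset_tag: str = "",
) -> list[DrugCorrelation]:
    """Per-drug Spearman correlation of AUC against membership probability.

    ``auc_table`` is drug-by-cell-line; missing AUC values are dropped
    pairwise. Drugs with fewer than 4 complete pairs, or with constant
    ranks on either side, are reported with NaN rho/p. ``alpha`` is carried
    for downstream filtering, not applied here.
    """
    shared = [c for c in auc_table.columns if c in probabilities]
    if len(shared) < 4:
        raise ValueError("fewer than 4 cell lines with probabilities")
    probs = np.array([probabilities[c] for c in shared], dtype=float)
    results = []
    for drug_id, row in auc_table[shared].iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < 4:
            results.append(DrugCorrelation(str(drug_id), float("nan"), float("nan"), n, dataset_tag))
            continue
        x, yy = probs[ok], y[ok]
        if np.unique(x).size < 2 or np.unique(yy).size < 2:
            results.append(DrugCorrelation(str(drug_id), float("nan"), float("nan"), n, dataset_tag))
            continue
        rho = _spearman_rho(x, yy)
        p = _spearman_p(x, yy, rho)
        results.append(DrugCorrelation(str(drug_id), rho, p, n, dataset_tag))
    return results


def concordant_hits(
    screens: list[list[DrugCorrelation]],
    alpha: float = 0.05,
    sign: str = "negative",
) -> list[str]:
    """Drugs significant with the required correlation sign in EVERY screen."""
    if len(screens) < 2:
        raise ValueError("need screens from >=2 datasets")
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    per_screen = [{d.drug_id: d for d in screen} for screen in screens]
    shared = set(per_screen[0])
    for s in per_screen[1:]:
        shared &= set(s)
    if not shared:
        raise ValueError("no drugs shared across screens")

    def ok(d: DrugCorrelation) -> bool:
        if math.isnan(d.rho) or math.isnan(d.p):
            return False
        right_sign = d.rho < 0 if sign == "negative" else d.rho > 0
        return right_sign and d.p < alpha

    return sorted(drug for drug in shared if all(ok(s[drug]) for s in per_screen))


def drug_screen_frame(screens: list[list[DrugCorrelation]]) -> pd.DataFrame:
    rows = [
        {"drug": d.drug_id, "dataset": d.dataset_tag, "rho": d.rho, "p": d.p, "n": d.n}
        for screen in screens
        for d in screen
    ]
    return pd.DataFrame(rows)


def enrichment_score(
    metrics_sorted: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum ES for a ranked list (already sorted).

    Hits increment proportionally to |metric|^weight (normalized to sum 1
    over hits), misses decrement uniformly by 1/(N - N_hits). The ES is the
    running sum's maximum deviation from zero, with its sign. With
    ``weight=0`` this is the classical unweighted KS statistic.
    """
    in_set = np.asarray(in_set, dtype=bool)
    n = len(metrics_sorted)
    n_hits = int(in_set.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    hit_w = np.abs(metrics_sorted) ** weight * in_set
    denom = hit_w.sum()
    if denom == 0:  # all set genes have zero metric: fall back to equal steps
        hit_w = in_set.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~in_set) / (n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running


def preranked_gsea(
    ranked: dict[str, float],
    gene_set: set[str] | list[str],
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    set_name: str = "gene_set",
) -> GseaResult:
    """Pre-ranked GSEA of one gene set against a gene -> metric ranking.

    Genes are ordered by decreasing metric (ties broken by gene ID); the
    p-value permutes set membership uniformly over genes, comparing same-sign
    permuted enrichment scores; NES divides the ES by the mean |permuted ES|
    of the same sign. The permutation p has floor 1/(n_permutations + 1).
    """
    gene_set = set(gene_set)
    genes = sorted(ranked, key=lambda g: (-ranked[g], g))
    overlap = gene_set & set(genes)
    if not overlap:
        raise ValueError("gene set has no overlap with the ranked list")
    if len(overlap) >= len(genes):
        raise ValueError("gene set must be smaller than the ranked list")
    metrics = np.array([ranked[g] for g in genes], dtype=float)
    in_set = np.array([g in gene_set for g in genes])
    es, _ = enrichment_score(metrics, in_set, weight)
    rng = np.random.default_rng(seed)
    n_hits = int(in_set.sum())
    perm_es = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=n_hits, replace=False)] = True
        perm_es[b], _ = enrichment_score(metrics, perm, weight)
    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_permutations, bool)
    n_same = int(same_sign.sum())
    p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    nes = es / np.abs(perm_es[same_sign]).mean() if n_same else float("nan")
    return GseaResult(
        set_name=set_name, es=es, nes=float(nes), p=float(p),
        n_permutations=n_permutations,
    )
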