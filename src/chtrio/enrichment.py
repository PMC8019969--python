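"""Gene-list overlap, association-score thresholding and over-representation.

Over-representation analysis (ORA) tests each pathway gene set against the
candidate genes with a hypergeometric upper tail, adjusts across pathways
with the Benjamini-Hochberg step-up procedure, and additionally reports
Storey-style q-values.  Pathways are retained when the adjusted p-value and
the q-value both fall at or below their cutoffs (defaults 0.05 and 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AssociationRow, FilterThresholds, PathwayCollection, sample_gene_pairs

DEFAULT_THRESHOLDS = FilterThresholds()


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _validate_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (np.any(arr <= 0) or np.any(arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return arr


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = _validate_pvalues(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(pvalues: Sequence[float], lambdas: Optional[np.ndarray] = None) -> float:
    """Storey's estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is evaluated on a
    lambda grid and smoothed with a cubic fit evaluated at the largest
    lambda, then clipped into (0, 1].
    """
    p = _validate_pvalues(pvalues)
    m = p.size
    if m < 2:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    degree = min(3, len(lambdas) - 1)
    coeffs = np.polyfit(lambdas, pi0_raw, degree)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = float(min(1.0, pi0_raw.mean())) or 1.0
    return float(min(pi0, 1.0))


def q_values(pvalues: Sequence[float], pi0: Optional[float] = None) -> np.ndarray:
    """Storey-style q-values; with pi0 forced to 1 they equal BH-adjusted p.

    With fewer than two p-values the BH values are returned unchanged.
    """
    p = _validate_pvalues(pvalues)
    m = p.size
    if m < 2:
        return bh_adjust(pvalues)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested pathway with its overlap and significance measures."""

    pathway: str
    k: int  # candidate genes in the pathway
    K: int  # pathway size within the universe
    n: int  # candidate-list size within the universe
    N: int  # universe size
    p: float
    padj: float
    q: float
    genes: tuple[str, ...]
    retained: bool


def run_ora(
    candidate_genes: Iterable[str],
    pathways: PathwayCollection,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    universe: Optional[Iterable[str]] = None,
    min_pathway_size: int = 2,
    max_pathway_size: int = 500,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of candidate genes in pathways.

    Candidates are intersected with the universe (default: union of all
    pathway genes) before testing.  Only pathways with >= 1 overlapping
    candidate and a within-universe size inside the gate are tested; the
    ``retained`` flag applies both the adjusted-p and q cutoffs.  Results
    are ordered by p-value then name, independent of pathway input order.
    """
    universe_set = frozenset(universe) if universe is not None else pathways.universe
    if not universe_set:
        raise ValueError("the gene universe is empty")
    candidates = set(candidate_genes) & universe_set
    N = len(universe_set)
    n = len(candidates)
    tested: list[tuple[str, int, int, tuple[str, ...]]] = []
    for name in sorted(pathways.pathways):
        genes = pathways.pathways[name] & universe_set
        K = len(genes)
        if not (min_pathway_size <= K <= max_pathway_size):
            continue
        overlap = tuple(sorted(candidates & genes))
        if not overlap:
            continue
        tested.append((name, len(overlap), K, overlap))
    if not tested:
        return []
    pvals = [hypergeom_tail(k, K, n, N) for _, k, K, _ in tested]
    padj = bh_adjust(pvals)
    qvals = q_values(pvals)
    results = [
        EnrichmentResult(
            pathway=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            padj=float(pa),
            q=float(q),
            genes=genes,
            retained=bool(pa <= thresholds.ora_padj_max and q <= thresholds.ora_q_max),
        )
        for (name, k, K, genes), p, pa, q in zip(tested, pvals, padj, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway": r.pathway,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "padj": r.padj,
            "q": r.q,
            "genes": ",".join(r.genes),
            "retained": r.retained,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p", "padj", "q", "genes", "retained"]
    )


def gene_list_overlap(
    calls_by_disease: Mapping[str, Iterable],
    gene_lists: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per disease x named gene list: called genes hit and carrier counts.

    Typical gene lists are known tumor-suppressor genes and developmental-
    biology genes; a row is emitted for every called gene found in a list,
    with the number of distinct carrier samples.
    """
    rows = []
    for disease in sorted(calls_by_disease):
        pairs = sample_gene_pairs(calls_by_disease[disease])
        samples_by_gene: dict[str, set[str]] = {}
        for sample, gene in pairs:
            samples_by_gene.setdefault(gene, set()).add(sample)
        for list_name in sorted(gene_lists):
            listed = set(gene_lists[list_name])
            for gene in sorted(set(samples_by_gene) & listed):
                rows.append(
                    {
                        "disease": disease,
                        "gene_list": list_name,
                        "gene": gene,
                        "n_samples": len(samples_by_gene[gene]),
                    }
                )
    return pd.DataFrame(rows, columns=["disease", "gene_list", "gene", "n_samples"])


def association_filter(
    table: Iterable[AssociationRow],
    min_score: float = DEFAULT_THRESHOLDS.gda_min,
) -> list[AssociationRow]:
    """Rows with association score >= min_score (strong evidence), any kind."""
    return [row for row in table if row.score >= min_score]
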