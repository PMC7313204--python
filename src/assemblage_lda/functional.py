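"""Functional assemblages: LDA on KO profiles, matching, category summaries.

Fitting LDA to KEGG-orthology count profiles of the same samples (at the
same K) yields functional assemblages; each is matched one-to-one to a
taxonomic assemblage by maximizing the summed Pearson correlation between
their theta columns across samples (an exact bipartite assignment). KO-level
phi rows are then aggregated into functional-category abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import CountTable
from .lda import LDAFit, fit_lda


@dataclass
class AssemblageMatching:
    """Bijection functional -> taxonomic assemblage index, with scores."""

    mapping: dict[int, int]
    score_matrix: np.ndarray  # (K, K): [func, taxa] Pearson r of theta columns
    total_score: float

    def __post_init__(self) -> None:
        K = self.score_matrix.shape[0]
        if sorted(self.mapping) != list(range(K)) or sorted(self.mapping.values()) != list(range(K)):
            raise ValueError("mapping must be a permutation of 0..K-1")


@dataclass
class CategoryAbundance:
    """Per-assemblage relative abundance over functional categories."""

    categories: list[str]
    abundance: np.ndarray  # (K, C), rows sum to 1
    argmax_assemblage: np.ndarray  # (C,) assemblage index with top abundance


def fit_functional_lda(ko_table: CountTable, K: int, **lda_settings) -> LDAFit:
    """LDA on a (preprocessed) KO count table; delegates to :func:`fit_lda`."""
    return fit_lda(ko_table, K, **lda_settings)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_assemblages(theta_taxa: np.ndarray, theta_func: np.ndarray) -> AssemblageMatching:
    """Optimal one-to-one matching of functional to taxonomic assemblages.

    score_matrix[a, b] is the Pearson correlation of functional theta column
    ``a`` with taxonomic theta column ``b`` across samples (0 for
    zero-variance columns, with a warning); the mapping is the permutation
    maximizing the summed matched correlations.
    """
    theta_taxa = np.asarray(theta_taxa, dtype=float)
    theta_func = np.asarray(theta_func, dtype=float)
    if theta_taxa.shape != theta_func.shape:
        raise ValueError("theta matrices must share shape (same samples, same K)")
    K = theta_taxa.shape[1]
    if any(np.ptp(theta_taxa[:, k]) == 0 for k in range(K)) or any(
        np.ptp(theta_func[:, k]) == 0 for k in range(K)
    ):
        warnings.warn("zero-variance theta column; its correlations set to 0")
    score = np.array(
        [[_safe_corr(theta_func[:, a], theta_taxa[:, b]) for b in range(K)] for a in range(K)]
    )
    rows, cols = linear_sum_assignment(-score)
    mapping = {int(a): int(b) for a, b in zip(rows, cols)}
    total = float(score[rows, cols].sum())
    return AssemblageMatching(mapping=mapping, score_matrix=score, total_score=total)


def category_abundance(
    phi_func: np.ndarray, ko_ids: list[str], ko_to_category: dict[str, str]
) -> CategoryAbundance:
    """Aggregate KO-level phi rows into functional-category abundances.

    Each KO maps to exactly one category; KOs absent from the map are pooled
    into "unmapped". abundance[k, c] is the summed phi mass of category c in
    assemblage k, renormalized over categories; argmax per category breaks
    ties toward the lower assemblage index.
    """
    if not ko_to_category:
        raise ValueError("empty KO-to-category map")
    for ko, cat in ko_to_category.items():
        if not isinstance(cat, str):
            raise ValueError(f"KO {ko!r} maps to a non-string category {cat!r}")
    phi_func = np.asarray(phi_func, dtype=float)
    if phi_func.shape[1] != len(ko_ids):
        raise ValueError("phi_func columns must match ko_ids")
    cats = [ko_to_category.get(ko, "unmapped") for ko in ko_ids]
    categories = list(dict.fromkeys(cats))
    idx = {c: i for i, c in enumerate(categories)}
    K = phi_func.shape[0]
    abundance = np.zeros((K, len(categories)))
    for j, c in enumerate(cats):
        abundance[:, idx[c]] += phi_func[:, j]
    totals = abundance.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("an assemblage has zero total phi mass")
    abundance = abundance / totals
    argmax = abundance.argmax(axis=0)  # first (lowest) index on ties
    return CategoryAbundance(categories=categories, abundance=abundance, argmax_assemblage=argmax)


def read_ko_category_map(path) -> dict[str, str]:
    """Read a two-column TSV (KO id, category); duplicate KOs with differing
    categories are rejected (each KO must map to exactly one category)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["ko", "category"], dtype=str)
    mapping: dict[str, str] = {}
    for ko, cat in zip(df["ko"], df["category"]):
        if ko in mapping and mapping[ko] != cat:
            raise ValueError(f"KO {ko!r} mapped to multiple categories")
        mapping[ko] = cat
    return mapping
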