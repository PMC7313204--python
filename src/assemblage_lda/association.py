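"""Correlation analyses with Benjamini-Hochberg multiple-testing correction.

Links assemblage proportions (theta columns) to functional relative
abundances by Pearson correlation, and genus pairs to each other by Spearman
correlation, with two-sided p-values and BH step-up adjustment over the
whole family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import RelativeAbundanceTable


@dataclass
class AssociationTable:
    """Pairwise correlation results: one row per (variable_a, variable_b) pair.

    ``table`` has columns variable_a, variable_b, r, p_raw, p_adj,
    significant. Pairs with a zero-variance column carry NaN statistics and
    are excluded from the BH family.
    """

    table: pd.DataFrame
    method: str
    alpha: float = 0.01

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{l >= i} (p_(l) * m / l), capped at 1, where p_(1) <= ... <=
    p_(m) are the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float, n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def _finalize(rows: list[dict], method: str, alpha: float) -> AssociationTable:
    df = pd.DataFrame(rows, columns=["variable_a", "variable_b", "r", "p_raw"])
    valid = df["p_raw"].notna()
    p_adj = np.full(len(df), np.nan)
    if valid.any():
        p_adj[valid.to_numpy()] = bh_adjust(df.loc[valid, "p_raw"].to_numpy())
    df["p_adj"] = p_adj
    sig = pd.array(df["p_adj"] < alpha, dtype="boolean")
    sig[~valid.to_numpy()] = pd.NA
    df["significant"] = sig
    return AssociationTable(df, method=method, alpha=alpha)


def pearson_assemblage_function(
    theta: np.ndarray,
    function_profiles: RelativeAbundanceTable,
    function_ids: list[str],
    alpha: float = 0.01,
    assemblage_names: list[str] | None = None,
    p_mode: str = "t",
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationTable:
    """Pearson correlation of every assemblage theta column with every function.

    Two-sided p-values from the t-distribution with N-2 degrees of freedom
    (or label permutation when ``p_mode='permutation'``); BH adjustment over
    the full K x F family; significance at adjusted p < ``alpha`` (0.01 by
    default). Zero-variance columns yield NaN rows excluded from the family.
    """
    theta = np.asarray(theta, dtype=float)
    N, K = theta.shape
    if N < 3:
        raise ValueError("need at least 3 samples")
    if function_profiles.n_samples != N:
        raise ValueError("sample counts of theta and function profiles differ")
    missing = [f for f in function_ids if f not in function_profiles.feature_ids]
    if missing:
        raise ValueError(f"functions not present in profiles: {missing}")
    names = assemblage_names or [f"assemblage_{k + 1}" for k in range(K)]

    rows = []
    for k in range(K):
        x = theta[:, k]
        for fid in function_ids:
            y = function_profiles.proportions[:, function_profiles.feature_ids.index(fid)]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"zero-variance column for pair ({names[k]}, {fid}); skipped")
                rows.append(dict(variable_a=names[k], variable_b=fid, r=np.nan, p_raw=np.nan))
                continue
            r, p = sps.pearsonr(x, y)
            if p_mode == "permutation":
                p = _permutation_p(x, y, r, n_perm, seed)
            rows.append(dict(variable_a=names[k], variable_b=fid, r=float(r), p_raw=float(p)))
    return _finalize(rows, "pearson", alpha)


def spearman_feature_pairs(
    profiles: RelativeAbundanceTable,
    feature_subset: list[str],
    alpha: float = 0.01,
) -> AssociationTable:
    """Spearman rank correlation over all unordered pairs of the given features.

    Average ranks for ties; two-sided p via the t-approximation; BH over all
    pairs. Constant columns yield NaN rows excluded from the family.
    """
    if len(feature_subset) < 2:
        raise ValueError("need at least 2 features")
    if profiles.n_samples < 3:
        raise ValueError("need at least 3 samples")
    missing = [f for f in feature_subset if f not in profiles.feature_ids]
    if missing:
        raise ValueError(f"features not present: {missing}")
    cols = {f: profiles.proportions[:, profiles.feature_ids.index(f)] for f in feature_subset}
    rows = []
    for a_idx, fa in enumerate(feature_subset):
        for fb in feature_subset[a_idx + 1:]:
            x, y = cols[fa], cols[fb]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant column for pair ({fa}, {fb}); skipped")
                rows.append(dict(variable_a=fa, variable_b=fb, r=np.nan, p_raw=np.nan))
                continue
            rho, p = sps.spearmanr(x, y)
            rows.append(dict(variable_a=fa, variable_b=fb, r=float(rho), p_raw=float(p)))
    return _finalize(rows, "spearman", alpha)
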