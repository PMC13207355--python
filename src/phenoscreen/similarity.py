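"""Potency x basal-protein similarity: Spearman matrix and clustering.

Per-compound IC50 profiles and per-protein basal expression profiles
across the shared cell-line panel (nominally six lines) are correlated
by Spearman rank correlation (average ranks on ties, pairwise-complete,
>= 3 shared lines required per cell). Negative rho means higher
expression accompanies lower IC50 — greater sensitivity — flagging the
protein as a candidate response biomarker; positive rho suggests a
resistance marker. Rows and columns are ordered by agglomerative
clustering with distance one-minus-Spearman under complete linkage.

IC50 profiles with no fit ("inactive") are right-censored at the top
tested dose for ranking purposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class SimilarityMatrix:
    rho: pd.DataFrame          # proteins x compounds
    n_shared: pd.DataFrame     # shared lines per cell
    min_shared: int = 3


def censor_inactive(ic50: pd.DataFrame, top_dose_nM: float = 3000.0) -> pd.DataFrame:
    """Replace missing ("inactive") IC50s with the top tested dose (right-censoring)."""
    return ic50.fillna(top_dose_nM)


def spearman_matrix(ic50_profiles: pd.DataFrame, protein_profiles: pd.DataFrame,
                    min_shared: int = 3) -> SimilarityMatrix:
    """Spearman rho for every protein x compound pair over shared cell lines.

    Inputs are wide tables: compounds x lines and proteins x lines
    (indexes = labels, columns = cell lines). Cells with fewer than
    ``min_shared`` pairwise-complete lines are NaN (flagged missing).
    """
    lines = [c for c in protein_profiles.columns if c in ic50_profiles.columns]
    if not lines:
        raise ValueError("no shared cell lines between the two profiles")
    rho = pd.DataFrame(index=protein_profiles.index, columns=ic50_profiles.index,
                       dtype=float)
    n_sh = pd.DataFrame(index=protein_profiles.index, columns=ic50_profiles.index,
                        dtype=int)
    for prot in protein_profiles.index:
        pv = protein_profiles.loc[prot, lines].to_numpy(dtype=float)
        for cpd in ic50_profiles.index:
            cv = ic50_profiles.loc[cpd, lines].to_numpy(dtype=float)
            ok = np.isfinite(pv) & np.isfinite(cv)
            n_sh.loc[prot, cpd] = int(ok.sum())
            if ok.sum() < min_shared:
                rho.loc[prot, cpd] = np.nan
                continue
            r = stats.spearmanr(pv[ok], cv[ok]).statistic
            rho.loc[prot, cpd] = r
    return SimilarityMatrix(rho=rho, n_shared=n_sh, min_shared=min_shared)


def _one_minus_spearman_dist(mat: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 - Spearman distance between the rows of ``mat``."""
    n = mat.shape[0]
    if n < 2:
        return np.zeros(0)
    rho = stats.spearmanr(mat.T).statistic
    if np.isscalar(rho):  # spearmanr collapses 2-row input to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - np.asarray(rho)
    d = np.nan_to_num(d, nan=1.0)  # constant rows: treat as uncorrelated
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def hclust_order(matrix: SimilarityMatrix, linkage: str = "complete"
                 ) -> tuple[list[str], list[str], np.ndarray | None, np.ndarray | None]:
    """Leaf orders for rows and columns under 1 - Spearman, complete linkage.

    Missing cells are imputed as 0 (with a warning) before clustering.
    Single-row or single-column matrices get the identity ordering.
    Returns (row_order, col_order, row_linkage, col_linkage).
    """
    rho = matrix.rho
    if rho.isna().any().any():
        warnings.warn("missing similarity cells imputed as 0 for clustering")
        rho = rho.fillna(0.0)

    def order_axis(mat: np.ndarray, labels: list[str]):
        if len(labels) < 2:
            return list(labels), None
        # deterministic tie-break: rows pre-sorted by label
        idx = np.argsort(labels)
        Z = hierarchy.linkage(_one_minus_spearman_dist(mat[idx]), method=linkage)
        leaves = hierarchy.leaves_list(Z)
        return [labels[idx[i]] for i in leaves], Z

    row_order, row_Z = order_axis(rho.to_numpy(dtype=float), list(rho.index))
    col_order, col_Z = order_axis(rho.to_numpy(dtype=float).T, list(rho.columns))
    return row_order, col_order, row_Z, col_Z
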