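"""Phenotypic distance in principal-component space with a Poisson null.

The screening statistic: well profiles (robust-Z scaled features) are
projected onto principal components — at least 20 retained, enough to
exceed 60% of variance — and each well's Euclidean distance to its
plate's DMSO reference point is computed in that score space. Distances
are converted to p-values under a Poisson null whose rate λ is the mean
of the observed distance distribution, evaluated for non-integer
distances by the regularized-incomplete-gamma continuous extension

    P(X >= d) = P_reg(d, λ)   (p(0) ≡ 1),

which agrees with the integer Poisson tail at every integer d. Replicate
(well) distances are medianed per compound x dose x cell line; the
treatment p-value is the Poisson tail at the median distance under the
pooled λ, and q-values come from Benjamini-Hochberg (or
Benjamini-Yekutieli) FDR across treatments within a cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_plate import FeatureTable


@dataclass
class ComponentModel:
    """Principal components retained under the >=20 / >60%-variance rule."""

    loadings: np.ndarray          # features x m
    mean: np.ndarray              # feature means used for centering
    explained_variance: np.ndarray  # per-component fractions (all components)
    m: int
    feature_names: list[str]
    k_min: int = 20
    var_target: float = 0.60


def retained_components(explained: np.ndarray, k_min: int, var_target: float,
                        cap: int) -> int:
    """Smallest m' whose cumulative variance fraction exceeds ``var_target``,
    floored at ``k_min`` and capped at the available component count."""
    cum = np.cumsum(explained)
    above = np.flatnonzero(cum > var_target)
    m_prime = int(above[0]) + 1 if len(above) else cap
    return min(max(k_min, m_prime), cap)


def fit_components(scaled: FeatureTable | pd.DataFrame | np.ndarray,
                   k_min: int = 20, var_target: float = 0.60,
                   feature_names: list[str] | None = None) -> ComponentModel:
    """Fit PCA on the well x feature matrix and retain components per the rule.

    Component signs are fixed by making each loading vector's
    largest-magnitude entry positive, so the decomposition is
    deterministic.
    """
    if isinstance(scaled, FeatureTable):
        X = scaled.matrix
        feature_names = list(scaled.feature_names)
    else:
        X = np.asarray(scaled, dtype=float)
        feature_names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for component analysis")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    pca = PCA(svd_solver="full").fit(X)
    explained = pca.explained_variance_ratio_
    cap = pca.components_.shape[0]
    m = retained_components(explained, k_min, var_target, cap)
    loadings = pca.components_[:m].T.copy()  # features x m
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    return ComponentModel(loadings=loadings, mean=pca.mean_, explained_variance=explained,
                          m=m, feature_names=feature_names,
                          k_min=k_min, var_target=var_target)


def score_wells(model: ComponentModel, table: FeatureTable) -> pd.DataFrame:
    """Project wells onto the retained components; returns metadata + PC columns."""
    missing = [f for f in model.feature_names if f not in table.feature_names]
    if missing:
        raise ValueError(f"table lacks model features: {missing[:10]}")
    X = table.data[model.feature_names].to_numpy(dtype=float)
    scores = (X - model.mean) @ model.loadings
    out = table.metadata.copy()
    pc_cols = [f"PC{i + 1}" for i in range(model.m)]
    out[pc_cols] = scores
    return out


def score_columns(scores: pd.DataFrame) -> list[str]:
    return [c for c in scores.columns if c.startswith("PC")]


def phenotypic_distance(scores: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance of each well to its plate's DMSO reference point.

    The reference is the component-wise median of the plate's DMSO
    scores; plates are treated separately. Returns the score table with a
    ``distance`` column appended.
    """
    pcs = score_columns(scores)
    if not pcs:
        raise ValueError("no PC columns in score table")
    out = scores.copy()
    out["distance"] = np.nan
    for plate, idx in scores.groupby("plate").groups.items():
        sub = scores.loc[idx]
        dmso = sub[sub["role"] == "dmso"]
        if dmso.empty:
            raise ValueError(f"plate {plate!r} has no DMSO control scores")
        ref = dmso[pcs].median(axis=0).to_numpy()
        diff = sub[pcs].to_numpy() - ref
        out.loc[idx, "distance"] = np.sqrt((diff ** 2).sum(axis=1))
    return out


def poisson_tail(d: np.ndarray | float, lam: float) -> np.ndarray:
    """Continuous-extension Poisson upper tail P(X >= d) with X ~ Poisson(λ).

    Evaluated as the regularized lower incomplete gamma P_reg(d, λ)
    (shape d, argument λ), which equals the discrete tail at integer d;
    p(0) ≡ 1 by convention.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    with np.errstate(invalid="ignore"):
        p = special.gammainc(d, lam)
    p = np.where(d == 0, 1.0, p)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def poisson_pvalue(distances: np.ndarray) -> tuple[float, np.ndarray]:
    """λ = mean of the observed distance distribution; per-replicate tail p."""
    d = np.asarray(distances, dtype=float)
    if len(d) < 2:
        raise ValueError("need >= 2 distances to estimate lambda")
    lam = float(d.mean())
    return lam, poisson_tail(d, lam)


def replicate_pvalues(dist_table: pd.DataFrame, lambda_scope: str = "plate",
                      lambda_reference: str = "all") -> pd.DataFrame:
    """Attach λ and per-replicate p-values to a distance table.

    ``lambda_scope``: "plate" estimates λ from each plate's distance
    distribution (plates vary; mixing replicate distributions is
    avoided); "pooled" uses the whole table. ``lambda_reference``:
    "all" uses every well's distance (default), "dmso" restricts to
    vehicle wells.
    """
    out = dist_table.copy()
    out["lambda"] = np.nan
    groups = ([("all", out.index)] if lambda_scope == "pooled"
              else list(out.groupby("plate").groups.items()))
    for _, idx in groups:
        sub = out.loc[idx]
        pool = sub[sub["role"] == "dmso"] if lambda_reference == "dmso" else sub
        lam = float(pool["distance"].mean())
        out.loc[idx, "lambda"] = lam
        out.loc[idx, "p_r"] = poisson_tail(sub["distance"].to_numpy(), lam)
    return out


def summarize_and_fdr(records: pd.DataFrame, fdr_method: str = "bh") -> pd.DataFrame:
    """Collapse replicate wells to treatments and FDR-adjust.

    Input: per-well rows with compound, dose_nM, cell_line, distance.
    The pooled λ is the mean of the line's full observed distance
    distribution — every well, controls included. Per compound x dose x
    line (sample wells): d_med = median replicate distance; p = Poisson
    tail at d_med under the pooled λ; q = BH (or BY) across treatments
    within each cell line.
    """
    if fdr_method not in ("bh", "by"):
        raise ValueError("fdr_method must be 'bh' or 'by'")
    samples = records[records["role"] == "sample"] if "role" in records.columns else records
    if samples.empty:
        raise ValueError("no treatment records to summarize")
    rows = []
    lam_by_line = records.groupby("cell_line", dropna=False)["distance"].mean()
    for line, line_df in samples.groupby("cell_line", dropna=False):
        lam_pooled = float(lam_by_line.loc[line])
        summ = (line_df.groupby(["compound", "dose_nM"], dropna=False)["distance"]
                .agg(d_med="median", n_replicates="size").reset_index())
        summ["cell_line"] = line
        summ["lambda"] = lam_pooled
        summ["p"] = poisson_tail(summ["d_med"].to_numpy(), lam_pooled)
        method = "fdr_bh" if fdr_method == "bh" else "fdr_by"
        summ["q"] = multipletests(summ["p"].to_numpy(), method=method)[1]
        rows.append(summ)
    out = pd.concat(rows, ignore_index=True)
    out["neglog10p"] = -np.log10(out["p"])
    cols = ["compound", "dose_nM", "cell_line", "n_replicates", "d_med",
            "lambda", "p", "q", "neglog10p"]
    return out[cols]


def profile_screen(scaled: FeatureTable, k_min: int = 20, var_target: float = 0.60,
                   fdr_method: str = "bh", lambda_scope: str = "plate") -> pd.DataFrame:
    """Scaled well table -> treatment-level distance/p/q table (full stage)."""
    model = fit_components(scaled, k_min=k_min, var_target=var_target)
    scores = score_wells(model, scaled)
    dist = phenotypic_distance(scores)
    dist = replicate_pvalues(dist, lambda_scope=lambda_scope)
    return summarize_and_fdr(dist, fdr_method=fdr_method)
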