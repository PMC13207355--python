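"""Per-plate preprocessing of cell-painting feature tables.

The chain turns raw field-level features into plate-normalized,
robust-Z-scaled well profiles:

    aggregate fields -> (QC-exclude flagged fields) -> drop redundant
    features -> normalize to plate controls -> transform skewed features
    -> robust-Z scale

Stages are tracked on the table and must run in contract order. The
normalization reference is the plate's DMSO wells by default (all sample
wells optionally); redundant features are removed above an absolute
Pearson correlation of 0.99; a feature is log-transformed when a
D'Agostino skewness test on the reference wells is significant at
0.0001; and scaling uses the robust Z score (median / 1.4826 x MAD),
per plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_plate import FeatureTable, PipelineStateError, PlateFormatError

MAD_CONSISTENCY = 1.4826  # Gaussian consistency constant for the MAD


@dataclass
class ProcessingConfig:
    corr_cutoff: float = 0.99
    skew_alpha: float = 1e-4
    qc_flag_fraction_max: float = 0.05
    qc_quantile: float = 0.995
    reference: str = "dmso"  # or "all_samples"

    def __post_init__(self):
        if not (0 < self.corr_cutoff <= 1):
            raise ValueError("corr_cutoff must be in (0, 1]")
        if not (0 < self.skew_alpha < 1):
            raise ValueError("skew_alpha must be in (0, 1)")
        if self.reference not in ("dmso", "all_samples"):
            raise ValueError("reference must be 'dmso' or 'all_samples'")


def _reference_mask(data: pd.DataFrame, reference: str) -> pd.Series:
    role = data["role"] if "role" in data.columns else pd.Series("sample", index=data.index)
    return role == ("dmso" if reference == "dmso" else "sample")


def aggregate_fields(table: FeatureTable,
                     exclude: set[tuple] | None = None) -> FeatureTable:
    """Median-aggregate field-level rows to one row per well.

    ``exclude`` is a set of flagged ``(plate, well, field)`` addresses
    (e.g. from :func:`qc_flag_images`) dropped before taking the per-well
    median. Wells losing every field are dropped with a warning.
    """
    if table.level != "field":
        raise PipelineStateError("aggregate_fields requires a field-level table")
    table.require_stage("raw")
    df = table.data
    if exclude:
        keys = list(zip(df["plate"], df["well"], df["field"]))
        keep = ~pd.Series([k in exclude for k in keys], index=df.index)
        dropped_wells = set(zip(df["plate"], df["well"])) - set(
            zip(df.loc[keep, "plate"], df.loc[keep, "well"]))
        if dropped_wells:
            warnings.warn(f"{len(dropped_wells)} well(s) lost all fields to QC flags "
                          f"and were dropped")
        df = df[keep]
    meta_cols = [c for c in ("plate", "well", "cell_line", "compound", "dose_nM", "role")
                 if c in df.columns]
    grouped = df.groupby(meta_cols, dropna=False, sort=True, as_index=False)
    agg = grouped[table.feature_names].median()
    return FeatureTable(agg.reset_index(drop=True), list(table.feature_names),
                        level="well", stage="aggregated")


def qc_flag_images(qc_table: FeatureTable, quantile: float = 0.995,
                   flag_fraction_max: float = 0.05) -> tuple[set[tuple], float]:
    """Flag outlying fields from image-level QC features.

    QC features are standardized and projected by PCA; each field's
    robust squared distance in score space (per-component median/MAD
    standardization) is compared to a chi-square reference at the given
    quantile. Returns the flagged ``(plate, well, field)`` set and the
    flagged fraction; warns when the fraction exceeds
    ``flag_fraction_max`` (plate review advised).
    """
    X = qc_table.matrix
    sd = X.std(axis=0)
    informative = sd > 0
    if not informative.any():
        return set(), 0.0
    Z = (X[:, informative] - X[:, informative].mean(axis=0)) / sd[informative]
    n_comp = min(Z.shape[0] - 1, Z.shape[1], 10)
    if n_comp < 1:
        return set(), 0.0
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(Z)
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * MAD_CONSISTENCY
    mad[mad == 0] = 1.0
    d2 = (((scores - med) / mad) ** 2).sum(axis=1)
    thresh = stats.chi2.ppf(quantile, df=n_comp)
    flagged_idx = np.flatnonzero(d2 > thresh)
    df = qc_table.data
    flagged = {(df["plate"].iat[i], df["well"].iat[i], df["field"].iat[i])
               for i in flagged_idx}
    frac = len(flagged_idx) / len(df)
    if frac > flag_fraction_max:
        warnings.warn(f"QC flagged {frac:.1%} of fields (> {flag_fraction_max:.1%}); "
                      f"plate review advised")
    return flagged, frac


def remove_redundant_features(table: FeatureTable,
                              cutoff: float = 0.99) -> tuple[FeatureTable, list[str]]:
    """Drop later features whose |Pearson r| with an earlier kept feature exceeds cutoff.

    A single greedy pass in feature (column) order; the surviving set has
    no pair above the cutoff. Returns the filtered table and the dropped
    feature names.
    """
    if table.level != "well":
        raise PipelineStateError("redundancy filter runs on well-level tables")
    table.require_stage("raw", "aggregated")
    X = table.matrix
    if X.shape[1] < 2:
        raise PlateFormatError("need at least 2 features")
    sd = X.std(axis=0)
    if not (sd > 0).any():
        raise PlateFormatError("no informative features (all constant)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant features correlate with nothing
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        if kept and np.any(np.abs(corr[j, kept]) > cutoff):
            dropped.append(table.feature_names[j])
        else:
            kept.append(j)
    names = [table.feature_names[j] for j in kept]
    out = pd.concat([table.metadata.reset_index(drop=True),
                     pd.DataFrame(X[:, kept], columns=names)], axis=1)
    return FeatureTable(out, names, level="well", stage="filtered"), dropped


def normalize_to_controls(table: FeatureTable,
                          config: ProcessingConfig | None = None) -> FeatureTable:
    """Center each feature on its per-plate reference median (DMSO by default)."""
    config = config or ProcessingConfig()
    table.require_stage("filtered")
    df = table.data
    ref = _reference_mask(df, config.reference)
    out_blocks = []
    for plate, idx in df.groupby("plate").groups.items():
        sub = df.loc[idx]
        ref_sub = sub[ref.loc[idx]]
        if len(ref_sub) < 8:
            raise PlateFormatError(
                f"plate {plate!r} has {len(ref_sub)} reference wells (need >= 8)")
        med = ref_sub[table.feature_names].median(axis=0)
        block = sub.copy()
        block[table.feature_names] = sub[table.feature_names] - med
        out_blocks.append(block)
    out = pd.concat(out_blocks).loc[df.index]
    return FeatureTable(out, list(table.feature_names), level="well", stage="normalized")


def transform_skewed(table: FeatureTable,
                     config: ProcessingConfig | None = None
                     ) -> tuple[FeatureTable, list[str]]:
    """Signed-log transform features whose reference wells fail a skewness test.

    Per feature, a D'Agostino skewness test runs on the reference wells
    (pooled across plates); when p < ``skew_alpha`` the whole column is
    mapped through sign(x) * log1p(|x| / s), s the reference MAD.
    Features with < 8 reference values or zero MAD pass through.
    """
    config = config or ProcessingConfig()
    table.require_stage("normalized")
    df = table.data.copy()
    ref = _reference_mask(df, config.reference)
    transformed: list[str] = []
    for name in table.feature_names:
        x_ref = df.loc[ref, name].to_numpy(dtype=float)
        x_ref = x_ref[np.isfinite(x_ref)]
        if len(x_ref) < 8 or np.ptp(x_ref) == 0:
            continue
        try:
            _, p = stats.skewtest(x_ref)
        except ValueError:
            continue
        if p < config.skew_alpha:
            s = np.median(np.abs(x_ref - np.median(x_ref))) * MAD_CONSISTENCY
            if s == 0:
                continue
            col = df[name].to_numpy(dtype=float)
            df[name] = np.sign(col) * np.log1p(np.abs(col) / s)
            transformed.append(name)
    return FeatureTable(df, list(table.feature_names), level="well",
                        stage="transformed"), transformed


def robust_z_scale(table: FeatureTable,
                   config: ProcessingConfig | None = None
                   ) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Robust Z per plate and feature: z = (x - median_ref) / (1.4826 * MAD_ref).

    Features with zero reference MAD on a plate are set to 0 there and
    returned in the degenerate list as (plate, feature).
    """
    config = config or ProcessingConfig()
    table.require_stage("transformed", "scaled")
    df = table.data
    ref = _reference_mask(df, config.reference)
    degenerate: list[tuple[str, str]] = []
    out_blocks = []
    for plate, idx in df.groupby("plate").groups.items():
        sub = df.loc[idx]
        ref_vals = sub.loc[ref.loc[idx], table.feature_names].to_numpy(dtype=float)
        med = np.median(ref_vals, axis=0)
        mad = np.median(np.abs(ref_vals - med), axis=0) * MAD_CONSISTENCY
        z = (sub[table.feature_names].to_numpy(dtype=float) - med)
        ok = mad > 0
        z[:, ok] = z[:, ok] / mad[ok]
        z[:, ~ok] = 0.0
        for j in np.flatnonzero(~ok):
            degenerate.append((str(plate), table.feature_names[j]))
        block = sub.copy()
        block[table.feature_names] = z
        out_blocks.append(block)
    out = pd.concat(out_blocks).loc[df.index]
    return FeatureTable(out, list(table.feature_names), level="well",
                        stage="scaled"), degenerate


def preprocess_screen(table: FeatureTable, config: ProcessingConfig | None = None,
                      qc_table: FeatureTable | None = None) -> tuple[FeatureTable, dict]:
    """Run the full chain on a field-level table; returns (scaled table, report)."""
    config = config or ProcessingConfig()
    report: dict = {}
    exclude: set[tuple] = set()
    if qc_table is not None:
        exclude, frac = qc_flag_images(qc_table, config.qc_quantile,
                                       config.qc_flag_fraction_max)
        report["qc_flagged_fraction"] = frac
        report["qc_flagged_fields"] = sorted(map(list, exclude))
    well_table = aggregate_fields(table, exclude) if table.level == "field" else table
    filtered, dropped = remove_redundant_features(well_table, config.corr_cutoff)
    report["dropped_features"] = dropped
    normed = normalize_to_controls(filtered, config)
    transformed, tlist = transform_skewed(normed, config)
    report["transformed_features"] = tlist
    scaled, degen = robust_z_scale(transformed, config)
    report["degenerate_mad"] = degen
    report["n_features_out"] = len(scaled.feature_names)
    return scaled, report
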