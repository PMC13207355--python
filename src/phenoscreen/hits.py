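"""Hit selection: survival robust Z, plate Z' QC, dual-threshold calls, triage.

A compound is a hit in a cell line when it crosses the cell-survival
threshold (nuclei-count robust Z < -3) and/or the phenotypic-distance
threshold (-log10 p > 2); it is a primary hit when it does so in at
least two lines. Plate quality is gated by robust Z'
(1 - 3(σ̃_pos + σ̃_neg)/|m̃_pos - m̃_neg| > 0.35) computed from the
positive (staurosporine) and negative (DMSO) control nuclei counts.
Triage de-prioritizes hits by MOA blocklist (overtly cytotoxic classes)
or activity confined to the top tested concentration; nothing is
deleted, reasons are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MAD_CONSISTENCY

DEFAULT_Z_THRESH = -3.0
DEFAULT_P_THRESH = 2.0
DEFAULT_MIN_LINES = 2
ZPRIME_THRESHOLD = 0.35

#: MOA classes de-prioritized by default as overtly cytotoxic.
DEFAULT_MOA_BLOCKLIST = ("microtubule", "topoisomerase", "proteasome")


def _robust_stats(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    sigma = float(np.median(np.abs(x - med)) * MAD_CONSISTENCY)
    return med, sigma


def survival_zscore(counts: pd.DataFrame, count_col: str = "count") -> pd.DataFrame:
    """Per-well survival robust Z of nuclei counts vs the plate's DMSO wells.

    ``counts``: rows with plate, role and a count column. Returns the
    table with a ``survival_z`` column; a plate whose DMSO counts have
    zero MAD raises.
    """
    out = counts.copy()
    out["survival_z"] = np.nan
    for plate, idx in counts.groupby("plate").groups.items():
        sub = counts.loc[idx]
        dmso = sub.loc[sub["role"] == "dmso", count_col].to_numpy(dtype=float)
        if len(dmso) < 8:
            raise ValueError(f"plate {plate!r} has {len(dmso)} DMSO wells (need >= 8)")
        med, sigma = _robust_stats(dmso)
        if sigma == 0:
            raise ValueError(f"plate {plate!r}: zero MAD in DMSO nuclei counts")
        out.loc[idx, "survival_z"] = (sub[count_col].to_numpy(dtype=float) - med) / sigma
    return out


def treatment_survival(agg_table, count_col: str = "Count_nuclei") -> pd.DataFrame:
    """Treatment-level survival Z from a well-level aggregated feature table.

    Computes per-well robust Z of the nuclei-count feature against each
    plate's DMSO wells, then medians over replicate wells per
    compound x dose x cell line (sample wells only).
    """
    df = agg_table.data if hasattr(agg_table, "data") else agg_table
    cols = [c for c in ("plate", "well", "cell_line", "compound", "dose_nM", "role")
            if c in df.columns]
    counts = df[cols].copy()
    counts["count"] = df[count_col].to_numpy(dtype=float)
    z = survival_zscore(counts)
    samples = z[z["role"] == "sample"]
    return (samples.groupby(["compound", "dose_nM", "cell_line"], dropna=False)
            ["survival_z"].median().reset_index())


def zprime_robust(positive: np.ndarray, negative: np.ndarray) -> float:
    """Robust Z' = 1 - 3(σ̃_p + σ̃_n) / |m̃_p - m̃_n| (median / scaled-MAD form).

    Returns -inf (with a warning) when the control medians coincide.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 4 or len(neg) < 4:
        raise ValueError("need >= 4 wells in each control group")
    m_p, s_p = _robust_stats(pos)
    m_n, s_n = _robust_stats(neg)
    if m_p == m_n:
        warnings.warn("identical control medians; Z' undefined, returning -inf")
        return float("-inf")
    return 1.0 - 3.0 * (s_p + s_n) / abs(m_p - m_n)


def plate_qc(counts: pd.DataFrame, count_col: str = "count",
             threshold: float = ZPRIME_THRESHOLD) -> pd.DataFrame:
    """Per-plate robust Z' from positive/DMSO control counts; pass ⇔ Z' > threshold."""
    rows = []
    for plate, sub in counts.groupby("plate"):
        pos = sub.loc[sub["role"] == "positive", count_col].to_numpy(dtype=float)
        neg = sub.loc[sub["role"] == "dmso", count_col].to_numpy(dtype=float)
        zp = zprime_robust(pos, neg)
        rows.append({"plate": plate, "zprime_robust": zp, "pass": zp > threshold})
    return pd.DataFrame(rows)


def select_hits(records: pd.DataFrame, z_thresh: float = DEFAULT_Z_THRESH,
                p_thresh: float = DEFAULT_P_THRESH, min_lines: int = DEFAULT_MIN_LINES,
                dose_collapse: str = "best") -> pd.DataFrame:
    """Dual-threshold, multi-line hit call.

    ``records``: per compound x dose x cell line rows with ``survival_z``
    and ``neglog10p``. Doses collapse per compound x line either to the
    most significant dose (``"best"``: max neglog10p) or to a pass at
    any dose (``"any"``). A line is hit when survival_z < z_thresh OR
    neglog10p > p_thresh (strict); a compound is a primary hit when hit
    in >= ``min_lines`` lines. Returns one row per compound x line plus
    compound-level flags.
    """
    if dose_collapse not in ("best", "any"):
        raise ValueError("dose_collapse must be 'best' or 'any'")
    n_lines = records["cell_line"].nunique()
    if n_lines < min_lines:
        raise ValueError(f"{n_lines} cell line(s) present but min_lines={min_lines}")

    df = records.copy()
    df["_pass"] = (df["survival_z"] < z_thresh) | (df["neglog10p"] > p_thresh)
    collapsed = []
    for (cpd, line), sub in df.groupby(["compound", "cell_line"], dropna=False):
        if dose_collapse == "best":
            row = sub.loc[sub["neglog10p"].idxmax()]
            hit = bool(row["_pass"])
        else:
            row = sub.loc[sub["neglog10p"].idxmax()]
            hit = bool(sub["_pass"].any())
        collapsed.append({
            "compound": cpd, "cell_line": line, "dose_nM": row["dose_nM"],
            "survival_z": row["survival_z"], "neglog10p": row["neglog10p"],
            "is_hit_in_line": hit,
        })
    out = pd.DataFrame(collapsed)
    n_hit = out.groupby("compound")["is_hit_in_line"].sum().rename("n_lines_hit")
    out = out.merge(n_hit, on="compound")
    out["is_primary_hit"] = out["n_lines_hit"] >= min_lines
    return out


def hit_summary(hits: pd.DataFrame) -> dict:
    """Counts a screener reports: candidates, per-line hits, primary hits."""
    per_line = (hits.groupby("cell_line")["is_hit_in_line"].sum().astype(int).to_dict())
    primary = hits.loc[hits["is_primary_hit"], "compound"].nunique()
    return {
        "n_compounds": int(hits["compound"].nunique()),
        "hits_per_line": per_line,
        "n_primary_hits": int(primary),
    }


@dataclass
class TriageRules:
    moa_blocklist: tuple[str, ...] = DEFAULT_MOA_BLOCKLIST
    deprioritize_top_conc_only: bool = False
    top_conc_nM: float = 3000.0


def triage(hits: pd.DataFrame, annotations: pd.DataFrame | None = None,
           rules: TriageRules | None = None) -> pd.DataFrame:
    """Rule-driven de-prioritization of primary hits; nothing is deleted.

    ``annotations``: compound -> moa CSV-style table. A hit whose MOA
    contains a blocklisted class (case-insensitive substring) is
    de-prioritized; optionally, so is a hit active only at the top
    tested concentration. Unannotated compounds stay ``untriaged``.
    """
    rules = rules or TriageRules()
    out = hits.copy()
    moa_map: dict[str, str] = {}
    if annotations is not None:
        moa_map = dict(zip(annotations["compound"], annotations["moa"].astype(str)))

    statuses, reasons = [], []
    top_only: set[str] = set()
    if rules.deprioritize_top_conc_only and "dose_nM" in out.columns:
        for cpd, sub in out[out["is_hit_in_line"]].groupby("compound"):
            if (sub["dose_nM"] == rules.top_conc_nM).all():
                top_only.add(cpd)
    for row in out.itertuples(index=False):
        if not row.is_primary_hit:
            statuses.append("untriaged")
            reasons.append("not a primary hit")
            continue
        moa = moa_map.get(row.compound)
        if moa is None:
            statuses.append("untriaged")
            reasons.append("no MOA annotation")
            continue
        blocked = [b for b in rules.moa_blocklist if b.lower() in moa.lower()]
        if blocked:
            statuses.append("deprioritized")
            reasons.append(f"MOA class blocklisted: {blocked[0]}")
        elif row.compound in top_only:
            statuses.append("deprioritized")
            reasons.append(f"active only at top concentration ({rules.top_conc_nM:g} nM)")
        else:
            statuses.append("priority")
            reasons.append("")
    out["triage_status"] = statuses
    out["triage_reason"] = reasons
    return out
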