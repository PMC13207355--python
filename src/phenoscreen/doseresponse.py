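"""Dose-response validation: viability normalization, nAUC, logistic IC50.

Viability is the DMSO-normalized nuclei-count fraction per plate. Two
summaries are computed per compound x line:

* nAUC — trapezoidal integral of viability (clipped to [0, 1]) over
  log10(dose), divided by the log-dose span, so 1 means fully viable at
  every dose and 0 means complete death everywhere. Compounds validate
  when nAUC < 0.85 in at least one line.
* the normalized variable-slope logistic inhibition model

      Y = 100 / (1 + 10^((LogIC50 - X) * HillSlope)),

  X = log10(molar concentration), fit by nonlinear least squares for
  LogIC50 and HillSlope (HillSlope constrained negative: inhibition),
  with a profile-likelihood 95% CI for LogIC50. Flat or non-convergent
  curves are reported inactive rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_NAUC_THRESHOLD = 0.85


@dataclass
class DoseResponseFit:
    compound: str
    cell_line: str
    log_ic50: float          # log10 molar
    hill_slope: float
    ic50_nM: float           # 10^(LogIC50 + 9)
    ci95: tuple[float, float]
    nauc: float
    converged: bool
    inactive: bool


def normalize_viability(counts: pd.DataFrame, count_col: str = "count") -> pd.DataFrame:
    """Viability = count / median(plate DMSO counts), per plate."""
    out = counts.copy()
    out["viability"] = np.nan
    for plate, idx in counts.groupby("plate").groups.items():
        sub = counts.loc[idx]
        dmso = sub.loc[sub["role"] == "dmso", count_col].to_numpy(dtype=float)
        if len(dmso) == 0:
            raise ValueError(f"plate {plate!r} has no DMSO wells")
        med = float(np.median(dmso))
        if med == 0:
            raise ValueError(f"plate {plate!r}: DMSO median count is 0")
        out.loc[idx, "viability"] = sub[count_col].to_numpy(dtype=float) / med
    return out


def compute_nauc(doses_nM: np.ndarray, viability: np.ndarray, clip: bool = True) -> float:
    """Normalized AUC in [0, 1] over log10(dose); requires >= 2 dose points.

    Unit-invariant: rescaling all doses by a constant shifts log-dose but
    not the spacing, leaving nAUC unchanged.
    """
    doses = np.asarray(doses_nM, dtype=float)
    y = np.asarray(viability, dtype=float)
    if len(doses) < 2:
        raise ValueError("nAUC needs >= 2 dose points")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    order = np.argsort(doses)
    x = np.log10(doses[order])
    y = y[order]
    if clip:
        y = np.clip(y, 0.0, 1.0)
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("doses must span more than one log point")
    return float(np.trapezoid(y, x) / span)


def _logistic_percent(x: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def fit_logistic(doses_nM: np.ndarray, viability: np.ndarray,
                 compound: str = "", cell_line: str = "",
                 flat_span_pct: float = 10.0) -> DoseResponseFit:
    """Fit LogIC50/HillSlope on percent viability vs X = log10(molar dose).

    Curves that never fall below 50% viability, or whose fitted span
    across the tested range is < ``flat_span_pct`` percent, are reported
    inactive (no IC50). HillSlope is bounded negative.
    """
    doses = np.asarray(doses_nM, dtype=float)
    y_pct = np.asarray(viability, dtype=float) * 100.0
    if len(doses) < 4:
        raise ValueError("need >= 4 dose points to fit")
    x = np.log10(doses) - 9.0
    nauc = compute_nauc(doses, np.asarray(viability, dtype=float))

    def inactive_fit() -> DoseResponseFit:
        return DoseResponseFit(compound, cell_line, float("nan"), float("nan"),
                               float("nan"), (float("nan"), float("nan")),
                               nauc, converged=False, inactive=True)

    # mean per dose guards replicated tables
    df = pd.DataFrame({"x": x, "y": y_pct}).groupby("x", as_index=False).mean()
    if df["y"].min() > 50.0:
        return inactive_fit()

    def resid(theta):
        return _logistic_percent(x, theta[0], theta[1]) - y_pct

    x0_guess = df.loc[(df["y"] - 50.0).abs().idxmin(), "x"]
    sol = optimize.least_squares(
        resid, x0=[x0_guess, -1.0],
        bounds=([x.min() - 6.0, -20.0], [x.max() + 6.0, -1e-6]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    log_ic50, hill = sol.x
    fitted = _logistic_percent(x, log_ic50, hill)
    if not sol.success or (fitted.max() - fitted.min()) < flat_span_pct:
        return inactive_fit()

    ci = _profile_ci_logic50(x, y_pct, log_ic50, hill, float(sol.cost))
    return DoseResponseFit(compound, cell_line, float(log_ic50), float(hill),
                           float(10.0 ** (log_ic50 + 9.0)), ci, nauc,
                           converged=True, inactive=False)


def _profile_ci_logic50(x, y, log_ic50, hill, best_cost) -> tuple[float, float]:
    """Profile-likelihood 95% CI: SSR(θ) crossing SSR_min (1 + F(0.95;1,n-2)/(n-2))."""
    n = len(x)
    dof = n - 2
    if dof <= 0:
        return (float("nan"), float("nan"))
    ssr_min = 2.0 * best_cost  # least_squares cost = SSR/2
    if ssr_min <= 0:
        return (log_ic50, log_ic50)  # perfect fit: degenerate interval
    crit = ssr_min * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

    def profile_ssr(theta0: float) -> float:
        sol = optimize.least_squares(
            lambda h: _logistic_percent(x, theta0, h[0]) - y,
            x0=[hill], bounds=([-20.0], [-1e-6]))
        return 2.0 * float(sol.cost)

    def bracket(direction: float) -> float:
        step, theta = 0.05, log_ic50
        for _ in range(200):
            theta += direction * step
            if profile_ssr(theta) > crit:
                lo, hi = theta - direction * step, theta
                for _ in range(50):  # bisection
                    mid = 0.5 * (lo + hi)
                    if profile_ssr(mid) > crit:
                        hi = mid
                    else:
                        lo = mid
                return 0.5 * (lo + hi)
            step *= 1.5
        return float("nan")

    return (bracket(-1.0), bracket(+1.0))


def fit_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every compound x line in a long-format viability table."""
    rows = []
    for (cpd, line), sub in table.groupby(["compound", "cell_line"], dropna=False):
        f = fit_logistic(sub["dose_nM"].to_numpy(), sub["viability"].to_numpy(),
                         compound=str(cpd), cell_line=str(line))
        rows.append({
            "compound": f.compound, "cell_line": f.cell_line,
            "log_ic50": f.log_ic50, "hill_slope": f.hill_slope,
            "ic50_nM": f.ic50_nM, "ci95_lo": f.ci95[0], "ci95_hi": f.ci95[1],
            "nauc": f.nauc, "converged": f.converged, "inactive": f.inactive,
        })
    return pd.DataFrame(rows)


def rank_validation(fits: pd.DataFrame,
                    threshold: float = DEFAULT_NAUC_THRESHOLD) -> pd.DataFrame:
    """Validated ⇔ nAUC < threshold in >= 1 line (strict); reports min nAUC per compound."""
    summ = (fits.groupby("compound")["nauc"].min().rename("min_nauc").reset_index())
    summ["validated"] = summ["min_nauc"] < threshold
    return summ
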