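"""Synthetic multi-plate cell-painting screens with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* 384-well plates with DMSO vehicle controls (32-48 per plate), a strong
  cytotoxic positive control (16 per plate, staurosporine-like), and up
  to 320 sample wells;
* six imaging fields per well, with a nuclei-count feature drawn as a
  negative-binomial count (typically 75-150 cells per field);
* several hundred collinear morphological features produced by a
  latent-factor model (features = loadings x latent state), so that PCA
  recovers low-dimensional structure;
* additive per-plate offsets, skewed noise on a subset of features, and
  compound perturbations that shift morphology along latent factors
  (delta, in latent-sd units) and/or reduce nuclei counts (viability
  multiplier v);
* seven-point semi-log dose-response series (3-3,000 nM) following the
  normalized variable-slope logistic inhibition model.

Identical seeds reproduce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_plate import FeatureTable, format_well

#: Feature name carrying the per-field nuclei count.
NUCLEI_FEATURE = "Count_nuclei"

#: Default 7-point semi-log dose series, 3-3,000 nM (half-log steps).
DEFAULT_DOSES_NM = tuple(3.0 * 10 ** (0.5 * i) for i in range(7))

_ROWS = "ABCDEFGHIJKLMNOP"
_WELLS_384 = [format_well(r, c) for r in _ROWS for c in range(1, 25)]


class ConfigError(ValueError):
    """Raised when a screen configuration cannot fit the plate budget."""


@dataclass
class ScreenConfig:
    """Layout and generative parameters for one simulated screen."""

    n_plates: int = 2
    n_features: int = 300          # full-scale option: 1006
    n_fields: int = 6
    n_dmso: int = 48               # 32-48 vehicle wells per plate
    n_positive: int = 16           # staurosporine-like wells per plate
    n_latent: int = 10
    n_compounds: int | None = None  # default: fill every sample well
    n_replicates: int = 2          # wells per compound x dose
    doses_nM: tuple[float, ...] = (1000.0,)
    cell_line: str = "LINE1"
    plate_effect_sd: float = 0.5
    noise_sd: float = 0.4          # per-field feature noise
    latent_sd: float = 1.0         # well-to-well biological variability
    skew: float = 0.8              # exponential-transform strength on skewed features
    skew_fraction: float = 0.2     # fraction of features given skewed noise
    block_corr: float = 0.7        # within-block loading similarity, [0, 1)
    nuclei_mean: float = 110.0     # mean nuclei per field (75-150 range)
    nuclei_dispersion: float = 30.0  # negative-binomial size parameter
    effect_grid: tuple[tuple[float, float], ...] = (
        (3.0, 0.25), (4.0, 0.30), (5.0, 0.25), (3.5, 0.20),
    )
    positive_effect: tuple[float, float] = (6.0, 0.15)
    fraction_null: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not (32 <= self.n_dmso <= 48):
            raise ConfigError(f"n_dmso must be in [32, 48], got {self.n_dmso}")
        if not (0.0 <= self.fraction_null <= 1.0):
            raise ConfigError("fraction_null must be in [0, 1]")
        if not (0.0 <= self.block_corr < 1.0):
            raise ConfigError("block_corr must be in [0, 1)")
        if self.n_dmso + self.n_positive >= 384:
            raise ConfigError("control wells exceed the 384-well budget")

    @property
    def samples_per_plate(self) -> int:
        return 384 - self.n_dmso - self.n_positive

    @property
    def well_budget(self) -> int:
        return self.n_plates * self.samples_per_plate


@dataclass
class SyntheticTruth:
    """Per-compound ground truth: null flag, morphology shift, viability."""

    compounds: pd.DataFrame  # compound, is_null, delta, viability, factors

    def table(self) -> pd.DataFrame:
        """Exportable ground-truth table (one row per compound)."""
        out = self.compounds.copy()
        out["active"] = ~out["is_null"]
        return out


def _loading_matrix(rng: np.random.Generator, n_features: int, n_latent: int,
                    block_corr: float) -> np.ndarray:
    """Loadings with correlated feature blocks: features in a block share a
    template loading vector, mixed with an independent part."""
    n_blocks = max(n_latent, n_features // 30)
    templates = rng.normal(size=(n_blocks, n_latent))
    block_of = rng.integers(0, n_blocks, size=n_features)
    indiv = rng.normal(size=(n_features, n_latent))
    w = math.sqrt(block_corr)
    load = w * templates[block_of] + math.sqrt(1.0 - block_corr) * indiv
    return load


def _make_truth(rng: np.random.Generator, n_compounds: int,
                config: ScreenConfig) -> tuple[SyntheticTruth, np.ndarray]:
    """Draw per-compound ground truth and unit latent shift directions."""
    n_active = int(round(n_compounds * (1.0 - config.fraction_null)))
    active_idx = rng.choice(n_compounds, size=n_active, replace=False)
    is_null = np.ones(n_compounds, dtype=bool)
    is_null[active_idx] = False
    deltas = np.zeros(n_compounds)
    viab = np.ones(n_compounds)
    factor_lists: list[tuple[int, ...]] = [()] * n_compounds
    grid = list(config.effect_grid)
    for j, c in enumerate(sorted(active_idx)):
        d, v = grid[j % len(grid)]
        deltas[c], viab[c] = d, v
        k = int(rng.integers(1, min(3, config.n_latent) + 1))
        factor_lists[c] = tuple(sorted(rng.choice(config.n_latent, size=k, replace=False)))
    compounds = [f"CPD{i + 1:04d}" for i in range(n_compounds)]
    truth = SyntheticTruth(pd.DataFrame({
        "compound": compounds,
        "is_null": is_null,
        "delta": deltas,
        "viability": viab,
        "factors": [";".join(map(str, f)) for f in factor_lists],
    }))
    directions = np.zeros((n_compounds, config.n_latent))
    for c in range(n_compounds):
        if factor_lists[c]:
            u = np.zeros(config.n_latent)
            u[list(factor_lists[c])] = rng.normal(size=len(factor_lists[c]))
            directions[c] = u / np.linalg.norm(u)
    return truth, directions


def simulate_screen(config: ScreenConfig,
                    shared_truth: tuple[SyntheticTruth, np.ndarray] | None = None
                    ) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a field-level feature table for one cell line.

    Wells are laid out per plate: ``n_dmso`` DMSO wells, ``n_positive``
    positive-control wells, and sample wells for compound x dose
    replicates. Each well's morphology is a latent state (baseline
    variability plus the compound's shift along its affected factors)
    pushed through a loading matrix, plus a per-plate additive offset and
    per-field noise; a subset of features receives exponentially skewed
    noise. The nuclei-count feature is a negative-binomial count whose
    mean is scaled by the compound's viability multiplier.
    """
    rng = np.random.default_rng(config.seed)
    n_treat_wells = config.n_replicates * len(config.doses_nM)
    if config.n_compounds is None:
        n_compounds = config.well_budget // n_treat_wells
    else:
        n_compounds = config.n_compounds
    if n_compounds * n_treat_wells > config.well_budget:
        raise ConfigError(
            f"{n_compounds} compounds x {n_treat_wells} wells exceed the "
            f"budget of {config.well_budget} sample wells"
        )

    if shared_truth is None:
        truth, directions = _make_truth(rng, n_compounds, config)
    else:
        truth, directions = shared_truth
        if len(truth.compounds) != n_compounds:
            raise ConfigError("shared truth does not match n_compounds")
    compounds = list(truth.compounds["compound"])
    deltas = truth.compounds["delta"].to_numpy()
    viab = truth.compounds["viability"].to_numpy()
    pos_dir = np.zeros(config.n_latent)
    pos_dir[0] = 1.0

    loadings = _loading_matrix(rng, config.n_features, config.n_latent, config.block_corr)
    skewed = rng.random(config.n_features) < config.skew_fraction
    feature_names = [NUCLEI_FEATURE] + [f"Feat_{i + 1:04d}" for i in range(config.n_features - 1)]

    # Assign sample wells: compound x dose x replicate, round-robin over plates.
    assignments = [(c, d) for c in range(n_compounds) for d in config.doses_nM
                   for _ in range(config.n_replicates)]
    rng.shuffle(assignments)

    rows_meta = []
    latent_states = []
    viab_mults = []
    per_assign = 0
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:02d}"
        well_iter = iter(_WELLS_384)
        plate_wells: list[tuple[str, str, str | None, float | None, str,
                                np.ndarray, float]] = []
        for _ in range(config.n_dmso):
            plate_wells.append((plate_id, next(well_iter), None, None, "dmso",
                                np.zeros(config.n_latent), 1.0))
        for _ in range(config.n_positive):
            d, v = config.positive_effect
            plate_wells.append((plate_id, next(well_iter), "staurosporine", 1000.0,
                                "positive", d * pos_dir, v))
        for _ in range(config.samples_per_plate):
            if per_assign >= len(assignments):
                break
            c, dose = assignments[per_assign]
            per_assign += 1
            plate_wells.append((plate_id, next(well_iter), compounds[c], dose,
                                "sample", deltas[c] * directions[c], viab[c]))
        for plate, well, cpd, dose, role, shift, v in plate_wells:
            z = shift + rng.normal(scale=config.latent_sd, size=config.n_latent)
            for f in range(1, config.n_fields + 1):
                rows_meta.append((plate, well, f, config.cell_line, cpd, dose, role))
                latent_states.append(z)
                viab_mults.append(v)

    latent = np.asarray(latent_states)
    signal = latent @ loadings.T  # (rows, n_features)

    # Per-plate additive offsets (recomputed deterministically per plate order).
    meta = pd.DataFrame(rows_meta, columns=["plate", "well", "field", "cell_line",
                                            "compound", "dose_nM", "role"])
    offsets = {}
    rng_off = np.random.default_rng(config.seed + 1)
    for p in range(config.n_plates):
        offsets[f"P{p + 1:02d}"] = rng_off.normal(scale=config.plate_effect_sd,
                                                  size=config.n_features)
    offset_block = np.vstack([offsets[p] for p in meta["plate"]])

    noise = rng.normal(scale=config.noise_sd, size=signal.shape)
    feats = signal + offset_block + noise
    if config.skew > 0:
        # exponential transform injects right-skew on the flagged features
        s = config.skew
        feats[:, skewed] = np.expm1(s * feats[:, skewed]) / s

    # Nuclei counts: negative binomial, mean scaled by viability.
    v_arr = np.asarray(viab_mults)
    mean_counts = config.nuclei_mean * v_arr
    size = config.nuclei_dispersion
    p_nb = size / (size + mean_counts)
    counts = rng.negative_binomial(size, p_nb).astype(float)

    mat = np.column_stack([counts, feats[:, 1:]])
    data = pd.concat([meta, pd.DataFrame(mat, columns=feature_names)], axis=1)
    return FeatureTable(data, feature_names, level="field", stage="raw"), truth


def simulate_panel(config: ScreenConfig, cell_lines: list[str]
                   ) -> tuple[list[FeatureTable], SyntheticTruth]:
    """Simulate one screen per cell line with a single shared compound truth.

    Compound effects (delta, viability, affected factors) are drawn once
    from ``config.seed``; each line's screen then uses its own noise
    stream (seed offset by line index), emulating consistent compound
    biology across a heterogeneous panel.
    """
    rng = np.random.default_rng((config.seed, 777))
    n_treat = config.n_replicates * len(config.doses_nM)
    n_compounds = (config.n_compounds if config.n_compounds is not None
                   else config.well_budget // n_treat)
    truth, directions = _make_truth(rng, n_compounds, config)
    tables = []
    for i, line in enumerate(cell_lines):
        cfg_i = replace(config, cell_line=line, seed=config.seed + i + 1,
                        n_compounds=n_compounds)
        t, _ = simulate_screen(cfg_i, shared_truth=(truth, directions))
        tables.append(t)
    return tables, truth


def logistic_viability(dose_nM: np.ndarray | float, log_ic50: float,
                       hill_slope: float) -> np.ndarray:
    """Fractional viability under Y = 100 / (1 + 10^((LogIC50 - X) * HillSlope)),
    with X = log10(molar concentration); returned on the 0-1 scale."""
    x = np.log10(np.asarray(dose_nM, dtype=float)) - 9.0
    return 1.0 / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def simulate_dose_response(log_ic50: float, hill_slope: float,
                           doses_nM: tuple[float, ...] = DEFAULT_DOSES_NM,
                           noise_sd: float = 0.05, n_replicates: int = 1,
                           compound: str = "CPD0001", cell_line: str = "LINE1",
                           seed: int = 0) -> pd.DataFrame:
    """Simulate a dose-response viability table from the logistic model.

    Returns a long-format DataFrame (compound, cell_line, dose_nM,
    replicate, viability) with Gaussian noise added and viability clipped
    to [0, 1.2].
    """
    doses = np.asarray(doses_nM, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        y = logistic_viability(doses, log_ic50, hill_slope)
        y = y + rng.normal(scale=noise_sd, size=len(doses))
        y = np.clip(y, 0.0, 1.2)
        for d, v in zip(doses, y):
            rows.append((compound, cell_line, d, rep, v))
    return pd.DataFrame(rows, columns=["compound", "cell_line", "dose_nM",
                                       "replicate", "viability"])


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-compound ground truth for recall/precision scoring of hit calls."""
    return truth.table()
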