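"""Synthetic multi-organism study with known ground truth.

The generator emulates the structure of a targeted quantitative metabolomics
study of eight biological systems (four microorganisms, two of them
proline-rich microalgae, and four human cell lines) with five biological
replicates each:

* ground-truth intracellular concentrations drawn log-uniformly per
  metabolite class, spanning at least three orders of magnitude within each
  group and about seven across the panel, with the adenylates constrained so
  the adenylate energy charge of every group falls in a physiological band;
* per-replicate biomass records (dry weight for microorganisms, cell density
  and measured cell volume for cell lines) with small lognormal jitter;
* raw analyte/internal-standard peak areas, where a lognormal matrix factor
  is shared between the two channels of the same (sample, metabolite) — the
  isotope-dilution ratio cancels it by construction — plus independent
  lognormal detector noise, single-replicate outlier spikes, and missing
  cells;
* calibration series (matrix factor 1, blank included) on a per-metabolite
  balanced standard scale.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import lognormal_factors
from .biomass import MICROORGANISM, ORGANISM_KINDS, BIOMASS_COLUMNS, CellModel, load_cell_models
from .errors import ValidationError
from .panel import MetabolitePanel, MetClass
from .quantify import (
    CHANNEL_ANALYTE,
    CHANNEL_IS,
    ROLE_BLANK,
    ROLE_CALIBRANT,
    ROLE_SAMPLE,
    PrepFactors,
    default_prep_factors,
)

__all__ = [
    "GroupSpec",
    "StudyConfig",
    "GroundTruth",
    "default_study_config",
    "generate_ground_truth",
    "simulate_biomass",
    "simulate_raw_peaks",
    "simulate_calibration",
    "simulate_study",
    "true_extract_concentrations",
]

# log10 intracellular molar ranges per metabolite class; amino acids sit
# higher in eukaryote-like systems (cell lines) than in microbes.
CLASS_LOG10_RANGES: dict[str, tuple[float, float]] = {
    "amino_acid": (-4.8, -2.4),
    "nucleoside_phosphate": (-5.0, -3.0),
    "deoxynucleoside_phosphate": (-8.0, -6.5),
    "glycolysis": (-6.0, -3.5),
    "PPP": (-6.5, -4.0),
    "TCA": (-5.5, -3.0),
    "organic_acid_other": (-5.0, -2.5),
}
AMINO_LOG10_CELL_LINE = (-4.0, -2.0)
PROLINE_RICH_LOG10 = (-1.3, -1.0)
ADENYLATE_TOTAL_LOG10 = (-3.5, -2.5)
ADP_FRACTION_RANGE = (0.04, 0.12)

DEFAULT_CAL_LEVELS = (1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class GroupSpec:
    """One biological group: organism kind plus its biomass parameters."""

    group_id: str
    organism_kind: str
    cell_model_id: str | None = None  # microorganisms: key into cell_models
    dry_weight_g: float | None = None  # microorganisms: mean sampled DW
    cell_density_per_L: float | None = None  # cell lines
    cell_volume_pL: float | None = None  # cell lines: mean measured volume
    sampled_volume_L: float = 0.01
    extract_volume_L: float = 5e-3
    proline_rich: bool = False

    def __post_init__(self):
        if self.organism_kind not in ORGANISM_KINDS:
            raise ValidationError(f"unknown organism_kind {self.organism_kind!r}")
        if self.organism_kind == MICROORGANISM:
            if self.dry_weight_g is None or self.cell_model_id is None:
                raise ValidationError(
                    f"{self.group_id}: microorganism groups need dry_weight_g and cell_model_id"
                )
        else:
            if self.cell_density_per_L is None or self.cell_volume_pL is None:
                raise ValidationError(
                    f"{self.group_id}: cell-line groups need cell_density_per_L and cell_volume_pL"
                )


@dataclass(frozen=True)
class StudyConfig:
    groups: tuple[GroupSpec, ...]
    n_replicates: int = 5
    seed: int = 74
    noise_cv: float = 0.10
    matrix_effect_sd: float = 0.30
    missing_rate: float = 0.04
    outlier_rate: float = 0.02
    biomass_cv: float = 0.05
    calibration_levels: tuple[float, ...] = DEFAULT_CAL_LEVELS
    calibration_replicates: int = 3
    ec_range: tuple[float, float] = (0.75, 0.93)

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "calibration_levels", tuple(self.calibration_levels))
        if self.n_replicates < 3:
            raise ValidationError("n_replicates must be >= 3 (outlier testing needs n >= 3)")
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValidationError(f"{name} must be in [0, 0.5)")
        if any(l <= 0 for l in self.calibration_levels):
            raise ValidationError("calibration levels must be positive")
        if len(self.calibration_levels) < 5:
            raise ValidationError("need at least 5 calibration levels")
        if self.calibration_replicates < 1:
            raise ValidationError("calibration_replicates must be >= 1")
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValidationError("group_id values must be unique")

    def noiseless(self) -> "StudyConfig":
        """Copy of the config with every stochastic term switched off."""
        return StudyConfig(
            groups=self.groups,
            n_replicates=self.n_replicates,
            seed=self.seed,
            noise_cv=0.0,
            matrix_effect_sd=0.0,
            missing_rate=0.0,
            outlier_rate=0.0,
            biomass_cv=0.0,
            calibration_levels=self.calibration_levels,
            calibration_replicates=self.calibration_replicates,
            ec_range=self.ec_range,
        )


def default_study_config(seed: int = 74) -> StudyConfig:
    """The default 8-group x 5-replicate study mirroring a panel of two
    bacteria/yeast-like microbes, two proline-rich microalgae, two adherent
    and two suspension human cell lines."""
    groups = (
        GroupSpec("bsubtilis", MICROORGANISM, "B_subtilis", dry_weight_g=4e-3),
        GroupSpec("scerevisiae", MICROORGANISM, "S_cerevisiae", dry_weight_g=5e-3),
        GroupSpec("noceanica", MICROORGANISM, "N_oceanica", dry_weight_g=3e-3,
                  sampled_volume_L=0.015, proline_rich=True),
        GroupSpec("ptricornutum", MICROORGANISM, "P_tricornutum", dry_weight_g=3e-3,
                  sampled_volume_L=0.015, proline_rich=True),
        GroupSpec("hek293", "adherent_cell_line", cell_density_per_L=1e8,
                  cell_volume_pL=1.5, sampled_volume_L=0.03),
        GroupSpec("helas3", "adherent_cell_line", cell_density_per_L=1e8,
                  cell_volume_pL=2.6, sampled_volume_L=0.03),
        GroupSpec("nb4", "suspension_cell_line", cell_density_per_L=5e8,
                  cell_volume_pL=0.9, sampled_volume_L=0.005),
        GroupSpec("mccar", "suspension_cell_line", cell_density_per_L=5e8,
                  cell_volume_pL=1.1, sampled_volume_L=0.005),
    )
    return StudyConfig(groups=groups, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """True intracellular molarity per (metabolite, group)."""

    conc: pd.DataFrame  # index metabolite_id, columns group_id, values M

    def value(self, group_id: str, metabolite_id: str) -> float:
        return float(self.conc.at[metabolite_id, group_id])

    def to_long(self) -> pd.DataFrame:
        long = self.conc.stack().rename("conc_true_M").reset_index()
        long.columns = ["metabolite_id", "group_id", "conc_true_M"]
        return long

    def group_span_decades(self) -> pd.Series:
        return np.log10(self.conc.max() / self.conc.min())

    def panel_span_decades(self) -> float:
        return float(np.log10(self.conc.values.max() / self.conc.values.min()))


def _rng(config: StudyConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_ground_truth(config: StudyConfig, panel: MetabolitePanel) -> GroundTruth:
    """Draw ground-truth intracellular concentrations.

    Log-uniform per class with class-specific location; proline boosted to
    the 10–100 mM range in proline-rich groups; AMP/ADP/ATP drawn jointly so
    that each group's energy charge lies inside ``config.ec_range``.
    """
    rng = _rng(config, 1)
    mids = panel.metabolite_ids
    class_of = panel.class_of()
    conc = pd.DataFrame(index=mids, columns=[g.group_id for g in config.groups], dtype=float)
    ec_lo, ec_hi = config.ec_range
    for g in config.groups:
        is_cell_line = g.organism_kind != MICROORGANISM
        for mid in mids:
            cls = class_of[mid]
            lo, hi = CLASS_LOG10_RANGES[cls]
            if cls == "amino_acid" and is_cell_line:
                lo, hi = AMINO_LOG10_CELL_LINE
            if mid == "pro" and g.proline_rich:
                lo, hi = PROLINE_RICH_LOG10
            conc.at[mid, g.group_id] = 10.0 ** rng.uniform(lo, hi)
        # adenylates: total pool, target EC and ADP fraction fix all three
        total = 10.0 ** rng.uniform(*ADENYLATE_TOTAL_LOG10)
        ec = rng.uniform(ec_lo, ec_hi)
        f_adp = rng.uniform(*ADP_FRACTION_RANGE)
        conc.at["adp", g.group_id] = total * f_adp
        conc.at["atp", g.group_id] = total * (ec - 0.5 * f_adp)
        conc.at["amp", g.group_id] = total * (1.0 - ec - 0.5 * f_adp)
    return GroundTruth(conc=conc)


def simulate_biomass(config: StudyConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-replicate biomass records with lognormal jitter (CV biomass_cv)."""
    rng = rng if rng is not None else _rng(config, 2)
    rows = []
    for g in config.groups:
        jit = lognormal_factors(rng, config.biomass_cv, (config.n_replicates, 3))
        for r in range(config.n_replicates):
            row = {
                "sample_id": f"{g.group_id}_r{r + 1}",
                "group_id": g.group_id,
                "organism_kind": g.organism_kind,
                "sampled_volume_L": g.sampled_volume_L,
                "dry_weight_g": np.nan,
                "cell_density_per_L": np.nan,
                "cell_volume_pL": np.nan,
                "extract_volume_L": g.extract_volume_L,
            }
            if g.organism_kind == MICROORGANISM:
                row["dry_weight_g"] = g.dry_weight_g * jit[r, 0]
            else:
                row["cell_density_per_L"] = g.cell_density_per_L * jit[r, 0]
                row["cell_volume_pL"] = g.cell_volume_pL * jit[r, 1]
            rows.append(row)
    return pd.DataFrame(rows, columns=BIOMASS_COLUMNS)


def _group_specs(config: StudyConfig) -> dict[str, GroupSpec]:
    return {g.group_id: g for g in config.groups}


def group_cell_model_map(config: StudyConfig) -> dict[str, str]:
    """group_id -> organism_id for microorganism groups."""
    return {
        g.group_id: g.cell_model_id
        for g in config.groups
        if g.organism_kind == MICROORGANISM
    }


def true_extract_concentrations(
    truth: GroundTruth,
    biomass: pd.DataFrame,
    panel: MetabolitePanel,
    prep: dict[str, PrepFactors],
    config: StudyConfig,
    cell_models: dict[str, CellModel] | None = None,
) -> pd.DataFrame:
    """Forward normalization chain: intracellular truth -> concentration in
    the measured (post-preparation) extract, per (sample, metabolite).

    This is the exact inverse of the quantify/biomass recovery chain and the
    basis for the noiseless round-trip contract.
    """
    cell_models = cell_models if cell_models is not None else load_cell_models()
    model_map = group_cell_model_map(config)
    method_of = panel.method_of()
    rows = []
    for b in biomass.itertuples(index=False):
        if b.organism_kind == MICROORGANISM:
            v_cells = b.dry_weight_g * cell_models[model_map[b.group_id]].specific_volume_L_per_g
        else:
            v_cells = b.cell_density_per_L * b.sampled_volume_L * b.cell_volume_pL * 1e-12
        for mid in panel.metabolite_ids:
            c_int = truth.value(b.group_id, mid)
            c_extract0 = c_int * v_cells / b.extract_volume_L
            c_meas = c_extract0 * prep[method_of[mid].value].forward_factor
            rows.append(
                {
                    "sample_id": b.sample_id,
                    "group_id": b.group_id,
                    "metabolite_id": mid,
                    "c_meas_M": c_meas,
                }
            )
    return pd.DataFrame(rows)


def _instrument_params(panel: MetabolitePanel, config: StudyConfig) -> pd.DataFrame:
    """Fixed per-metabolite response-ratio slope and IS base area."""
    rng = _rng(config, 10)
    n = len(panel)
    return pd.DataFrame(
        {
            "metabolite_id": panel.metabolite_ids,
            "ratio_slope": 10.0 ** rng.uniform(3.5, 5.5, n),  # ratio units per M
            "is_base_area": 10.0 ** rng.uniform(4.0, 6.0, n),
        }
    ).set_index("metabolite_id")


def simulate_raw_peaks(
    truth: GroundTruth,
    biomass: pd.DataFrame,
    panel: MetabolitePanel,
    config: StudyConfig,
    prep: dict[str, PrepFactors] | None = None,
    cell_models: dict[str, CellModel] | None = None,
) -> pd.DataFrame:
    """Simulate analyte and internal-standard peak areas for all samples.

    analyte = slope_m * c_meas * IS0_m * matrix * eps,
    IS      = IS0_m * matrix * eps'
    with the matrix factor shared between channels of the same
    (sample, metabolite) and eps/eps' independent lognormal (CV noise_cv).
    """
    prep = prep if prep is not None else default_prep_factors()
    params = _instrument_params(panel, config)
    cells = true_extract_concentrations(truth, biomass, panel, prep, config, cell_models)
    rng = _rng(config, 3)
    n = len(cells)

    matrix = lognormal_factors(rng, config.matrix_effect_sd, n)
    eps_a = lognormal_factors(rng, config.noise_cv, n)
    eps_i = lognormal_factors(rng, config.noise_cv, n)

    slope = params.loc[cells["metabolite_id"], "ratio_slope"].to_numpy()
    is0 = params.loc[cells["metabolite_id"], "is_base_area"].to_numpy()

    analyte = slope * cells["c_meas_M"].to_numpy() * is0 * matrix * eps_a
    is_area = is0 * matrix * eps_i

    df = cells[["sample_id", "group_id", "metabolite_id"]].copy()
    df["analyte"] = analyte
    df["internal_standard"] = is_area

    # single-replicate multiplicative outliers, at most one per (group, metabolite)
    if config.outlier_rate > 0:
        for (group_id, metabolite_id), idx in df.groupby(["group_id", "metabolite_id"]).groups.items():
            if rng.random() < config.outlier_rate:
                pick = idx[rng.integers(len(idx))]
                df.loc[pick, "analyte"] *= rng.uniform(3.0, 10.0)

    # missing cells: both channels dropped
    if config.missing_rate > 0:
        keep = rng.random(len(df)) >= config.missing_rate
        df = df[keep]

    long = df.melt(
        id_vars=["sample_id", "group_id", "metabolite_id"],
        value_vars=["analyte", "internal_standard"],
        var_name="channel",
        value_name="area",
    )
    long["role"] = ROLE_SAMPLE
    long["level_conc"] = np.nan
    return long.sort_values(["sample_id", "metabolite_id", "channel"]).reset_index(drop=True)


def calibration_scales(
    truth: GroundTruth,
    biomass: pd.DataFrame,
    panel: MetabolitePanel,
    prep: dict[str, PrepFactors],
    config: StudyConfig,
    cell_models: dict[str, CellModel] | None = None,
) -> pd.Series:
    """Per-metabolite balanced-standard scale: geometric mean of the true
    measured extract concentration over all study samples."""
    cells = true_extract_concentrations(truth, biomass, panel, prep, config, cell_models)
    return cells.groupby("metabolite_id")["c_meas_M"].apply(
        lambda s: float(np.exp(np.mean(np.log(s))))
    )


def simulate_calibration(
    truth: GroundTruth,
    biomass: pd.DataFrame,
    panel: MetabolitePanel,
    config: StudyConfig,
    prep: dict[str, PrepFactors] | None = None,
    cell_models: dict[str, CellModel] | None = None,
) -> pd.DataFrame:
    """Simulate the calibration series (matrix factor 1, IS spiked as in
    samples, plus a blank level)."""
    prep = prep if prep is not None else default_prep_factors()
    params = _instrument_params(panel, config)
    scales = calibration_scales(truth, biomass, panel, prep, config, cell_models)
    rng = _rng(config, 4)
    rows = []
    levels = [0.0] + list(config.calibration_levels)
    n_rep = config.calibration_replicates
    for mid in panel.metabolite_ids:
        slope = params.at[mid, "ratio_slope"]
        is0 = params.at[mid, "is_base_area"]
        eps_a = lognormal_factors(rng, config.noise_cv, (len(levels), n_rep))
        eps_i = lognormal_factors(rng, config.noise_cv, (len(levels), n_rep))
        for j, rel in enumerate(levels):
            conc = rel * scales[mid]
            role = ROLE_BLANK if rel == 0.0 else ROLE_CALIBRANT
            for r in range(n_rep):
                sample_id = f"cal_{mid}_L{j}_i{r + 1}"
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group_id": "calibration",
                        "metabolite_id": mid,
                        "channel": CHANNEL_ANALYTE,
                        "area": slope * conc * is0 * float(eps_a[j, r]),
                        "role": role,
                        "level_conc": conc,
                    }
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group_id": "calibration",
                        "metabolite_id": mid,
                        "channel": CHANNEL_IS,
                        "area": is0 * float(eps_i[j, r]),
                        "role": role,
                        "level_conc": conc,
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    config: StudyConfig,
    panel: MetabolitePanel,
    prep: dict[str, PrepFactors] | None = None,
    cell_models: dict[str, CellModel] | None = None,
) -> dict:
    """Generate the complete study: truth, biomass, sample and calibration
    peak tables (returned separately and concatenated)."""
    prep = prep if prep is not None else default_prep_factors()
    cell_models = cell_models if cell_models is not None else load_cell_models()
    truth = generate_ground_truth(config, panel)
    biomass = simulate_biomass(config)
    peaks = simulate_raw_peaks(truth, biomass, panel, config, prep, cell_models)
    calibration = simulate_calibration(truth, biomass, panel, config, prep, cell_models)
    raw = pd.concat([peaks, calibration], ignore_index=True)
    return {
        "config": config,
        "truth": truth,
        "biomass": biomass,
        "sample_peaks": peaks,
        "calibration_peaks": calibration,
        "raw": raw,
        "prep": prep,
        "cell_models": cell_models,
    }
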