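"""Raw peak areas -> extract concentrations.

Quantification follows the isotope-dilution convention: every analyte peak
area is divided by the peak area of its co-measured stable-isotope-labeled
internal standard (IS), which cancels multiplicative matrix/ionization
effects shared by the two channels.  Corrected responses of calibration
standards are fit by least-squares linear regression with 1/x weighting, the
quantification range is bounded by back-calculation accuracy (LLOQ/ULOQ),
and sample responses are interpolated and corrected for the dilution and
concentration steps of sample preparation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CalibrationError, MissingInternalStandardError, ValidationError
from .panel import MetabolitePanel

__all__ = [
    "FLAG_OK",
    "FLAG_BELOW_LLOQ",
    "FLAG_ABOVE_ULOQ",
    "FLAG_MISSING_IS",
    "FLAG_MISSING",
    "RAW_PEAK_COLUMNS",
    "PrepFactors",
    "CalibrationModel",
    "corrected_response",
    "fit_calibration",
    "fit_all_calibrations",
    "interpolate",
    "apply_prep_factors",
    "quantify_table",
    "default_prep_factors",
    "models_to_frame",
    "models_from_frame",
]

FLAG_OK = "ok"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_MISSING_IS = "missing_is"
FLAG_MISSING = "missing"

RAW_PEAK_COLUMNS = [
    "sample_id",
    "group_id",
    "metabolite_id",
    "channel",
    "area",
    "role",
    "level_conc",
]

CHANNEL_ANALYTE = "analyte"
CHANNEL_IS = "internal_standard"

ROLE_SAMPLE = "sample"
ROLE_CALIBRANT = "calibrant"
ROLE_BLANK = "blank"


@dataclass(frozen=True)
class PrepFactors:
    """Dilution/concentration factors applied during sample preparation.

    ``spike_fraction`` is the IS spike (v/v) added to the extract; spiking
    dilutes the analyte by (1 - spike_fraction).  Lyophilization concentrates
    by ``lyophilization_concentration_factor`` and reconstitution dilutes by
    ``reconstitution_dilution_factor``.
    """

    spike_fraction: float
    lyophilization_concentration_factor: float = 1.0
    reconstitution_dilution_factor: float = 1.0

    def __post_init__(self):
        if not 0 <= self.spike_fraction < 1:
            raise ValidationError("spike_fraction must be in [0, 1)")
        if self.lyophilization_concentration_factor <= 0 or self.reconstitution_dilution_factor <= 0:
            raise ValidationError("concentration/dilution factors must be positive")

    @property
    def net_factor(self) -> float:
        """Multiplier taking measured extract conc back to the original extract."""
        return (
            1.0
            / (1.0 - self.spike_fraction)
            * self.reconstitution_dilution_factor
            / self.lyophilization_concentration_factor
        )

    @property
    def forward_factor(self) -> float:
        """Multiplier taking original extract conc to the measured extract."""
        return 1.0 / self.net_factor


def default_prep_factors() -> dict[str, PrepFactors]:
    """Per-method defaults: 20% v/v labeled-extract spike on the IC and
    organic-acid methods, 5% v/v labeled amino-acid mix on the amino-acid
    method; a common 10x lyophilization concentration."""
    return {
        "capIC": PrepFactors(0.20, 10.0, 1.0),
        "LC_organic_acid": PrepFactors(0.20, 10.0, 1.0),
        "LC_amino_acid": PrepFactors(0.05, 10.0, 1.0),
    }


@dataclass(frozen=True)
class CalibrationModel:
    metabolite_id: str
    slope: float  # corrected-response units per M
    intercept: float
    weighting: str  # "one_over_x" | "none"
    r_squared: float
    lloq: float  # M
    uloq: float  # M
    n_levels_used: int

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError(f"{self.metabolite_id}: non-positive calibration slope")
        if not self.lloq < self.uloq:
            raise CalibrationError(f"{self.metabolite_id}: LLOQ must be below ULOQ")


def corrected_response(analyte_area: float, is_area: float) -> float:
    """Isotope-dilution corrected response: analyte area / IS area."""
    if analyte_area < 0 or is_area < 0:
        raise ValidationError("peak areas must be non-negative")
    if is_area == 0 or not np.isfinite(is_area):
        raise MissingInternalStandardError("internal-standard area is zero or absent")
    return analyte_area / is_area


def _weighted_linear_fit(x: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """WLS fit of y = a + b*x.  x is rescaled by its maximum before solving;
    molar x values (~1e-11) would otherwise make the design matrix too
    ill-conditioned to honor the noiseless round-trip contract."""
    scale = float(np.max(x))
    xs = x / scale
    res = sm.WLS(y, sm.add_constant(xs), weights=weights).fit()
    intercept, slope_scaled = res.params
    return float(intercept), float(slope_scaled) / scale, float(res.rsquared)


def fit_calibration(
    series: pd.DataFrame,
    weighting: str = "one_over_x",
    *,
    use_isotope_correction: bool = True,
    backcalc_tol: float = 0.20,
    backcalc_tol_lowest: float = 0.25,
) -> CalibrationModel:
    """Fit one metabolite's calibration series.

    ``series`` is a long-format slice of a raw peak table (one metabolite,
    roles calibrant/blank, both channels).  The blank is excluded from the
    weighted fit (1/x is undefined at x = 0) and the quantification range is
    set by back-calculation accuracy: LLOQ is the lowest calibrant whose
    back-calculated concentration is within ±20% of nominal (±25% at the
    lowest level), ULOQ the highest within ±20%.
    """
    if weighting not in ("one_over_x", "none"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    mets = series["metabolite_id"].unique()
    if len(mets) != 1:
        raise ValidationError("calibration slice must contain exactly one metabolite")
    metabolite_id = mets[0]

    cal = series[series["role"] == ROLE_CALIBRANT]
    wide = cal.pivot_table(
        index="level_conc", columns="channel", values="area", aggfunc="mean"
    ).sort_index()
    if CHANNEL_ANALYTE not in wide.columns:
        raise CalibrationError(f"{metabolite_id}: no analyte calibration levels")
    if use_isotope_correction:
        if CHANNEL_IS not in wide.columns or (wide[CHANNEL_IS] <= 0).any():
            raise CalibrationError(f"{metabolite_id}: calibration IS channel absent or zero")
        response = wide[CHANNEL_ANALYTE] / wide[CHANNEL_IS]
    else:
        response = wide[CHANNEL_ANALYTE]
    response = response.dropna()

    x = response.index.to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise CalibrationError(f"{metabolite_id}: fewer than 3 usable calibration levels")
    if np.ptp(y) == 0:
        raise CalibrationError(f"{metabolite_id}: degenerate calibration (all responses equal)")

    w = 1.0 / x if weighting == "one_over_x" else np.ones_like(x)
    intercept, slope, r2 = _weighted_linear_fit(x, y, w)
    if slope <= 0:
        raise CalibrationError(f"{metabolite_id}: non-positive calibration slope")

    back = (y - intercept) / slope
    rel_err = np.abs(back / x - 1.0)
    tol = np.full_like(x, backcalc_tol)
    tol[np.argmin(x)] = backcalc_tol_lowest
    passing = x[rel_err <= tol]
    if len(passing) == 0:
        raise CalibrationError(f"{metabolite_id}: no calibration level meets back-calculation accuracy")
    lloq, uloq = float(np.min(passing)), float(np.max(passing))
    if not lloq < uloq:
        raise CalibrationError(f"{metabolite_id}: accepted calibration range is empty")

    return CalibrationModel(
        metabolite_id=metabolite_id,
        slope=slope,
        intercept=intercept,
        weighting=weighting,
        r_squared=r2,
        lloq=lloq,
        uloq=uloq,
        n_levels_used=len(x),
    )


def fit_all_calibrations(
    raw: pd.DataFrame,
    weighting: str = "one_over_x",
    *,
    use_isotope_correction: bool = True,
) -> tuple[dict[str, CalibrationModel], dict[str, str]]:
    """Fit every metabolite with calibrant rows; returns (models, failures)."""
    models: dict[str, CalibrationModel] = {}
    failures: dict[str, str] = {}
    cal = raw[raw["role"].isin([ROLE_CALIBRANT, ROLE_BLANK])]
    for metabolite_id, sl in cal.groupby("metabolite_id", sort=True):
        try:
            models[metabolite_id] = fit_calibration(
                sl, weighting, use_isotope_correction=use_isotope_correction
            )
        except CalibrationError as exc:
            failures[metabolite_id] = str(exc)
    return models, failures


def interpolate(model: CalibrationModel, ratio: float) -> tuple[float, str]:
    """Invert the calibration line; clamp negatives to 0 and flag the range."""
    conc = (ratio - model.intercept) / model.slope
    if conc < 0:
        return 0.0, FLAG_BELOW_LLOQ
    if conc < model.lloq:
        return conc, FLAG_BELOW_LLOQ
    if conc > model.uloq:
        return conc, FLAG_ABOVE_ULOQ
    return conc, FLAG_OK


def apply_prep_factors(conc: float, factors: PrepFactors) -> float:
    """Correct a measured extract concentration for preparation steps."""
    return conc * factors.net_factor


def quantify_table(
    raw: pd.DataFrame,
    models: dict[str, CalibrationModel],
    factors: dict[str, PrepFactors],
    panel: MetabolitePanel,
    *,
    use_isotope_correction: bool = True,
) -> pd.DataFrame:
    """Quantify all sample rows of a raw peak table.

    Returns one row per (sample, metabolite) of the sample grid with columns
    sample_id, group_id, metabolite_id, conc_extract_M, flag.  Cells without
    an analyte record are flagged ``missing``; cells whose IS channel is
    absent or zero are flagged ``missing_is``.  Metabolites without a fitted
    model are flagged ``missing`` for every sample (other metabolites are
    unaffected).
    """
    samples = raw[raw["role"] == ROLE_SAMPLE]
    sample_ids = samples["sample_id"].unique()
    groups = samples.drop_duplicates("sample_id").set_index("sample_id")["group_id"]
    method_of = panel.method_of()

    wide = samples.pivot_table(
        index=["sample_id", "metabolite_id"], columns="channel", values="area", aggfunc="mean"
    )
    grid = pd.MultiIndex.from_product(
        [sample_ids, panel.metabolite_ids], names=["sample_id", "metabolite_id"]
    )
    wide = wide.reindex(grid)
    if CHANNEL_ANALYTE not in wide.columns:
        wide[CHANNEL_ANALYTE] = np.nan
    if CHANNEL_IS not in wide.columns:
        wide[CHANNEL_IS] = np.nan

    records = []
    for (sample_id, metabolite_id), row in wide.iterrows():
        analyte = row[CHANNEL_ANALYTE]
        is_area = row[CHANNEL_IS]
        model = models.get(metabolite_id)
        if model is None or not np.isfinite(analyte):
            conc, flag = np.nan, FLAG_MISSING
        elif use_isotope_correction and not (np.isfinite(is_area) and is_area > 0):
            conc, flag = np.nan, FLAG_MISSING_IS
        else:
            response = analyte / is_area if use_isotope_correction else analyte
            conc, flag = interpolate(model, response)
            method = method_of[metabolite_id].value
            conc = apply_prep_factors(conc, factors[method])
        records.append(
            {
                "sample_id": sample_id,
                "group_id": groups.get(sample_id),
                "metabolite_id": metabolite_id,
                "conc_extract_M": conc,
                "flag": flag,
            }
        )
    return pd.DataFrame.from_records(records)


def models_to_frame(models: dict[str, CalibrationModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_id": m.metabolite_id,
                "slope": m.slope,
                "intercept": m.intercept,
                "weighting": m.weighting,
                "r_squared": m.r_squared,
                "lloq": m.lloq,
                "uloq": m.uloq,
                "n_levels_used": m.n_levels_used,
            }
            for m in models.values()
        ]
    )


def models_from_frame(df: pd.DataFrame) -> dict[str, CalibrationModel]:
    return {
        r.metabolite_id: CalibrationModel(
            r.metabolite_id,
            float(r.slope),
            float(r.intercept),
            str(r.weighting),
            float(r.r_squared),
            float(r.lloq),
            float(r.uloq),
            int(r.n_levels_used),
        )
        for r in df.itertuples(index=False)
    }
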