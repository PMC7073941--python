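"""Biomass normalization: extract concentration -> intracellular molarity.

Extract concentrations are first normalized to the amount of biomass that was
sampled (mol per g dry weight for microorganisms, mol per cell for cell
lines), then converted to intracellular molar concentration by dividing by
the volume that biomass occupies: a literature specific cell volume (L/g) for
microorganisms, or the replicate-level measured cell volume (pL/cell) for
cell lines.  The conversion assumes all extracted metabolite originated from
the cell interior and distributes over the total cell volume (no subcellular
compartments).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._utils import round_sig
from .errors import ValidationError

__all__ = [
    "ORGANISM_KINDS",
    "MICROORGANISM",
    "BIOMASS_COLUMNS",
    "CellModel",
    "load_cell_models",
    "specific_cell_volume",
    "half_parallelepiped_volume",
    "per_biomass_amount",
    "intracellular_concentration",
    "intracellular_table",
]

MICROORGANISM = "microorganism"
ORGANISM_KINDS = (MICROORGANISM, "suspension_cell_line", "adherent_cell_line")

BIOMASS_COLUMNS = [
    "sample_id",
    "group_id",
    "organism_kind",
    "sampled_volume_L",
    "dry_weight_g",
    "cell_density_per_L",
    "cell_volume_pL",
    "extract_volume_L",
]


@dataclass(frozen=True)
class CellModel:
    """Literature single-cell dry weight and volume for a microorganism."""

    organism_id: str
    cell_dw_g: float
    cell_volume_L: float
    specific_volume_L_per_g: float  # printed/tabulated value, kept verbatim

    def __post_init__(self):
        for name in ("cell_dw_g", "cell_volume_L", "specific_volume_L_per_g"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_cell_models() -> dict[str, CellModel]:
    """Load the packaged literature cell models (dry weight, volume, L/g)."""
    with resources.files("ccmquant.data").joinpath("cell_models.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return {
        r.organism_id: CellModel(
            r.organism_id,
            float(r.cell_dw_g),
            float(r.cell_volume_L),
            float(r.specific_volume_L_per_g),
        )
        for r in df.itertuples(index=False)
    }


def specific_cell_volume(cell_dw_g: float, cell_volume_L: float) -> float:
    """Cell volume per gram dry weight, L/g."""
    if cell_dw_g <= 0 or cell_volume_L <= 0:
        raise ValidationError("cell dry weight and cell volume must be positive")
    return cell_volume_L / cell_dw_g


def half_parallelepiped_volume(length_um: float, width_um: float, height_um: float) -> float:
    """Geometric cell volume length*width*height/2, returned in liters.

    Used for organisms with a fusiform (half-parallelepiped) shape;
    1 um^3 = 1e-15 L.
    """
    if length_um <= 0 or width_um <= 0 or height_um <= 0:
        raise ValidationError("all cell dimensions must be positive")
    return length_um * width_um * height_um / 2.0 * 1e-15


def per_biomass_amount(conc_extract_M: float, extract_volume_L: float, biomass) -> tuple[float, str]:
    """Normalize an extract concentration to sampled biomass.

    ``biomass`` is a mapping/row with the BIOMASS_COLUMNS fields.  Returns
    ``(amount, unit)`` with unit ``"mol/gDW"`` for microorganisms and
    ``"mol/cell"`` for cell lines.
    """
    kind = biomass["organism_kind"]
    moles = conc_extract_M * extract_volume_L
    if kind == MICROORGANISM:
        dw = biomass.get("dry_weight_g") if hasattr(biomass, "get") else biomass["dry_weight_g"]
        if dw is None or not np.isfinite(dw):
            raise ValidationError("microorganism biomass record lacks dry_weight_g")
        return moles / dw, "mol/gDW"
    if kind in ORGANISM_KINDS:
        density = biomass["cell_density_per_L"]
        vol_sampled = biomass["sampled_volume_L"]
        if density is None or not np.isfinite(density):
            raise ValidationError("cell-line biomass record lacks cell_density_per_L")
        if vol_sampled is None or not np.isfinite(vol_sampled):
            raise ValidationError("cell-line biomass record lacks sampled_volume_L")
        return moles / (density * vol_sampled), "mol/cell"
    raise ValidationError(f"unknown organism_kind {kind!r}")


def intracellular_concentration(
    per_biomass: float,
    *,
    specific_volume_L_per_g: float | None = None,
    cell_volume_L: float | None = None,
) -> float:
    """Convert a per-biomass amount into intracellular molarity.

    mol/gDW pairs with a specific cell volume (L/g); mol/cell pairs with a
    single-cell volume (L).  Supplying both or neither is a unit mismatch.
    """
    if (specific_volume_L_per_g is None) == (cell_volume_L is None):
        raise ValidationError("provide exactly one of specific_volume_L_per_g or cell_volume_L")
    divisor = specific_volume_L_per_g if specific_volume_L_per_g is not None else cell_volume_L
    if divisor <= 0:
        raise ValidationError("cell volume terms must be positive")
    return per_biomass / divisor


def intracellular_table(
    extract: pd.DataFrame,
    biomass: pd.DataFrame,
    cell_models: dict[str, CellModel] | None = None,
    group_cell_model: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorized extract -> intracellular conversion for a whole study.

    ``extract`` carries sample_id, metabolite_id, conc_extract_M and flag
    columns; ``biomass`` one row per sample.  Microorganism groups resolve
    their specific cell volume through ``group_cell_model`` (group_id ->
    organism_id in ``cell_models``); cell-line samples use their measured
    cell volume (pL).
    """
    cell_models = cell_models if cell_models is not None else load_cell_models()
    group_cell_model = group_cell_model or {}
    bio = biomass.set_index("sample_id")
    df = extract.merge(
        bio[
            [
                "group_id",
                "organism_kind",
                "sampled_volume_L",
                "dry_weight_g",
                "cell_density_per_L",
                "cell_volume_pL",
                "extract_volume_L",
            ]
        ],
        left_on="sample_id",
        right_index=True,
        how="left",
        suffixes=("", "_bio"),
    )
    if "group_id_bio" in df.columns:
        df["group_id"] = df["group_id"].fillna(df.pop("group_id_bio"))
    if df["organism_kind"].isna().any():
        missing = sorted(df.loc[df["organism_kind"].isna(), "sample_id"].unique())
        raise ValidationError(f"no biomass record for sample(s): {', '.join(map(str, missing))}")

    moles = df["conc_extract_M"] * df["extract_volume_L"]
    is_micro = df["organism_kind"] == MICROORGANISM

    per_biomass = pd.Series(np.nan, index=df.index)
    unit = pd.Series("", index=df.index)
    if is_micro.any():
        dw = df.loc[is_micro, "dry_weight_g"]
        if dw.isna().any():
            raise ValidationError("microorganism biomass record lacks dry_weight_g")
        per_biomass[is_micro] = moles[is_micro] / dw
        unit[is_micro] = "mol/gDW"
    if (~is_micro).any():
        cells = df.loc[~is_micro, "cell_density_per_L"] * df.loc[~is_micro, "sampled_volume_L"]
        if cells.isna().any():
            raise ValidationError("cell-line biomass record lacks cell_density_per_L/sampled_volume_L")
        per_biomass[~is_micro] = moles[~is_micro] / cells
        unit[~is_micro] = "mol/cell"

    # volume divisor: L/g for microorganisms, L/cell for cell lines
    divisor = pd.Series(np.nan, index=df.index)
    if is_micro.any():
        spec = df.loc[is_micro, "group_id"].map(
            lambda g: cell_models[group_cell_model[g]].specific_volume_L_per_g
            if g in group_cell_model
            else np.nan
        )
        if spec.isna().any():
            bad = sorted(df.loc[is_micro, "group_id"][spec.isna()].unique())
            raise ValidationError(f"no cell model mapped for microorganism group(s): {', '.join(bad)}")
        divisor[is_micro] = spec
    divisor[~is_micro] = df.loc[~is_micro, "cell_volume_pL"] * 1e-12

    out = pd.DataFrame(
        {
            "group_id": df["group_id"],
            "sample_id": df["sample_id"],
            "metabolite_id": df["metabolite_id"],
            "per_biomass": per_biomass,
            "per_biomass_unit": unit,
            "conc_intracellular_M": per_biomass / divisor,
            "flag": df["flag"],
        }
    )
    return out.reset_index(drop=True)


def tabulated_specific_volume_sig3(model: CellModel) -> float:
    """Specific volume recomputed from the model's own DW and volume, 3 s.f."""
    return round_sig(specific_cell_volume(model.cell_dw_g, model.cell_volume_L), 3)
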