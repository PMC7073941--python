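"""Metabolite panel registry.

The packaged default panel covers 68 central-carbon metabolites: the 20
proteinogenic amino acids, 12 ribonucleoside mono-/di-/triphosphates, 12
deoxyribonucleoside mono-/di-/triphosphates, and 24 intermediates of
glycolysis, the pentose phosphate pathway (PPP), the TCA cycle and related
organic acids.  Each metabolite carries exactly one analytical-method
assignment (capillary ion chromatography for phosphorylated metabolites and
TCA intermediates, a dedicated LC-MS/MS method for organic acids, and a
derivatization-based LC-MS/MS method for amino acids) and one
internal-standard kind (commercial matched U13C/15N isotopologue, U13C-labeled
whole-cell extract, or a labeled amino-acid mixture).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = [
    "MetClass",
    "Method",
    "IsKind",
    "MetaboliteDef",
    "MetabolitePanel",
    "default_panel",
    "load_panel",
    "save_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = [
    "metabolite_id",
    "name",
    "abbreviation",
    "met_class",
    "method",
    "is_kind",
    "pathway_position",
]


class MetClass(str, enum.Enum):
    amino_acid = "amino_acid"
    glycolysis = "glycolysis"
    PPP = "PPP"
    TCA = "TCA"
    nucleoside_phosphate = "nucleoside_phosphate"
    deoxynucleoside_phosphate = "deoxynucleoside_phosphate"
    organic_acid_other = "organic_acid_other"


class Method(str, enum.Enum):
    capIC = "capIC"
    LC_organic_acid = "LC_organic_acid"
    LC_amino_acid = "LC_amino_acid"


class IsKind(str, enum.Enum):
    matched_isotopologue = "matched_isotopologue"
    labeled_extract = "labeled_extract"
    labeled_amino_acid_mix = "labeled_amino_acid_mix"


@dataclass(frozen=True)
class MetaboliteDef:
    metabolite_id: str
    name: str
    abbreviation: str
    met_class: MetClass
    method: Method
    is_kind: IsKind
    pathway_position: str = ""

    def __post_init__(self):
        # coerce plain strings so loaders can pass raw tokens
        object.__setattr__(self, "met_class", MetClass(self.met_class))
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "is_kind", IsKind(self.is_kind))


@dataclass(frozen=True)
class MetabolitePanel:
    metabolites: tuple[MetaboliteDef, ...]
    version: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        ids = [m.metabolite_id for m in self.metabolites]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate metabolite_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.metabolites)

    def __iter__(self):
        return iter(self.metabolites)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.metabolite_id for m in self.metabolites]

    def get(self, metabolite_id: str) -> MetaboliteDef:
        for m in self.metabolites:
            if m.metabolite_id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def by_class(self, met_class: MetClass | str) -> list[MetaboliteDef]:
        met_class = MetClass(met_class)
        return [m for m in self.metabolites if m.met_class is met_class]

    def class_of(self) -> dict[str, str]:
        return {m.metabolite_id: m.met_class.value for m in self.metabolites}

    def method_of(self) -> dict[str, Method]:
        return {m.metabolite_id: m.method for m in self.metabolites}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metabolite_id": m.metabolite_id,
                "name": m.name,
                "abbreviation": m.abbreviation,
                "met_class": m.met_class.value,
                "method": m.method.value,
                "is_kind": m.is_kind.value,
                "pathway_position": m.pathway_position,
            }
            for m in self.metabolites
        ]
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)


# --- packaged default registry ------------------------------------------------
# (id, name, abbreviation); classes/methods assigned in blocks below.

_AMINO_ACIDS = [
    ("ala", "Alanine", "Ala"),
    ("arg", "Arginine", "Arg"),
    ("asn", "Asparagine", "Asn"),
    ("asp", "Aspartic acid", "Asp"),
    ("cys", "Cysteine", "Cys"),
    ("gln", "Glutamine", "Gln"),
    ("glu", "Glutamic acid", "Glu"),
    ("gly", "Glycine", "Gly"),
    ("his", "Histidine", "His"),
    ("ile", "Isoleucine", "Ile"),
    ("leu", "Leucine", "Leu"),
    ("lys", "Lysine", "Lys"),
    ("met", "Methionine", "Met"),
    ("phe", "Phenylalanine", "Phe"),
    ("pro", "Proline", "Pro"),
    ("ser", "Serine", "Ser"),
    ("thr", "Threonine", "Thr"),
    ("trp", "Tryptophan", "Trp"),
    ("tyr", "Tyrosine", "Tyr"),
    ("val", "Valine", "Val"),
]

_NXP = [
    (f"{b}{p}", f"{base} {phos}", f"{b.upper()}{p.upper()}")
    for b, base in [("a", "Adenosine"), ("g", "Guanosine"), ("c", "Cytidine"), ("u", "Uridine")]
    for p, phos in [("mp", "monophosphate"), ("dp", "diphosphate"), ("tp", "triphosphate")]
]

_DNXP = [
    (f"d{b}{p}", f"Deoxy{base.lower()} {phos}", f"d{b.upper()}{p.upper()}")
    for b, base in [("a", "Adenosine"), ("g", "Guanosine"), ("c", "Cytidine"), ("t", "Thymidine")]
    for p, phos in [("mp", "monophosphate"), ("dp", "diphosphate"), ("tp", "triphosphate")]
]

_GLYCOLYSIS = [
    ("g6p", "Glucose 6-phosphate", "G6P", "glycolysis:01"),
    ("f6p", "Fructose 6-phosphate", "F6P", "glycolysis:02"),
    ("fbp", "Fructose 1,6-bisphosphate", "FBP", "glycolysis:03"),
    ("dhap", "Dihydroxyacetone phosphate", "DHAP", "glycolysis:04"),
    ("ga3p", "Glyceraldehyde 3-phosphate", "GA3P", "glycolysis:05"),
    ("3pg", "3-Phosphoglyceric acid", "3PG", "glycolysis:06"),
    ("pep", "Phosphoenolpyruvic acid", "PEP", "glycolysis:07"),
    ("pyr", "Pyruvic acid", "Pyr", "glycolysis:08"),
]

_PPP = [
    ("6pg", "6-Phosphogluconic acid", "6PG", "ppp:01"),
    ("rl5p", "Ribulose 5-phosphate", "RL5P", "ppp:02"),
    ("x5p", "Xylulose 5-phosphate", "X5P", "ppp:03"),
    ("r5p", "Ribose 5-phosphate", "R5P", "ppp:04"),
    ("s7p", "Sedoheptulose 7-phosphate", "S7P", "ppp:05"),
    ("e4p", "Erythrose 4-phosphate", "E4P", "ppp:06"),
]

_TCA = [
    ("cit", "Citric acid", "Cit", "tca:01"),
    ("aco", "cis-Aconitic acid", "Aco", "tca:02"),
    ("akg", "alpha-Ketoglutaric acid", "aKG", "tca:03"),
    ("suc", "Succinic acid", "Suc", "tca:04"),
    ("fum", "Fumaric acid", "Fum", "tca:05"),
    ("mal", "Malic acid", "Mal", "tca:06"),
    ("oaa", "Oxaloacetic acid", "OAA", "tca:07"),
]

_ORGANIC_OTHER = [
    ("lac", "Lactic acid", "Lac", "fermentation:01"),
    ("ace", "Acetic acid", "Ace", "fermentation:02"),
    ("glx", "Glyoxylic acid", "Glx", "glyoxylate:01"),
]

# Organic acids measured on the dedicated LC method against the U13C-labeled
# whole-cell extract (pyruvate and lactate isotopologues are supplemented).
_LC_ORGANIC_IDS = {"pyr", "lac", "ace", "glx"}


def _build_default() -> tuple[MetaboliteDef, ...]:
    mets: list[MetaboliteDef] = []
    for mid, name, abbr in _AMINO_ACIDS:
        mets.append(
            MetaboliteDef(mid, name, abbr, MetClass.amino_acid,
                          Method.LC_amino_acid, IsKind.labeled_amino_acid_mix,
                          "amino_acid_pool")
        )
    for mid, name, abbr in _NXP:
        mets.append(
            MetaboliteDef(mid, name, abbr, MetClass.nucleoside_phosphate,
                          Method.capIC, IsKind.matched_isotopologue,
                          "nucleotide_pool")
        )
    for mid, name, abbr in _DNXP:
        mets.append(
            MetaboliteDef(mid, name, abbr, MetClass.deoxynucleoside_phosphate,
                          Method.capIC, IsKind.matched_isotopologue,
                          "deoxynucleotide_pool")
        )
    for group, met_class in [
        (_GLYCOLYSIS, MetClass.glycolysis),
        (_PPP, MetClass.PPP),
        (_TCA, MetClass.TCA),
        (_ORGANIC_OTHER, MetClass.organic_acid_other),
    ]:
        for mid, name, abbr, pos in group:
            if mid in _LC_ORGANIC_IDS:
                method, is_kind = Method.LC_organic_acid, IsKind.labeled_extract
            else:
                method, is_kind = Method.capIC, IsKind.matched_isotopologue
            mets.append(MetaboliteDef(mid, name, abbr, met_class, method, is_kind, pos))
    return tuple(mets)


_DEFAULT = _build_default()


def default_panel() -> MetabolitePanel:
    """Return the packaged 68-metabolite registry (deterministic)."""
    return MetabolitePanel(metabolites=_DEFAULT, version="1.0")


def save_panel(panel: MetabolitePanel, path) -> None:
    """Write a panel as UTF-8 CSV with the canonical header."""
    panel.to_frame().to_csv(path, index=False)


def load_panel(path) -> MetabolitePanel:
    """Load a panel CSV, enforcing unique ids and known enum tokens."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "pathway_position"]
    if missing:
        raise ValidationError(f"panel file missing column(s): {', '.join(missing)}")
    if "pathway_position" not in df.columns:
        df["pathway_position"] = ""
    mets = []
    for row in df.itertuples(index=False):
        try:
            mets.append(
                MetaboliteDef(
                    metabolite_id=row.metabolite_id,
                    name=row.name,
                    abbreviation=row.abbreviation,
                    met_class=row.met_class,
                    method=row.method,
                    is_kind=row.is_kind,
                    pathway_position=row.pathway_position,
                )
            )
        except ValueError as exc:
            raise ValidationError(
                f"invalid panel entry {row.metabolite_id!r}: {exc}"
            ) from exc
    return MetabolitePanel(metabolites=tuple(mets), version="file")
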