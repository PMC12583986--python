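"""Structural taxonomy of bacteriohopanepolyol derivatives (BHPDs).

A BHPD is described as a hopanoid core (optionally methylated in ring A at
C-2 or C-3, optionally unsaturated at the 6 and/or 11 position) combined
with one of five groups of functionalized side chains:

* nucleoside   -- adenosyl/inosyl hopanes and their N-methylated variants
* polyol       -- BHT (bacteriohopanetetrol), BHpentol, BHhexol and simple
                  tetrol derivatives (methyl ether, ethenolamine, acyl esters,
                  anhydro forms)
* ce           -- cyclitol ethers and their biosynthetic precursors
                  (N-acetylglucosamine and glucosamine adducts of the polyol)
* carbamoyl    -- C-35 carbamoyl esters of the polyols
* amino        -- 35-amino polyols and their N-acyl amino-acid conjugates

The C-22 side-chain stereocentre is tracked separately (R, S or unknown)
because the 22S epimer is diagnostic for a clade of Acetobacteraceae.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BhpdStructure",
    "SIDE_CHAIN_GROUPS",
    "parse_code",
    "reference_structures",
]

#: The five side-chain groups used for inventory summaries.
SIDE_CHAIN_GROUPS = ("nucleoside", "polyol", "ce", "carbamoyl", "amino")

_NUCLEOSIDE_SUBTYPES = {"adenosyl", "Me-adenosyl", "diMe-adenosyl", "inosyl", "N-Me-inosyl"}
_TETROL_DERIV_SUBTYPES = {"Me-ether", "ethenolamine", "monoacyl", "diacyl"}
_AMINO_SUBTYPES = {"aminotriol", "aminotetrol", "N-acyl-amino-acid"}
_CE_STAGES = {"acetylglucosamine", "glucosamine", "cyclitol", "Me-cyclitol"}
_BASES = {"tetrol", "pentol", "hexol"}

_CLASSES = {
    "nucleoside", "tetrol", "tetrol_derivative", "pentol", "hexol",
    "anhydro_pentol", "ce_series", "carbamoyl", "amino",
}


@dataclass(frozen=True)
class BhpdStructure:
    """One BHPD as core x side chain x unsaturation x C-22 configuration."""

    side_chain_class: str
    subtype: str | None = None
    base: str | None = None
    stage: str | None = None
    ring_a_methyl: str = "none"          # none | 2Me | 3Me
    unsaturation: frozenset = frozenset()  # subset of {"D6", "D11"}
    c22_config: str = "unknown"          # R | S | unknown
    isomer_note: str | None = None

    def __post_init__(self):
        cls = self.side_chain_class
        if cls not in _CLASSES:
            raise ValueError(f"unknown side-chain class {cls!r}")
        if cls == "nucleoside":
            if self.subtype not in _NUCLEOSIDE_SUBTYPES:
                raise ValueError(f"nucleoside subtype must be one of {sorted(_NUCLEOSIDE_SUBTYPES)}")
        elif cls == "tetrol_derivative":
            if self.subtype not in _TETROL_DERIV_SUBTYPES:
                raise ValueError(f"tetrol derivative subtype must be one of {sorted(_TETROL_DERIV_SUBTYPES)}")
        elif cls == "amino":
            if self.subtype not in _AMINO_SUBTYPES:
                raise ValueError(f"amino subtype must be one of {sorted(_AMINO_SUBTYPES)}")
        elif self.subtype is not None:
            raise ValueError(f"{cls} takes no subtype")
        if cls == "ce_series":
            if self.base not in _BASES or self.stage not in _CE_STAGES:
                raise ValueError("ce_series requires base in {tetrol,pentol,hexol} and a valid stage")
        elif cls == "carbamoyl":
            if self.base not in _BASES:
                raise ValueError("carbamoyl requires base in {tetrol,pentol,hexol}")
            if self.stage is not None:
                raise ValueError("carbamoyl takes no stage")
        else:
            if self.base is not None or self.stage is not None:
                raise ValueError(f"{cls} takes neither base nor stage")
        if self.ring_a_methyl not in {"none", "2Me", "3Me"}:
            raise ValueError("ring_a_methyl must be none, 2Me or 3Me")
        if not isinstance(self.unsaturation, frozenset):
            object.__setattr__(self, "unsaturation", frozenset(self.unsaturation))
        if not self.unsaturation <= {"D6", "D11"}:
            raise ValueError("unsaturation positions limited to D6 and D11")
        if self.c22_config not in {"R", "S", "unknown"}:
            raise ValueError("c22_config must be R, S or unknown")

    @property
    def group(self) -> str:
        """The side-chain group used in inventory summaries."""
        if self.side_chain_class == "nucleoside":
            return "nucleoside"
        if self.side_chain_class == "ce_series":
            return "ce"
        if self.side_chain_class == "carbamoyl":
            return "carbamoyl"
        if self.side_chain_class == "amino":
            return "amino"
        return "polyol"

    @property
    def pentol_or_hexol_based(self) -> bool:
        """True for side chains carrying five or six oxygen functions.

        Covers BHpentol/BHhexol themselves, their anhydro, cyclitol-ether and
        carbamoyl derivatives, and the amino tetrol (which degrades like a
        pentol: its first hydroxyl sits at C-31).
        """
        if self.side_chain_class in {"pentol", "hexol", "anhydro_pentol"}:
            return True
        if self.side_chain_class in {"ce_series", "carbamoyl"}:
            return self.base in {"pentol", "hexol"}
        return self.side_chain_class == "amino" and self.subtype == "aminotetrol"

    @property
    def is_unsaturated(self) -> bool:
        return bool(self.unsaturation)


# --- code table -----------------------------------------------------------
# Roman-numeral base codes for the structure roster; suffixes select the
# ring-A methyl ("2Me"/"3Me"), unsaturation ("d6"/"d11"), epimer ("22S")
# and isomer annotations ("iso2", "iso3").

_BASE_CODES: dict[str, dict] = {
    "Ia": dict(side_chain_class="nucleoside", subtype="adenosyl", c22_config="R"),
    "Ib": dict(side_chain_class="nucleoside", subtype="Me-adenosyl"),
    "Ic": dict(side_chain_class="nucleoside", subtype="diMe-adenosyl"),
    "Id": dict(side_chain_class="nucleoside", subtype="inosyl"),
    "Ie": dict(side_chain_class="nucleoside", subtype="N-Me-inosyl"),
    "IIa": dict(side_chain_class="tetrol", c22_config="R"),
    "IIb": dict(side_chain_class="tetrol_derivative", subtype="Me-ether"),
    "IIc": dict(side_chain_class="tetrol_derivative", subtype="ethenolamine"),
    "IId": dict(side_chain_class="tetrol_derivative", subtype="monoacyl"),
    "IIe": dict(side_chain_class="tetrol_derivative", subtype="diacyl"),
    "IIf": dict(side_chain_class="pentol"),
    "IIg": dict(side_chain_class="anhydro_pentol"),
    "IIi": dict(side_chain_class="hexol"),
    "IIIa": dict(side_chain_class="ce_series", base="tetrol", stage="acetylglucosamine"),
    "IIIb": dict(side_chain_class="ce_series", base="tetrol", stage="glucosamine"),
    "IIIc": dict(side_chain_class="ce_series", base="tetrol", stage="cyclitol"),
    "IIIcMe": dict(side_chain_class="ce_series", base="tetrol", stage="Me-cyclitol"),
    "IIId": dict(side_chain_class="ce_series", base="pentol", stage="cyclitol"),
    "IIIe": dict(side_chain_class="ce_series", base="hexol", stage="cyclitol"),
    "IVa": dict(side_chain_class="carbamoyl", base="tetrol"),
    "IVb": dict(side_chain_class="carbamoyl", base="pentol"),
    "IVc": dict(side_chain_class="carbamoyl", base="hexol"),
    "Va": dict(side_chain_class="amino", subtype="aminotriol"),
    "Vb": dict(side_chain_class="amino", subtype="aminotetrol"),
    "Vc": dict(side_chain_class="amino", subtype="N-acyl-amino-acid", isomer_note="N-tryptophanyl"),
    "Vd": dict(side_chain_class="amino", subtype="N-acyl-amino-acid", isomer_note="N-phenylalanyl"),
    "Ve": dict(side_chain_class="amino", subtype="N-acyl-amino-acid", isomer_note="N-ornithinyl"),
}


def parse_code(code: str) -> BhpdStructure:
    """Build a :class:`BhpdStructure` from a compact code like ``IIa-3Me-d6``.

    The leading token selects the side chain (see the roster in
    :func:`reference_structures`); optional dash-separated suffixes add
    ring-A methylation (``2Me``/``3Me``), double bonds (``d6``/``d11``),
    the C-22 epimer (``22S``/``22R``) or an isomer annotation (``iso<n>``).
    """
    tokens = code.split("-")
    base = tokens[0]
    # "IIIc-Me" denotes the methylated-cyclitol variant, not ring-A methylation
    if len(tokens) > 1 and tokens[1] == "Me":
        base, tokens = "IIIcMe", [base] + tokens[2:]
    if base not in _BASE_CODES:
        raise ValueError(f"unknown structure code {code!r}")
    kwargs = dict(_BASE_CODES[base])
    uns = set()
    for tok in tokens[1:]:
        if tok in {"2Me", "3Me"}:
            kwargs["ring_a_methyl"] = tok
        elif tok == "d6":
            uns.add("D6")
        elif tok == "d11":
            uns.add("D11")
        elif tok in {"22S", "22R"}:
            kwargs["c22_config"] = tok[-1]
        elif tok.startswith("iso"):
            kwargs["isomer_note"] = tok
        else:
            raise ValueError(f"unknown suffix {tok!r} in structure code {code!r}")
    if uns:
        kwargs["unsaturation"] = frozenset(uns)
    return BhpdStructure(**kwargs)


_ROSTER_CODES = [
    # nucleosides
    "Ia", "Ia-22S", "Ia-d6", "Ia-2Me",
    "Ib-iso1", "Ib-iso2", "Ib-iso3", "Ic", "Id", "Ie",
    # tetrol / pentol / hexol and simple derivatives
    "IIa", "IIa-22S", "IIa-d6", "IIa-d11", "IIa-d6-d11",
    "IIa-2Me", "IIa-3Me", "IIa-3Me-d6", "IIa-3Me-d11", "IIa-3Me-d6-d11",
    "IIb", "IIb-d6", "IIc", "IId", "IIe",
    "IIf", "IIf-d6", "IIg", "IIg-d6", "IIi",
    # cyclitol ethers and precursors
    "IIIa", "IIIb", "IIIb-iso2", "IIIb-d6", "IIIb-3Me",
    "IIIc", "IIIc-22S", "IIIc-iso2", "IIIc-d6", "IIIc-d11", "IIIc-Me",
    "IIIc-3Me", "IIIc-3Me-d6",
    "IIId", "IIId-d6", "IIId-d11", "IIId-d6-d11", "IIId-3Me", "IIId-3Me-d6",
    "IIIe", "IIIe-d6",
    # carbamoyl
    "IVa", "IVb", "IVc",
    # amino
    "Va", "Va-iso2", "Va-d6", "Va-2Me", "Vb", "Vc", "Vd", "Ve",
    # remaining unsaturated CE variant
    "IIIa-d6",
]


def reference_structures() -> dict[str, BhpdStructure]:
    """The packaged roster of 63 distinct BHPD structures, keyed by code."""
    roster = {code: parse_code(code) for code in _ROSTER_CODES}
    assert len(roster) == 63
    return roster
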