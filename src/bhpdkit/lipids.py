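"""Measurement-side arithmetic for hopanoid lipid quantification.

Covers internal-standard quantification of hopanols released by periodate/
borohydride (Rohmer) degradation, the MRM-based degree of ring-A
methylation, the C-22 epimer fraction, relative-abundance normalization of
LC inventories, and inventory summary statistics.

Degree-of-methylation measurements rely on separate MRM channels: the
non-methylated skeleton is read from the transition to *m/z* 191 (the
AB-ring fragment) and the ring-A methylated skeleton from the transition to
*m/z* 205, so coelution of the two species does not bias the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import SIDE_CHAIN_GROUPS, BhpdStructure

__all__ = [
    "MrmPeak",
    "LipidInventory",
    "InventorySummary",
    "quantify_by_internal_standard",
    "methylation_degree",
    "epimer_fraction",
    "normalize_inventory",
    "summarize_inventory",
    "render_value",
    "DETECTION_FLOOR_PCT",
]

#: Relative-abundance detection floor of the MRM method (percent).
DETECTION_FLOOR_PCT = 0.01


@dataclass(frozen=True)
class MrmPeak:
    """One integrated MRM transition peak (areas in arbitrary units)."""

    analyte: str
    transition: tuple  # (precursor m/z, product m/z)
    area: float

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class LipidInventory:
    """Per-species list of (structure, relative abundance %) entries."""

    species: str
    entries: list  # (BhpdStructure, float) with abundances summing to 100

    def total(self) -> float:
        return sum(a for _, a in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class InventorySummary:
    n_bhpds: int
    pct_unsaturated: float
    pct_pentol_plus_hexol: float
    pct_by_group: dict
    pct_22s: float | None = None  # None when no structure has a known C-22 config


def quantify_by_internal_standard(analyte_area: float, is_area: float,
                                  is_mass_mg: float, biomass_g: float) -> float:
    """Semi-quantitative concentration in mg per g dry cells.

    Assumes a response factor of 1 relative to the internal standard
    (n-tricosan-1-ol): concentration = analyte/IS area ratio x IS mass /
    biomass.
    """
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    if analyte_area < 0:
        raise ValueError("analyte area must be non-negative")
    return (analyte_area / is_area) * is_mass_mg / biomass_g


def methylation_degree(area_methylated: float, area_unmethylated: float) -> float:
    """Percent ring-A methylation: 100 x Me / (Me + non-Me) peak areas."""
    if area_methylated < 0 or area_unmethylated < 0:
        raise ValueError("areas must be non-negative")
    total = area_methylated + area_unmethylated
    if total == 0:
        raise ValueError("degree of methylation undefined: both areas are zero")
    return 100.0 * area_methylated / total


def epimer_fraction(area_22s: float, area_22r: float) -> float:
    """Percent 22S epimer: 100 x S / (S + R) peak areas."""
    if area_22s < 0 or area_22r < 0:
        raise ValueError("areas must be non-negative")
    total = area_22s + area_22r
    if total == 0:
        raise ValueError("epimer fraction undefined: both areas are zero")
    return 100.0 * area_22s / total


def normalize_inventory(raw: list, species: str = "sample") -> LipidInventory:
    """Turn (structure, response) pairs into relative abundances (sum 100).

    Structures with zero response are dropped; an all-zero input is an
    error rather than an empty inventory.
    """
    for s, r in raw:
        if r < 0:
            raise ValueError("responses must be non-negative")
    total = sum(r for _, r in raw)
    if total == 0:
        raise ValueError("cannot normalize an all-zero inventory")
    entries = [(s, 100.0 * r / total) for s, r in raw if r > 0]
    return LipidInventory(species, entries)


def summarize_inventory(inv: LipidInventory) -> InventorySummary:
    """Summary statistics over a normalized inventory.

    ``pct_pentol_plus_hexol`` sums abundances of every structure whose side
    chain is pentol- or hexol-based, including cyclitol-ether and carbamoyl
    derivatives.  ``pct_22s`` is computed over the subset of structures with
    a known C-22 configuration (None when there is none).
    """
    if not inv.entries:
        return InventorySummary(0, 0.0, 0.0, {g: 0.0 for g in SIDE_CHAIN_GROUPS})
    by_group = {g: 0.0 for g in SIDE_CHAIN_GROUPS}
    unsat = 0.0
    pentol_hexol = 0.0
    known_cfg = 0.0
    s22 = 0.0
    for s, a in inv.entries:
        by_group[s.group] += a
        if s.is_unsaturated:
            unsat += a
        if s.pentol_or_hexol_based:
            pentol_hexol += a
        if s.c22_config != "unknown":
            known_cfg += a
            if s.c22_config == "S":
                s22 += a
    pct_22s = 100.0 * s22 / known_cfg if known_cfg > 0 else None
    return InventorySummary(
        n_bhpds=len(inv.entries),
        pct_unsaturated=unsat,
        pct_pentol_plus_hexol=pentol_hexol,
        pct_by_group=by_group,
        pct_22s=pct_22s,
    )


def render_value(value: float) -> str:
    """Report-style rendering: one decimal below 10, nearest integer above."""
    if value >= 10:
        return str(int(round(value)))
    return f"{value:.1f}"
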