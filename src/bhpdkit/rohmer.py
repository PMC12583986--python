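"""In-silico periodate/borohydride (Rohmer) degradation of BHPDs.

Periodic acid cleaves the BHPD side chain at vicinal diols; borohydride
reduction then yields a GC-amenable hopanol whose carbon number
fingerprints the parent polyol class:

====================================  =======================
parent side chain                     product
====================================  =======================
nucleoside (no free vicinal diol)     none
tetrol-based (incl. CE stages,
carbamoyl tetrol, aminotriol,
Me-ether / ethenolamine / acyl
tetrol derivatives)                   bishomohopan-32-ol (C32)
pentol-based (incl. aminotetrol)      homohopan-31-ol  (C31)
hexol-based                           hopan-30-ol      (C30)
anhydro-pentol (internal ether
consumes the free diol)               none
====================================  =======================

Cyclitol-ether and glucosamine side chains are treated as cleavable at the
polyol diols; the sugar/cyclitol ring's own diols do not change the product
carbon number.  Ring-A methylation, ring unsaturation and the C-22
configuration survive degradation unchanged, which is what makes the GC
profile a cross-platform check on the LC inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lipids import InventorySummary, LipidInventory
from .structures import BhpdStructure

__all__ = [
    "HopanolProduct",
    "GcProfile",
    "ConsistencyReport",
    "degradation_product",
    "predict_gc_profile",
    "cross_platform_check",
]

_BASE_CARBON = {"tetrol": 32, "pentol": 31, "hexol": 30}


@dataclass(frozen=True)
class HopanolProduct:
    carbon_number: int           # 30 | 31 | 32
    ring_a_methyl: str = "none"  # none | 2Me | 3Me
    n_double_bonds: int = 0
    c22_config: str = "unknown"

    def __post_init__(self):
        if self.carbon_number not in {30, 31, 32}:
            raise ValueError("hopanol carbon number must be 30, 31 or 32")
        if not 0 <= self.n_double_bonds <= 2:
            raise ValueError("0-2 double bonds supported")


def degradation_product(s: BhpdStructure) -> HopanolProduct | None:
    """Map an intact BHPD to its Rohmer product, or None if uncleavable."""
    cls = s.side_chain_class
    if cls == "nucleoside" or cls == "anhydro_pentol":
        return None
    if cls in {"tetrol", "tetrol_derivative"}:
        carbon = 32
    elif cls == "pentol":
        carbon = 31
    elif cls == "hexol":
        carbon = 30
    elif cls in {"ce_series", "carbamoyl"}:
        carbon = _BASE_CARBON[s.base]
    else:  # amino
        carbon = 31 if s.subtype == "aminotetrol" else 32
    return HopanolProduct(
        carbon_number=carbon,
        ring_a_methyl=s.ring_a_methyl,
        n_double_bonds=len(s.unsaturation),
        c22_config=s.c22_config,
    )


@dataclass
class GcProfile:
    """Distribution over hopanol products plus the LC-invisible fraction."""

    shares: dict  # HopanolProduct -> percent of visible products
    invisible_pct: float  # inventory share that yields no product

    def share_by_carbon(self, carbon: int) -> float:
        return sum(p for prod, p in self.shares.items() if prod.carbon_number == carbon)

    @property
    def pct_unsaturated(self) -> float:
        return sum(p for prod, p in self.shares.items() if prod.n_double_bonds > 0)

    @property
    def pct_22s(self) -> float | None:
        known = sum(p for prod, p in self.shares.items() if prod.c22_config != "unknown")
        if known == 0:
            return None
        s = sum(p for prod, p in self.shares.items() if prod.c22_config == "S")
        return 100.0 * s / known


def predict_gc_profile(inv: LipidInventory) -> GcProfile:
    """Abundance-weighted degradation of a normalized LC inventory."""
    visible: dict[HopanolProduct, float] = {}
    invisible = 0.0
    for s, a in inv.entries:
        prod = degradation_product(s)
        if prod is None:
            invisible += a
        else:
            visible[prod] = visible.get(prod, 0.0) + a
    total = sum(visible.values())
    shares = {p: 100.0 * a / total for p, a in visible.items()} if total > 0 else {}
    return GcProfile(shares, invisible)


@dataclass
class ConsistencyReport:
    """Cross-platform deltas between an LC summary and a GC profile."""

    deltas: dict          # metric -> absolute difference in percentage points
    passed: dict          # metric -> bool
    tolerance_pct: float

    @property
    def all_pass(self) -> bool:
        return all(self.passed.values())


def cross_platform_check(lc: InventorySummary, gc: GcProfile,
                         tolerance_pct: float = 15.0) -> ConsistencyReport:
    """Compare polyol-class, unsaturation and epimer signals across platforms.

    The LC pentol+hexol share should match the C31+C30 share of the visible
    GC products; unsaturation and 22S fractions likewise.  Metrics that
    neither platform can measure (e.g. no structure with a known C-22
    configuration) are skipped.
    """
    deltas = {}
    deltas["pentol_plus_hexol"] = abs(
        lc.pct_pentol_plus_hexol - (gc.share_by_carbon(31) + gc.share_by_carbon(30)))
    deltas["unsaturated"] = abs(lc.pct_unsaturated - gc.pct_unsaturated)
    if lc.pct_22s is not None and gc.pct_22s is not None:
        deltas["epimer_22s"] = abs(lc.pct_22s - gc.pct_22s)
    passed = {k: v <= tolerance_pct for k, v in deltas.items()}
    return ConsistencyReport(deltas, passed, tolerance_pct)
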