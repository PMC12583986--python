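"""Genotype assembly and biosynthesis rules predicting producible chemotypes.

The rule engine encodes the known pathway logic:

* ``shc`` alone permits C30 hopanoids (diploptene/diplopterol);
* ``shc + hpnH`` opens the C35 branch via adenosylhopane;
* ``+ hpnG`` (adenine removal) permits BHT;
* ``+ hpnO`` permits 35-aminobacteriohopanetriol;
* ``hpnI / hpnK / hpnJ`` select the terminal cyclitol-ether stage
  (N-acetylglucosamine -> glucosamine -> cyclitol ether);
* ``hpnP`` / ``hpnR`` confer the *capacity* for ring-A methylation at C-2 /
  C-3 -- the gene does not guarantee detectable product;
* ``ths`` permits tetrahymanol;
* a desaturase-like gene only *suggests* unsaturation capacity; BHpentol,
  BHhexol and unsaturation have no established genes, so no rule asserts
  them.

Genes with "unknown" status never switch a flag on; they are surfaced as
confidence notes instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import GeneFamilyCatalog, load_gene_catalog

__all__ = ["GenomeGenotype", "ChemotypePrediction", "assemble_genotype", "predict_chemotype"]

_MEP_CORE = ("dxr", "ispE", "ispG", "ispH", "ispA")


@dataclass
class GenomeGenotype:
    genome_id: str
    presence: dict  # family_id -> "present" | "absent" | "unknown"
    mep_complete: bool
    mep_bypass_note: str | None = None
    architecture: object | None = None

    def state(self, family_id: str) -> str:
        return self.presence.get(family_id, "absent")

    def has(self, family_id: str) -> bool:
        return self.state(family_id) == "present"


@dataclass
class ChemotypePrediction:
    """Producible lipid classes implied by a genotype.

    All flags are capacities, not guarantees; ``unsaturation_suggested`` is
    advisory only (no unsaturation gene is established).
    """

    c30_hopanoids: bool = False
    bhpd_any: bool = False
    adenosylhopane: bool = False
    bht: bool = False
    aminotriol: bool = False
    ce_acetylglucosamine_terminal: bool = False
    ce_glucosamine_terminal: bool = False
    ce_terminal: bool = False
    methyl_2: bool = False
    methyl_3: bool = False
    dimethyl_2_3_possible: bool = False
    tetrahymanol: bool = False
    unsaturation_suggested: bool = False
    confidence_notes: list = field(default_factory=list)

    def __post_init__(self):
        assert not self.bhpd_any or self.c30_hopanoids
        assert not self.bht or self.bhpd_any
        assert not self.ce_terminal or self.bht
        assert sum([self.ce_acetylglucosamine_terminal,
                    self.ce_glucosamine_terminal, self.ce_terminal]) <= 1


def assemble_genotype(hits: list, architecture=None,
                      catalog: GeneFamilyCatalog | None = None,
                      genome_id: str | None = None) -> GenomeGenotype:
    """Fold scanner hits into a presence map over the full catalog.

    MEP-pathway completeness requires dxs (or an aceE-like bypass), dxr,
    ispD+ispF (or the fused ispDF), ispE, ispG, ispH and ispA.
    """
    catalog = catalog or load_gene_catalog()
    genomes = {h.genome_id for h in hits}
    if len(genomes) > 1:
        raise ValueError(f"hits from multiple genomes: {sorted(genomes)}")
    gid = genome_id or (genomes.pop() if genomes else "genome")
    accepted = {h.family_id for h in hits if h.call == "accepted"}
    presence = {fam: ("present" if fam in accepted else "absent")
                for fam in catalog.family_ids()}
    g = lambda fam: presence.get(fam) == "present"

    bypass_note = None
    dxs_ok = g("dxs")
    if not dxs_ok and g("aceE"):
        dxs_ok = True
        bypass_note = "dxs absent; aceE-like bypass present"
    ispdf_ok = (g("ispD") and g("ispF")) or g("ispDF")
    mep = dxs_ok and ispdf_ok and all(g(f) for f in _MEP_CORE)
    return GenomeGenotype(gid, presence, mep, bypass_note, architecture)


def predict_chemotype(genotype: GenomeGenotype) -> ChemotypePrediction:
    """Apply the biosynthesis rules to a genotype."""
    notes: list[str] = []

    def has(fam: str) -> bool:
        state = genotype.state(fam)
        if state == "unknown":
            notes.append(f"{fam} status unknown; treated as absent for prediction")
            return False
        return state == "present"

    shc = has("shc")
    hpnH = has("hpnH")
    hpnG = has("hpnG")
    c30 = shc
    bhpd = shc and hpnH
    bht = bhpd and hpnG
    amino = bht and has("hpnO")
    hpnI, hpnK, hpnJ = has("hpnI"), has("hpnK"), has("hpnJ")
    ce_acgn = bht and hpnI and not hpnK
    ce_gn = bht and hpnI and hpnK and not hpnJ
    ce = bht and hpnI and hpnK and hpnJ
    me2, me3 = has("hpnP"), has("hpnR")
    if not genotype.mep_complete:
        notes.append("MEP pathway incomplete; isoprenoid supply not confirmed")
    if genotype.mep_bypass_note:
        notes.append(genotype.mep_bypass_note)
    return ChemotypePrediction(
        c30_hopanoids=c30,
        bhpd_any=bhpd,
        adenosylhopane=bhpd,
        bht=bht,
        aminotriol=amino,
        ce_acetylglucosamine_terminal=ce_acgn,
        ce_glucosamine_terminal=ce_gn,
        ce_terminal=ce,
        methyl_2=me2,
        methyl_3=me3,
        dimethyl_2_3_possible=me2 and me3,
        tetrahymanol=has("ths"),
        unsaturation_suggested=has("desat") or has("hpnX"),
        confidence_notes=notes,
    )
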