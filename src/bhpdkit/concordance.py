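"""Genotype-vs-phenotype concordance and survey statistics.

Each concordance feature pairs a diagnostic marker gene with a measured
phenotype: squalene-hopene cyclase (shc) for BHPD production, hpnP/hpnR
for ring-A methylation at C-2/C-3, and ths for tetrahymanol.  Every
(species, feature) pair falls into one of the cells gene+product+,
gene+product-, gene-product+, gene-product- or unknown.  A
gene-present/product-absent cell is a legitimate biological outcome (a
methylation gene is a capacity, not a guarantee), not a pipeline error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .catalog import FixtureTable, load_fixture
from .lipids import DETECTION_FLOOR_PCT, render_value

__all__ = [
    "FEATURE_MARKERS",
    "PanelRecord",
    "ConcordanceReport",
    "SurveyStats",
    "PanelSummary",
    "concordance_table",
    "survey_fractions",
    "panel_counts",
    "build_fixture_panel",
]

#: Marker gene whose presence defines the "gene+" state of each feature.
FEATURE_MARKERS = {
    "c30_hopanoids": "shc",
    "bhpd_any": "shc",
    "methyl_2": "hpnP",
    "methyl_3": "hpnR",
    "tetrahymanol": "ths",
}

OUTCOMES = ("gene+product+", "gene+product-", "gene-product+", "gene-product-", "unknown")


@dataclass
class PanelRecord:
    """One species' matched genotype and phenotype observations."""

    species: str
    gene_states: dict      # family_id -> present | absent | unknown
    phenotype: dict        # feature -> True | False | None (not determined)
    prediction: object | None = None


@dataclass
class ConcordanceReport:
    counts: dict   # feature -> Counter over OUTCOMES
    n_species: int

    def outcome(self, feature: str, cell: str) -> int:
        return self.counts[feature][cell]

    def positive_predictive_value(self, feature: str) -> float | None:
        c = self.counts[feature]
        denom = c["gene+product+"] + c["gene+product-"]
        return c["gene+product+"] / denom if denom else None

    def negative_predictive_value(self, feature: str) -> float | None:
        c = self.counts[feature]
        denom = c["gene-product-"] + c["gene-product+"]
        return c["gene-product-"] / denom if denom else None

    def n_gene_positive(self, feature: str) -> int:
        c = self.counts[feature]
        return c["gene+product+"] + c["gene+product-"]


def concordance_table(panel: list, features=None) -> ConcordanceReport:
    """Tabulate 2x2 concordance cells per feature over a species panel."""
    features = list(features or FEATURE_MARKERS)
    missing = [f for f in features if f not in FEATURE_MARKERS]
    if missing:
        raise ValueError(f"no marker gene defined for features: {missing}")
    species = [r.species for r in panel]
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(f"duplicate species in panel: {dupes}")
    counts = {f: Counter({o: 0 for o in OUTCOMES}) for f in features}
    for rec in panel:
        for feat in features:
            gene = rec.gene_states.get(FEATURE_MARKERS[feat], "unknown")
            product = rec.phenotype.get(feat)
            if gene == "unknown" or product is None:
                counts[feat]["unknown"] += 1
                continue
            cell = f"gene{'+' if gene == 'present' else '-'}product{'+' if product else '-'}"
            counts[feat][cell] += 1
    return ConcordanceReport(counts, len(panel))


@dataclass(frozen=True)
class SurveyStats:
    taxon: str
    level: str       # genus | genome
    n_total: int
    n_with_gene: int
    fraction_pct: float
    rendered: str

    def __post_init__(self):
        assert 0 <= self.n_with_gene <= self.n_total


def survey_fractions(counts, level: str | None = None) -> list:
    """Percentage of taxa carrying the gene, with report-style rounding.

    ``counts`` is a FixtureTable or DataFrame with columns taxon, level,
    n_total, n_with_gene.
    """
    frame = counts.frame if isinstance(counts, FixtureTable) else counts
    out = []
    for _, row in frame.iterrows():
        if level is not None and row["level"] != level:
            continue
        n_total, n_gene = int(row["n_total"]), int(row["n_with_gene"])
        if n_total <= 0:
            raise ValueError(f"zero denominator for taxon {row['taxon']!r}")
        pct = 100.0 * n_gene / n_total
        out.append(SurveyStats(row["taxon"], row["level"], n_total, n_gene,
                               pct, render_value(pct)))
    return out


@dataclass
class PanelSummary:
    """Derived counts and statistics over the measured lipid panel."""

    n_species: int
    n_rohmer_measured: int
    n_no_rohmer_products: int
    n_c30_measured: int
    n_no_c30_hopanoids: int
    n_no_intact_bhpds: int
    n_tetrahymanol_producers: int
    max_22s_pct: float
    mean_2me_c32_hopanol: float
    max_2me_c32_hopanol: float
    n_2me_c32_detected: int
    mean_2me_hop17_21_ene: float
    mean_2me_tetrahymanol: float


_C30_COLUMNS = ("hop22_29_ene", "hop17_21_ene", "diplopterol")


def panel_counts(rohmer: FixtureTable | None = None,
                 methylation: FixtureTable | None = None) -> PanelSummary:
    """Compute the lipid-panel statistics from the fixture tables.

    Counts with "determined" denominators exclude species whose
    measurement is marked not-determined; counts over the whole panel use
    all rows.  Column means are taken over species where the analyte was
    detected (the detection floor of the MRM method is 0.01%).
    """
    t3 = rohmer or load_fixture("rohmer_T3")
    t4 = methylation or load_fixture("methylation_T4")

    sum_bhpds = t3.numeric("sum_bhpds")
    measured = ~t3.not_determined("sum_bhpds")
    no_rohmer = (measured & t3.below_detection("sum_bhpds")).sum()

    c30_nd = t3.not_determined(_C30_COLUMNS[0])
    for col in _C30_COLUMNS[1:]:
        c30_nd |= t3.not_determined(col)
    no_c30 = (~c30_nd).copy()
    for col in _C30_COLUMNS:
        no_c30 &= t3.below_detection(col)

    n_bhpds = t3.numeric("n_bhpds")
    tetra = t3.numeric("tetrahymanol")

    me2_c32 = t4.numeric("me2_c32_hopanol").dropna()
    me2_hop17 = t4.numeric("me2_hop17_21_ene").dropna()
    me2_tetra = t4.numeric("me2_tetrahymanol").dropna()

    return PanelSummary(
        n_species=len(t3),
        n_rohmer_measured=int(measured.sum()),
        n_no_rohmer_products=int(no_rohmer),
        n_c30_measured=int((~c30_nd).sum()),
        n_no_c30_hopanoids=int(no_c30.sum()),
        n_no_intact_bhpds=int((n_bhpds == 0).sum()),
        n_tetrahymanol_producers=int((tetra > 0).sum()),
        max_22s_pct=float(t3.numeric("pct_22s").max()),
        mean_2me_c32_hopanol=float(me2_c32.mean()),
        max_2me_c32_hopanol=float(me2_c32.max()),
        n_2me_c32_detected=int(len(me2_c32)),
        mean_2me_hop17_21_ene=float(me2_hop17.mean()),
        mean_2me_tetrahymanol=float(me2_tetra.mean()),
    )


# Phenotype facts narrated outside the numeric tables: K. xylinus was not
# analyzed by the degradation method but its intact BHPDs include abundant
# 3-methyl forms, while M. palustris shows no ring-A methylation at all.
_NARRATED_OVERRIDES = {
    ("Komagataeibacter xylinus", "methyl_3"): True,
    ("Komagataeibacter xylinus", "methyl_2"): False,
    ("Methylocella palustris", "methyl_2"): False,
    ("Methylocella palustris", "methyl_3"): False,
}

_ME2_COLUMNS = ("me2_hop22_29_ene", "me2_hop17_21_ene", "me2_diplopterol",
                "me2_tetrahymanol", "me2_c31_hopanol", "me2_c32_hopanol")
_ME3_COLUMNS = ("me3_c31_hopanol", "me3_c32_hopanol")


def build_fixture_panel(genotype: FixtureTable | None = None,
                        rohmer: FixtureTable | None = None,
                        methylation: FixtureTable | None = None) -> list:
    """Assemble the cultivated-species panel from the packaged fixtures."""
    geno = genotype or load_fixture("genotype_F2")
    t3 = rohmer or load_fixture("rohmer_T3")
    t4 = methylation or load_fixture("methylation_T4")
    gene_cols = [c for c in geno.columns() if c not in {"species", "order"}]
    t4_species = set(t4.frame["species"])

    panel = []
    for _, row in geno.frame.iterrows():
        sp = row["species"]
        genes = {c: row[c] for c in gene_cols}
        t3r = t3.row(sp)
        pheno: dict[str, bool | None] = {}

        n_bhpds = int(t3r["n_bhpds"])
        sum_raw = t3r["sum_bhpds"]
        if n_bhpds > 0:
            pheno["bhpd_any"] = True
        elif sum_raw == "NA":
            pheno["bhpd_any"] = None
        else:
            pheno["bhpd_any"] = sum_raw != "BD" and float(sum_raw) > 0

        c30_vals = [t3r[c] for c in _C30_COLUMNS]
        if any(v == "NA" for v in c30_vals):
            pheno["c30_hopanoids"] = None
        else:
            pheno["c30_hopanoids"] = any(v != "BD" and float(v) > 0 for v in c30_vals)

        tet = t3r["tetrahymanol"]
        pheno["tetrahymanol"] = None if tet == "NA" else (tet != "BD" and float(tet) > 0)

        def detected(columns) -> bool:
            if sp not in t4_species:
                return False
            r = t4.row(sp)
            return any(r[c] != "BD" and float(r[c]) >= DETECTION_FLOOR_PCT
                       for c in columns)

        pheno["methyl_2"] = detected(_ME2_COLUMNS)
        pheno["methyl_3"] = detected(_ME3_COLUMNS)
        for (osp, feat), val in _NARRATED_OVERRIDES.items():
            if osp == sp:
                pheno[feat] = val
        panel.append(PanelRecord(species=sp, gene_states=genes, phenotype=pheno))
    return panel
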