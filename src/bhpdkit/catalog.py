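"""Gene-family catalog and packaged fixture tables.

The catalog lists every gene family of the hopanoid/BHPD pathway that the
scanner searches for: the MEP isoprenoid-supply genes (dxs ... ispH, ispA),
the squalene-synthesis trio (hpnC/D/E), squalene-hopene cyclase (shc), the
side-chain extension and decoration genes (hpnG, hpnH, hpnI/J/K, hpnO), the
ring-A methyltransferases (hpnP, hpnR), transporters and accessory genes
(hpnN, hpnM, hpnA, hpnB, hpnL), tetrahymanol synthase (ths) and two
desaturase-like families.  Shipped query proteins are frozen surrogate
sequences; all fixture-driven results are independent of their residues.

Fixture tables transcribe the published strain panel, survey counts, lipid
panel, methylation panel, narrated genotypes and narrated inventories.
Missing values keep their semantics: ``BD`` (below detection) and ``NA``
(not determined / not applicable) are distinct states and are never coerced
to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .align import ProteinRecord

__all__ = [
    "GeneFamily",
    "GeneFamilyCatalog",
    "FixtureTable",
    "load_gene_catalog",
    "load_fixture",
    "BELOW_DETECTION",
    "NOT_DETERMINED",
    "FIXTURE_IDS",
]

BELOW_DETECTION = "BD"
NOT_DETERMINED = "NA"

FIXTURE_IDS = (
    "strains_T1", "survey_T2", "rohmer_T3", "methylation_T4",
    "genotype_F2", "inventory_F3",
)


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    pathway_stage: str
    canonical_bgc_member: bool
    canonical_rank: int | None
    similarity_threshold: float
    query_label: str

    def __post_init__(self):
        if not 0.0 < self.similarity_threshold <= 100.0:
            raise ValueError("similarity_threshold must lie in (0, 100]")


class GeneFamilyCatalog:
    """Immutable lookup over gene families plus their query proteins."""

    def __init__(self, families: list[GeneFamily], queries: dict[str, ProteinRecord]):
        ids = [f.family_id for f in families]
        if len(set(ids)) != len(ids):
            raise ValueError("family_ids must be unique")
        self._families = {f.family_id: f for f in families}
        self._queries = queries

    def __iter__(self):
        return iter(self._families.values())

    def __len__(self) -> int:
        return len(self._families)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._families

    def get(self, family_id: str) -> GeneFamily:
        try:
            return self._families[family_id]
        except KeyError:
            raise KeyError(f"unknown gene family {family_id!r}") from None

    def family_ids(self) -> list[str]:
        return list(self._families)

    def threshold(self, family_id: str) -> float:
        return self.get(family_id).similarity_threshold

    def query_protein(self, family_id: str) -> ProteinRecord:
        return self._queries[self.get(family_id).query_label]

    def canonical_order(self) -> list[str]:
        """Canonical-cluster member families in their defined genomic order."""
        members = [f for f in self if f.canonical_bgc_member]
        members.sort(key=lambda f: f.canonical_rank)
        return [f.family_id for f in members]


def _read_fasta(text: str) -> dict[str, ProteinRecord]:
    records = {}
    name, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records[name] = ProteinRecord(name, "".join(chunks))
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records[name] = ProteinRecord(name, "".join(chunks))
    return records


def load_gene_catalog() -> GeneFamilyCatalog:
    """Load the shipped gene-family catalog with its reference queries."""
    pkg = resources.files("bhpdkit") / "data"
    doc = json.loads((pkg / "gene_catalog.json").read_text())
    families = [
        GeneFamily(
            family_id=f["family_id"],
            pathway_stage=f["pathway_stage"],
            canonical_bgc_member=f["canonical_bgc_member"],
            canonical_rank=f.get("canonical_rank"),
            similarity_threshold=f["similarity_threshold"],
            query_label=f["query_label"],
        )
        for f in doc["families"]
    ]
    queries = _read_fasta((pkg / "query_proteins.fasta").read_text())
    return GeneFamilyCatalog(families, queries)


class FixtureTable:
    """A packaged table with explicit missing-value semantics.

    Cells are kept as strings; :meth:`numeric` converts a column to floats
    with ``NaN`` standing in for *both* missing markers, while
    :meth:`below_detection` and :meth:`not_determined` expose the markers
    themselves.  Writing and re-reading a fixture reproduces every cell
    bit-exactly.
    """

    def __init__(self, table_id: str, frame: pd.DataFrame):
        self.table_id = table_id
        self.frame = frame.astype(str)

    def __len__(self) -> int:
        return len(self.frame)

    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def numeric(self, column: str) -> pd.Series:
        s = self.frame[column]
        return pd.to_numeric(
            s.where(~s.isin([BELOW_DETECTION, NOT_DETERMINED])), errors="raise")

    def below_detection(self, column: str) -> pd.Series:
        return self.frame[column] == BELOW_DETECTION

    def not_determined(self, column: str) -> pd.Series:
        return self.frame[column] == NOT_DETERMINED

    def row(self, species: str) -> pd.Series:
        m = self.frame[self.frame["species"] == species]
        if m.empty:
            raise KeyError(f"species {species!r} not in fixture {self.table_id}")
        return m.iloc[0]

    def value(self, species: str, column: str) -> float | str:
        raw = self.row(species)[column]
        if raw in (BELOW_DETECTION, NOT_DETERMINED):
            return raw
        return float(raw)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, table_id: str, path) -> "FixtureTable":
        return cls(table_id, pd.read_csv(
            path, dtype=str, keep_default_na=False, na_values=[]))


def load_fixture(table_id: str) -> FixtureTable:
    """Load one of the packaged fixture tables by id."""
    if table_id not in FIXTURE_IDS:
        raise ValueError(
            f"unknown fixture {table_id!r}; valid ids: {', '.join(FIXTURE_IDS)}")
    path = resources.files("bhpdkit") / "data" / "fixtures" / f"{table_id}.csv"
    with resources.as_file(path) as p:
        return FixtureTable.read_csv(table_id, p)
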