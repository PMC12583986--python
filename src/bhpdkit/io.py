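"""File readers/writers: FASTA proteomes, GFF3/TSV feature tables, configs."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import ProteinRecord
from .clusters import GenomeFeature

__all__ = [
    "RunConfig",
    "read_proteome",
    "write_proteome",
    "read_features",
    "write_features",
    "write_inventory_csv",
    "write_peaks_csv",
]


def read_proteome(path) -> list[ProteinRecord]:
    """Read a protein FASTA into records; duplicate ids are an error."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path.name}:{lineno}: malformed FASTA, expected '>' header first")
                break
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path.name}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def write_proteome(records: list, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_features(path) -> list[GenomeFeature]:
    """Read gene features from GFF3 (gene/CDS rows with a locus_tag
    attribute) or from a headered TSV with columns contig, start, end,
    strand, locus_tag.  Coordinates are 1-based inclusive in both dialects.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    features = []
    is_gff = any(l.startswith("##gff-version") for l in lines[:5]) or \
        any(len(l.split("\t")) == 9 for l in lines if l and not l.startswith("#"))
    if is_gff:
        for lineno, line in enumerate(lines, 1):
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                continue
            if cols[2] not in {"gene", "CDS"}:
                continue
            attrs = _parse_gff_attributes(cols[8])
            tag = attrs.get("locus_tag") or attrs.get("ID", f"feature_{lineno}")
            try:
                features.append(GenomeFeature(cols[0], int(cols[3]), int(cols[4]),
                                              cols[6], tag))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
        # GFF3 lists gene and CDS rows for the same locus; keep one per tag
        dedup = {}
        for f in features:
            dedup.setdefault(f.locus_tag, f)
        return list(dedup.values())
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                features.append(GenomeFeature(
                    row["contig"], int(row["start"]), int(row["end"]),
                    row["strand"], row["locus_tag"]))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
    return features


def write_features(features: list, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig", "start", "end", "strand", "locus_tag"])
        for f in features:
            w.writerow([f.contig, f.start, f.end, f.strand, f.locus_tag])


def write_inventory_csv(inventory, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "side_chain_class", "subtype", "base", "stage",
                    "ring_a_methyl", "unsaturation", "c22_config", "rel_abundance_pct"])
        for s, a in inventory.entries:
            w.writerow([inventory.species, s.side_chain_class, s.subtype or "",
                        s.base or "", s.stage or "", s.ring_a_methyl,
                        "+".join(sorted(s.unsaturation)), s.c22_config, f"{a:.6f}"])


def write_peaks_csv(peaks, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["analyte", "precursor_mz", "product_mz", "area"])
        for p in peaks:
            w.writerow([p.analyte, p.transition[0], p.transition[1], f"{p.area:.4f}"])


@dataclass
class RunConfig:
    """Plain-text run configuration (JSON on disk; unknown keys rejected)."""

    input_proteome: str | None = None
    input_features: str | None = None
    output_dir: str = "."
    seed: int = 0
    coverage_floor: float = 0.70
    max_intervening: int = 5
    max_locus_gap: int = 50
    tolerance_pct: float = 15.0
    threshold_overrides: dict = field(default_factory=dict)
    verbosity: int = 1

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        valid = set(cls.__dataclass_fields__)
        unknown = set(doc) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
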