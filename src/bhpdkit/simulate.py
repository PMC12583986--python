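"""Synthetic genomes and lipid measurements with known ground truth.

Every pipeline stage is testable without downloads: genomes are built by
planting mutated copies of the catalog's reference query proteins in a
background of shuffled-residue decoy genes, with the biosynthetic gene
cluster laid out in canonical order (locus tags stepping by 5) and
optionally split into fragments; lipidomes are drawn from the structure
classes a chemotype permits, with relative abundances from a symmetric
Dirichlet and peak areas perturbed by multiplicative lognormal noise.

All randomness flows through explicit integer seeds; the same seed always
reproduces the same outputs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .align import ProteinRecord, ScoringScheme, DEFAULT_SCORING, align_local
from .catalog import GeneFamilyCatalog, load_gene_catalog
from .chemotype import ChemotypePrediction, GenomeGenotype, predict_chemotype
from .clusters import GenomeFeature
from .lipids import LipidInventory, MrmPeak, normalize_inventory
from .rohmer import degradation_product
from .structures import parse_code

__all__ = [
    "SimulationTruth",
    "GenotypeScenario",
    "mutate_protein",
    "simulate_genome",
    "simulate_lipidome",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside each simulated artifact."""

    seed: int
    presence: dict | None = None            # family_id -> bool (genome sims)
    gene_target_similarity: dict | None = None
    bgc_layout: list | None = None          # list of fragments (family lists)
    decoys: list | None = None              # (family_id, target_similarity, protein_id)
    chemotype: ChemotypePrediction | None = None
    inventory: list | None = None           # (structure, true relative %)
    methyl2_pct: float | None = None
    methyl3_pct: float | None = None
    epimer_22s_pct: float | None = None
    noise_cv: float = 0.0


def _low_scoring_partner(aa: str, rng: random.Random, scoring: ScoringScheme) -> str:
    """A replacement residue drawn among non-positive-scoring exchanges."""
    options = [b for b in _AA if b != aa and scoring.pair_score(aa, b) <= 0]
    if not options:  # never happens for BLOSUM62, kept for exotic matrices
        options = [b for b in _AA if b != aa]
    return rng.choice(options)


def mutate_protein(reference: ProteinRecord, target_similarity: float, seed: int,
                   scoring: ScoringScheme = DEFAULT_SCORING,
                   tolerance: float = 2.0) -> ProteinRecord:
    """Mutate a protein to a target percent similarity (measured by alignment).

    Substitutions replace residues with non-positive-scoring partners, so
    realized similarity falls roughly linearly with the substituted
    fraction; a bisection on that fraction, scored by :func:`align_local`,
    homes in on the target.  Deterministic for a given seed.
    """
    if not 0 < target_similarity <= 100:
        raise ValueError("target similarity must lie in (0, 100]")
    if target_similarity == 100:
        return ProteinRecord(f"{reference.id}_mut100", reference.sequence)
    rng = random.Random(seed)
    seq = list(reference.sequence)
    n = len(seq)
    order = list(range(n))
    rng.shuffle(order)
    replacement = {i: _low_scoring_partner(seq[i], rng, scoring) for i in order}

    def realize(frac: float) -> tuple[str, float]:
        k = min(n, int(round(frac * n)))
        mutated = seq.copy()
        for i in order[:k]:
            mutated[i] = replacement[i]
        s = "".join(mutated)
        res = align_local(reference, ProteinRecord("m", s), scoring)
        return s, res.percent_similarity

    lo, hi = 0.0, 1.0
    best_seq, best_sim = realize((100 - target_similarity) / 100)
    if abs(best_sim - target_similarity) > tolerance:
        for _ in range(14):
            mid = (lo + hi) / 2
            s, sim = realize(mid)
            if abs(sim - target_similarity) < abs(best_sim - target_similarity):
                best_seq, best_sim = s, sim
            if sim > target_similarity:
                lo = mid
            else:
                hi = mid
            if abs(best_sim - target_similarity) <= tolerance:
                break
    return ProteinRecord(f"{reference.id}_mut{int(round(target_similarity))}", best_seq)


@dataclass
class GenotypeScenario:
    """Blueprint for one simulated genome."""

    genome_id: str = "sim"
    families_present: frozenset = frozenset()
    planted_similarity: float = 90.0
    similarity_overrides: dict = field(default_factory=dict)
    n_fragments: int = 1
    decoys: tuple = ()          # (family_id, target_similarity) pairs
    background_n: int = 300
    n_contigs: int = 2


def _shuffled_background(rng: random.Random, catalog: GeneFamilyCatalog) -> str:
    fam = rng.choice(catalog.family_ids())
    residues = list(catalog.query_protein(fam).sequence)
    rng.shuffle(residues)
    return "".join(residues)


class _ContigWriter:
    """Lays genes onto contigs with locus tags stepping by 5."""

    def __init__(self, genome_id: str):
        self.genome_id = genome_id
        self.features: list[GenomeFeature] = []
        self.proteome: list[ProteinRecord] = []
        self._pos: dict[str, int] = {}
        self._num: dict[str, int] = {}

    def add(self, contig: str, sequence: str, strand: str = "+") -> str:
        start = self._pos.get(contig, 1)
        num = self._num.get(contig, 0) + 5
        self._num[contig] = num
        tag = f"{self.genome_id.upper()}_{contig}_{num:05d}"
        end = start + 3 * len(sequence) + 2
        feat = GenomeFeature(contig, start, end, strand, tag)
        self.features.append(feat)
        self.proteome.append(ProteinRecord(tag, sequence, source_feature=feat))
        self._pos[contig] = end + 200
        return tag


def simulate_genome(scenario: GenotypeScenario, seed: int,
                    catalog: GeneFamilyCatalog | None = None):
    """Build (proteome, features, truth) for a genotype scenario.

    Canonical-cluster families present in the scenario are laid out in
    canonical order, split into ``n_fragments`` runs over the contigs with
    a wide spacer of background genes between runs; the remaining present
    families are placed far from the cluster.  Decoys are planted below
    their family thresholds; background genes are shuffled reference
    residues.
    """
    catalog = catalog or load_gene_catalog()
    rng = random.Random(seed)
    present = sorted(scenario.families_present)
    unknown = [f for f in present if f not in catalog]
    if unknown:
        raise ValueError(f"scenario names unknown families: {unknown}")
    canon = [f for f in catalog.canonical_order() if f in present]
    others = [f for f in present if f not in canon]

    n_frag = max(1, min(scenario.n_fragments, len(canon))) if canon else 0
    fragments = []
    if canon:
        cut = sorted(rng.sample(range(1, len(canon)), n_frag - 1)) if n_frag > 1 else []
        edges = [0] + cut + [len(canon)]
        fragments = [canon[a:b] for a, b in zip(edges, edges[1:])]

    sims = {f: scenario.similarity_overrides.get(f, scenario.planted_similarity)
            for f in present}
    writer = _ContigWriter(scenario.genome_id)
    contigs = [f"ctg{i + 1}" for i in range(max(1, scenario.n_contigs))]
    background_left = scenario.background_n
    per_block = max(1, background_left // (len(fragments) + len(others) + 2)) if background_left else 0

    def emit_background(contig: str, n: int):
        nonlocal background_left
        for _ in range(min(n, background_left)):
            writer.add(contig, _shuffled_background(rng, catalog))
            background_left -= 1

    planted_ids: dict[str, str] = {}
    for i, frag in enumerate(fragments):
        contig = contigs[i % len(contigs)]
        emit_background(contig, per_block)
        strand = rng.choice("+-")
        members = list(frag) if strand == "+" else list(reversed(frag))
        for fam in members:
            mut = mutate_protein(catalog.query_protein(fam), sims[fam],
                                 rng.randrange(2**31))
            planted_ids[fam] = writer.add(contig, mut.sequence, strand)
        emit_background(contig, per_block)
    for fam in others:
        contig = contigs[-1]
        emit_background(contig, max(per_block, 7))
        mut = mutate_protein(catalog.query_protein(fam), sims[fam],
                             rng.randrange(2**31))
        planted_ids[fam] = writer.add(contig, mut.sequence, rng.choice("+-"))
    decoy_records = []
    for fam, target in scenario.decoys:
        contig = contigs[0]
        emit_background(contig, max(per_block, 7))
        mut = mutate_protein(catalog.query_protein(fam), target, rng.randrange(2**31))
        tag = writer.add(contig, mut.sequence, rng.choice("+-"))
        decoy_records.append((fam, target, tag))
    emit_background(contigs[-1], background_left)

    genotype = GenomeGenotype(
        scenario.genome_id,
        {f: ("present" if f in scenario.families_present else "absent")
         for f in catalog.family_ids()},
        mep_complete=all(f in scenario.families_present
                         for f in ("dxs", "dxr", "ispDF", "ispE", "ispG", "ispH", "ispA")),
    )
    truth = SimulationTruth(
        seed=seed,
        presence={f: f in scenario.families_present for f in catalog.family_ids()},
        gene_target_similarity=sims,
        bgc_layout=fragments,
        decoys=decoy_records,
        chemotype=predict_chemotype(genotype),
    )
    return writer.proteome, writer.features, truth


_PRODUCT_NAMES = {30: "hopan-30-ol", 31: "homohopan-31-ol", 32: "bishomohopan-32-ol"}
_CHANNEL = {"none": 191.2, "2Me": 205.2, "3Me": 205.2}
_PRECURSOR = {  # M+.-90 of the TMS ether, per carbon number and ring-A methyl
    (30, "none"): 500.5, (31, "none"): 514.5, (32, "none"): 528.5,
    (30, "2Me"): 514.5, (31, "2Me"): 528.5, (32, "2Me"): 542.5,
    (30, "3Me"): 514.5, (31, "3Me"): 528.5, (32, "3Me"): 542.5,
}
INTERNAL_STANDARD = "n-tricosan-1-ol"


def simulate_lipidome(chemotype: ChemotypePrediction, seed: int, noise_cv: float = 0.05,
                      methyl2_pct: float | None = None,
                      methyl3_pct: float | None = None,
                      epimer_22s_pct: float | None = None,
                      total_area: float = 1e6, is_area: float = 5e5):
    """Draw an LC inventory and GC-MRM peak table from a chemotype.

    Only structure classes the chemotype permits are emitted.  Relative
    abundances come from a symmetric Dirichlet; MRM peak areas are the true
    proportions scaled by ``total_area`` under multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (0 = noiseless).  A
    planted ring-A methylation degree moves the stated fraction of each
    cleavable skeleton into the methylated MRM channel; a planted 22S
    fraction splits the C32 product into epimer peaks.

    Returns ``(inventory, peaks, truth)``.
    """
    codes = []
    if chemotype.bht:
        codes.append("IIa")
        if chemotype.ce_terminal:
            codes.append("IIIc")
        elif chemotype.ce_glucosamine_terminal:
            codes.append("IIIb")
        elif chemotype.ce_acetylglucosamine_terminal:
            codes.append("IIIa")
        if chemotype.aminotriol:
            codes.append("Va")
    if chemotype.adenosylhopane:
        codes.append("Ia")
    if not codes:
        raise ValueError("chemotype permits no BHPD structure to simulate")
    if methyl2_pct is not None and not chemotype.methyl_2:
        raise ValueError("cannot plant a 2-methyl degree: chemotype lacks methyl_2")
    if methyl3_pct is not None and not chemotype.methyl_3:
        raise ValueError("cannot plant a 3-methyl degree: chemotype lacks methyl_3")

    nrng = np.random.default_rng(seed)
    shares = nrng.dirichlet(np.ones(len(codes)))
    entries = []
    for c, share in zip(codes, shares):
        if c == "IIa" and epimer_22s_pct is not None:
            entries.append((parse_code("IIa-22R"), float(share * (100 - epimer_22s_pct))))
            entries.append((parse_code("IIa-22S"), float(share * epimer_22s_pct)))
        else:
            entries.append((parse_code(c), float(100.0 * share)))
    inventory = LipidInventory("simulated", entries)

    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma == 0.0:
            return x
        return x * float(nrng.lognormal(-sigma**2 / 2, sigma))

    # degrade to hopanols, splitting each skeleton into MRM channels
    skeleton: dict[tuple, float] = {}
    for s, pct in entries:
        prod = degradation_product(s)
        if prod is None:
            continue
        key = (prod.carbon_number, prod.c22_config)
        skeleton[key] = skeleton.get(key, 0.0) + pct
    peaks = [MrmPeak(INTERNAL_STANDARD, (430.5, 75.1), noisy(is_area))]
    for (carbon, cfg), pct in sorted(skeleton.items()):
        base = total_area * pct / 100.0
        me_splits = []
        if methyl2_pct:
            me_splits.append(("2Me", methyl2_pct))
        if methyl3_pct:
            me_splits.append(("3Me", methyl3_pct))
        me_total = sum(p for _, p in me_splits)
        name = _PRODUCT_NAMES[carbon]
        suffix = f" (22{cfg})" if cfg != "unknown" else ""
        peaks.append(MrmPeak(
            name + suffix, (_PRECURSOR[(carbon, "none")], _CHANNEL["none"]),
            noisy(base * (100 - me_total) / 100)))
        for me, p in me_splits:
            peaks.append(MrmPeak(
                f"{me[0]}-methyl {name}{suffix}",
                (_PRECURSOR[(carbon, me)], _CHANNEL[me]),
                noisy(base * p / 100)))

    truth = SimulationTruth(
        seed=seed,
        chemotype=chemotype,
        inventory=list(entries),
        methyl2_pct=methyl2_pct,
        methyl3_pct=methyl3_pct,
        epimer_22s_pct=epimer_22s_pct,
        noise_cv=noise_cv,
    )
    return inventory, peaks, truth
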