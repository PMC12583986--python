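"""Grouping of pathway gene hits into biosynthetic gene clusters (BGCs).

Accepted hits are chained into clusters when they sit on the same contig
and are separated by at most ``G`` intervening non-pathway genes, or when
their locus-tag numbers differ by at most ``L`` units (annotation pipelines
typically step locus tags by 5 per gene, so adjacent pathway genes differ
by small multiples of 5 even when a few unrelated genes intervene).

Cluster architecture is classified against the canonical hpn gene order
(hpnA..hpnN with shc in the F slot) using a Kendall-type rank correlation
that is invariant to whole-cluster strand flips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomeFeature",
    "GapPolicy",
    "GeneCluster",
    "ArchitectureReport",
    "cluster_hits",
    "classify_architecture",
]

_LOCUS_SUFFIX = re.compile(r"(\d+)$")


@dataclass(frozen=True)
class GenomeFeature:
    """A gene feature with 1-based inclusive coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus_tag!r}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.locus_tag!r}: strand must be + or -")

    @property
    def locus_number(self) -> int | None:
        m = _LOCUS_SUFFIX.search(self.locus_tag)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GapPolicy:
    """Adjacency tolerances for cluster chaining.

    ``max_intervening``: how many non-pathway genes may sit between two
    cluster members.  ``max_locus_gap``: the largest locus-tag number
    difference still treated as adjacent (50 units = 10 genes at step 5).
    """

    max_intervening: int = 5
    max_locus_gap: int = 50


@dataclass
class GeneCluster:
    genome_id: str
    members: list  # (GeneHit, GenomeFeature) sorted by start
    fragment_index: int = 0

    @property
    def contig(self) -> str:
        return self.members[0][1].contig

    @property
    def span_bp(self) -> int:
        return self.members[-1][1].end - self.members[0][1].start + 1

    @property
    def family_ids(self) -> list[str]:
        return [h.family_id for h, _ in self.members]

    def intervening_gene_counts(self, features: list) -> list[int]:
        """Non-member genes inside each gap between consecutive members."""
        member_tags = {f.locus_tag for _, f in self.members}
        counts = []
        for (_, a), (_, b) in zip(self.members, self.members[1:]):
            n = sum(1 for f in features
                    if f.contig == a.contig and a.end < f.start and f.end < b.start
                    and f.locus_tag not in member_tags)
            counts.append(n)
        return counts


@dataclass
class ArchitectureReport:
    n_fragments: int
    cluster_class: str  # contiguous | fragmented | dispersed | absent
    order_concordance: float
    genes_outside_cluster: list = field(default_factory=list)

    def __post_init__(self):
        if self.cluster_class == "contiguous":
            assert self.n_fragments == 1
        if self.cluster_class == "absent":
            assert self.n_fragments == 0


def _intervening(a: GenomeFeature, b: GenomeFeature, features, hit_tags) -> int:
    return sum(1 for f in features
               if f.contig == a.contig and a.end < f.start and f.end < b.start
               and f.locus_tag not in hit_tags)


def cluster_hits(hits: list, features: list, policy: GapPolicy = GapPolicy(),
                 genome_id: str | None = None) -> list:
    """Chain accepted hits into maximal clusters.

    Two pathway genes join one cluster iff they lie on the same contig and
    either at most ``max_intervening`` non-pathway genes separate them or
    their locus-tag numbers differ by at most ``max_locus_gap``.  The result
    is independent of input order and idempotent.
    """
    accepted = [h for h in hits if h.call == "accepted"]
    if not accepted:
        return []
    by_tag = {f.locus_tag: f for f in features}
    pairs = []
    for h in accepted:
        f = by_tag.get(h.protein_id)
        if f is None:
            raise ValueError(f"no genome feature found for protein {h.protein_id!r}")
        pairs.append((h, f))
    gid = genome_id or accepted[0].genome_id
    hit_tags = {f.locus_tag for _, f in pairs}
    pairs.sort(key=lambda p: (p[1].contig, p[1].start, p[0].family_id))

    clusters: list[GeneCluster] = []
    current = [pairs[0]]
    for prev, cur in zip(pairs, pairs[1:]):
        pf, cf = prev[1], cur[1]
        joined = False
        if pf.contig == cf.contig:
            if _intervening(pf, cf, features, hit_tags) <= policy.max_intervening:
                joined = True
            elif (pf.locus_number is not None and cf.locus_number is not None
                  and abs(cf.locus_number - pf.locus_number) <= policy.max_locus_gap):
                joined = True
        if joined:
            current.append(cur)
        else:
            clusters.append(GeneCluster(gid, current))
            current = [cur]
    clusters.append(GeneCluster(gid, current))
    for i, c in enumerate(clusters):
        c.fragment_index = i
    return clusters


def _strand_normalized_order(cluster: GeneCluster, canonical: set) -> list[str]:
    members = [(h, f) for h, f in cluster.members if h.family_id in canonical]
    if not members:
        return []
    minus = sum(1 for _, f in members if f.strand == "-")
    ordered = [h.family_id for h, _ in members]
    if minus * 2 > len(members):
        ordered.reverse()
    return ordered


def classify_architecture(clusters: list, catalog) -> ArchitectureReport:
    """Classify BGC architecture and score gene order against the canon.

    Order concordance is the Kendall rank correlation between the observed
    genomic order of canonical-cluster genes and their canonical order,
    computed only over genes present; fragments are concatenated in order
    of their earliest canonical rank, each normalized for strand so that a
    minus-strand operon scores the same as its plus-strand mirror.
    """
    canon = catalog.canonical_order()
    canon_rank = {fam: i for i, fam in enumerate(canon)}
    frags = []
    for c in clusters:
        order = _strand_normalized_order(c, set(canon_rank))
        if order:
            frags.append(order)
    n_frag = len(frags)
    if n_frag == 0:
        return ArchitectureReport(0, "absent", 1.0, [])
    frags.sort(key=lambda fams: min(canon_rank[f] for f in fams))
    observed = [fam for frag in frags for fam in frag]
    if len(observed) < 2:
        tau = 1.0
    else:
        # Kendall tau-a over the canonical ranks in observed order; ranks are
        # unique, so integer pair counting is exact
        ranks = [canon_rank[f] for f in observed]
        n = len(ranks)
        diff = sum((ranks[j] > ranks[i]) - (ranks[j] < ranks[i])
                   for i in range(n) for j in range(i + 1, n))
        tau = diff / (n * (n - 1) / 2)
    if n_frag == 1:
        cls = "contiguous"
    elif all(len(f) == 1 for f in frags):
        cls = "dispersed"
    else:
        cls = "fragmented"
    largest = max(frags, key=len)
    outside = sorted(set(observed) - set(largest))
    return ArchitectureReport(n_frag, cls, tau, outside)
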