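"""Protein homology search by local alignment with similarity thresholds.

Pathway genes are detected by Smith-Waterman local alignment of reference
query proteins against every protein of an annotated genome, scored with
BLOSUM62 and affine gap penalties.  A candidate counts as a hit for a gene
family when its percent similarity (the BLAST "positives" convention:
positive-scoring aligned columns over all alignment columns) reaches the
family threshold and the alignment covers enough of the query.

The secondary squalene-hopene cyclase clade -- proteins annotated as Shc
but < 40% similar to the reference and not part of the hpn cluster -- is
filtered out by :func:`exclude_secondary_shc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = [
    "ProteinRecord",
    "ScoringScheme",
    "AlignmentResult",
    "GeneHit",
    "ThresholdPolicy",
    "align_local",
    "scan_proteome",
    "exclude_secondary_shc",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional genome feature link."""

    id: str
    sequence: str
    source_feature: object | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(f"protein {self.id!r} contains invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length ``n`` costs ``gap_open + (n - 1) * gap_extend``.
    """

    def __init__(self, matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1):
        if gap_open <= 0 or gap_extend <= 0:
            raise ValueError("gap penalties must be positive costs")
        self.matrix_name = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        if matrix == "BLOSUM62":
            self.matrix = balign.SubstitutionMatrix.std_protein_matrix()
        else:
            alph = bseq.ProteinSequence.alphabet
            self.matrix = balign.SubstitutionMatrix(alph, alph, matrix)

    def pair_score(self, a: str, b: str) -> int:
        return int(self.matrix.get_score(a, b))


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    aligned_length: int
    percent_identity: float
    percent_similarity: float
    query_coverage: float

    def __post_init__(self):
        assert 0.0 <= self.percent_identity <= self.percent_similarity <= 100.0
        assert 0.0 <= self.query_coverage <= 1.0


@dataclass(frozen=True)
class GeneHit:
    genome_id: str
    family_id: str
    protein_id: str
    percent_similarity: float
    query_coverage: float
    call: str  # accepted | rejected_low_similarity | rejected_decoy
    score: int = 0


@dataclass(frozen=True)
class ThresholdPolicy:
    """Acceptance policy for proteome scans.

    ``coverage_floor`` is the minimum fraction of the query that must be
    aligned (guards against single-domain fragments).  ``prefilter_k`` is
    the word size of the shared-k-mer seeding screen that skips hopeless
    query/target pairs; set to 0 to align every pair exhaustively.
    ``shc_decoy_floor`` is the percent-similarity floor below which Shc
    candidates belong to the distantly related secondary clade.
    """

    coverage_floor: float = 0.70
    prefilter_k: int = 4
    shc_decoy_floor: float = 40.0
    threshold_overrides: dict = field(default_factory=dict)


def align_local(query: ProteinRecord, target: ProteinRecord,
                scoring: ScoringScheme = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal local alignment of two proteins.

    Percent identity and percent similarity are computed over all alignment
    columns; a gap column can never score positive, so gaps dilute both.
    Query coverage is the fraction of query residues inside the local
    alignment.
    """
    qs = bseq.ProteinSequence(query.sequence)
    ts = bseq.ProteinSequence(target.sequence)
    aln = balign.align_optimal(
        qs, ts, scoring.matrix,
        gap_penalty=(-scoring.gap_open, -scoring.gap_extend),
        local=True, max_number=1,
    )[0]
    codes = balign.get_codes(aln)  # shape (2, n_columns); -1 encodes a gap
    qc, tc = codes[0], codes[1]
    n_cols = codes.shape[1]
    score_mat = scoring.matrix.score_matrix()
    ident = 0
    positive = 0
    q_aligned = 0
    for i in range(n_cols):
        a, b = int(qc[i]), int(tc[i])
        if a >= 0:
            q_aligned += 1
        if a < 0 or b < 0:
            continue
        if a == b:
            ident += 1
        if score_mat[a, b] > 0:
            positive += 1
    if n_cols == 0:  # no positive-scoring pair at all
        return AlignmentResult(0, 0, 0.0, 0.0, 0.0)
    return AlignmentResult(
        score=int(aln.score),
        aligned_length=n_cols,
        percent_identity=100.0 * ident / n_cols,
        percent_similarity=100.0 * positive / n_cols,
        query_coverage=q_aligned / len(query),
    )


def _kmers(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def scan_proteome(proteome: list, catalog, policy: ThresholdPolicy = ThresholdPolicy(),
                  scoring: ScoringScheme = DEFAULT_SCORING, genome_id: str = "genome") -> list:
    """Detect pathway genes in a proteome.

    For each gene family the best-scoring candidate protein is retained; it
    is accepted when its percent similarity reaches the family threshold and
    its query coverage reaches the policy floor, otherwise it is reported as
    ``rejected_low_similarity``.  Candidates that fail a filter are kept in
    the output with their rejection reason.  Output is sorted by
    (family_id, protein_id); ties for the best candidate break toward the
    lexicographically lowest protein id.
    """
    if not proteome:
        return []
    k = policy.prefilter_k
    target_kmers = None
    if k:
        target_kmers = [(_kmers(p.sequence, k) if len(p) >= k else None) for p in proteome]
    hits = []
    for family in catalog:
        query = catalog.query_protein(family.family_id)
        threshold = policy.threshold_overrides.get(
            family.family_id, family.similarity_threshold)
        qk = _kmers(query.sequence, k) if k and len(query) >= k else None
        evaluated = []
        for idx, prot in enumerate(proteome):
            if qk is not None and target_kmers[idx] is not None and not (qk & target_kmers[idx]):
                continue
            res = align_local(query, prot, scoring)
            if res.aligned_length == 0:
                continue
            evaluated.append((prot, res))
        if not evaluated:
            continue
        evaluated.sort(key=lambda e: (-e[1].score, e[0].id))
        best_prot, best_res = evaluated[0]
        passes = (best_res.percent_similarity >= threshold
                  and best_res.query_coverage >= policy.coverage_floor)
        # rejections are only worth reporting when the alignment spans a
        # substantial part of the query; incidental short local matches of
        # unrelated proteins are dropped silently
        substantial = lambda res: res.query_coverage >= 0.5 * policy.coverage_floor
        if passes or substantial(best_res):
            hits.append(GeneHit(
                genome_id=genome_id, family_id=family.family_id, protein_id=best_prot.id,
                percent_similarity=best_res.percent_similarity,
                query_coverage=best_res.query_coverage,
                call="accepted" if passes else "rejected_low_similarity",
                score=best_res.score,
            ))
        for prot, res in evaluated[1:]:
            if (res.percent_similarity >= threshold
                    and res.query_coverage >= policy.coverage_floor):
                continue  # outranked duplicates that would otherwise pass are dropped
            if substantial(res):
                hits.append(GeneHit(
                    genome_id=genome_id, family_id=family.family_id, protein_id=prot.id,
                    percent_similarity=res.percent_similarity,
                    query_coverage=res.query_coverage,
                    call="rejected_low_similarity", score=res.score,
                ))
    hits.sort(key=lambda h: (h.family_id, h.protein_id))
    return hits


def exclude_secondary_shc(hits: list, floor: float = 40.0) -> list:
    """Mark Shc candidates below the similarity floor as the secondary clade.

    Only ``shc`` hits are affected; every other hit passes through
    untouched.
    """
    out = []
    for h in hits:
        if h.family_id == "shc" and h.percent_similarity < floor:
            out.append(replace(h, call="rejected_decoy"))
        else:
            out.append(h)
    return out
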