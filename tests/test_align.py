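"""Local alignment, similarity computation and proteome scanning."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhpdkit import (ProteinRecord, ScoringScheme, ThresholdPolicy, align_local,
                     exclude_secondary_shc, scan_proteome)
from bhpdkit.align import GeneHit

from .oracle import sw_score

SCORING = ScoringScheme()
ALPHABET4 = "AGWC"  # scores in BLOSUM62 range from strongly negative to +11

peptides = st.text(alphabet=ALPHABET4, min_size=1, max_size=12)


def test_self_alignment_is_perfect():
    p = ProteinRecord("p", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    res = align_local(p, p)
    assert res.percent_identity == 100.0
    assert res.percent_similarity == 100.0
    assert res.query_coverage == 1.0


def test_reversed_peptide_is_not_identical():
    p = ProteinRecord("p", "MKTAYIAKQRQISFVKSHFS")
    res = align_local(p, ProteinRecord("r", p.sequence[::-1]))
    assert res.percent_identity < 100.0


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        ProteinRecord("bad", "")


@settings(max_examples=300, deadline=None, derandomize=True)
@given(peptides, peptides)
def test_score_matches_dynamic_programming_oracle(q, t):
    """The alignment score equals an independently coded Gotoh recursion."""
    res = align_local(ProteinRecord("q", q), ProteinRecord("t", t), SCORING)
    expected = sw_score(q, t, SCORING.pair_score, SCORING.gap_open, SCORING.gap_extend)
    assert res.score == expected


def test_score_exhaustive_on_short_peptides():
    rng = random.Random(7)
    pool = ["".join(rng.choices(ALPHABET4, k=rng.randint(1, 6))) for _ in range(25)]
    for q in pool:
        for t in pool:
            res = align_local(ProteinRecord("q", q), ProteinRecord("t", t), SCORING)
            assert res.score == sw_score(q, t, SCORING.pair_score,
                                         SCORING.gap_open, SCORING.gap_extend)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(peptides, peptides)
def test_score_symmetric_under_swap(q, t):
    a = align_local(ProteinRecord("q", q), ProteinRecord("t", t), SCORING)
    b = align_local(ProteinRecord("t", t), ProteinRecord("q", q), SCORING)
    assert a.score == b.score


def test_similarity_bounds_and_coverage():
    q = ProteinRecord("q", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQMKTAYIAKQR")
    t = ProteinRecord("t", "MKTAYLAKQRQISYVKSHFARQLEERAGLIEVQ")
    res = align_local(q, t)
    assert 0 <= res.percent_identity <= res.percent_similarity <= 100
    assert 0 <= res.query_coverage <= 1


def test_point_mutation_never_raises_identity(catalog):
    """Mutating a target away from the query does not increase identity
    (checked statistically over single-residue mutants)."""
    rng = random.Random(42)
    query = catalog.query_protein("hpnG")
    baseline = align_local(query, query).percent_identity
    worse = 0
    for _ in range(25):
        seq = list(query.sequence)
        i = rng.randrange(len(seq))
        seq[i] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != seq[i]])
        res = align_local(query, ProteinRecord("m", "".join(seq)))
        assert res.percent_identity <= baseline
        worse += res.percent_identity < baseline
    assert worse >= 20  # the vast majority of mutants lose identity


class TestScanProteome:
    def test_exact_copy_accepted_at_full_similarity(self, catalog):
        shc = catalog.query_protein("shc")
        hits = scan_proteome([ProteinRecord("G_00005", shc.sequence)], catalog,
                             genome_id="g")
        accepted = [h for h in hits if h.call == "accepted"]
        assert [h.family_id for h in accepted] == ["shc"]
        assert accepted[0].percent_similarity == 100.0

    def test_empty_proteome_yields_empty_hit_list(self, catalog):
        assert scan_proteome([], catalog) == []

    def test_candidate_below_family_threshold_is_rejected(self, catalog):
        from bhpdkit import mutate_protein
        hpnp = catalog.query_protein("hpnP")
        mut = mutate_protein(hpnp, 54.0, seed=1)
        hits = scan_proteome([ProteinRecord("G_00005", mut.sequence)], catalog,
                             genome_id="g")
        call = {h.family_id: h.call for h in hits}
        assert call["hpnP"] == "rejected_low_similarity"

    def test_deterministic_ordering(self, catalog):
        prots = [ProteinRecord("G_00010", catalog.query_protein("shc").sequence),
                 ProteinRecord("G_00005", catalog.query_protein("hpnH").sequence)]
        hits = scan_proteome(prots, catalog, genome_id="g")
        assert hits == sorted(hits, key=lambda h: (h.family_id, h.protein_id))


class TestExcludeSecondaryShc:
    def _hit(self, family, sim):
        return GeneHit("g", family, "p1", sim, 0.9, "accepted")

    def test_low_similarity_shc_marked_decoy(self):
        out = exclude_secondary_shc([self._hit("shc", 35.0)])
        assert out[0].call == "rejected_decoy"

    def test_shc_above_floor_unchanged(self):
        out = exclude_secondary_shc([self._hit("shc", 65.0)])
        assert out[0].call == "accepted"

    def test_rule_scoped_to_shc_only(self):
        out = exclude_secondary_shc([self._hit("hpnH", 35.0)])
        assert out[0].call == "accepted"
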