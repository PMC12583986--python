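"""Synthetic genomes and lipidomes with known ground truth."""

import pytest

from bhpdkit import (GenotypeScenario, align_local, assemble_genotype,
                     classify_architecture, cluster_hits, exclude_secondary_shc,
                     methylation_degree, mutate_protein, predict_chemotype,
                     scan_proteome, simulate_genome, simulate_lipidome)

CORE = frozenset({"dxs", "dxr", "ispDF", "ispE", "ispG", "ispH", "ispA",
                  "hpnC", "hpnD", "hpnE", "shc", "hpnG", "hpnH", "hpnN"})


class TestMutateProtein:
    def test_target_100_is_identity(self, catalog):
        ref = catalog.query_protein("shc")
        assert mutate_protein(ref, 100, seed=1).sequence == ref.sequence

    def test_out_of_range_target(self, catalog):
        with pytest.raises(ValueError):
            mutate_protein(catalog.query_protein("shc"), 0, seed=1)

    @pytest.mark.parametrize("target", [90, 70, 55])
    def test_realized_similarity_near_target(self, catalog, target):
        ref = catalog.query_protein("hpnH")  # 320 aa
        for seed in range(5):
            mut = mutate_protein(ref, target, seed=seed)
            sim = align_local(ref, mut).percent_similarity
            assert abs(sim - target) <= 5

    def test_deterministic_under_seed(self, catalog):
        ref = catalog.query_protein("shc")
        a = mutate_protein(ref, 60, seed=9).sequence
        b = mutate_protein(ref, 60, seed=9).sequence
        c = mutate_protein(ref, 60, seed=10).sequence
        assert a == b and a != c


class TestSimulateGenome:
    def test_full_canonical_bgc_recovered_contiguous(self, catalog):
        sc = GenotypeScenario(genome_id="full", families_present=CORE,
                              background_n=40, n_fragments=1)
        proteome, features, truth = simulate_genome(sc, seed=3, catalog=catalog)
        hits = exclude_secondary_shc(scan_proteome(proteome, catalog, genome_id="full"))
        accepted = {h.family_id for h in hits if h.call == "accepted"}
        assert accepted == CORE
        arch = classify_architecture(cluster_hits(hits, features), catalog)
        assert arch.cluster_class == "contiguous"
        assert arch.order_concordance == 1.0

    def test_shc_only_predicts_c30_without_bhpd(self, catalog):
        fams = frozenset({"dxs", "dxr", "ispDF", "ispE", "ispG", "ispH", "ispA",
                          "hpnC", "hpnD", "hpnE", "shc"})
        sc = GenotypeScenario(genome_id="ens", families_present=fams, background_n=30)
        proteome, features, _ = simulate_genome(sc, seed=4, catalog=catalog)
        hits = exclude_secondary_shc(scan_proteome(proteome, catalog, genome_id="ens"))
        pred = predict_chemotype(assemble_genotype(hits, catalog=catalog))
        assert pred.c30_hopanoids and not pred.bhpd_any

    def test_planted_decoy_rejected(self, catalog):
        sc = GenotypeScenario(genome_id="dec", families_present=frozenset(),
                              background_n=20, decoys=(("shc", 35.0),))
        proteome, _, truth = simulate_genome(sc, seed=5, catalog=catalog)
        hits = exclude_secondary_shc(scan_proteome(proteome, catalog, genome_id="dec"))
        (fam, target, tag), = truth.decoys
        decoy_hits = [h for h in hits if h.protein_id == tag and h.family_id == "shc"]
        assert decoy_hits and decoy_hits[0].call == "rejected_decoy"
        assert abs(decoy_hits[0].percent_similarity - target) <= 5

    def test_locus_tags_step_by_five(self, catalog):
        sc = GenotypeScenario(genome_id="s", families_present=CORE, background_n=10)
        _, features, _ = simulate_genome(sc, seed=6, catalog=catalog)
        by_contig = {}
        for f in features:
            by_contig.setdefault(f.contig, []).append(f)
        for feats in by_contig.values():
            nums = [f.locus_number for f in sorted(feats, key=lambda f: f.start)]
            assert all(b - a == 5 for a, b in zip(nums, nums[1:]))

    def test_determinism_and_seed_sensitivity(self, catalog):
        sc = GenotypeScenario(genome_id="d", families_present=CORE, background_n=15)
        p1, f1, _ = simulate_genome(sc, seed=7, catalog=catalog)
        p2, f2, _ = simulate_genome(sc, seed=7, catalog=catalog)
        p3, _, _ = simulate_genome(sc, seed=8, catalog=catalog)
        assert [p.sequence for p in p1] == [p.sequence for p in p2]
        assert f1 == f2
        assert [p.sequence for p in p1] != [p.sequence for p in p3]


def _bht_chemotype(catalog):
    from bhpdkit.align import GeneHit
    fams = ["dxs", "dxr", "ispDF", "ispE", "ispG", "ispH", "ispA",
            "hpnC", "hpnD", "hpnE", "shc", "hpnG", "hpnH", "hpnP", "hpnO"]
    hits = [GeneHit("g", f, f"p_{f}", 90.0, 1.0, "accepted") for f in fams]
    return predict_chemotype(assemble_genotype(hits, catalog=catalog))


class TestSimulateLipidome:
    def test_noiseless_recovery_is_exact(self, catalog):
        chem = _bht_chemotype(catalog)
        _, peaks, truth = simulate_lipidome(chem, seed=1, noise_cv=0.0,
                                            methyl2_pct=5.1, epimer_22s_pct=79.0)
        un = {p.analyte: p.area for p in peaks if p.transition[1] == 191.2}
        me = {p.analyte: p.area for p in peaks if p.transition[1] == 205.2}
        me32 = sum(a for n, a in me.items() if "bishomohopan-32-ol" in n)
        un32 = sum(a for n, a in un.items() if "bishomohopan-32-ol" in n)
        assert methylation_degree(me32, un32) == pytest.approx(5.1, rel=1e-12)
        s = sum(a for n, a in un.items() if "(22S)" in n)
        r = sum(a for n, a in un.items() if "(22R)" in n)
        from bhpdkit import epimer_fraction
        assert epimer_fraction(s, r) == pytest.approx(79.0, rel=1e-12)

    def test_monte_carlo_mean_near_planted_degree(self, catalog):
        chem = _bht_chemotype(catalog)
        recovered = []
        for seed in range(200):
            _, peaks, _ = simulate_lipidome(chem, seed=seed, noise_cv=0.05,
                                            methyl2_pct=5.1)
            un = sum(p.area for p in peaks
                     if p.transition[1] == 191.2 and "32-ol" in p.analyte)
            me = sum(p.area for p in peaks
                     if p.transition[1] == 205.2 and "32-ol" in p.analyte)
            recovered.append(methylation_degree(me, un))
        mean = sum(recovered) / len(recovered)
        assert abs(mean - 5.1) < 0.5

    def test_methyl_structures_require_capacity(self, catalog):
        chem = _bht_chemotype(catalog)
        assert not chem.methyl_3
        with pytest.raises(ValueError):
            simulate_lipidome(chem, seed=1, methyl3_pct=2.0)

    def test_inventory_respects_chemotype(self, catalog):
        chem = _bht_chemotype(catalog)
        inv, _, _ = simulate_lipidome(chem, seed=2)
        classes = {s.side_chain_class for s, _ in inv.entries}
        assert classes <= {"tetrol", "nucleoside", "amino"}
        assert inv.total() == pytest.approx(100.0)

    def test_unproducible_chemotype_is_an_error(self, catalog):
        from bhpdkit.chemotype import ChemotypePrediction
        with pytest.raises(ValueError):
            simulate_lipidome(ChemotypePrediction(), seed=1)
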