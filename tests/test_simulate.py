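"""The truth-known fixture generator itself."""

import math

import numpy as np
import pytest

from draftweaver.gapclose import find_nruns
from draftweaver.model import revcomp
from draftweaver.motifs import MotifAlignment, train_profile
from draftweaver.simulate import (
    SimConfig,
    build_scaffold,
    corrupt_nruns,
    diverge,
    fragment,
    plant_features,
    simulate_genome,
)


class TestSimulateGenome:
    def test_gc_within_binomial_bound(self):
        cfg = SimConfig(seed=3, genome_len=100_000, gc=0.6)
        g = simulate_genome(cfg)
        gc = (g.count("G") + g.count("C")) / len(g)
        sd = math.sqrt(0.6 * 0.4 / 100_000)
        assert abs(gc - 0.6) < 3 * sd

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=42, genome_len=20_000)
        assert simulate_genome(cfg) == simulate_genome(SimConfig(seed=42, genome_len=20_000))
        assert simulate_genome(cfg) != simulate_genome(SimConfig(seed=43, genome_len=20_000))

    def test_pure_gc_genome(self):
        g = simulate_genome(SimConfig(seed=1, genome_len=1000, gc=1.0))
        assert set(g) <= {"G", "C"}


class TestDiverge:
    def test_zero_rates_identity(self):
        cfg = SimConfig(seed=5, genome_len=50_000)
        g = simulate_genome(cfg)
        ref, dmap = diverge(g, cfg)
        assert ref == g
        assert dmap["n_substitutions"] == 0 and dmap["inversions"] == []

    def test_substitution_count_poisson_bound(self):
        cfg = SimConfig(seed=6, genome_len=100_000, sub_rate=0.01)
        g = simulate_genome(cfg)
        ref, dmap = diverge(g, cfg)
        expected = 1000
        assert abs(dmap["n_substitutions"] - expected) < 3 * math.sqrt(expected)
        observed = sum(1 for a, b in zip(g, ref) if a != b)
        assert observed == dmap["n_substitutions"]

    def test_impossible_inversions_error(self):
        cfg = SimConfig(seed=7, genome_len=12_000, n_inversions=5, inversion_len=(10_000, 11_000))
        g = simulate_genome(cfg)
        with pytest.raises(ValueError, match="reduce n_inversions"):
            diverge(g, cfg)

    def test_inversion_reverse_complements_segment(self):
        cfg = SimConfig(seed=8, genome_len=50_000, n_inversions=1, inversion_len=(8000, 8000))
        g = simulate_genome(cfg)
        ref, dmap = diverge(g, cfg)
        s, e = dmap["inversions"][0]
        assert ref[s:e] == revcomp(g[s:e])


class TestFragment:
    def test_explicit_plan(self):
        cfg = SimConfig(seed=9, genome_len=15_400, fragment_plan=[(5000, 400), (5000, 0), (5000, 0)])
        g = simulate_genome(cfg)
        asm, truth = fragment(g, cfg)
        assert asm.ids == ["c0001", "c0002", "c0003"]
        assert truth.true_adjacencies == [("c0001", "c0002", 400, 0), ("c0002", "c0003", 0, 0)]
        assert asm["c0001"].seq == g[:5000] and asm["c0002"].seq == g[5400:10_400]

    def test_conservation_identity(self):
        cfg = SimConfig(seed=10, genome_len=80_000, n_contigs=8, gap_range=(0, 500))
        g = simulate_genome(cfg)
        asm, truth = fragment(g, cfg)
        total = sum(truth.contig_lengths.values()) + sum(gap - ov for _, _, gap, ov in truth.true_adjacencies)
        assert total == len(g)
        truth.validate()

    def test_duplicated_junction_fixture(self):
        cfg = SimConfig(seed=11, genome_len=30_000, fragment_plan=[(10_000, 0), (10_000, 0), (10_000, 0)], overlap_bp=20)
        g = simulate_genome(cfg)
        asm, truth = fragment(g, cfg)
        assert asm["c0001"].seq[-20:] == asm["c0002"].seq[:20]
        assert all(ov == 20 for _, _, _, ov in truth.true_adjacencies)
        truth.validate()

    def test_plan_exceeding_genome_errors(self):
        cfg = SimConfig(seed=12, genome_len=1000, fragment_plan=[(800, 400), (300, 0)])
        with pytest.raises(ValueError, match="exceeds genome length"):
            fragment(simulate_genome(cfg), cfg)

    def test_shuffle_and_rc_recorded_in_truth(self):
        cfg = SimConfig(seed=13, genome_len=60_000, n_contigs=6, gap_range=(0, 100), shuffle=True, n_rc=3)
        g = simulate_genome(cfg)
        asm, truth = fragment(g, cfg)
        assert sorted(asm.ids) == [cid for cid, _ in truth.true_order_orientation]
        assert sum(1 for _, o in truth.true_order_orientation if o == "-") == 3


class TestScaffoldCorruption:
    def _fixture(self, wrong="fixed:10000"):
        cfg = SimConfig(seed=14, genome_len=60_000, fragment_plan=[(20_000, 480), (20_000, 0), (19_520, 0)])
        g = simulate_genome(cfg)
        asm, truth = fragment(g, cfg)
        scaf, truth = build_scaffold(asm, truth)
        return g, corrupt_nruns(scaf, truth, wrong)

    def test_fixed_rule_and_truth_positions(self):
        g, (corrupted, truth) = self._fixture()
        runs = find_nruns(corrupted)
        assert [(r.start, r.length) for r in runs] == [(20_000, 10_000)]
        assert truth.true_nrun_sizes == [("scaffold_1", 20_000, 480)]

    def test_zero_gap_emits_no_run(self):
        g, (corrupted, truth) = self._fixture()
        assert len(find_nruns(corrupted)) == 1  # only the 480 bp gap, not the 0 bp one

    def test_exact_rule_is_negative_control(self):
        g, (scaf, truth) = self._fixture(wrong="exact")
        (run,) = find_nruns(scaf)
        assert run.length == 480
        assert scaf["scaffold_1"].seq.replace("N" * 480, "", 1) == g[:20_000] + g[20_480:]


@pytest.fixture(scope="module")
def profile():
    return train_profile(MotifAlignment(["GGAACCGATTCCGACAGATGGGCCACT"] * 2 + ["GGAACCGATTCCGACAGATGGGCCACA"]))


class TestPlantFeatures:
    def test_planted_sites_pass_distance_filter_by_construction(self, profile):
        from draftweaver.motifs import MotifHit, filter_near_cds

        cfg = SimConfig(seed=15, genome_len=100_000, n_genes=12, n_motifs=12)
        g, genes, sites = plant_features(simulate_genome(cfg), cfg, profile)
        hits = [MotifHit("genome", s["start"], s["end"], s["strand"], 99.0) for s in sites]
        kept = filter_near_cds(hits, genes, max_dist=500)
        assert len(kept) == len(sites) == 12
        assert [h.distance for h in kept] == [s["distance"] for s in sites]

    def test_planted_instance_written_into_genome(self, profile):
        cfg = SimConfig(seed=16, genome_len=100_000, n_genes=10, n_motifs=10)
        g, genes, sites = plant_features(simulate_genome(cfg), cfg, profile)
        for s in sites:
            segment = g[s["start"] : s["end"]]
            assert segment == (s["instance"] if s["strand"] == "+" else revcomp(s["instance"]))

    def test_genes_never_overlap(self, profile):
        cfg = SimConfig(seed=17, genome_len=200_000, n_genes=30)
        _, genes, _ = plant_features(simulate_genome(cfg), cfg, None)
        intervals = sorted((g.start, g.end) for g in genes)
        assert all(a[1] < b[0] for a, b in zip(intervals, intervals[1:]))

    def test_site_600_bp_upstream_is_excluded_by_filter(self):
        """Negative control: the filter's reach really is 500."""
        from draftweaver.motifs import MotifHit, filter_near_cds
        from draftweaver.model import GeneFeature

        gene = GeneFeature("g", 5001, 5600, "+", "x")
        box = MotifHit("g", 5000 - 600 - 27, 5000 - 600, "+", 9.0)
        assert filter_near_cds([box], [gene], max_dist=500) == []
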