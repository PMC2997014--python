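"""Gap-candidate discovery, joining, and N-run resizing."""

import numpy as np
import pytest

from conftest import rand_seq
from draftweaver.gapclose import (
    JoinProposal,
    apply_joins,
    extract_ends,
    find_gap_candidates,
    find_nruns,
    merge_overlaps,
    pair_by_shared_gene,
    resize_nruns,
)
from draftweaver.model import Assembly, Contig, GapRecord, GeneFeature, Thresholds, revcomp

TH = Thresholds()


class TestExtractEnds:
    def test_both_ends_of_long_contig(self, rng):
        asm = Assembly([Contig("c", rand_seq(rng, 5000))])
        ends = extract_ends(asm, TH)
        assert [(e.side, e.start, e.end) for e in ends] == [("left", 0, 300), ("right", 4700, 5000)]
        assert ends[1].seq == asm["c"].seq[4700:]

    @pytest.mark.parametrize("length,n_ends", [(900, 0), (1000, 0), (1001, 2)], ids=["short", "at-1kb-boundary", "just-over"])
    def test_one_kb_is_strict(self, rng, length, n_ends):
        asm = Assembly([Contig("c", rand_seq(rng, length))])
        assert len(extract_ends(asm, TH)) == n_ends


@pytest.fixture(scope="module")
def deletion_fixture():
    """Reference = intact genome; contigs = genome with a 400 bp deletion."""
    rng = np.random.default_rng(77)
    ref = rand_seq(rng, 30_000)
    asm = Assembly([Contig("cA", ref[:12_000]), Contig("cB", ref[12_400:])])
    return ref, asm


class TestFindGapCandidates:
    def test_recovers_deletion_with_gap_size(self, deletion_fixture):
        ref, asm = deletion_fixture
        cands = find_gap_candidates(extract_ends(asm, TH), {"ref": ref}, TH)
        assert len(cands) == 1
        c = cands[0]
        assert {c.end_a.contig_id, c.end_b.contig_id} == {"cA", "cB"}
        assert c.implied_gap == 400 and not c.overlap
        assert max(c.evalue_a, c.evalue_b) <= TH.max_evalue

    def test_hits_on_different_references_never_pair(self, rng):
        refs = {"r1": rand_seq(rng, 10_000), "r2": rand_seq(rng, 10_000)}
        asm = Assembly([Contig("cA", refs["r1"][:5000]), Contig("cB", refs["r2"][:5000])])
        assert find_gap_candidates(extract_ends(asm, TH), refs, TH) == []

    def test_separation_beyond_one_kb_rejected(self, rng):
        ref = rand_seq(rng, 30_000)
        asm = Assembly([Contig("cA", ref[:10_000]), Contig("cB", ref[15_000:])])
        assert find_gap_candidates(extract_ends(asm, TH), {"ref": ref}, TH) == []

    def test_same_contig_ends_never_pair(self, rng):
        ref = rand_seq(rng, 10_000)
        asm = Assembly([Contig("cA", ref[:2000])])
        assert find_gap_candidates(extract_ends(asm, TH), {"ref": ref}, TH) == []

    def test_reverse_complemented_contig_still_pairs(self, deletion_fixture):
        ref, asm = deletion_fixture
        flipped = Assembly([Contig("cA", asm["cA"].seq), Contig("cB", revcomp(asm["cB"].seq))])
        cands = find_gap_candidates(extract_ends(flipped, TH), {"ref": ref}, TH)
        assert len(cands) == 1 and cands[0].implied_gap == 400


class TestMergeOverlaps:
    def _pair(self, rng, overlap, mismatch=False):
        a = rand_seq(rng, 2000)
        b_head = a[-overlap:] if overlap else ""
        if mismatch and overlap:
            i = overlap // 2
            b_head = b_head[:i] + ("A" if b_head[i] != "A" else "C") + b_head[i + 1 :]
        b = b_head + rand_seq(rng, 2000)
        return Assembly([Contig("A", a), Contig("B", b)])

    def test_twenty_bp_exact_overlap_merges(self, rng):
        asm = self._pair(rng, 20)
        props = merge_overlaps(asm, [(("A", "+"), ("B", "+"))], TH)
        assert len(props) == 1 and props[0].merge_overlap == 20
        scaffolds, _ = apply_joins(asm, props)
        assert len(scaffolds[0].sequence(asm)) == len(asm["A"]) + len(asm["B"]) - 20

    def test_fourteen_bp_overlap_rejected(self, rng):
        asm = self._pair(rng, 14)
        assert merge_overlaps(asm, [(("A", "+"), ("B", "+"))], TH) == []

    def test_single_mismatch_disqualifies(self, rng):
        asm = self._pair(rng, 20, mismatch=True)
        assert merge_overlaps(asm, [(("A", "+"), ("B", "+"))], TH) == []

    def test_orientation_search_without_hints(self, rng):
        asm0 = self._pair(rng, 25)
        asm = Assembly([Contig("A", asm0["A"].seq), Contig("B", revcomp(asm0["B"].seq))])
        props = merge_overlaps(asm, [("A", "B")], TH)
        assert len(props) == 1 and props[0].merge_overlap == 25
        assert props[0].side_b == "right"


@pytest.fixture(scope="module")
def gene_fixture():
    rng = np.random.default_rng(88)
    ref = rand_seq(rng, 20_000)
    gs = 10_000  # gene occupies ref[10000:10600), 1-based 10001..10600
    gene = GeneFeature("ref", gs + 1, gs + 600, "+", "geneX")
    return ref, gs, gene


class TestPairBySharedGene:
    def test_disjoint_gene_portions_pair_with_gap(self, gene_fixture):
        ref, gs, gene = gene_fixture
        # A's right end covers gene bases 1..180; B's left end covers 241..600
        asm = Assembly([Contig("A", ref[gs + 180 - 2000 : gs + 180]), Contig("B", ref[gs + 240 : gs + 240 + 2000])])
        props = pair_by_shared_gene(extract_ends(asm, TH), [gene], {"ref": ref}, TH)
        assert len(props) == 1
        assert props[0].kind == "shared_gene" and props[0].gap.n_count == 60

    def test_overlapping_portions_do_not_pair(self, gene_fixture):
        ref, gs, gene = gene_fixture
        asm = Assembly([Contig("A", ref[gs + 180 - 2000 : gs + 180]), Contig("B", ref[gs + 100 : gs + 100 + 2000])])
        assert pair_by_shared_gene(extract_ends(asm, TH), [gene], {"ref": ref}, TH) == []

    def test_hits_to_different_genes_do_not_pair(self, gene_fixture):
        ref, gs, _ = gene_fixture
        genes = [GeneFeature("ref", gs - 3000, gs - 2500, "+", "g1"), GeneFeature("ref", gs + 1, gs + 600, "+", "g2")]
        asm = Assembly([Contig("A", ref[gs - 2800 - 2000 : gs - 2800]), Contig("B", ref[gs + 240 : gs + 240 + 2000])])
        assert pair_by_shared_gene(extract_ends(asm, TH), genes, {"ref": ref}, TH) == []


def _adjacency_proposal(a, side_a, b, side_b, gap=100, score=1.0):
    return JoinProposal("reference_adjacency", a, side_a, b, side_b, score,
                        gap=GapRecord(gap, "physical_gap_closed"))


class TestApplyJoins:
    def _asm(self, rng, ids):
        return Assembly([Contig(i, rand_seq(rng, 1500)) for i in ids])

    def test_chain_becomes_one_scaffold(self, rng):
        asm = self._asm(rng, "ABC")
        props = [_adjacency_proposal("A", "right", "B", "left"), _adjacency_proposal("B", "right", "C", "left")]
        scaffolds, report = apply_joins(asm, props)
        assert len(scaffolds) == 1
        assert [p.contig_id for p in scaffolds[0].contig_parts()] == ["A", "B", "C"]
        assert len(report.accepted) == 2

    def test_competing_end_resolved_by_rank(self, rng):
        asm = self._asm(rng, "ABC")
        winner = JoinProposal("overlap_merge", "A", "right", "B", "left", 20.0, merge_overlap=20)
        loser = _adjacency_proposal("A", "right", "C", "left")
        scaffolds, report = apply_joins(asm, [loser, winner])
        assert winner in report.accepted
        assert report.rejected and report.rejected[0][0] is loser

    def test_cycle_broken_at_lowest_ranked_edge(self, rng):
        asm = self._asm(rng, "ABC")
        props = [
            _adjacency_proposal("A", "right", "B", "left", score=3.0),
            _adjacency_proposal("B", "right", "C", "left", score=2.0),
            _adjacency_proposal("C", "right", "A", "left", score=1.0),
        ]
        scaffolds, report = apply_joins(asm, props)
        assert len(scaffolds) == 1 and len(report.accepted) == 2
        assert report.rejected[0][1] == "would close a cycle"
        assert report.rejected[0][0].score == 1.0

    def test_unknown_contig_errors(self, rng):
        with pytest.raises(ValueError, match="unknown contig"):
            apply_joins(self._asm(rng, "AB"), [_adjacency_proposal("A", "right", "Z", "left")])

    def test_sequence_conservation(self, rng):
        """Joins never lose or duplicate contig sequence (non-N bases)."""
        asm = self._asm(rng, "ABCDE")
        props = [
            _adjacency_proposal("A", "right", "B", "left", gap=7),
            _adjacency_proposal("C", "left", "B", "right", gap=11),
            _adjacency_proposal("D", "right", "E", "right", gap=13),
        ]
        scaffolds, _ = apply_joins(asm, props)
        rendered = "".join(s.sequence(asm) for s in scaffolds)
        assert len(rendered) - rendered.count("N") == asm.total_bases()
        assert rendered.count("N") == 7 + 11 + 13


class TestFindNruns:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGNNNNACG", [(3, 4)]), ("NNNACG", [(0, 3)]), ("ACGT", []), ("acgnnnACG", [(3, 3)])],
        ids=["internal", "edge", "none", "case-insensitive"],
    )
    def test_maximal_runs(self, seq, expected):
        runs = find_nruns({"s": seq})
        assert [(r.start, r.length) for r in runs] == expected


@pytest.fixture(scope="module")
def ref():
    return rand_seq(np.random.default_rng(99), 60_000)


class TestResizeNruns:
    def _scaffold_with_gap(self, ref, true_gap, wrong_n, at=30_000):
        return {"s": ref[:at] + "N" * wrong_n + ref[at + true_gap :]}

    def test_mapped_flanks_restore_true_size(self, ref):
        scaf = self._scaffold_with_gap(ref, 480, 12_000)
        out, report = resize_nruns(scaf, {"ref": ref}, TH)
        assert report[0].rule == "reference" and report[0].new_n == 480
        assert out["s"].seq == ref[:30_000] + "N" * 480 + ref[30_480:]

    def test_unmapped_flanks_capped_at_300(self, rng, ref):
        foreign = rand_seq(rng, 2000) + "N" * 8000 + rand_seq(rng, 2000)
        _, report = resize_nruns({"s": foreign}, {"ref": ref}, TH)
        assert report[0].rule == "cap" and report[0].new_n == 300

    @pytest.mark.parametrize("n,touched", [(200, False), (300, False), (301, True)], ids=["small", "at-300", "just-over"])
    def test_300_boundary_is_strict(self, ref, n, touched):
        scaf = self._scaffold_with_gap(ref, 500, n)
        _, report = resize_nruns(scaf, {"ref": ref}, TH)
        assert (report[0].rule != "untouched") is touched

    def test_reverse_complement_region_still_resized(self, ref):
        scaf = {"s": revcomp(ref[:30_000]) }
        scaf = {"s": revcomp(ref[30_480:]) + "N" * 5000 + revcomp(ref[:30_000])}
        _, report = resize_nruns(scaf, {"ref": ref}, TH)
        assert report[0].rule == "reference" and report[0].new_n == 480

    def test_negative_implied_distance_floors_to_one(self, ref):
        # flanks overlap by 50 bp on the reference -> implied distance < 0
        scaf = {"s": ref[:30_000] + "N" * 400 + ref[29_950:]}
        _, report = resize_nruns(scaf, {"ref": ref}, TH)
        assert report[0].new_n == 1 and report[0].overlap

    def test_run_flush_with_boundary_left_unchanged(self, ref, caplog):
        scaf = {"s": "N" * 400 + ref[:5000]}
        with caplog.at_level("WARNING", logger="draftweaver"):
            out, report = resize_nruns(scaf, {"ref": ref}, TH)
        assert report[0].rule == "boundary" and out["s"].seq.startswith("N" * 400)
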