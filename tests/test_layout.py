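"""Unique-k-mer anchoring, reference-guided reordering, and congruency."""

import numpy as np
import pytest

from conftest import rand_seq
from draftweaver.layout import anchor_scaffolds, congruency_report, reorder_scaffolds
from draftweaver.model import Assembly, Contig, Thresholds, revcomp

TH = Thresholds()


class TestAnchorScaffolds:
    def test_verbatim_copy_anchors_forward(self, rng):
        ref = rand_seq(rng, 5000)
        sets = anchor_scaffolds({"s": ref[1000:2000]}, {"ref": ref}, k=25)
        anchors = sets[0].anchors
        assert len(anchors) == 1000 - 24
        assert all(strand == "+" and rpos == spos + 1000 for spos, _, rpos, strand in anchors)

    def test_reverse_complement_anchors_minus(self, rng):
        ref = rand_seq(rng, 5000)
        sets = anchor_scaffolds({"s": revcomp(ref[1000:2000])}, {"ref": ref}, k=25)
        assert sets[0].anchors and all(s == "-" for _, _, _, s in sets[0].anchors)

    def test_duplicated_reference_kmer_not_anchored(self):
        unit = "ACGTTGCAAGGCTTAGGCACTCAATGGCA"  # 29 bp, repeated twice in ref
        ref = unit + "T" * 40 + unit
        sets = anchor_scaffolds({"s": unit}, {"ref": ref}, k=25)
        assert sets[0].anchors == []

    def test_k_floor(self):
        with pytest.raises(ValueError):
            anchor_scaffolds({"s": "A" * 100}, {"r": "A" * 100}, k=10)


class TestReorderScaffolds:
    def test_fragmentation_round_trip(self, rng):
        """Cutting a reference into shuffled, partly reverse-complemented
        pieces and reordering recovers the truth exactly."""
        ref = rand_seq(rng, 200_000)
        bounds = sorted(rng.choice(np.arange(5000, 195_000), size=9, replace=False).tolist())
        pieces = []
        prev = 0
        for i, b in enumerate(bounds + [200_000]):
            pieces.append((f"p{i:02d}", ref[prev:b]))
            prev = b
        flip = {f"p{i:02d}" for i in rng.choice(10, size=4, replace=False).tolist()}
        scrambled = {pid: (revcomp(s) if pid in flip else s) for pid, s in pieces}
        order = list(scrambled)
        rng.shuffle(order)
        anchors = anchor_scaffolds({pid: scrambled[pid] for pid in order}, {"ref": ref}, k=25)
        lengths = {pid: len(scrambled[pid]) for pid in scrambled}
        ordered, unplaced = reorder_scaffolds(anchors, lengths, TH)
        assert not unplaced
        assert [d.scaffold_id for d in ordered] == [pid for pid, _ in pieces]
        for d in ordered:
            assert d.orientation == ("-" if d.scaffold_id in flip else "+")

    def test_no_anchors_reason(self, rng):
        ref = rand_seq(rng, 10_000)
        foreign = rand_seq(np.random.default_rng(5), 2000)
        _, unplaced = reorder_scaffolds(anchor_scaffolds({"x": foreign}, {"ref": ref}, 25), {"x": 2000}, TH)
        assert unplaced[0].reason_if_unplaced == "no anchors"

    def test_short_scaffold_unplaced(self, rng):
        ref = rand_seq(rng, 10_000)
        _, unplaced = reorder_scaffolds(anchor_scaffolds({"x": ref[:1000]}, {"ref": ref}, 25), {"x": 1000}, TH)
        assert "length" in unplaced[0].reason_if_unplaced

    def _mixed_strand_anchorset(self, rng, plus, minus):
        from draftweaver.layout import AnchorSet

        anchors = [(i, "ref", 1000 + i, "+") for i in range(plus)]
        anchors += [(plus + i, "ref", 2000 + i, "-") for i in range(minus)]
        return AnchorSet("x", anchors, 25)

    def test_majority_strand_orientation(self, rng):
        aset = self._mixed_strand_anchorset(rng, 6, 4)
        ordered, _ = reorder_scaffolds([aset], {"x": 5000}, TH)
        assert ordered[0].orientation == "+"

    def test_strand_tie_is_unplaced(self, rng):
        aset = self._mixed_strand_anchorset(rng, 5, 5)
        _, unplaced = reorder_scaffolds([aset], {"x": 5000}, TH)
        assert unplaced[0].reason_if_unplaced == "orientation tie"


@pytest.fixture(scope="module")
def congruency_base():
    return rand_seq(np.random.default_rng(13), 30_000)


def _split(base, label, *cuts):
    bounds = [0, *cuts, len(base)]
    return Assembly(
        [Contig(f"{label}{i}", base[a:b]) for i, (a, b) in enumerate(zip(bounds, bounds[1:]))],
        label=label,
    )


class TestCongruency:
    def test_identical_assemblies_all_keep(self, congruency_base):
        asms = [_split(congruency_base, lab, 12_000) for lab in ("a", "b", "c")]
        report = congruency_report(asms)
        assert all(c.supported for c in report.contigs)
        assert set(report.verdicts.values()) == {"keep"}

    def test_chimeric_large_contig_culls_assembly(self, congruency_base):
        base = congruency_base
        a1 = _split(base, "a", 12_000)
        a2 = _split(base, "b", 12_000)
        chimera = base[:6000] + base[20_000:26_000]  # two distant regions, 12 kb
        a3 = Assembly([Contig("z_chim", chimera), Contig("z2", base[:12_000]), Contig("z3", base[12_000:])], label="c")
        report = congruency_report([a1, a2, a3])
        assert report.verdicts == {"a": "keep", "b": "keep", "c": "cull"}
        assert "z_chim" in report.offending["c"]
        chim_row = next(c for c in report.contigs if c.contig_id == "z_chim")
        assert not chim_row.supported and chim_row.best_support_fraction < 0.95

    def test_small_unsupported_contig_flagged_but_kept(self, congruency_base, rng):
        base = congruency_base
        a1 = _split(base, "a", 12_000)
        a2 = _split(base, "b", 12_000)
        a3 = Assembly([Contig("z1", base[:12_000]), Contig("z2", base[12_000:]), Contig("z_alien", rand_seq(rng, 5000))], label="c")
        report = congruency_report([a1, a2, a3])
        alien = next(c for c in report.contigs if c.contig_id == "z_alien")
        assert not alien.supported
        assert report.verdicts["c"] == "keep"

    def test_verdicts_symmetric_under_relabeling(self, congruency_base):
        base = congruency_base
        asms = [_split(base, lab, 12_000) for lab in ("a", "b")]
        chimera = Assembly([Contig("z", base[:6000] + base[20_000:26_000]), Contig("z2", base)], label="c")
        fwd = congruency_report([*asms, chimera]).verdicts
        rev = congruency_report([chimera, *reversed(asms)]).verdicts
        assert fwd == rev

    def test_requires_two_assemblies(self, congruency_base):
        with pytest.raises(ValueError):
            congruency_report([_split(congruency_base, "a", 12_000)])
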