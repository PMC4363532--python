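"""Regulatory signatures: coverage rule, selection, merging, composites."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffcoex import (
    RegulatorAnnotation,
    SignatureNetwork,
    composite_signature,
    covered_pairs,
    merge_signatures,
    select_signatures,
)
from diffcoex.signatures import (
    MIRNA,
    TF,
    demo_annotations,
    demo_network_pairs,
    read_annotations,
    write_signature_pajek,
)


def ann(rid, cls, targets):
    return RegulatorAnnotation(rid, cls, frozenset(targets))


class TestCoveredPairs:
    def test_both_endpoint_rule(self):
        a = ann("m1", MIRNA, {"A", "B", "C"})
        net = [("A", "B"), ("A", "D")]
        assert covered_pairs(net, a) == {("A", "B")}

    def test_single_endpoint_variant(self):
        a = ann("m1", MIRNA, {"A"})
        net = [("A", "B"), ("C", "D")]
        assert covered_pairs(net, a, both_endpoints=False) == {("A", "B")}

    def test_no_targets_in_network(self):
        assert covered_pairs([("A", "B")], ann("m1", MIRNA, {"X"})) == set()

    def test_universal_regulator_covers_everything(self):
        net = [("A", "B"), ("B", "C")]
        assert covered_pairs(net, ann("t", TF, {"A", "B", "C"})) == set(
            map(tuple, net)
        )

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_coverage_is_subset_of_network(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        net = {
            tuple(sorted(rng.choice(genes, 2, replace=False))) for _ in range(10)
        }
        a = ann("r", TF, set(rng.choice(genes, 4, replace=False)))
        assert covered_pairs(net, a) <= net


class TestSelectSignatures:
    def test_inclusive_minimum(self):
        net = [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D")]
        a = ann("m", MIRNA, {"A", "B", "C", "D"})
        selected, report = select_signatures(net, [a], min_pairs=4)
        assert len(selected) == 1
        assert report.loc[0, "selected"] == "yes"
        assert report.loc[0, "n_covered_pairs"] == 4

    def test_below_threshold_excluded_but_reported(self):
        net = [("A", "B"), ("A", "C"), ("B", "C")]
        a = ann("m", MIRNA, {"A", "B", "C"})
        selected, report = select_signatures(net, [a], min_pairs=4)
        assert selected == []
        assert report.loc[0, "n_covered_pairs"] == 3
        assert report.loc[0, "selected"] == "no"

    def test_permissive_minimum(self):
        net = [("A", "B")]
        selected, _ = select_signatures(net, [ann("m", MIRNA, {"A", "B"})],
                                        min_pairs=1)
        assert len(selected) == 1


class TestMergeSignatures:
    def sig(self, rid, pairs):
        return SignatureNetwork({rid: MIRNA}, {tuple(sorted(p)) for p in pairs})

    def test_shared_genes_merge(self):
        s1 = self.sig("m1", [("BAK1", "BCL2"), ("BAK1", "X")])
        s2 = self.sig("m2", [("BCL2", "Y"), ("BAK1", "BCL2")])
        merged = merge_signatures([s1, s2])
        assert len(merged) == 1
        assert merged[0].merged
        assert set(merged[0].regulators) == {"m1", "m2"}
        assert merged[0].covered_pairs == s1.covered_pairs | s2.covered_pairs

    def test_disjoint_signatures_stay_separate(self):
        s1 = self.sig("m1", [("A", "B")])
        s2 = self.sig("m2", [("C", "D")])
        merged = merge_signatures([s1, s2])
        assert len(merged) == 2
        assert not any(m.merged for m in merged)

    def test_single_signature_is_identity(self):
        s = self.sig("m1", [("A", "B")])
        (m,) = merge_signatures([s])
        assert m.covered_pairs == s.covered_pairs and not m.merged

    def test_order_independent(self):
        sigs = [
            self.sig("m1", [("A", "B")]),
            self.sig("m2", [("B", "C")]),
            self.sig("m3", [("D", "E")]),
        ]
        expected = None
        for perm in itertools.permutations(sigs):
            merged = merge_signatures(list(perm))
            key = sorted(
                (tuple(sorted(m.regulators)), tuple(sorted(m.covered_pairs)))
                for m in merged
            )
            if expected is None:
                expected = key
            assert key == expected

    def test_class_check(self):
        s = SignatureNetwork({"t": TF}, {("A", "B")})
        with pytest.raises(ValueError):
            merge_signatures([s], by_class=MIRNA)


class TestCompositeSignature:
    def test_intersection_and_containment(self):
        mrs = SignatureNetwork(
            {"m": MIRNA}, {("A", "B"), ("A", "C"), ("B", "C"), ("X", "Y")}
        )
        trs = SignatureNetwork({"t": TF}, {("A", "B"), ("A", "C"), ("B", "C")})
        crs = composite_signature(mrs, trs)
        assert crs.covered_pairs == {("A", "B"), ("A", "C"), ("B", "C")}
        assert crs.covered_pairs <= mrs.covered_pairs
        assert crs.covered_pairs <= trs.covered_pairs

    def test_disjoint_networks_give_empty_crs(self):
        mrs = SignatureNetwork({"m": MIRNA}, {("A", "B")})
        trs = SignatureNetwork({"t": TF}, {("C", "D")})
        assert composite_signature(mrs, trs).covered_pairs == set()

    def test_identical_networks_idempotent(self):
        pairs = {("A", "B"), ("B", "C")}
        mrs = SignatureNetwork({"m": MIRNA}, set(pairs))
        trs = SignatureNetwork({"t": TF}, set(pairs))
        assert composite_signature(mrs, trs).covered_pairs == pairs


class TestDemoFixture:
    """The shipped synthetic annotation fixture reproduces the documented
    behaviours: two mergeable miRNA signatures, three TF signatures sharing
    one hub gene, and a 3-gene triangle composite."""

    def test_selection_matches_coverage_counts(self):
        net = demo_network_pairs()
        anns = demo_annotations()
        selected, report = select_signatures(net, anns, min_pairs=4)
        expected = {
            a.regulator_id
            for a in anns
            if len(covered_pairs(net, a)) >= 4
        }
        got = {list(s.regulators)[0] for s in selected}
        assert got == expected
        assert "hsa-miR-15a" not in got  # covers only 1 demo pair

    def test_mrs_trs_merge_structure(self):
        net = demo_network_pairs()
        selected, _ = select_signatures(net, demo_annotations(), min_pairs=4)
        mirna = [s for s in selected if set(s.regulators.values()) == {MIRNA}]
        tf = [s for s in selected if set(s.regulators.values()) == {TF}]
        (mrs,) = merge_signatures(mirna)
        (trs,) = merge_signatures(tf)
        assert set(mrs.regulators) == {"hsa-miR-504", "hsa-miR-125a"}
        assert {"BAK1", "BCL2"} <= mrs.genes
        assert set(trs.regulators) == {"AP-4", "E2F", "VDR"}
        assert "E2F2" in trs.genes

    def test_composite_is_the_planted_triangle(self):
        net = demo_network_pairs()
        anns = demo_annotations()
        selected, _ = select_signatures(net, anns, min_pairs=4)
        (mrs,) = merge_signatures(
            [s for s in selected if set(s.regulators.values()) == {MIRNA}]
        )
        (trs,) = merge_signatures(
            [s for s in selected if set(s.regulators.values()) == {TF}]
        )
        crs = composite_signature(mrs, trs, anns)
        assert crs.genes == {"E2F2", "BAK1", "PIK3R5"}
        assert crs.covered_pairs == {
            ("BAK1", "E2F2"), ("E2F2", "PIK3R5"), ("BAK1", "PIK3R5")
        }
        # regulators whose target sets cover the whole triangle
        assert set(crs.regulators) == {"hsa-miR-125a", "AP-4"}


def test_annotation_table_round_trip(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "m1\tmiRNA\tA\nm1\tmiRNA\tB\nt1\tTF\tA\n# comment\nt1\tTF\tC\n"
    )
    anns = read_annotations(path)
    by_id = {a.regulator_id: a for a in anns}
    assert by_id["m1"].targets == {"A", "B"}
    assert by_id["t1"].regulator_class == TF


def test_signature_pajek_export(tmp_path):
    s = SignatureNetwork({"m": MIRNA}, {("A", "B")})
    path = tmp_path / "sig.net"
    write_signature_pajek(s, path)
    text = path.read_text()
    assert "*Vertices 3" in text and '"m (miRNA)"' in text
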