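"""Variation-graph construction and generator operations."""
import networkx as nx
import pytest

import mtmixgraph as mg
from mtmixgraph.graph import KIND_BASE, KIND_EPSILON, base_id, eps_id

from conftest import make_reference


class TestReferenceGraph:
    def test_linear_backbone_counts(self):
        ref = mg.ReferenceSequence("r", "ACG")
        vg = mg.build_reference_graph(ref)
        kinds = [d["kind"] for _, d in vg.g.nodes(data=True)]
        assert kinds.count(KIND_BASE) == 3
        assert kinds.count(KIND_EPSILON) == 4
        assert mg.count_generated(vg) == 1

    def test_single_base(self):
        vg = mg.build_reference_graph(mg.ReferenceSequence("r", "A"))
        assert nx.has_path(vg.g, "source", "sink")
        assert mg.enumerate_generated(vg).sequences == frozenset({"A"})

    def test_generates_exactly_the_reference(self):
        ref = make_reference(40, seed=2)
        vg = mg.build_reference_graph(ref)
        assert mg.enumerate_generated(vg).sequences == frozenset({ref.bases})

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            mg.ReferenceSequence("r", "")


class TestSubstitution:
    def test_parallel_allele_nodes(self):
        ref = mg.ReferenceSequence("r", "AACCT")
        vg = mg.build_reference_graph(ref)
        out = mg.apply_substitution(
            vg, mg.VariantCall.substitution(3, {"T", "C"}, ref)
        )
        assert base_id(3, "T") in out.g and base_id(3, "C") in out.g
        assert set(out.g.predecessors(base_id(3, "T"))) == {eps_id(2)}
        assert set(out.g.successors(base_id(3, "T"))) == {eps_id(3)}

    def test_self_substitution_is_identity(self):
        ref = mg.ReferenceSequence("r", "AACCT")
        vg = mg.build_reference_graph(ref)
        out = mg.apply_substitution(vg, mg.VariantCall.substitution(3, {"C"}, ref))
        assert out == vg

    def test_fixed_substitution_removes_reference_base(self, worked_ref):
        profile = mg.parse_variant_string("73G", worked_ref)
        vg = mg.build_mixture_graph(profile)
        gen = mg.enumerate_generated(vg)
        (seq,) = gen.sequences
        assert seq[72] == "G"

    def test_double_modification_rejected(self):
        ref = mg.ReferenceSequence("r", "AACCT")
        vg = mg.apply_substitution(
            mg.build_reference_graph(ref), mg.VariantCall.substitution(3, {"T"}, ref)
        )
        with pytest.raises(mg.GraphConstructionError):
            mg.apply_substitution(vg, mg.VariantCall.substitution(3, {"G"}, ref))


class TestInsertion:
    def test_retained_insertion_generates_both(self, fig3_graph):
        assert mg.enumerate_generated(fig3_graph).sequences == frozenset(
            {"AACT", "AACCT"}
        )

    def test_fixed_insertion_generates_only_inserted(self, fig3_ref):
        profile = mg.parse_variant_string("3.1C!", fig3_ref)
        vg = mg.build_mixture_graph(profile)
        assert mg.enumerate_generated(vg).sequences == frozenset({"AACCT"})

    def test_conflicting_insertion_rejected(self, fig3_ref):
        vg = mg.build_mixture_graph(mg.parse_variant_string("3.1C", fig3_ref))
        with pytest.raises(mg.GraphConstructionError):
            mg.apply_insertion(vg, mg.VariantCall.insertion(3, "T"))


class TestDeletion:
    def test_homopolymer_placements_generate_identical_sets(self, homopolymer_ref):
        g4 = mg.build_mixture_graph(mg.parse_variant_string("4 del", homopolymer_ref))
        g5 = mg.build_mixture_graph(mg.parse_variant_string("5 del", homopolymer_ref))
        s4 = mg.enumerate_generated(g4).sequences
        assert s4 == mg.enumerate_generated(g5).sequences
        assert "AACAGT" in s4

    def test_fixed_deletion_removes_base_everywhere(self, homopolymer_ref):
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("6 del!", homopolymer_ref)
        )
        gen = mg.enumerate_generated(vg)
        assert gen.sequences == frozenset({"AACAAT"})

    def test_insertion_and_deletion_coexist(self, homopolymer_ref):
        # optional insertion after 4 plus optional deletion of 5..6
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("4.1T 5 del 6 del", homopolymer_ref)
        )
        gen = mg.enumerate_generated(vg).sequences
        assert {"AACAAGT", "AACATAGT", "AACAT"} <= gen

    def test_overlapping_deletions_rejected_at_graph_level(self, homopolymer_ref):
        vg = mg.build_reference_graph(homopolymer_ref)
        vg = mg.apply_deletion(vg, mg.VariantCall.deletion(4, 5))
        with pytest.raises(mg.GraphConstructionError):
            mg.apply_deletion(vg, mg.VariantCall.deletion(5, 6))


class TestMixtureGraph:
    def test_fig2_recast_with_epsilon_bottleneck(self, fig2_graph):
        assert mg.enumerate_generated(fig2_graph).sequences == frozenset(
            {"AATTT", "AATCT", "AACTT", "AACCT"}
        )
        assert mg.count_generated(fig2_graph) == 4

    def test_empty_profile_gives_reference_graph(self, fig2_ref):
        profile = mg.parse_variant_string("", fig2_ref)
        assert mg.build_mixture_graph(profile) == mg.build_reference_graph(fig2_ref)

    def test_worked_example_generates_four(self, worked_ref):
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("73G 154W 178M", worked_ref)
        )
        assert mg.enumerate_generated(vg).count == 4

    def test_deterministic_construction(self, worked_ref):
        p = mg.parse_variant_string("73G 154W 178M", worked_ref)
        assert mg.build_mixture_graph(p) == mg.build_mixture_graph(p)

    def test_acyclic_and_connected_after_construction(self):
        from mtmixgraph.simulate import PopulationModel, simulate_database, make_mixture

        model = PopulationModel(
            reference_length=100, n_haplotypes=20, indel_rate=0.02, seed=9
        )
        db = mg.simulate_database(model)
        built = 0
        for i in range(0, 18, 2):
            merged = make_mixture(db.records[i], db.records[i + 1], db.reference)
            if isinstance(merged, mg.MixtureRejection):
                continue
            vg = mg.build_mixture_graph(merged)
            assert nx.is_directed_acyclic_graph(vg.g)
            desc = nx.descendants(vg.g, "source") | {"source"}
            anc = nx.ancestors(vg.g, "sink") | {"sink"}
            assert set(vg.g.nodes) == desc == anc
            built += 1
        assert built >= 5

    def test_epsilon_bottleneck_no_base_to_base_edges_across_positions(self):
        # base->base edges exist only inside insertion chains
        ref = make_reference(50, seed=4)
        profile = mg.MixtureProfile.from_calls(
            ref,
            [
                mg.VariantCall.substitution(10, {"A", "C", "G", "T"}, ref),
                mg.VariantCall.substitution(11, {"A", "C"}, ref),
                mg.VariantCall.insertion(20, "TTG"),
                mg.VariantCall.deletion(30, 32),
            ],
        )
        vg = mg.build_mixture_graph(profile)
        for u, v in vg.g.edges():
            if vg.kind(u) == KIND_BASE and vg.kind(v) == KIND_BASE:
                assert u.startswith("bi:") or v.startswith("bi:")


class TestGeneratorOperations:
    @pytest.mark.parametrize("k", [1, 4, 8, 12])
    def test_path_count_matches_enumeration(self, k):
        ref = make_reference(3 * k + 5, seed=k)
        calls = []
        for i in range(k):
            pos = 2 + 3 * i
            alt = "A" if ref.base_at(pos) != "A" else "C"
            calls.append(
                mg.VariantCall.substitution(pos, {ref.base_at(pos), alt}, ref)
            )
        vg = mg.build_mixture_graph(mg.MixtureProfile.from_calls(ref, calls))
        gen = mg.enumerate_generated(vg, cap=10_000)
        assert not gen.truncated
        assert mg.count_generated(vg) == 2**k == gen.count

    def test_truncation_flagged(self, fig2_graph):
        gen = mg.enumerate_generated(fig2_graph, cap=2)
        assert gen.truncated and gen.count <= 2

    def test_single_source_graph_generates_decoded_haplotype(self):
        ref = make_reference(60, seed=5)
        profile = mg.parse_variant_string(
            "10G 20 del 30.1TT", ref, single_source=True
        )
        vg = mg.build_mixture_graph(profile)
        assert mg.enumerate_generated(vg).sequences == frozenset(
            {mg.decode_haplotype(ref, profile.calls)}
        )


class TestExport:
    def test_json_roundtrip(self, fig2_graph):
        assert mg.VariantGraph.from_json(fig2_graph.to_json()) == fig2_graph

    def test_json_roundtrip_with_indels(self, homopolymer_ref):
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("4.1T 5 del 6 del", homopolymer_ref)
        )
        assert mg.VariantGraph.from_json(vg.to_json()) == vg

    def test_dot_export_mentions_nodes(self, fig2_graph):
        dot = fig2_graph.to_dot()
        assert dot.startswith("digraph") and "b:3:T" in dot
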