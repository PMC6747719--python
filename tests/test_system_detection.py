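import networkx as nx
import pytest
from hypothesis import given, strategies as st

from ubiqscan.io_formats import (
    GeneFeature,
    GenomeAnnotation,
    SequenceRecord,
    SystemModel,
    ValidationError,
)
from ubiqscan.system_detection import (
    ArchitectureCall,
    adjacency_fraction,
    call_genome,
    classify_architecture,
    cooccurrence_summary,
    detect_loci,
    reseed_colocalized_profile,
    summarize_by_taxon,
)


def genome_with_members(member_ranks, m=30, genome_id="g", circular=False):
    """A single-replicon genome; member_ranks maps rank -> family tuple."""
    feats = [
        GeneFeature(genome_id, "chr", r, "+", f"{genome_id}p{r}") for r in range(m)
    ]
    annotation = GenomeAnnotation(
        genome_id, {"chr": feats}, {"chr": circular}
    )
    assignments = {
        f"{genome_id}p{r}": fams for r, fams in member_ranks.items()
    }
    return annotation, assignments


@pytest.fixture
def model():
    return SystemModel(
        "ubiTUV",
        mandatory=frozenset({"ubiT", "ubiU", "ubiV"}),
        accessory=frozenset({"U32"}),
        inter_gene_max_space=5,
    )


class TestDetectLoci:
    def test_gapped_members_form_one_locus(self, model):
        g, a = genome_with_members({10: ("ubiT",), 13: ("ubiU",), 17: ("ubiV",)})
        loci = detect_loci(a, g, model)
        assert len(loci) == 1
        assert loci[0].gap_signature == (2, 3)

    def test_boundary_gap_exactly_max_space_is_same_locus(self, model):
        g, a = genome_with_members({10: ("ubiU",), 16: ("ubiV",)})
        assert len(detect_loci(a, g, model)) == 1
        g, a = genome_with_members({10: ("ubiU",), 17: ("ubiV",)})
        assert len(detect_loci(a, g, model)) == 2

    def test_single_member_is_a_singleton_locus(self, model):
        g, a = genome_with_members({5: ("ubiT",)})
        loci = detect_loci(a, g, model)
        assert len(loci) == 1
        assert loci[0].span == (5, 5)

    def test_unknown_protein_id_errors(self, model):
        g, _ = genome_with_members({5: ("ubiT",)})
        with pytest.raises(ValidationError, match="ghost"):
            detect_loci({"ghost": ("ubiT",)}, g, model)

    def test_circular_wraparound_merges_terminal_loci(self, model):
        g, a = genome_with_members(
            {0: ("ubiU",), 28: ("ubiT",)}, m=30, circular=True
        )
        assert len(detect_loci(a, g, model)) == 1  # wrap gap = 1
        g, a = genome_with_members({0: ("ubiU",), 28: ("ubiT",)}, m=40, circular=True)
        assert len(detect_loci(a, g, model)) == 2  # wrap gap = 11

    def test_rank_offset_invariance(self, model):
        g1, a1 = genome_with_members({3: ("ubiT",), 5: ("ubiU",), 9: ("ubiV",)})
        g2, a2 = genome_with_members({13: ("ubiT",), 15: ("ubiU",), 19: ("ubiV",)})
        l1 = detect_loci(a1, g1, model)
        l2 = detect_loci(a2, g2, model)
        assert [l.gap_signature for l in l1] == [l.gap_signature for l in l2]

    @given(
        members=st.sets(st.integers(0, 11), min_size=1, max_size=6),
        max_space=st.integers(0, 11),
    )
    def test_partition_matches_graph_components(self, members, max_space):
        """Brute force: connected components of the 'within max_space' graph
        over member genes (<=12-gene replicon) equal the greedy partition."""
        model = SystemModel(
            "m", mandatory=frozenset({"fam"}), inter_gene_max_space=max_space
        )
        ranks = sorted(members)
        g, a = genome_with_members({r: ("fam",) for r in ranks}, m=12)
        loci = detect_loci(a, g, model)
        graph = nx.Graph()
        graph.add_nodes_from(ranks)
        for x in ranks:
            for y in ranks:
                if x < y and y - x - 1 <= max_space:
                    graph.add_edge(x, y)
        expected = sorted(
            tuple(sorted(c)) for c in nx.connected_components(graph)
        )
        got = sorted(tuple(m.rank for m in l.members) for l in loci)
        assert got == expected

    @given(
        members=st.sets(st.integers(0, 29), min_size=1, max_size=6),
        spaces=st.tuples(st.integers(0, 10), st.integers(0, 10)),
    )
    def test_raising_max_space_only_coarsens(self, members, spaces):
        lo, hi = sorted(spaces)
        g, a = genome_with_members({r: ("ubiU",) for r in members})
        m_lo = SystemModel("m", mandatory=frozenset({"ubiU"}), inter_gene_max_space=lo)
        m_hi = SystemModel("m", mandatory=frozenset({"ubiU"}), inter_gene_max_space=hi)
        fine = [set(m.rank for m in l.members) for l in detect_loci(a, g, m_lo)]
        coarse = [set(m.rank for m in l.members) for l in detect_loci(a, g, m_hi)]
        assert len(coarse) <= len(fine)
        for f in fine:  # every fine locus is contained in one coarse locus
            assert any(f <= c for c in coarse)


class TestClassification:
    def test_contiguous_three_gene_locus(self, model):
        g, a = genome_with_members({4: ("ubiT",), 5: ("ubiU",), 6: ("ubiV",)})
        call = call_genome(a, g, model)
        assert call.arch_class == "three_gene_locus"
        assert call.ubiU_ubiV_adjacent
        assert call.gap_signature == ((0, 0),)

    def test_two_gene_locus_with_distal_third(self, model):
        feats1 = [GeneFeature("g", "chr1", r, "+", f"p{r}") for r in range(10)]
        feats2 = [GeneFeature("g", "chr2", r, "+", f"q{r}") for r in range(10)]
        genome = GenomeAnnotation("g", {"chr1": feats1, "chr2": feats2})
        a = {"p3": ("ubiU",), "p4": ("ubiV",), "q5": ("ubiT",)}
        call = call_genome(a, genome, model)
        assert call.arch_class == "two_gene_locus"
        assert call.ubiU_ubiV_adjacent

    def test_fusion_protein_counts_as_adjacency(self, model):
        g, a = genome_with_members({9: ("ubiT", "ubiU"), 10: ("ubiV",)})
        call = call_genome(a, g, model)
        assert call.arch_class == "three_gene_locus"
        assert call.ubiU_ubiV_adjacent

    def test_dispersed_and_incomplete(self, model):
        g, a = genome_with_members({0: ("ubiT",), 14: ("ubiU",), 28: ("ubiV",)})
        assert call_genome(a, g, model).arch_class == "dispersed"
        g, a = genome_with_members({0: ("ubiT",), 14: ("ubiU",)})
        assert call_genome(a, g, model).arch_class == "incomplete"

    def test_exchangeable_profiles_collapse_to_one_component(self):
        model = SystemModel(
            "m",
            mandatory=frozenset({"yhbT1", "ubiU", "ubiV"}),
            accessory=frozenset({"yhbT2"}),
            exchangeable=(("yhbT1", "yhbT2"),),
            inter_gene_max_space=5,
        )
        g, a = genome_with_members({4: ("yhbT2",), 5: ("ubiU",), 6: ("ubiV",)})
        call = call_genome(a, g, model, adjacent_pair=("ubiU", "ubiV"))
        assert call.arch_class == "three_gene_locus"

    def test_accessory_family_never_drives_the_class(self, model):
        # U32 bridges ubiT to the U/V pair but must not merge core loci
        g, a = genome_with_members(
            {0: ("ubiT",), 4: ("U32",), 8: ("U32",), 12: ("ubiU",), 13: ("ubiV",)}
        )
        call = call_genome(a, g, model)
        assert call.arch_class == "two_gene_locus"

    @given(
        ranks=st.lists(
            st.integers(0, 29), min_size=0, max_size=3, unique=True
        ),
        fams=st.permutations(["ubiT", "ubiU", "ubiV"]),
    )
    def test_classes_are_exclusive_and_exhaustive(self, ranks, fams, model):
        member_ranks = {r: (f,) for r, f in zip(sorted(ranks), fams)}
        g, a = genome_with_members(member_ranks)
        call = call_genome(a, g, model)
        assert call.arch_class in (
            "three_gene_locus", "two_gene_locus", "dispersed", "incomplete"
        )
        if len(ranks) < 3:
            assert call.arch_class == "incomplete"


def fake_call(genome_id, arch_class, adjacent=False, families=None):
    if families is None:
        families = (
            frozenset({"ubiT", "ubiU", "ubiV"})
            if arch_class != "incomplete"
            else frozenset({"ubiT"})
        )
    return ArchitectureCall(
        genome_id=genome_id,
        arch_class=arch_class,
        present_families=families,
        loci=(),
        ubiU_ubiV_adjacent=adjacent,
        gap_signature=(),
    )


class TestSummaries:
    def test_headline_percentage_rounds_to_nearest_integer(self):
        calls = [fake_call(f"g{i}", "three_gene_locus") for i in range(210)]
        calls += [fake_call(f"h{i}", "incomplete") for i in range(11)]
        s = cooccurrence_summary(calls)
        assert (s.n_with_any_core, s.n_with_all_core) == (221, 210)
        assert s.pct_all_core_of_any == 95
        assert s.frac_all_core_of_any == pytest.approx(210 / 221)

    def test_empty_panel_reports_na(self):
        s = cooccurrence_summary([])
        assert s.pct_all_core_of_any is None
        assert s.frac_all_core_of_any is None

    def test_duplicate_genome_errors(self):
        calls = [fake_call("g", "dispersed"), fake_call("g", "dispersed")]
        with pytest.raises(ValidationError, match="duplicate"):
            cooccurrence_summary(calls)

    def test_marker_and_hydroxylase_counts(self):
        calls = [fake_call("g1", "three_gene_locus"), fake_call("g2", "three_gene_locus")]
        markers = {
            "g1": {"ubiA", "ubiE", "ubiG", "ubiH"},
            "g2": {"ubiA", "ubiE"},
        }
        s = cooccurrence_summary(calls, markers)
        assert s.n_with_all_markers == 1
        assert s.n_with_two_markers == 2
        assert s.n_all_core_no_hydroxylase == 1  # g2 lacks any hydroxylase

    @given(
        st.lists(
            st.sampled_from(
                ["three_gene_locus", "two_gene_locus", "dispersed", "incomplete"]
            ),
            max_size=30,
        )
    )
    def test_all_three_never_exceeds_at_least_one(self, classes):
        calls = [fake_call(f"g{i}", c) for i, c in enumerate(classes)]
        s = cooccurrence_summary(calls)
        assert s.n_with_all_core <= s.n_with_any_core <= s.n_genomes

    def test_adjacency_fraction_edge_cases(self):
        assert adjacency_fraction([]) is None
        calls = [fake_call(f"g{i}", "three_gene_locus", adjacent=True) for i in range(4)]
        assert adjacency_fraction(calls) == 1.0
        calls = [fake_call(f"g{i}", "dispersed", adjacent=False) for i in range(4)]
        assert adjacency_fraction(calls) == 0.0

    def test_adjacency_denominator_excludes_incomplete_genomes(self):
        calls = [
            fake_call("g1", "three_gene_locus", adjacent=True),
            fake_call("g2", "two_gene_locus", adjacent=False),
            fake_call("g3", "incomplete"),
        ]
        assert adjacency_fraction(calls) == pytest.approx(0.5)

    def test_per_order_table(self):
        calls = (
            [fake_call(f"a{i}", "three_gene_locus") for i in range(3)]
            + [fake_call("a3", "incomplete")]
            + [fake_call("b0", "dispersed"), fake_call("b1", "incomplete")]
        )
        orders = {c.genome_id: ("OrdA" if c.genome_id[0] == "a" else "OrdB") for c in calls}
        df = summarize_by_taxon(calls, orders)
        assert list(df["taxon_order"]) == ["OrdA", "OrdB"]
        assert list(df["n_genomes"]) == [4, 2]
        assert list(df["frac_all_three"]) == pytest.approx([0.75, 0.5])
        assert df["frac_single_locus"].iloc[0] == pytest.approx(1.0)

    def test_unlabeled_genome_errors(self):
        calls = [fake_call("g1", "dispersed")]
        with pytest.raises(ValidationError, match="g1"):
            summarize_by_taxon(calls, {})


class TestReseed:
    def _setup(self, model):
        g1, a1 = genome_with_members(
            {4: ("ubiT",), 5: ("ubiU",), 6: ("ubiV",)}, genome_id="g1"
        )
        g2, a2 = genome_with_members({4: ("ubiT",)}, genome_id="g2")
        g3, a3 = genome_with_members(
            {8: ("ubiT",), 9: ("ubiU",), 10: ("ubiV",)}, genome_id="g3"
        )
        calls = [
            call_genome(a, g, model)
            for g, a in [(g1, a1), (g2, a2), (g3, a3)]
        ]
        proteome = {
            pid: SequenceRecord(pid, "ACDEFGHIK")
            for a in (a1, a2, a3)
            for pid in a
        }
        return calls, proteome

    def test_colocalized_target_sequences_returned_in_order(self, model):
        calls, proteome = self._setup(model)
        seeds = reseed_colocalized_profile(
            calls, proteome, {"ubiU", "ubiV"}, "ubiT"
        )
        assert [s.id for s in seeds] == ["g1p4", "g3p8"]

    def test_target_without_anchors_excluded(self, model):
        calls, proteome = self._setup(model)
        seeds = reseed_colocalized_profile(
            calls, proteome, {"ubiU", "ubiV"}, "ubiT"
        )
        assert "g2p4" not in [s.id for s in seeds]

    def test_no_colocalization_returns_empty(self, model):
        g, a = genome_with_members({4: ("ubiT",)})
        calls = [call_genome(a, g, model)]
        proteome = {pid: SequenceRecord(pid, "ACD") for pid in a}
        assert reseed_colocalized_profile(calls, proteome, {"ubiU", "ubiV"}, "ubiT") == []
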