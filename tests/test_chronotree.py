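"""Parsing, validation, clade resolution and annotated output of dated trees."""

import numpy as np
import pytest

from hgtclock.chronotree import (
    Chronogram,
    CladeDefinition,
    clade_age_trace,
    parse_trace,
    resolve_node,
    validate_ultrametric,
    write_annotated_tree,
)
from hgtclock.errors import (
    AnnotationMismatchError,
    EmptyTraceError,
    LeafSetMismatchError,
    NoStemNodeError,
    NotMonophyleticError,
    TraceParseError,
    UltrametricityError,
    UnknownTaxonError,
)
from hgtclock.simulate import JitterSpec, simulate_posterior_trace, yule_topology


class TestParseTrace:
    def test_single_tree_path_sum_ages(self):
        trace = parse_trace("((A:1.0,B:1.0):1.0,C:2.0);")
        assert len(trace) == 1
        sample = trace.samples[0]
        assert sample.mrca({"A", "B"}).age == pytest.approx(1.0)
        assert sample.root_age == pytest.approx(2.0)

    def test_empty_stream_rejected(self):
        with pytest.raises(EmptyTraceError):
            parse_trace("\n\n")

    def test_header_line_tolerated(self):
        trace = parse_trace("250\n((A:1,B:1):1,C:2);\n((A:1,B:1):1,C:2);\n")
        assert len(trace) == 2

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(TraceParseError, match="line 2"):
            parse_trace("((A:1,B:1):1,C:2);\n((A:1,B:1:1,C:2);\n")

    def test_leaf_set_mismatch_across_lines(self):
        with pytest.raises(LeafSetMismatchError):
            parse_trace("((A:1,B:1):1,C:2);\n((A:1,D:1):1,C:2);\n")

    def test_simulator_round_trip_preserves_ages(self, truth_chronogram):
        """Serialize 5 simulator trees to datedist text, reparse, compare ages."""
        trace, ledger = simulate_posterior_trace(
            JitterSpec(truth=truth_chronogram, sd=40.0, n_samples=5, seed=9)
        )
        reparsed = parse_trace(trace.as_datedist())
        assert len(reparsed) == 5
        checks = {
            "anc_Alphaproteobacteria_1_15": truth_chronogram.leaf_labels,
            "anc_GSB_1_2": frozenset({"GSB_1", "GSB_2"}),
            "anc_Cyanobacteria_1_5": frozenset(
                {"Melainabacteria_1", "Melainabacteria_2", "Cyanobacteria_Gloeobacter",
                 "Cyanobacteria_1", "Cyanobacteria_2"}
            ),
        }
        for key, leaves in checks.items():
            extracted = clade_age_trace(reparsed, CladeDefinition(key, leaves, "crown"))
            np.testing.assert_allclose(extracted.ages, ledger[key].values, rtol=1e-9)

    def test_parent_strictly_older_invariant(self, jitter_run):
        trace, _ = jitter_run
        for sample in trace.samples[:25]:
            for node in sample.tree.preorder_node_iter():
                for child in node.child_nodes():
                    assert node.age > child.age

    def test_tie_ages_rejected(self):
        with pytest.raises(TraceParseError, match="strictly exceed"):
            parse_trace("((A:1.0,B:1.0):0.0,C:1.0);")


class TestUltrametricity:
    def test_unequal_depths_flag_deviant_leaf(self):
        chrono = Chronogram.from_newick("((A:1,B:2):1,C:2);", ultrametricity="defer")
        violations = validate_ultrametric(chrono)
        assert [v.leaf for v in violations] == ["B"]
        assert violations[0].observed_depth == pytest.approx(3.0)

    def test_simulator_output_is_clean(self, jitter_run):
        trace, _ = jitter_run
        assert all(not validate_ultrametric(s) for s in trace.samples[:20])

    def test_single_perturbed_terminal_branch_flagged(self, truth_chronogram):
        tol = 1e-6
        nwk = truth_chronogram.as_newick()
        # stretch exactly one terminal branch by 10x the relative tolerance
        target = "GSB_1:1750.0"
        assert target in nwk
        perturbed = nwk.replace(target, f"GSB_1:{1750 + 10 * tol * 3900}")
        chrono = Chronogram.from_newick(perturbed, ultrametricity="defer")
        violations = validate_ultrametric(chrono, rel_tol=tol)
        assert [v.leaf for v in violations] == ["GSB_1"]

    def test_reject_vs_repair_modes(self):
        bad = "((A:1,B:1.3):1,C:2);"
        with pytest.raises(UltrametricityError):
            Chronogram.from_newick(bad)
        repaired = Chronogram.from_newick(bad, ultrametricity="repair")
        # cherry age = mean of its two leaf path sums
        assert repaired.mrca({"A", "B"}).age == pytest.approx(1.15)


class TestResolveNode:
    def test_crown_of_all_leaves_is_root(self, truth_chronogram):
        clade = CladeDefinition("all", truth_chronogram.leaf_labels, "crown")
        assert resolve_node(truth_chronogram, clade) is truth_chronogram.root

    def test_stem_of_all_leaves_has_no_node(self, truth_chronogram):
        clade = CladeDefinition("all", truth_chronogram.leaf_labels, "stem")
        with pytest.raises(NoStemNodeError):
            resolve_node(truth_chronogram, clade)

    @pytest.mark.parametrize("seed", range(8))
    def test_crown_mrca_matches_root_path_intersection(self, seed):
        """Brute-force oracle: MRCA = deepest node on every leaf's root path."""
        topo = yule_topology(8, seed=seed)
        for leaf in topo.leaf_node_iter():
            leaf.edge.length = 1.0
        for node in topo.postorder_internal_node_iter():
            node.edge.length = 1.0
        # make ultrametric: set each edge so that all leaves sit at depth d
        depth = {}
        for node in topo.preorder_node_iter():
            depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
        max_depth = max(depth[id(lf)] for lf in topo.leaf_node_iter())
        for lf in topo.leaf_node_iter():
            lf.edge.length = float(max_depth - depth[id(lf)] + 1)
        chrono = Chronogram(topo)
        rng = np.random.default_rng(seed)
        labels = sorted(chrono.leaf_labels)
        chosen = frozenset(rng.choice(labels, size=3, replace=False))
        mrca = chrono.mrca(chosen)

        def root_path(label):
            node = next(
                lf for lf in chrono.tree.leaf_node_iter() if lf.taxon.label == label
            )
            path = []
            while node is not None:
                path.append(id(node))
                node = node.parent_node
            return path

        paths = [root_path(l) for l in chosen]
        common = set(paths[0]).intersection(*map(set, paths[1:]))
        deepest = next(pid for pid in paths[0] if pid in common)
        assert id(mrca) == deepest

    def test_non_monophyletic_strict_vs_fallback(self):
        chrono = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clade = CladeDefinition("AC", frozenset({"A", "C"}), "crown")
        with pytest.raises(NotMonophyleticError):
            resolve_node(chrono, clade)
        node = resolve_node(chrono, clade, strict=False)
        assert node is chrono.root

    def test_crown_younger_than_stem_everywhere(self, jitter_run, clade_defs):
        trace, _ = jitter_run
        by_key = {(c.name, c.selector): c for c in clade_defs}
        crown = clade_age_trace(trace, by_key[("GNS", "crown")])
        stem = clade_age_trace(trace, by_key[("GNS", "stem")])
        assert np.all(crown.ages < stem.ages)


class TestCladeAgeTrace:
    def test_root_clade_yields_per_sample_root_ages(self, jitter_run, truth_chronogram):
        trace, _ = jitter_run
        clade = CladeDefinition("all", truth_chronogram.leaf_labels, "crown")
        ages = clade_age_trace(trace, clade)
        expected = np.array([s.root_age for s in trace])
        np.testing.assert_array_equal(ages.ages, expected)

    def test_ages_match_generator_ledger_exactly(self, jitter_run, clade_defs):
        trace, ledger = jitter_run
        by_key = {(c.name, c.selector): c for c in clade_defs}
        crown_gsb = clade_age_trace(trace, by_key[("GSB", "crown")])
        np.testing.assert_allclose(
            crown_gsb.ages, ledger["anc_GSB_1_2"].values, rtol=1e-9
        )

    def test_unknown_label_error_names_the_label(self, jitter_run):
        trace, _ = jitter_run
        clade = CladeDefinition("bogus", frozenset({"GSB_1", "Nessie"}), "crown")
        with pytest.raises(UnknownTaxonError, match="Nessie"):
            clade_age_trace(trace, clade)


class TestAnnotatedOutput:
    @pytest.fixture
    def topology(self):
        return Chronogram.from_newick("((A:1,B:1):1,C:2);")

    @pytest.fixture
    def clades(self):
        return [
            CladeDefinition("all", frozenset("ABC"), "crown"),
            CladeDefinition("cherry", frozenset("AB"), "crown"),
        ]

    def test_newick_path_sums_reproduce_medians(self, topology, clades):
        rows = {"all": (2.0, None, None), "cherry": (1.0, None, None)}
        text = write_annotated_tree(topology, rows, clades, dialect="newick")
        reparsed = parse_trace(text).samples[0]
        assert reparsed.root_age == pytest.approx(2.0, abs=1e-9)
        assert reparsed.mrca({"A", "B"}).age == pytest.approx(1.0, abs=1e-9)

    def test_nexus_one_annotation_per_internal_node(self, topology, clades):
        rows = {"all": (2.0, 1.5, 2.5), "cherry": (1.0, 0.8, 1.2)}
        text = write_annotated_tree(topology, rows, clades, dialect="nexus")
        assert text.startswith("#NEXUS")
        assert text.count("[&median=") == 2
        assert "hpd={0.8,1.2}" in text

    def test_round_trip_preserves_summary_ages(self, truth_chronogram, clade_defs):
        internal_ages = {
            "Root": 3900.0,
            "CyanobacteriaMelainabacteria": 2800.0,
            "Cyanobacteria": 2400.0,
            "CyanobacteriaNoGloeobacter": 2000.0,
            "GNS": 1900.0,
            "GSB": 1750.0,
            "Chloroflexi": 3200.0,
        }
        # remaining internal nodes of the 15-leaf tree need rows too
        extra = {
            "CMS": (frozenset({"Sericytochromatia_1", "Melainabacteria_1",
                               "Melainabacteria_2", "Cyanobacteria_Gloeobacter",
                               "Cyanobacteria_1", "Cyanobacteria_2"}), 3000.0),
            "Melainabacteria": (frozenset({"Melainabacteria_1", "Melainabacteria_2"}), 2000.0),
            "Terrabacteria": (frozenset({"Sericytochromatia_1", "Melainabacteria_1",
                                         "Melainabacteria_2", "Cyanobacteria_Gloeobacter",
                                         "Cyanobacteria_1", "Cyanobacteria_2",
                                         "Chloroflexi_1", "Chloroflexi_2", "GNS_1", "GNS_2"}), 3500.0),
            "GNSline": (frozenset({"Chloroflexi_2", "GNS_1", "GNS_2"}), 2600.0),
            "AlphaFCB": (frozenset({"Alphaproteobacteria_1", "Bacteroidetes_1",
                                    "Ignavibacteria_1", "GSB_1", "GSB_2"}), 3600.0),
            "FCB": (frozenset({"Bacteroidetes_1", "Ignavibacteria_1", "GSB_1", "GSB_2"}), 3300.0),
            "IgGSB": (frozenset({"Ignavibacteria_1", "GSB_1", "GSB_2"}), 3000.0),
        }
        clades = [c for c in clade_defs if c.selector == "crown"]
        clades += [CladeDefinition(n, lv, "crown") for n, (lv, _) in extra.items()]
        rows = {n: (a, None, None) for n, a in internal_ages.items()}
        rows |= {n: (a, None, None) for n, (_, a) in extra.items()}
        text = write_annotated_tree(truth_chronogram, rows, clades)
        reparsed = parse_trace(text).samples[0]
        for name, age in internal_ages.items():
            clade = next(c for c in clades if c.name == name)
            assert resolve_node(reparsed, clade).age == pytest.approx(age, abs=1e-9)

    def test_missing_row_raises(self, topology, clades):
        with pytest.raises(AnnotationMismatchError):
            write_annotated_tree(topology, {"all": (2.0, None, None)}, clades)
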