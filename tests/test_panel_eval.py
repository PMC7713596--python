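"""Resolvability scoring, set-cover panel selection and decision trees."""

import itertools

import numpy as np
import pytest

from hrmbarcode import (
    BarcodeRecord,
    CandidateAmplicon,
    PrimerPair,
    ResolutionThresholds,
    SpeciesSet,
    build_decision_tree,
    exhaustive_panel,
    greedy_panel,
    helicity_curve,
    resolvability_matrix,
    species_profiles,
    tree_from_reference_tms,
)
from hrmbarcode.errors import DesignError, InputError
from hrmbarcode.panel_eval import (
    DecisionTree,
    Panel,
    PairResolution,
    ResolvabilityMatrix,
    SpeciesProfile,
)

MERGED_82 = frozenset({"Chrysomya_megacephala", "Chrysomya_albiceps"})
MERGED_124 = frozenset({"Lucilia_cuprina", "Lucilia_eximia"})


def fake_matrix(name, resolved_pairs, all_species):
    """Matrix stub from an explicit resolved-pair set (for cover tests)."""
    entries = {}
    for pair in itertools.combinations(sorted(all_species), 2):
        key = frozenset(pair)
        ok = key in resolved_pairs
        entries[key] = PairResolution(
            resolvable=ok, min_delta_tm=1.0 if ok else 0.0, min_curve_distance=0.0
        )
    return ResolvabilityMatrix(amplicon=name, entries=entries)


class Stub:
    """Minimal amplicon-like object for cover tests."""

    def __init__(self, name):
        self.name = name
        self.contained_variants = []
        self.interval = (0, 0)

    def max_product_size(self):
        return 0


class TestSpeciesProfiles:
    def test_six_profiles_with_haplotype_counts(self, table1_candidates, thermo):
        prof = species_profiles(table1_candidates[0], thermo)
        assert len(prof) == 6
        for pr in prof:
            assert len(pr.curves) == len(
                table1_candidates[0].per_species_haplotypes[pr.species]
            )
            assert len(pr.tm_set) == len(pr.curves)

    def test_identical_haplotypes_give_identical_curves(self, blowfly_profiles):
        by_species = {p.species: p for p in blowfly_profiles["HRM_82"]}
        a = by_species["Chrysomya_megacephala"].curves[0]
        b = by_species["Chrysomya_albiceps"].curves[0]
        assert np.array_equal(a.helicity, b.helicity)

    def test_single_ct_difference_shifts_tm(self, thermo):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 82))
        i = base.index("C", 40)
        mutated = base[:i] + "T" + base[i + 1 :]
        assert helicity_curve(mutated, thermo).tm != helicity_curve(base, thermo).tm


class TestResolvabilityMatrix:
    def test_identical_haplotypes_unresolvable(self, thermo):
        rng = np.random.default_rng(9)
        hap = "".join(rng.choice(list("ACGT"), 82))
        prof = [
            SpeciesProfile("A", "amp", [helicity_curve(hap, thermo)], [helicity_curve(hap, thermo).tm]),
            SpeciesProfile("B", "amp", [helicity_curve(hap, thermo)], [helicity_curve(hap, thermo).tm]),
        ]
        m = resolvability_matrix(prof)
        entry = m.entries[frozenset({"A", "B"})]
        assert not entry.resolvable
        assert entry.min_delta_tm == 0.0

    def test_blowfly_merge_pattern(self, blowfly_entries):
        by_name = {m.amplicon: m for _, m in blowfly_entries}
        unresolved_82 = {p for p, e in by_name["HRM_82"].entries.items() if not e.resolvable}
        unresolved_124 = {p for p, e in by_name["HRM_124"].entries.items() if not e.resolvable}
        assert unresolved_82 == {MERGED_82}
        assert unresolved_124 == {MERGED_124}

    def test_worst_case_over_haplotype_pairings(self, thermo):
        rng = np.random.default_rng(10)
        hap = "".join(rng.choice(list("ACGT"), 82))
        i = hap.index("A", 40)
        shifted = hap[:i] + "G" + hap[i + 1 :]
        # species B carries both the shared haplotype and a shifted one:
        # worst case pairing is identical -> unresolvable
        c_same = helicity_curve(hap, thermo)
        c_shift = helicity_curve(shifted, thermo)
        prof = [
            SpeciesProfile("A", "amp", [c_same], [c_same.tm]),
            SpeciesProfile("B", "amp", [c_same, c_shift], [c_same.tm, c_shift.tm]),
        ]
        m = resolvability_matrix(prof)
        assert not m.entries[frozenset({"A", "B"})].resolvable
        assert m.entries[frozenset({"A", "B"})].min_delta_tm == 0.0

    def test_class1_separates_better_than_class4(self, thermo):
        # matched fixtures: same context, C->T (class 1) vs A->T (class 4)
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), 82))
        ci = base.index("C", 40)
        ai = base.index("A", 40)

        def delta(i, alt):
            a = helicity_curve(base, thermo)
            b = helicity_curve(base[:i] + alt + base[i + 1 :], thermo)
            return abs(a.tm - b.tm)

        assert delta(ci, "T") > delta(ai, "T")

    def test_worst_snp_class_reported(self, blowfly_entries):
        by_name = {m.amplicon: m for _, m in blowfly_entries}
        # all planted substitutions in the reference model are A/G = class 1
        for m in by_name.values():
            for e in m.entries.values():
                if e.worst_snp_class is not None:
                    assert e.worst_snp_class.value == "class1_CT_GA"

    def test_needs_two_profiles(self, thermo):
        c = helicity_curve("ACGTACGTACGTACGT", thermo)
        with pytest.raises(DesignError):
            resolvability_matrix([SpeciesProfile("A", "amp", [c], [c.tm])])


class TestPanels:
    def test_single_fully_resolving_candidate(self):
        species = ["a", "b", "c"]
        all_pairs = {frozenset(p) for p in itertools.combinations(species, 2)}
        m = fake_matrix("X", all_pairs, species)
        panel = greedy_panel([(Stub("X"), m)])
        assert panel.names() == ["X"]
        assert panel.uncovered_pairs == frozenset()

    def test_blowfly_two_amplicon_cover(self, blowfly_panel):
        assert blowfly_panel.names() == ["HRM_82", "HRM_124"]
        assert len(blowfly_panel.covered_pairs) == 15
        assert blowfly_panel.uncovered_pairs == frozenset()

    def test_exhaustive_identity_on_single_candidate(self):
        species = ["a", "b"]
        m = fake_matrix("X", {frozenset({"a", "b"})}, species)
        panel = exhaustive_panel([(Stub("X"), m)])
        assert panel.names() == ["X"] and not panel.uncovered_pairs

    def test_exhaustive_matches_hand_enumeration(self):
        # X covers {ab}, Y covers {ac}, Z covers {ab, ac, bc}: optimum is [Z]
        species = ["a", "b", "c"]
        ab, ac, bc = (frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c")))
        entries = [
            (Stub("X"), fake_matrix("X", {ab}, species)),
            (Stub("Y"), fake_matrix("Y", {ac}, species)),
            (Stub("Z"), fake_matrix("Z", {ab, ac, bc}, species)),
        ]
        panel = exhaustive_panel(entries)
        assert panel.names() == ["Z"]

    def test_exhaustive_empty_coverage(self):
        species = ["a", "b"]
        m = fake_matrix("X", set(), species)
        panel = exhaustive_panel([(Stub("X"), m)])
        assert panel.covered_pairs == frozenset()
        assert panel.uncovered_pairs == {frozenset({"a", "b"})}

    def test_exhaustive_refuses_large_instances(self):
        species = ["a", "b"]
        entries = [
            (Stub(f"c{i}"), fake_matrix(f"c{i}", set(), species)) for i in range(13)
        ]
        with pytest.raises(InputError):
            exhaustive_panel(entries)

    def test_greedy_coverage_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_sp = int(rng.integers(2, 9))
            n_cand = int(rng.integers(1, 7))
            species = [f"s{i}" for i in range(n_sp)]
            pairs = [frozenset(p) for p in itertools.combinations(species, 2)]
            entries = []
            for ci in range(n_cand):
                resolved = {p for p in pairs if rng.random() < 0.4}
                entries.append((Stub(f"c{ci}"), fake_matrix(f"c{ci}", resolved, species)))
            g = greedy_panel(entries)
            e = exhaustive_panel(entries)
            assert len(g.covered_pairs) == len(e.covered_pairs)
            if not e.uncovered_pairs:
                assert len(g.amplicons) <= len(e.amplicons) + 1

    def test_greedy_coverage_monotone(self):
        rng = np.random.default_rng(13)
        species = [f"s{i}" for i in range(6)]
        pairs = [frozenset(p) for p in itertools.combinations(species, 2)]
        entries = [
            (
                Stub(f"c{ci}"),
                fake_matrix(f"c{ci}", {p for p in pairs if rng.random() < 0.3}, species),
            )
            for ci in range(5)
        ]
        panel = greedy_panel(entries)
        covered = set()
        sizes = []
        by_name = dict((s.name, m) for s, m in entries)
        for amp in panel.amplicons:
            covered |= by_name[amp.name].resolved_pairs()
            sizes.append(len(covered))
        assert sizes == sorted(sizes)
        assert len(covered) == len(panel.covered_pairs)


class TestDecisionTree:
    def test_blowfly_tree_structure(self, blowfly_tree):
        assert blowfly_tree.amplicon_order() == ["HRM_82", "HRM_124"]
        node1, node2 = blowfly_tree.nodes
        groups1 = {frozenset(g) for g in node1.partition}
        assert MERGED_82 in groups1
        assert sum(len(g) == 1 for g in node1.partition) == 4
        assert {frozenset(g) for g in node2.partition} == {
            frozenset({"Chrysomya_megacephala"}),
            frozenset({"Chrysomya_albiceps"}),
        }
        assert len(blowfly_tree.leaves) == 6
        assert all(leaf.resolved for leaf in blowfly_tree.leaves)
        assert blowfly_tree.all_species() == {
            sp for g in node1.partition for sp in g
        }

    def test_single_fully_resolving_amplicon_depth_one(self):
        tms = {"amp": {"a": 78.0, "b": 80.0, "c": 82.0}}
        tree = tree_from_reference_tms(["amp"], tms)
        assert len(tree.nodes) == 1
        assert all(leaf.resolved for leaf in tree.leaves)
        assert len(tree.leaves) == 3

    def test_all_identical_species_single_unresolved_leaf(self):
        tms = {"amp": {"a": 80.0, "b": 80.0, "c": 80.0}}
        tree = tree_from_reference_tms(["amp"], tms)
        (leaf,) = tree.leaves
        assert not leaf.resolved
        assert sorted(leaf.species) == ["a", "b", "c"]

    def test_leaves_partition_species(self, blowfly_tree, blowfly_set):
        leaf_species = [sp for leaf in blowfly_tree.leaves for sp in leaf.species]
        assert sorted(leaf_species) == sorted(blowfly_set.species())

    def test_single_linkage_chaining(self):
        # 0.2-spaced chain below the 0.3 threshold merges transitively
        tms = {"amp": {"a": 80.0, "b": 80.2, "c": 80.4, "d": 82.0}}
        tree = tree_from_reference_tms(["amp"], tms)
        groups = {frozenset(g) for g in tree.nodes[0].partition}
        assert frozenset({"a", "b", "c"}) in groups
        assert frozenset({"d"}) in groups

    def test_json_round_trip(self, blowfly_tree):
        back = DecisionTree.from_json(blowfly_tree.to_json())
        assert back.amplicon_order() == blowfly_tree.amplicon_order()
        assert [l.species for l in back.leaves] == [l.species for l in blowfly_tree.leaves]

    def test_dot_export_mentions_all_species(self, blowfly_tree):
        dot = blowfly_tree.to_dot()
        for sp in blowfly_tree.all_species():
            assert sp in dot
        assert dot.startswith("digraph")

    def test_empty_panel_rejected(self, blowfly_profiles):
        empty = Panel(amplicons=[], covered_pairs=frozenset(), uncovered_pairs=frozenset())
        with pytest.raises(DesignError):
            build_decision_tree(empty, blowfly_profiles)
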