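"""Distance trees, parsimony, congruence and orthology."""

import dendropy
import numpy as np
import pytest

from gluscreen.fixtures import load_probes
from gluscreen.orthology import reciprocal_best_hits, retrieval_ratio
from gluscreen.phylo import (
    DistanceMatrix,
    fitch_min_changes,
    minimum_transfers,
    monophyly,
    neighbor_joining,
    p_distance,
    region_tree_congruence,
    robinson_foulds,
    tree_from_rows,
)
from gluscreen.records import ProteinRecord
from gluscreen.synthetic import (
    generate_species_scenario,
    mutate,
    simulate_region_alignments,
)
from oracles import monophyly_brute, parsimony_brute


def additive_matrix_from_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return tree, DistanceMatrix(tuple(labels), m)


class TestPDistance:
    def test_identical_rows_all_zero(self):
        dm = p_distance([("a", "NSEY"), ("b", "NSEY"), ("c", "NSEY")])
        assert np.all(dm.matrix == 0)

    def test_two_of_ten_ungapped_mismatches(self):
        dm = p_distance([
            ("a", "AAAAAAAAAA"),
            ("b", "AACCAAAAAA"),
        ])
        assert dm.matrix[0, 1] == pytest.approx(0.2)

    def test_gap_columns_excluded_pairwise(self):
        dm = p_distance([
            ("a", "AA-AA"),
            ("b", "AACCA"),
        ])
        # 4 comparable columns, 1 mismatch
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACDE-")
        rows = [
            (f"r{i}", "".join(rng.choice(alphabet, size=30)))
            for i in range(5)
        ]
        dm = p_distance(rows)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = rows[i][1], rows[j][1]
                pairs = [
                    (x, y) for x, y in zip(a, b) if x != "-" and y != "-"
                ]
                expected = sum(x != y for x, y in pairs) / len(pairs)
                assert dm.matrix[i, j] == pytest.approx(expected)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError):
            p_distance([("a", "A-"), ("b", "-A")])


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree(self):
        newick = "((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);"
        truth, dm = additive_matrix_from_tree(newick)
        nj = neighbor_joining(dm)
        assert robinson_foulds(nj, truth) == 0

    def test_branch_lengths_recovered_on_additive_input(self):
        newick = "((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);"
        truth, dm = additive_matrix_from_tree(newick)
        nj = neighbor_joining(dm)
        # additive matrices are reproduced exactly: patristic distances match
        pdm = nj.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in nj.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                got = pdm.distance(taxa[a], taxa[b])
                assert got == pytest.approx(
                    dm.matrix[dm.labels.index(a), dm.labels.index(b)],
                    abs=1e-9,
                )

    def test_three_taxa_resolve_to_star(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = neighbor_joining(dm)
        assert len(tree.seed_node.child_nodes()) == 3

    def test_label_order_does_not_change_topology(self):
        newick = "((A:0.1,B:0.2):0.15,((C:0.3,D:0.1):0.1,E:0.2):0.05);"
        _, dm = additive_matrix_from_tree(newick)
        perm = [3, 1, 4, 0, 2]
        labels = tuple(dm.labels[i] for i in perm)
        matrix = dm.matrix[np.ix_(perm, perm)]
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(DistanceMatrix(labels, matrix))
        assert robinson_foulds(t1, t2) == 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(
                ("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]])
            )

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(("A", "B"), np.zeros((2, 2)))
            )

    def test_exact_recovery_over_random_trees(self):
        hits = 0
        for seed in range(25):
            newick, _ = generate_species_scenario(
                3 + seed % 3, 3 + (seed + 1) % 3, 0, rng_seed=seed
            )
            truth, dm = additive_matrix_from_tree(newick)
            hits += robinson_foulds(neighbor_joining(dm), truth) == 0
        assert hits == 25


class TestMonophylyAndParsimony:
    def test_clade_state_is_monophyletic(self):
        newick, groups = generate_species_scenario(4, 4, 0, rng_seed=1)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert monophyly(tree, groups, "group1")

    def test_scattered_state_is_not(self):
        newick, groups = generate_species_scenario(5, 5, 2, rng_seed=2)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert not monophyly(tree, groups, "group1")

    def test_monophyly_matches_exhaustive_bipartitions(self):
        for seed in range(8):
            newick, groups = generate_species_scenario(
                4, 4, seed % 3, rng_seed=seed
            )
            tree = dendropy.Tree.get(data=newick, schema="newick")
            for state in ("group1", "group2"):
                assert monophyly(tree, groups, state) == monophyly_brute(
                    tree, groups, state
                )

    def test_unmapped_leaf_rejected(self):
        newick, groups = generate_species_scenario(3, 3, 0, rng_seed=0)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        del groups["A01"]
        with pytest.raises(ValueError):
            monophyly(tree, groups, "group1")

    def test_two_monophyletic_states_cost_one_change(self):
        newick, groups = generate_species_scenario(4, 4, 0, rng_seed=3)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert fitch_min_changes(tree, groups) == 1

    def test_single_state_costs_nothing(self):
        newick, groups = generate_species_scenario(3, 3, 0, rng_seed=0)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert fitch_min_changes(tree, {k: "x" for k in groups}) == 0

    def test_matches_exhaustive_assignment_oracle(self):
        for seed in range(6):
            newick, groups = generate_species_scenario(
                5, 5, seed % 4, rng_seed=seed
            )
            tree = dendropy.Tree.get(data=newick, schema="newick")
            assert fitch_min_changes(tree, groups) == parsimony_brute(
                tree, groups
            )

    def test_invariant_to_rerooting(self):
        newick, groups = generate_species_scenario(4, 4, 2, rng_seed=5)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        reference = fitch_min_changes(tree, groups)
        for edge in list(tree.preorder_edge_iter()):
            if edge.tail_node is None or edge.length is None:
                continue
            rerooted = dendropy.Tree.get(
                data=tree.as_string(schema="newick"), schema="newick"
            )
            target = rerooted.find_node_with_taxon_label(
                next(iter(groups))
            )
            rerooted.reroot_at_edge(target.edge)
            assert fitch_min_changes(rerooted, groups) == reference
            break

    def test_planted_transfers_recovered(self):
        for k in (0, 1, 2, 3):
            newick, groups = generate_species_scenario(6, 6, k, rng_seed=13)
            tree = dendropy.Tree.get(data=newick, schema="newick")
            assert minimum_transfers(tree, groups) == k


class TestCongruence:
    def test_shared_topology_gives_zero_rf_everywhere(self):
        newick, _ = generate_species_scenario(4, 4, 0, rng_seed=6)
        alns = simulate_region_alignments(
            newick, {"S1": 57, "S2": 69, "channel": 50}, rng_seed=6
        )
        rf = region_tree_congruence(alns)
        assert set(rf.values()) == {0}

    def test_discordant_region_detected(self):
        newick_a, _ = generate_species_scenario(4, 4, 0, rng_seed=7)
        newick_b, _ = generate_species_scenario(4, 4, 0, rng_seed=77)
        alns = simulate_region_alignments(
            newick_a, {"S1": 57, "S2": 69}, rng_seed=7
        )
        other = simulate_region_alignments(
            newick_b, {"channel": 60}, rng_seed=78
        )
        alns["channel"] = other["channel"]
        rf = region_tree_congruence(alns)
        assert rf[("S1", "S2")] == 0
        assert rf[("S1", "channel")] > 0

    def test_rf_of_tree_with_itself_is_zero(self):
        newick, _ = generate_species_scenario(4, 4, 0, rng_seed=8)
        alns = simulate_region_alignments(newick, {"S1": 57}, rng_seed=8)
        tree = tree_from_rows(alns["S1"])
        assert robinson_foulds(tree, tree) == 0

    def test_taxa_mismatch_rejected(self):
        alns = {
            "S1": [("a", "AAA"), ("b", "AAC"), ("c", "ACC")],
            "S2": [("a", "AAA"), ("b", "AAC"), ("d", "ACC")],
        }
        with pytest.raises(ValueError):
            region_tree_congruence(alns)


class TestOrthology:
    def make_proteomes(self, seed=0, rate=0.1, n=4):
        probes = load_probes()
        rng = np.random.default_rng(seed)
        base = [probes.s1_sequence, probes.s2_sequence]
        a = [
            ProteinRecord(f"a{i}", mutate(base[i % 2], 0.25, rng))
            for i in range(n)
        ]
        b = [
            ProteinRecord(f"b{i}", mutate(a[i].sequence, rate, rng))
            for i in range(n)
        ]
        return a, b

    def test_identical_proteomes_pair_identically(self):
        a, _ = self.make_proteomes()
        b = [ProteinRecord(f"b{i}", rec.sequence) for i, rec in enumerate(a)]
        report = reciprocal_best_hits(a, b)
        assert report.pair_ids == {(f"a{i}", f"b{i}") for i in range(len(a))}

    def test_planted_pairs_recovered(self):
        a, b = self.make_proteomes(seed=3)
        report = reciprocal_best_hits(a, b)
        assert report.pair_ids == {(f"a{i}", f"b{i}") for i in range(len(a))}

    def test_symmetric_under_argument_swap(self):
        a, b = self.make_proteomes(seed=4)
        forward = reciprocal_best_hits(a, b)
        backward = reciprocal_best_hits(b, a)
        assert {(y, x) for x, y in forward.pair_ids} == backward.pair_ids

    def test_query_without_hit_excluded(self):
        a, b = self.make_proteomes(seed=5, n=2)
        a.append(ProteinRecord("orphan", "W" * 60))
        from gluscreen.align import ScoringParams

        report = reciprocal_best_hits(
            a, b, ScoringParams(evalue_threshold=1e-6)
        )
        assert all(x != "orphan" for x, _ in report.pair_ids)

    def test_empty_proteome_rejected(self):
        a, _ = self.make_proteomes()
        with pytest.raises(ValueError):
            reciprocal_best_hits(a, [])


class TestRetrievalRatio:
    def test_denominator_is_reference_size(self, study_tables):
        probes = load_probes()
        rng = np.random.default_rng(0)
        reference = [
            ProteinRecord(f"h{i}", mutate(probes.s2_sequence, 0.3, rng))
            for i in range(len(study_tables.human_iglur_table))
        ]
        hits, total = retrieval_ratio(
            ProteinRecord("probe", probes.s2_sequence), reference
        )
        assert total == 26
        assert 0 <= hits <= total

    def test_random_probe_strict_threshold_retrieves_nothing(self):
        from gluscreen.align import ScoringParams
        from gluscreen.synthetic import SyntheticSpec, generate_protein

        rng = np.random.default_rng(2)
        probe, _ = generate_protein(SyntheticSpec(), "random", rng, "probe")
        reference = [
            generate_protein(SyntheticSpec(), "random", rng, f"r{i}")[0]
            for i in range(10)
        ]
        hits, _ = retrieval_ratio(
            probe, reference, ScoringParams(evalue_threshold=1e-6)
        )
        assert hits == 0

    def test_identical_member_always_retrieved(self):
        probes = load_probes()
        rng = np.random.default_rng(1)
        from gluscreen.align import ScoringParams
        from gluscreen.synthetic import SyntheticSpec, generate_protein

        reference = [
            generate_protein(SyntheticSpec(), "random", rng, f"r{i}")[0]
            for i in range(5)
        ] + [ProteinRecord("self", probes.s1_sequence)]
        hits, total = retrieval_ratio(
            ProteinRecord("probe", probes.s1_sequence),
            reference,
            ScoringParams(evalue_threshold=1e-10),
        )
        assert hits >= 1
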