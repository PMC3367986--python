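import pytest

from orthoflora.clade import (
    NewickParseError,
    classify_og,
    classify_target_gene,
    parse_newick,
    patristic_distance,
    smallest_informative_clade,
)
from orthoflora.og_assignment import OrthologueGroup
from orthoflora.simulate import SimulationConfig, generate_gene_tree, stream_rng

from tests.oracles import (
    brute_classify,
    brute_informative_clade_leaves,
    brute_patristic,
)


def random_tree_text(rng, n_leaves, integer_lengths=True):
    """Random binary Newick over mixed-species leaves."""
    labels = []
    for i in range(n_leaves):
        prefix = "AT1G" if rng.random() < 0.4 else "Glyma01g"
        labels.append(f"{prefix}{i:04d}")
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la = rng.integers(1, 9) if integer_lengths else rng.uniform(0.1, 2)
        lb = rng.integers(1, 9) if integer_lengths else rng.uniform(0.1, 2)
        nodes.append(f"({a}:{la},{b}:{lb})")
    return nodes[0] + ";", labels


class TestParseNewick:
    def test_two_leaf_tree(self):
        tree = parse_newick("(AT1G1:1,Glyma01g1:2);")
        assert sorted(tree.leaf_names) == ["AT1G1", "Glyma01g1"]
        assert patristic_distance(tree, "AT1G1", "Glyma01g1") == pytest.approx(3.0)

    def test_support_labels_retained(self):
        tree = parse_newick("((AT1G1:1,AT1G2:1)950:1,Glyma01g1:2);")
        assert 950.0 in tree.support_labels().values()

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1;")

    def test_missing_terminator_rejected(self):
        with pytest.raises(NewickParseError, match="';'"):
            parse_newick("(A:1,B:1)")

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("(AT1G1:1,AT1G1:2);")

    def test_missing_branch_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            tree = parse_newick("(AT1G1,Glyma01g1);")
        assert patristic_distance(tree, "AT1G1", "Glyma01g1") == 0.0

    def test_species_inference(self):
        tree = parse_newick("(AT1G1:1,(Glyma01g1:1,Bradi1g1:1):1);")
        assert tree.species("AT1G1") == "reference"
        assert tree.species("Glyma01g1") == "target"
        assert tree.species("Bradi1g1") == "other:brachypodium"


class TestPatristicDistance:
    def test_self_distance_zero(self):
        tree = parse_newick("((AT1G1:1,Glyma01g1:2):3,Glyma01g2:4);")
        assert patristic_distance(tree, "Glyma01g1", "Glyma01g1") == 0.0

    def test_unknown_leaf_rejected(self):
        tree = parse_newick("(AT1G1:1,Glyma01g1:2);")
        with pytest.raises(KeyError):
            patristic_distance(tree, "AT1G1", "nope")

    def test_matches_brute_force_path_walk(self, rng):
        """All-pairs agreement with an explicit root-path oracle."""
        for _ in range(200):
            text, labels = random_tree_text(rng, int(rng.integers(3, 9)))
            tree = parse_newick(text)
            for a in labels:
                for b in labels:
                    assert patristic_distance(tree, a, b) == pytest.approx(
                        brute_patristic(tree, a, b), abs=1e-9
                    )

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(30):
            text, labels = random_tree_text(rng, 6, integer_lengths=False)
            tree = parse_newick(text)
            d = {
                (a, b): patristic_distance(tree, a, b)
                for a in labels
                for b in labels
            }
            for a in labels:
                for b in labels:
                    assert d[a, b] == pytest.approx(d[b, a])
                    for c in labels:
                        assert d[a, c] <= d[a, b] + d[b, c] + 1e-9


class TestSmallestInformativeClade:
    def test_cherry_is_smallest(self):
        tree = parse_newick("((Glyma01g1:1,AT1G1:1):1,AT1G2:5);")
        clade = smallest_informative_clade(tree, "Glyma01g1")
        names = {lf.taxon.label for lf in clade.leaf_iter()}
        assert names == {"Glyma01g1", "AT1G1"}

    def test_falls_back_to_root(self):
        tree = parse_newick("((Glyma01g1:1,Glyma01g2:1):1,AT1G1:1);")
        clade = smallest_informative_clade(tree, "Glyma01g1")
        assert len(list(clade.leaf_iter())) == 3

    def test_no_reference_leaf_is_error(self):
        tree = parse_newick("(Glyma01g1:1,Glyma01g2:1);")
        with pytest.raises(ValueError, match="reference"):
            smallest_informative_clade(tree, "Glyma01g1")

    def test_matches_exhaustive_clade_enumeration(self, rng):
        for _ in range(40):
            text, labels = random_tree_text(rng, 8)
            tree = parse_newick(text)
            targets = [l for l in labels if l.startswith("Glyma")]
            refs = [l for l in labels if l.startswith("AT")]
            if not refs:
                continue
            for leaf in targets:
                clade = smallest_informative_clade(tree, leaf)
                names = {lf.taxon.label for lf in clade.leaf_iter()}
                assert names == brute_informative_clade_leaves(tree, leaf)


class TestClassifyTargetGene:
    def test_strictly_closer_flowering_gene(self):
        tree = parse_newick("((Glyma01g1:1,AT1G1:1):1,AT1G2:5);")
        a = classify_target_gene(tree, "Glyma01g1", {"AT1G1"})
        assert a.status == "flowering_orthologue"
        assert a.min_distance_flowering == pytest.approx(2.0)
        assert a.min_distance_other == pytest.approx(7.0)

    def test_equally_close_other_gene_excludes(self):
        tree = parse_newick("((Glyma01g1:1,AT1G1:1):0,AT1G2:1);")
        a = classify_target_gene(tree, "Glyma01g1", {"AT1G1"}, tolerance=0.0)
        assert a.min_distance_flowering == pytest.approx(2.0)
        assert a.min_distance_other == pytest.approx(2.0)
        assert a.status == "other_orthologue"

    def test_non_target_leaf_rejected(self):
        tree = parse_newick("(AT1G1:1,Glyma01g1:1);")
        with pytest.raises(ValueError, match="target"):
            classify_target_gene(tree, "AT1G1", set())

    def test_matches_distance_matrix_oracle(self, rng):
        """200 simulated trees against the independent full-matrix rule."""
        config = SimulationConfig(seed=5, branch_noise_sd=0.05)
        trng = stream_rng(5, "trees")
        checked = 0
        for i in range(200):
            n_ref = int(trng.integers(1, 4))
            n_tgt = int(trng.integers(1, 5))
            refs = [f"AT1G{i:03d}{j:02d}" for j in range(n_ref)]
            tgts = [f"Glyma01g{i:03d}{j:02d}" for j in range(n_tgt)]
            newick, _ = generate_gene_tree(refs, tgts, config, trng)
            tree = parse_newick(newick)
            flowering = set(refs[: max(1, n_ref // 2)])
            for t in tgts:
                a = classify_target_gene(tree, t, flowering)
                assert a.status == brute_classify(tree, t, flowering)
                checked += 1
        assert checked > 200

    def test_invariant_under_leaf_order_permutation(self):
        before = parse_newick("((Glyma01g1:1,AT1G1:1):1,(AT1G2:2,Glyma01g2:3):1);")
        after = parse_newick("((Glyma01g2:3,AT1G2:2):1,(AT1G1:1,Glyma01g1:1):1);")
        for leaf in ("Glyma01g1", "Glyma01g2"):
            a = classify_target_gene(before, leaf, {"AT1G1"}, tolerance=0.0)
            b = classify_target_gene(after, leaf, {"AT1G1"}, tolerance=0.0)
            assert a.status == b.status
            assert a.min_distance_flowering == pytest.approx(
                b.min_distance_flowering
            )

    def test_planted_orthologue_recovery_at_low_noise(self):
        """>=95% of planted labels recovered with small branch noise.

        The flowering set is a whole co-orthologous reference group (the
        tie group of one target leaf), so the planted label is
        unambiguous: targets whose true anchors all lie in the group are
        flowering orthologues, targets with disjoint anchors are not.
        Targets whose anchor group straddles the flowering set are
        ambiguous by construction and excluded from the tally.
        """
        config = SimulationConfig(seed=9, branch_noise_sd=0.03)
        trng = stream_rng(9, "trees")
        hits = total = 0
        for i in range(120):
            n_ref = int(trng.integers(2, 4))
            n_tgt = int(trng.integers(2, 5))
            refs = [f"AT1G{i:03d}{j:02d}" for j in range(n_ref)]
            tgts = [f"Glyma01g{i:03d}{j:02d}" for j in range(n_tgt)]
            newick, truth = generate_gene_tree(refs, tgts, config, trng)
            tree = parse_newick(newick)
            flowering = set(truth[tgts[0]])
            for t in tgts:
                anchors = set(truth[t])
                if anchors <= flowering:
                    expected = "flowering_orthologue"
                elif not anchors & flowering:
                    expected = "other_orthologue"
                else:
                    continue
                got = classify_target_gene(tree, t, flowering).status
                hits += got == expected
                total += 1
        assert total > 150
        assert hits / total >= 0.95


class TestClassifyOg:
    def test_small_flowering_og_accepts_all_targets(self):
        og = OrthologueGroup(
            "OG5_s", members={"reference": {"AT1G1"}, "target": {"G1", "G2"}}
        )
        calls = classify_og(og, None, {"AT1G1"})
        assert [c.status for c in calls] == ["flowering_orthologue"] * 2
        assert all(c.via_small_og_rule for c in calls)

    def test_small_og_with_other_reference_unresolved(self):
        og = OrthologueGroup(
            "OG5_s", members={"reference": {"AT1G1", "AT1G2"}, "target": {"G1"}}
        )
        calls = classify_og(og, None, {"AT1G1"})
        assert [c.status for c in calls] == ["unresolved"]

    def test_large_og_delegates_to_per_leaf_rule(self):
        text = "((Glyma01g1:1,AT1G1:1):1,(AT1G2:1,Glyma01g2:1):1);"
        tree = parse_newick(text)
        og = OrthologueGroup(
            "OG5_l",
            members={
                "reference": {"AT1G1", "AT1G2"},
                "target": {"Glyma01g1", "Glyma01g2"},
            },
        )
        calls = {c.target_gene: c for c in classify_og(og, tree, {"AT1G1"})}
        expected = {
            g: classify_target_gene(tree, g, {"AT1G1"})
            for g in ("Glyma01g1", "Glyma01g2")
        }
        assert {g: c.status for g, c in calls.items()} == {
            g: c.status for g, c in expected.items()
        }

    def test_large_og_without_tree_is_error(self):
        og = OrthologueGroup(
            "OG5_l",
            members={"reference": {"AT1G1"}, "target": {"G1", "G2", "G3"}},
        )
        with pytest.raises(ValueError, match="no tree"):
            classify_og(og, None, {"AT1G1"})
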