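import numpy as np
import pytest
from scipy.stats import chisquare

from probdist import (
    NewickError,
    felsenstein_farris_pair,
    parse_newick,
    random_spr,
    restrict_to_taxa,
    sample_edge_lengths,
    scale_edges,
    write_newick,
    write_newick_list,
    yule_topology,
)
from probdist import parse_newick_list


def nx_path_lengths(tree):
    """Independent pairwise path-length oracle via networkx shortest paths."""
    import networkx as nx

    g = nx.Graph()
    for node in tree.postorder():
        if node.parent is not None:
            g.add_edge(id(node.parent), id(node), weight=node.edge_length)
    leaves = {n.label: id(n) for n in tree.leaves()}
    out = {}
    for a in leaves:
        for b in leaves:
            if a < b:
                out[(a, b)] = nx.shortest_path_length(
                    g, leaves[a], leaves[b], weight="weight"
                )
    return out


def unrooted_splits(tree):
    """Non-trivial bipartitions of the leaf set, for topology comparison."""
    taxa = tree.taxa
    splits = set()
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = frozenset(_leaves_below(node))
        if 1 < len(below) < len(taxa) - 1:
            splits.add(min(below, frozenset(taxa - below), key=sorted))
    return splits


def _leaves_below(node):
    if node.is_leaf:
        return [node.label]
    out = []
    for c in node.children:
        out.extend(_leaves_below(c))
    return out


class TestParseWrite:
    @pytest.mark.parametrize(
        "text,pair,expected",
        [
            ("(A:0.1,B:0.2);", ("A", "B"), 0.3),
            ("((A:0.1,B:0.2):0.3,C:0.4);", ("A", "C"), 0.8),
        ],
    )
    def test_path_lengths(self, text, pair, expected):
        tree = parse_newick(text)
        assert tree.leaf_path_lengths()[pair] == pytest.approx(expected)

    def test_duplicate_label_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            parse_newick("(A:0.1,A:0.2);")

    def test_negative_length_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("(A:0.1,B:-0.2);")

    def test_malformed_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:0.1,B:0.2;")

    def test_missing_length_strict_vs_lenient(self):
        with pytest.raises(NewickError, match="missing branch length"):
            parse_newick("(A,B:0.2);")
        with pytest.warns(UserWarning):
            tree = parse_newick("(A,B:0.2);", strict=False)
        assert tree.leaf_path_lengths()[("A", "B")] == pytest.approx(0.2)

    def test_internal_labels_and_quotes_ignored_or_kept(self):
        tree = parse_newick("(('A taxon':0.1,B:0.2)90:0.3,C:0.4);")
        assert tree.taxa == {"A taxon", "B", "C"}
        again = parse_newick(write_newick(tree))
        assert again.taxa == tree.taxa

    def test_roundtrip_small(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        again = parse_newick(write_newick(tree))
        assert again.leaf_path_lengths() == tree.leaf_path_lengths()

    def test_roundtrip_random_100_leaves(self):
        rng = np.random.default_rng(7)
        tree = sample_edge_lengths(yule_topology(100, rng), 0.1, 0.005, rng)
        again = parse_newick(write_newick(tree))
        orig = tree.leaf_path_lengths()
        new = again.leaf_path_lengths()
        assert set(orig) == set(new)
        for key in orig:
            assert new[key] == orig[key]  # full precision

    def test_write_is_deterministic_canonical(self):
        # same unrooted tree written from differently ordered newick inputs
        a = parse_newick("((B:0.2,A:0.1):0.3,C:0.4);")
        b = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        assert write_newick(a) == write_newick(b)


class TestTreeListIO:
    def test_roundtrip_with_provenance_sidecar(self, tmp_path):
        import json

        rng = np.random.default_rng(1)
        trees = [
            sample_edge_lengths(yule_topology(6, rng), 0.1, 0.005, rng)
            for _ in range(3)
        ]
        path = str(tmp_path / "trees.nwk")
        write_newick_list(trees, path, provenance={"seed": 1, "n_taxa": 6})
        back = parse_newick_list(path)
        assert len(back) == 3
        for orig, again in zip(trees, back):
            assert again.leaf_path_lengths() == orig.leaf_path_lengths()
        meta = json.load(open(path + ".meta.json"))
        assert meta["seed"] == 1

    def test_blank_lines_skipped_and_errors_located(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("(A:0.1,B:0.2);\n\n(A:0.1,A:0.2);\n")
        with pytest.raises(NewickError, match="line 3"):
            parse_newick_list(str(path))


class TestRestrict:
    def test_path_preserved_example(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        sub = restrict_to_taxa(tree, {"A", "C"})
        assert sub.taxa == {"A", "C"}
        assert sub.leaf_path_lengths()[("A", "C")] == pytest.approx(0.8)

    def test_full_set_is_identity(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        sub = restrict_to_taxa(tree, tree.taxa)
        assert sub.leaf_path_lengths() == tree.leaf_path_lengths()

    def test_single_taxon(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        sub = restrict_to_taxa(tree, {"B"})
        assert sub.taxa == {"B"}
        assert sub.n_leaves == 1

    def test_errors(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError):
            restrict_to_taxa(tree, {"Z"})
        with pytest.raises(ValueError):
            restrict_to_taxa(tree, set())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_trees_paths_preserved(self, seed):
        rng = np.random.default_rng(seed)
        tree = sample_edge_lengths(yule_topology(12, rng), 0.1, 0.005, rng)
        taxa = sorted(tree.taxa)
        keep = set(np.array(taxa)[rng.choice(12, size=5, replace=False)])
        sub = restrict_to_taxa(tree, keep)
        full = nx_path_lengths(tree)
        reduced = nx_path_lengths(sub)
        for (a, b), d in reduced.items():
            assert d == pytest.approx(full[(a, b)], abs=1e-12)


class TestScale:
    def test_identity_and_linearity(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        assert scale_edges(tree, 1.0).leaf_path_lengths() == tree.leaf_path_lengths()
        doubled = scale_edges(tree, 2.0)
        for key, d in tree.leaf_path_lengths().items():
            assert doubled.leaf_path_lengths()[key] == pytest.approx(2 * d)

    def test_composition(self):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        ab = scale_edges(scale_edges(tree, 2.0), 3.0)
        once = scale_edges(tree, 6.0)
        for key, d in once.leaf_path_lengths().items():
            assert ab.leaf_path_lengths()[key] == pytest.approx(d)

    def test_nonpositive_rejected(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        for s in (0.0, -1.0):
            with pytest.raises(ValueError):
                scale_edges(tree, s)


class TestYule:
    def test_two_leaves_unique(self, rng):
        tree = yule_topology(2, rng)
        assert tree.n_leaves == 2

    def test_three_leaf_topologies_uniform(self):
        # the three labeled rooted topologies are identified by the cherry
        rng = np.random.default_rng(11)
        counts = {"t1t2": 0, "t1t3": 0, "t2t3": 0}
        for _ in range(10_000):
            tree = yule_topology(3, rng)
            for node in tree.postorder():
                if not node.is_leaf and all(c.is_leaf for c in node.children) and node.parent is not None:
                    cherry = "".join(sorted(c.label for c in node.children))
                    counts[cherry] += 1
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_deterministic_under_seed(self):
        a = write_newick(yule_topology(10, np.random.default_rng(3)))
        b = write_newick(yule_topology(10, np.random.default_rng(3)))
        assert a == b

    def test_too_few_leaves(self, rng):
        with pytest.raises(ValueError):
            yule_topology(1, rng)


class TestEdgeLengths:
    def test_moment_matching_and_positivity(self):
        rng = np.random.default_rng(5)
        tree = yule_topology(100, rng)
        draws = []
        for _ in range(60):  # ~ 198 edges per tree -> ~12k draws
            t = sample_edge_lengths(tree, 0.1, 0.005, rng)
            draws.extend(n.edge_length for n in t.edges())
        draws = np.array(draws)
        assert np.all(draws > 0)
        se = np.sqrt(0.005 / draws.size)
        assert abs(draws.mean() - 0.1) < 3 * se

    def test_invalid_params(self, rng):
        tree = yule_topology(4, rng)
        with pytest.raises(ValueError):
            sample_edge_lengths(tree, -0.1, 0.005, rng)
        with pytest.raises(ValueError):
            sample_edge_lengths(tree, 0.1, 0.0, rng)


class TestSPR:
    def test_taxa_conserved_and_binary(self):
        rng = np.random.default_rng(9)
        tree = sample_edge_lengths(yule_topology(8, rng), 0.1, 0.005, rng)
        for _ in range(25):
            out = random_spr(tree, rng)
            assert out.taxa == tree.taxa
            for node in out.postorder():
                assert len(node.children) in (0, 2)
            tree = out

    def test_multiple_topologies_reached(self):
        rng = np.random.default_rng(13)
        tree = sample_edge_lengths(yule_topology(5, rng), 0.1, 0.005, rng)
        seen = set()
        for _ in range(1000):
            out = random_spr(tree, rng)
            seen.add(frozenset(unrooted_splits(out)))
        assert len(seen) > 1

    def test_small_tree_rejected(self, rng):
        tree = parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        with pytest.raises(ValueError):
            random_spr(tree, rng)


class TestFelsensteinFarris:
    def test_structure(self):
        fz, fa = felsenstein_farris_pair(1.0, 0.1)
        for tree in (fz, fa):
            assert tree.taxa == {"A", "B", "C", "D"}
            # rooted binary 4-leaf: 6 edges, i.e. 5 in the unrooted equivalent
            assert len(tree.edges()) == 6
        assert unrooted_splits(fz) != unrooted_splits(fa)

    def test_long_edges_placement(self):
        fz, fa = felsenstein_farris_pair(2.0, 0.1)
        paths_fz = fz.leaf_path_lengths()
        paths_fa = fa.leaf_path_lengths()
        # Felsenstein zone: long pendant edges A and C are non-sister
        assert paths_fz[("A", "B")] == pytest.approx(2.1)
        assert paths_fa[("A", "C")] == pytest.approx(4.0)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            felsenstein_farris_pair(0.0, 0.1)
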