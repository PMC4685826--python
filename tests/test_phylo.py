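import networkx as nx
import numpy as np
import pytest

from marfungi.phylo import (DistanceMatrix, MultipleAlignment,
                            SATURATION_DISTANCE, bipartitions,
                            bootstrap_support, leaf_distances, logdet_distance,
                            logdet_matrix, mask_columns, nj_tree)

from .conftest import mutate_subs, random_seq


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sympy_logdet_oracle(row_i: str, row_j: str, c: float = 0.1) -> float:
    """Independent symbolic evaluation of the LogDet formula."""
    import sympy
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = [[0] * 4 for _ in range(4)]
    for a, b in zip(row_i, row_j):
        if a != "-" and b != "-":
            counts[idx[a]][idx[b]] += 1
    F = sympy.Matrix(4, 4, lambda i, j: sympy.Rational(counts[i][j]) + sympy.Rational(c))
    F = F / sum(F)
    fi = [sum(F[i, j] for j in range(4)) for i in range(4)]
    fj = [sum(F[i, j] for i in range(4)) for j in range(4)]
    d = -sympy.Rational(1, 4) * (
        sympy.log(F.det())
        - sympy.Rational(1, 2) * (sum(sympy.log(x) for x in fi)
                                  + sum(sympy.log(x) for x in fj)))
    return float(d)


def random_additive_instance(rng, n_leaves):
    """A random binary unrooted tree (as a weighted graph) and the additive
    leaf-distance matrix it induces."""
    g = nx.Graph()
    g.add_edge("L0", "L1", weight=float(rng.uniform(0.1, 1.0)))
    internal = 0
    for i in range(2, n_leaves):
        u, v = list(g.edges())[int(rng.integers(0, g.number_of_edges()))]
        w = g[u][v]["weight"]
        t = float(rng.uniform(0.2, 0.8))
        node = f"I{internal}"
        internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, node, weight=w * t)
        g.add_edge(node, v, weight=w * (1 - t))
        g.add_edge(node, f"L{i}", weight=float(rng.uniform(0.1, 1.0)))
    leaves = sorted(n for n in g.nodes if n.startswith("L"))
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    m = np.array([[paths[a][b] for b in leaves] for a in leaves])
    m = (m + m.T) / 2  # exact symmetry despite float path sums
    np.fill_diagonal(m, 0.0)
    return g, leaves, m


def graph_bipartitions(g, leaves):
    ref = min(leaves)
    parts = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        side = frozenset(l for l in leaves if l in comp)
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(side)
    return parts


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

class TestMaskColumns:
    def test_gap_free_unchanged(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGA"])
        assert mask_columns(aln).rows == aln.rows

    def test_majority_gap_column_removed(self):
        aln = MultipleAlignment(
            ["a", "b", "c", "d"],
            ["A-CG", "A-CG", "A-CG", "AACG"])  # col 2 has 3/4 gaps
        masked = mask_columns(aln, max_gap_fraction=0.5)
        assert masked.rows == ["ACG", "ACG", "ACG", "ACG"]

    def test_boundary_is_inclusive(self):
        aln = MultipleAlignment(["a", "b"], ["A-", "AA"])  # 50% gaps kept
        assert mask_columns(aln, 0.5).n_columns == 2

    def test_all_columns_removed_is_error(self):
        aln = MultipleAlignment(["a", "b"], ["-A", "A-"])
        with pytest.raises(ValueError):
            mask_columns(aln, max_gap_fraction=0.0)


# ---------------------------------------------------------------------------
# LogDet
# ---------------------------------------------------------------------------

class TestLogDet:
    def test_identical_balanced_rows_near_zero(self):
        """On identical rows with balanced composition the distance is zero
        up to the pseudocount's O(c/n) bias."""
        row = "ACGT" * 100
        assert logdet_distance(row, row) == pytest.approx(0.0, abs=0.01)

    def test_symmetric(self, rng):
        for _ in range(10):
            a, b = random_seq(rng, 50), random_seq(rng, 50)
            assert logdet_distance(a, b) == pytest.approx(
                logdet_distance(b, a), abs=1e-12)

    def test_eight_nt_transition_matches_symbolic_oracle(self):
        a = "AACCGGTT"
        b = "AGCCGGTT"  # one A->G transition
        assert logdet_distance(a, b) == pytest.approx(
            sympy_logdet_oracle(a, b), abs=1e-9)

    def test_random_pairs_match_symbolic_oracle(self, rng):
        for _ in range(5):
            a = random_seq(rng, 30)
            b = mutate_subs(rng, a, 3)
            assert logdet_distance(a, b) == pytest.approx(
                sympy_logdet_oracle(a, b), rel=1e-9)

    def test_gapped_sites_skipped(self):
        assert logdet_distance("ACGT-ACGT", "ACGTTACGT") == pytest.approx(
            logdet_distance("ACGTACGT", "ACGTACGT"), abs=1e-12)

    def test_no_usable_sites_is_error(self):
        with pytest.raises(ValueError):
            logdet_distance("----", "AAAA")

    def test_monotone_in_substitution_load(self, rng):
        """Average distance grows with the number of substitutions."""
        L = 400
        loads = [0, 4, 12, 30, 60]
        means = []
        for k in loads:
            vals = []
            for _ in range(10):
                a = random_seq(rng, L)
                vals.append(logdet_distance(a, mutate_subs(rng, a, k)))
            means.append(np.mean(vals))
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:])), means

    def test_matrix_agrees_with_pairwise(self, rng):
        rows = [random_seq(rng, 40) for _ in range(5)]
        dm = logdet_matrix(MultipleAlignment(
            [f"t{i}" for i in range(5)], rows))
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else logdet_distance(rows[i], rows[j])
                assert dm.matrix[i, j] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], m)

    def test_recovers_known_six_leaf_topology(self, rng):
        g, leaves, m = random_additive_instance(rng, 6)
        tree = nj_tree(DistanceMatrix(leaves, m))
        assert bipartitions(tree) == graph_bipartitions(g, leaves)

    def test_additive_matrices_recover_topology_and_path_lengths(self, rng):
        """Random 5-8 leaf additive matrices: NJ returns the generating
        topology with exact path lengths."""
        for _ in range(25):
            n = int(rng.integers(5, 9))
            g, leaves, m = random_additive_instance(rng, n)
            tree = nj_tree(DistanceMatrix(leaves, m))
            assert bipartitions(tree) == graph_bipartitions(g, leaves)
            paths = leaf_distances(tree)
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    assert paths[(a, b)] == pytest.approx(
                        m[i, leaves.index(b)], abs=1e-9)

    def test_taxon_order_invariance(self, rng):
        g, leaves, m = random_additive_instance(rng, 7)
        tree = nj_tree(DistanceMatrix(leaves, m))
        perm = list(rng.permutation(len(leaves)))
        tree2 = nj_tree(DistanceMatrix(
            [leaves[i] for i in perm], m[np.ix_(perm, perm)]))
        assert bipartitions(tree) == bipartitions(tree2)

    def test_agrees_with_skbio_on_additive_matrices(self, rng):
        """Independent cross-check against scikit-bio's NJ."""
        import skbio
        for _ in range(5):
            g, leaves, m = random_additive_instance(rng, 7)
            mine = bipartitions(nj_tree(DistanceMatrix(leaves, m)))
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m, ids=leaves))
            ref = min(leaves)
            theirs = set()
            for node in sk_tree.non_tips():
                below = frozenset(t.name for t in node.tips())
                side = frozenset(leaves) - below if ref in below else below
                if 2 <= len(side) <= len(leaves) - 2:
                    theirs.add(side)
            assert mine == theirs

    def test_negative_branch_clamped(self):
        # classic instance driving one NJ branch negative
        m = np.array([
            [0.0, 5.0, 9.0, 9.0, 8.0],
            [5.0, 0.0, 10.0, 10.0, 9.0],
            [9.0, 10.0, 0.0, 8.0, 7.0],
            [9.0, 10.0, 8.0, 0.0, 3.0],
            [8.0, 9.0, 7.0, 3.0, 0.0]])
        tree = nj_tree(DistanceMatrix(list("ABCDE"), m))

        def all_lengths(node):
            out = [node.length]
            for c in node.children:
                out += all_lengths(c)
            return out
        assert min(all_lengths(tree)) >= 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def two_clade_alignment(n_cols=40):
    x = "A" * n_cols
    y = "C" * n_cols
    return MultipleAlignment(
        ["x1", "x2", "x3", "y1", "y2", "y3"], [x, x, x, y, y, y])


class TestBootstrap:
    def test_unanimous_signal_gives_100(self):
        """Two clearly separated 3-leaf clades with zero homoplasy: every
        internal edge has support exactly 100."""
        st = bootstrap_support(two_clade_alignment(), n_reps=50, seed=1)

        def supports(node):
            out = []
            for c in node.children:
                if not c.is_leaf:
                    out += [c.support] + supports(c)
            return out
        sup = supports(st.tree)
        assert sup and all(s == 100.0 for s in sup)

    def test_deterministic_for_seed(self, rng):
        rows = [random_seq(rng, 60)]
        rows += [mutate_subs(rng, rows[0], k) for k in (2, 4, 8, 12)]
        aln = MultipleAlignment([f"t{i}" for i in range(5)], rows)
        t1 = bootstrap_support(aln, n_reps=30, seed=99).to_newick()
        t2 = bootstrap_support(aln, n_reps=30, seed=99).to_newick()
        assert t1 == t2

    def test_supports_bounded_and_internal_only(self, rng):
        rows = [random_seq(rng, 60)]
        rows += [mutate_subs(rng, rows[0], k) for k in (2, 4, 8, 12, 20)]
        aln = MultipleAlignment([f"t{i}" for i in range(6)], rows)
        st = bootstrap_support(aln, n_reps=20, seed=3)

        def walk(node, depth=0):
            for c in node.children:
                if c.is_leaf:
                    assert c.support is None
                else:
                    assert c.support is None or 0.0 <= c.support <= 100.0
                walk(c, depth + 1)
        walk(st.tree)

    def test_invalid_args(self):
        aln = two_clade_alignment()
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0, seed=1)

    def test_newick_has_support_labels(self):
        st = bootstrap_support(two_clade_alignment(), n_reps=10, seed=1)
        assert st.to_newick().count("100") >= 1
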