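import numpy as np
import pytest

from mirest.phylo import (MultipleAlignment, TreeNode, align_matures,
                          neighbor_joining, p_distance_matrix,
                          position_frequency_matrix)


def random_additive_tree(rng, n_taxa):
    """A random unrooted binary tree with positive lengths, plus its
    leaf-to-leaf path-distance matrix (independent oracle for NJ)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = TreeNode()
        new.children = [(nodes[i], float(rng.uniform(0.05, 1.0))),
                        (nodes[j], float(rng.uniform(0.05, 1.0)))]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    root = TreeNode()
    root.children = [(x, float(rng.uniform(0.05, 1.0))) for x in nodes]

    # undirected adjacency, then leaf-to-leaf path lengths by DFS
    adj = {}
    leaf_of = {}

    def build(node):
        adj.setdefault(id(node), [])
        if not node.children:
            leaf_of[node.name] = id(node)
        for c, bl in node.children:
            adj[id(node)].append((id(c), bl))
            adj.setdefault(id(c), []).append((id(node), bl))
            build(c)

    build(root)
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(taxa):
        dist = {leaf_of[a]: 0.0}
        stack = [leaf_of[a]]
        while stack:
            u = stack.pop()
            for v, bl in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + bl
                    stack.append(v)
        for j, b in enumerate(taxa):
            if j > i:
                D[i, j] = D[j, i] = dist[leaf_of[b]]
    return taxa, root, D


class TestAlignment:
    def test_identical_sequences_gap_free(self):
        msa = align_matures({"a": "GGAUCCAAGGUUCCGGAAUCC",
                             "b": "GGAUCCAAGGUUCCGGAAUCC"})
        assert msa.rows[0] == msa.rows[1] and "-" not in msa.rows[0]

    def test_internal_deletion_gives_one_gap_column(self):
        s = "GGAUCCAAGGUUCCGGAAUCC"
        msa = align_matures({"full": s, "del": s[:10] + s[11:]})
        assert msa.length == len(s)
        assert msa.rows[msa.taxa.index("del")].count("-") == 1

    def test_substitutions_only_gap_free(self):
        s = "GGAUCCAAGGUUCCGGAAUCC"
        variants = {"a": s, "b": s[:5] + "A" + s[6:], "c": s[:8] + "U" + s[9:],
                    "d": s}
        msa = align_matures(variants)
        assert msa.length == 21 and all("-" not in r for r in msa.rows)

    def test_ungapping_recovers_inputs(self):
        seqs = {"a": "GGAUCCAAGGUUCCGGAAUCC", "b": "GGAUCAAGGUUCCGGAAUCCA",
                "c": "GGAUCCAAGGUCCGGAAUC"}
        msa = align_matures(seqs)
        for i, t in enumerate(msa.taxa):
            assert msa.ungapped(i) == seqs[t]

    def test_single_sequence_identity(self):
        msa = align_matures({"only": "GGAUCCAAGGUUCCGGAAUCC"})
        assert msa.rows == ["GGAUCCAAGGUUCCGGAAUCC"]


class TestPFM:
    def test_identical_rows_full_information(self):
        msa = MultipleAlignment(list("abcd"), ["ACGU"] * 4)
        pfm = position_frequency_matrix(msa)
        assert np.allclose(pfm["information"], 2.0)
        assert np.allclose(pfm["freq"].sum(axis=1), 1.0)

    def test_half_split_column_one_bit(self):
        msa = MultipleAlignment(list("abcd"), ["A", "A", "U", "U"])
        pfm = position_frequency_matrix(msa)
        assert pfm["information"][0] == pytest.approx(1.0)

    def test_three_one_column(self):
        msa = MultipleAlignment(list("abcd"), ["A", "A", "A", "C"])
        pfm = position_frequency_matrix(msa)
        h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert pfm["information"][0] == pytest.approx(2 - h, abs=1e-6)

    def test_all_gap_column_flagged(self):
        msa = MultipleAlignment(["a", "b"], ["-A", "-A"])
        pfm = position_frequency_matrix(msa)
        assert pfm["all_gap"][0] and pfm["information"][0] == 0.0


class TestPDistance:
    def test_identical_zero(self):
        msa = MultipleAlignment(["a", "b"], ["ACGU", "ACGU"])
        assert p_distance_matrix(msa)[0, 1] == 0.0

    def test_mismatch_fraction(self):
        a = "GGAUCCAAGGUUCCGGAAUCC"
        b = a[:3] + "C" + a[4:10] + "A" + a[11:17] + "G" + a[18:]
        msa = MultipleAlignment(["a", "b"], [a, b])
        assert p_distance_matrix(msa)[0, 1] == pytest.approx(3 / 21)

    def test_gap_columns_excluded_from_denominator(self):
        msa = MultipleAlignment(["a", "b"], ["AC-GU", "ACAGA"])
        # 4 comparable columns, 1 mismatch
        assert p_distance_matrix(msa)[0, 1] == pytest.approx(1 / 4)

    def test_no_comparable_columns_errors(self):
        msa = MultipleAlignment(["a", "b"], ["A--", "--A"])
        with pytest.raises(ValueError):
            p_distance_matrix(msa)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        assert sorted(tree.leaf_names()) == ["a", "b"]
        assert sum(bl for _, bl in tree.children) == pytest.approx(0.4)

    def test_three_taxa_star_resolution(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        assert len(tree.children) == 3
        assert all(bl == pytest.approx(1.0) for _, bl in tree.children)

    def test_additive_four_taxon_recovery(self, rng):
        taxa, true_tree, D = random_additive_tree(rng, 4)
        est = neighbor_joining(D, taxa)
        assert est.splits() == true_tree.splits()
        want, got = true_tree.edge_lengths(), est.edge_lengths()
        for key, bl in want.items():
            assert got[key] == pytest.approx(bl, abs=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        taxa, _, D = random_additive_tree(rng, 6)
        ours = neighbor_joining(D, taxa).splits()
        sk_tree = skbio_nj(DistanceMatrix(D, ids=taxa))
        leaves = frozenset(taxa)
        theirs = set()
        for node in sk_tree.traverse(include_self=False):
            if not node.is_tip():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(leaves) - 1:
                    theirs.add(min(side, leaves - side, key=sorted))
        assert ours == theirs

    def test_newick_output_parseable(self, rng):
        """The emitted newick string round-trips through an independent
        tree library with the same leaf set."""
        dendropy = pytest.importorskip("dendropy")
        taxa, _, D = random_additive_tree(rng, 5)
        nwk = neighbor_joining(D, taxa).newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(taxa)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1], [2, 0.0]]), ["a", "b"])

    def test_mir398_style_grouping(self):
        """Near-identical cowpea/soybean matures group together against
        the two distant species."""
        vun = "UGUGUUCUCAGGUCGCCCCUG"
        gma = vun[:14] + "A" + vun[15:]                      # 1 difference
        nta = vun[:2] + "AC" + vun[4:9] + "GA" + vun[11:]    # 4 differences
        cme = "ACACAAGAGUCCAGCGGGGAC"                        # unrelated-ish
        msa = align_matures({"vun": vun, "gma": gma, "nta": nta, "cme": cme})
        D = p_distance_matrix(msa)
        tree = neighbor_joining(D, msa.taxa)
        # on 4 taxa the {vun,gma} grouping is the same bipartition as {nta,cme}
        all_taxa = frozenset(msa.taxa)
        want = min(frozenset({"vun", "gma"}),
                   all_taxa - frozenset({"vun", "gma"}), key=sorted)
        assert want in tree.splits()
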