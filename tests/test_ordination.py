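import numpy as np
import pandas as pd
import pytest

import phyloemg as pe
from phyloemg.errors import FormatError, ValidationError


def random_euclidean_distance_matrix(n, dim, seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, dim))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d


def pairwise(coords):
    return np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))


class TestPCO:
    def test_two_taxa_symmetric_coordinates(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        emb = pe.pco(D)
        np.testing.assert_allclose(np.abs(emb.coordinates[:, 0]), 0.5, atol=1e-9)
        assert emb.coordinates[0, 0] == pytest.approx(-emb.coordinates[1, 0], abs=1e-9)

    def test_equilateral_triangle_reconstructs(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = pe.pco(D)
        rec = pairwise(emb.coordinates)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    @pytest.mark.parametrize("n,dim,seed", [(4, 2, 0), (6, 3, 1), (8, 5, 2)])
    def test_euclidean_input_reconstructs_without_correction(self, n, dim, seed):
        D = random_euclidean_distance_matrix(n, dim, seed)
        emb = pe.pco(D, correct=True)
        assert emb.additive_constant == 0.0
        np.testing.assert_allclose(pairwise(emb.coordinates), D, atol=1e-9)

    def test_cailliez_correction_makes_embeddable(self):
        # violates the triangle inequality (d14 > d12 + d24), so non-Euclidean
        D = np.array(
            [
                [0.0, 1.0, 1.0, 2.9],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [2.9, 1.0, 1.0, 0.0],
            ]
        )
        raw = pe.pco(D, correct=False)
        # genuinely non-Euclidean: uncorrected scaling cannot reproduce D
        assert np.max(np.abs(pairwise(raw.coordinates) - D)) > 0.01
        emb = pe.pco(D, correct=True)
        assert emb.additive_constant > 0
        assert emb.eigenvalues.min() >= -1e-8
        Dc = D + emb.additive_constant
        np.fill_diagonal(Dc, 0.0)
        np.testing.assert_allclose(pairwise(emb.coordinates), Dc, atol=1e-6)

    def test_matches_skbio_reference(self):
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix as SkbioDM

        D = random_euclidean_distance_matrix(5, 3, 7)
        emb = pe.pco(D)
        ref = pcoa(SkbioDM(D), number_of_dimensions=4)
        np.testing.assert_allclose(
            np.sort(emb.eigenvalues)[::-1][:4],
            np.sort(ref.eigvals.to_numpy())[::-1][:4],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            pairwise(emb.coordinates), pairwise(ref.samples.to_numpy()), atol=1e-8
        )

    def test_coordinates_centered_and_k_axes(self):
        D = random_euclidean_distance_matrix(6, 3, 3)
        emb = pe.pco(D)
        assert emb.k == 5
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            pe.pco(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValidationError):
            pe.pco(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative
        with pytest.raises(ValidationError):
            pe.pco(np.array([[0.0, np.nan], [np.nan, 0.0]]))  # excluded pair


class TestNewick:
    def test_parse_counts_nodes(self):
        tree = pe.parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert len(tree.internal_labels) == 2

    def test_round_trip_preserves_topology_and_lengths(self):
        text = "((A:1.25,B:1.25):0.75,C:2.0);"
        tree = pe.parse_newick(text)
        back = pe.parse_newick(pe.write_newick(tree))
        assert sorted(back.tip_labels) == sorted(tree.tip_labels)
        a = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in tree.tree.preorder_node_iter()
            if n.edge.length is not None
        }
        b = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in back.tree.preorder_node_iter()
            if n.edge.length is not None
        }
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_missing_semicolon_rejected(self):
        with pytest.raises(FormatError, match="position"):
            pe.parse_newick("((A:1,B:1):1,C:2)")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(FormatError):
            pe.parse_newick("((A:1,B):1,C:2);")

    def test_packaged_tree_loads(self):
        tree = pe.load_reference_tree()
        assert sorted(tree.tip_labels) == ["Alligator", "Sturnus", "Trachemys", "Varanus"]
        assert tree.root_length == 1.0


from oracles import gls_ancestral_oracle, random_tree


class TestBMAncestralStates:
    def test_two_tips_equal_branches_midpoint(self):
        tree = pe.parse_newick("(A:1,B:1);")
        anc = pe.bm_ancestral_states(tree, {"A": 0.0, "B": 1.0})
        assert list(anc.values())[0] == pytest.approx(0.5)

    def test_star_tree_inverse_length_weights(self):
        tree = pe.parse_newick("(A:1,B:1,C:2);")
        anc = pe.bm_ancestral_states(tree, {"A": 0.0, "B": 0.0, "C": 3.0})
        assert list(anc.values())[0] == pytest.approx(0.6)

    def test_constant_tips_constant_ancestors(self):
        tree = pe.parse_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        anc = pe.bm_ancestral_states(tree, {k: 4.2 for k in "ABCD"})
        assert all(v == pytest.approx(4.2) for v in anc.values())

    def test_label_mismatch_rejected(self):
        tree = pe.parse_newick("(A:1,B:1);")
        with pytest.raises(ValidationError):
            pe.bm_ancestral_states(tree, {"A": 0.0, "X": 1.0})

    def test_estimates_convex_and_translation_equivariant(self):
        tree = pe.parse_newick("(((A:1,B:0.5):0.7,C:2):0.4,(D:1,E:1.2):0.8);")
        vals = {"A": -1.0, "B": 2.0, "C": 0.5, "D": 3.0, "E": -2.0}
        anc = pe.bm_ancestral_states(tree, vals)
        lo, hi = min(vals.values()), max(vals.values())
        assert all(lo - 1e-12 <= v <= hi + 1e-12 for v in anc.values())
        tree2 = pe.parse_newick("(((A:1,B:0.5):0.7,C:2):0.4,(D:1,E:1.2):0.8);")
        shifted = pe.bm_ancestral_states(tree2, {k: v + 10.0 for k, v in vals.items()})
        for k in anc:
            assert shifted[k] == pytest.approx(anc[k] + 10.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_gls_oracle_on_random_trees(self, seed):
        tree = random_tree(6, seed)
        rng = np.random.default_rng(seed + 100)
        vals = {l: float(v) for l, v in zip(tree.tip_labels, rng.standard_normal(6))}
        mine = pe.bm_ancestral_states(tree, vals)
        oracle = gls_ancestral_oracle(tree, vals)
        for k in oracle:
            assert mine[k] == pytest.approx(oracle[k], abs=1e-9)


class TestPhyloEMGSpace:
    def embedding(self):
        D = random_euclidean_distance_matrix(4, 3, 11)
        df = pd.DataFrame(
            D, index=["Trachemys", "Alligator", "Sturnus", "Varanus"],
            columns=["Trachemys", "Alligator", "Sturnus", "Varanus"],
        )
        return pe.pco(df)

    def test_four_taxon_structure(self):
        emb = self.embedding()
        tree = pe.load_reference_tree()
        space = pe.phylo_emg_space(emb, tree)
        assert space.nodes["is_tip"].sum() == 4
        assert len(space.nodes) == 4 + len(tree.internal_labels)
        assert len(space.edges) == sum(1 for _ in tree.tree.preorder_node_iter()) - 1
        assert {"PCO1", "PCO2", "PCO3"}.issubset(space.nodes.columns)

    def test_label_mismatch_rejected(self):
        emb = self.embedding()
        tree = pe.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValidationError):
            pe.phylo_emg_space(emb, tree)

    def test_single_axis_embedding(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        emb = pe.pco(D)
        tree = pe.parse_newick("(A:1,B:1);")
        space = pe.phylo_emg_space(emb, tree)
        assert [c for c in space.nodes.columns if c.startswith("PCO")] == ["PCO1"]
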