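"""Residue graph construction: frames, edges, geometric edge features."""

import numpy as np
import pytest

from conftest import random_rigid_transform, transform_protein
from dtbind.fixtures import make_toy_protein, stub_embedder
from dtbind.geometry import canonical_quaternion
from dtbind.protein_featurizer import (build_residue_edges,
                                       build_residue_frames,
                                       build_residue_graph,
                                       compute_edge_features, embed_sequence)
from dtbind.structure_io import (AtomRecord, ProteinStructure, ResidueRecord)


def two_residue_protein(distance: float) -> ProteinStructure:
    def residue(idx, offset):
        base = np.array([offset, 0.0, 0.0])
        return ResidueRecord("A", idx + 1, "", "ALA", atoms=(
            AtomRecord("N", "N", base + [-1.0, 0.5, 0.0]),
            AtomRecord("CA", "C", base),
            AtomRecord("C", "C", base + [0.9, 1.2, 0.0])))
    return ProteinStructure([residue(0, 0.0), residue(1, distance)])


class TestFrames:
    def test_all_frames_orthonormal_right_handed(self, toy_protein):
        frames = build_residue_frames(toy_protein)
        assert len(frames) == toy_protein.n_residues
        for f, r in zip(frames, toy_protein.residues):
            assert f.is_orthonormal()
            np.testing.assert_allclose(f.origin, r.ca)

    def test_missing_backbone_atom_falls_back_to_orthonormal_frame(self):
        protein = make_toy_protein(6, seed=2)
        res = protein.residues[2]
        residues = list(protein.residues)
        residues[2] = ResidueRecord(res.chain_id, res.resnum, res.icode,
                                    res.resname,
                                    atoms=tuple(a for a in res.atoms
                                                if a.name != "N"))
        frames = build_residue_frames(ProteinStructure(residues))
        assert all(f.is_orthonormal() for f in frames)

    def test_frames_co_rotate_with_the_structure(self, toy_protein):
        rng = np.random.default_rng(11)
        rot, shift = random_rigid_transform(rng)
        moved = transform_protein(toy_protein, rot, shift)
        for f0, f1 in zip(build_residue_frames(toy_protein),
                          build_residue_frames(moved)):
            np.testing.assert_allclose(f1.basis, f0.basis @ rot.T, atol=1e-9)


class TestEdges:
    def test_pair_within_cutoff_connected_both_ways(self):
        edges = build_residue_edges(two_residue_protein(10.0))
        assert edges.tolist() == [[0, 1], [1, 0]]

    def test_pair_beyond_cutoff_not_connected(self):
        assert len(build_residue_edges(two_residue_protein(12.5))) == 0

    def test_helix_edges_match_brute_force_scan(self):
        protein = make_toy_protein(30, seed=9)
        edges = {tuple(e) for e in build_residue_edges(protein)}
        ca = protein.ca_coordinates()
        expected = {(i, j) for i in range(30) for j in range(30)
                    if i != j and np.linalg.norm(ca[i] - ca[j]) <= 12.0}
        assert edges == expected

    def test_rows_sorted_lexicographically(self, toy_protein):
        edges = [tuple(e) for e in build_residue_edges(toy_protein)]
        assert edges == sorted(edges)


class TestEdgeFeatures:
    def test_rbf_column_at_unit_distance(self):
        protein = two_residue_protein(1.0)
        frames = build_residue_frames(protein)
        feats = compute_edge_features(frames, protein.ca_coordinates(),
                                      np.array([[0, 1], [1, 0]]), sigma=1.0)
        np.testing.assert_allclose(feats[:, 3], np.exp(-0.5), atol=1e-12)

    def test_colocated_residues_boundary(self):
        protein = two_residue_protein(0.0)
        frames = build_residue_frames(protein)
        feats = compute_edge_features(frames, protein.ca_coordinates(),
                                      np.array([[0, 1]]))
        np.testing.assert_allclose(feats[0, :3], 0.0, atol=1e-12)
        assert feats[0, 3] == 1.0

    def test_rigid_motion_invariance(self, toy_protein):
        edges = build_residue_edges(toy_protein)
        base = compute_edge_features(build_residue_frames(toy_protein),
                                     toy_protein.ca_coordinates(), edges)
        rng = np.random.default_rng(13)
        for _ in range(5):
            rot, shift = random_rigid_transform(rng)
            moved = transform_protein(toy_protein, rot, shift)
            feats = compute_edge_features(build_residue_frames(moved),
                                          moved.ca_coordinates(), edges)
            np.testing.assert_allclose(feats, base, atol=1e-5)

    def test_directional_symmetry(self, toy_protein):
        edges = build_residue_edges(toy_protein)
        feats = compute_edge_features(build_residue_frames(toy_protein),
                                      toy_protein.ca_coordinates(), edges)
        lookup = {tuple(e): f for e, f in zip(map(tuple, edges), feats)}
        for (i, j), f in lookup.items():
            g = lookup[(j, i)]
            assert np.isclose(f[3], g[3], atol=1e-12)  # d_ij = d_ji
            conj = canonical_quaternion(
                np.array([f[4], -f[5], -f[6], -f[7]]))
            np.testing.assert_allclose(g[4:], conj, atol=1e-9)

    def test_quaternion_columns_unit_norm(self, toy_protein):
        edges = build_residue_edges(toy_protein)
        feats = compute_edge_features(build_residue_frames(toy_protein),
                                      toy_protein.ca_coordinates(), edges)
        np.testing.assert_allclose(np.linalg.norm(feats[:, 4:], axis=1), 1.0,
                                   atol=1e-6)


class TestEmbedding:
    def test_stub_embedder_shape_and_determinism(self, embedder):
        e1 = embed_sequence("ACD", embedder)
        e2 = embed_sequence("ACD", embedder)
        assert e1.shape == (3, 1024)
        np.testing.assert_array_equal(e1, e2)

    def test_position_awareness(self, embedder):
        e = embed_sequence("AA", embedder)
        assert not np.allclose(e[0], e[1])

    def test_misaligned_embedder_raises(self):
        class Bad:
            name, dimension, deterministic = "bad", 1024, True

            def __call__(self, seq):
                return np.zeros((len(seq) + 1, 1024))

        with pytest.raises(ValueError):
            embed_sequence("ACD", Bad())
        with pytest.raises(ValueError):
            embed_sequence("", stub_embedder())


def test_build_residue_graph_assembles_consistent_shapes(toy_protein, embedder):
    graph = build_residue_graph(toy_protein, embedder, with_surface=True)
    n = toy_protein.n_residues
    assert graph.node_features.shape == (n, 1024)
    assert graph.surface_features.shape == (n, 10)
    assert graph.edge_features.shape == (len(graph.edges), 8)
    assert len(graph.frames) == n
    # every edge respects the cutoff, symmetric closure
    edge_set = {tuple(e) for e in graph.edges}
    assert all((j, i) in edge_set for i, j in edge_set)
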