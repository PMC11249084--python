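"""Radius graph, RBF expansion and encoder correctness (oracle + symmetries)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import conformcl as c
from conformcl.autodiff import Tensor

from conftest import random_molecule


def dense_encoder_oracle(enc: c.SchNetEncoder, mol: c.Molecule3D) -> np.ndarray:
    """Straight-line, loop-based re-computation of the encoder forward pass."""
    cfg = enc.config
    W = [p.data for p in enc.parameters()]
    ssp = lambda x: np.logaddexp(0.0, x) - np.log(2.0)
    centers, gamma = enc._rbf.centers, enc._rbf.gamma
    v = np.stack([W[0][z] for z in mol.atomic_numbers])
    k = 1
    n = mol.n_atoms
    for _ in range(cfg.n_layers):
        in2fW, in2fb, f1W, f1b, f2W, f2b, u1W, u1b, u2W, u2b = W[k : k + 10]
        k += 10
        x = v @ in2fW + in2fb
        new_v = v.copy()
        for i in range(n):
            agg = np.zeros(cfg.hidden_dim)
            for j in range(n):
                if i == j:
                    continue
                d = np.linalg.norm(mol.positions[i] - mol.positions[j])
                if 0 < d <= cfg.cutoff:
                    e = np.exp(-gamma * (d - centers) ** 2)
                    filt = ssp(e @ f1W + f1b) @ f2W + f2b
                    agg += x[j] * filt
            new_v[i] = v[i] + ssp(agg @ u1W + u1b) @ u2W + u2b
        v = new_v
    r1W, r1b, r2W, r2b = W[k : k + 4]
    return sum(ssp(v[i] @ r1W + r1b) @ r2W + r2b for i in range(n))


class TestRadiusGraph:
    def test_single_pair_within_cutoff(self):
        mol = c.Molecule3D([6, 6], [[0, 0, 0], [1.0, 0, 0]])
        g = c.build_radius_graph(mol, cutoff=10.0)
        assert len(g.src) == 2
        np.testing.assert_allclose(g.distances, [1.0, 1.0])

    def test_pair_beyond_cutoff_excluded(self):
        mol = c.Molecule3D([6, 6], [[0, 0, 0], [11.0, 0, 0]])
        assert len(c.build_radius_graph(mol, cutoff=10.0).src) == 0

    def test_collinear_triplet_matches_brute_force(self):
        mol = c.Molecule3D([6, 6, 6], [[0, 0, 0], [6.0, 0, 0], [12.0, 0, 0]])
        g = c.build_radius_graph(mol, cutoff=10.0)
        assert set(zip(g.src.tolist(), g.dst.tolist())) == {(0, 1), (1, 0), (1, 2), (2, 1)}

    def test_matches_all_pairs_oracle_on_random_clouds(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mol = random_molecule(rng, n_atoms=7)
            g = c.build_radius_graph(mol, cutoff=2.5)
            expected = set()
            for i in range(7):
                for j in range(7):
                    if i != j:
                        d = np.linalg.norm(mol.positions[i] - mol.positions[j])
                        if 0 < d <= 2.5:
                            expected.add((i, j))
            assert set(zip(g.src.tolist(), g.dst.tolist())) == expected

    def test_symmetric_edges(self):
        rng = np.random.default_rng(4)
        mol = random_molecule(rng, n_atoms=8)
        g = c.build_radius_graph(mol, cutoff=3.0)
        edges = set(zip(g.src.tolist(), g.dst.tolist()))
        assert all((j, i) in edges for i, j in edges)


class TestRbf:
    def test_unit_at_center_and_bounded(self):
        cfg = c.RBFConfig.uniform(10, 5.0, gamma=10.0)
        e = c.rbf_expand(cfg.centers[3], cfg)
        assert e[3] == pytest.approx(1.0)
        assert np.all(e > 0) and np.all(e <= 1)

    def test_scalar_value(self):
        cfg = c.RBFConfig(centers=[0.0, 1.0], gamma=10.0)
        e = c.rbf_expand(1.1, cfg)
        assert e[1] == pytest.approx(np.exp(-0.1), rel=1e-6)

    def test_decays_beyond_last_center(self):
        cfg = c.RBFConfig.uniform(5, 3.0)
        vals = [c.rbf_expand(d, cfg).max() for d in (4.0, 6.0, 9.0)]
        assert vals[0] > vals[1] > vals[2]


class TestEncoderSymmetries:
    def test_rigid_motion_invariance(self, tiny_encoder):
        rng = np.random.default_rng(7)
        for k in range(5):
            mol = random_molecule(rng)
            R = Rotation.random(random_state=k).as_matrix()
            moved = c.Molecule3D(mol.atomic_numbers, mol.positions @ R.T + rng.normal(size=3))
            h0, h1 = tiny_encoder.encode(mol), tiny_encoder.encode(moved)
            np.testing.assert_allclose(h1, h0, rtol=1e-5, atol=1e-10)

    def test_permutation_invariance(self, tiny_encoder):
        rng = np.random.default_rng(8)
        mol = random_molecule(rng, n_atoms=6)
        perm = rng.permutation(6)
        permuted = c.Molecule3D(mol.atomic_numbers[perm], mol.positions[perm])
        np.testing.assert_allclose(
            tiny_encoder.encode(permuted), tiny_encoder.encode(mol), rtol=1e-8
        )

    def test_matches_dense_loop_oracle(self, tiny_encoder):
        rng = np.random.default_rng(9)
        for _ in range(5):
            mol = random_molecule(rng, n_atoms=4)
            np.testing.assert_allclose(
                tiny_encoder.encode(mol), dense_encoder_oracle(tiny_encoder, mol),
                rtol=1e-6, atol=1e-9,
            )

    def test_isolated_atom_contributes_like_lone_atom(self, tiny_encoder):
        rng = np.random.default_rng(10)
        mol = random_molecule(rng, n_atoms=4)
        far = np.vstack([mol.positions, [100.0, 100.0, 100.0]])
        with_far = c.Molecule3D(np.append(mol.atomic_numbers, 8), far)
        lone = c.Molecule3D([8], [[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(
            tiny_encoder.encode(with_far),
            tiny_encoder.encode(mol) + tiny_encoder.encode(lone),
            rtol=1e-8,
        )

    def test_batched_readout_equals_single_molecule(self, tiny_encoder):
        rng = np.random.default_rng(11)
        mols = [random_molecule(rng) for _ in range(4)]
        batch = c.MoleculeBatch.from_molecules(mols)
        h_batch = tiny_encoder(batch).h_G.data
        for k, mol in enumerate(mols):
            np.testing.assert_allclose(h_batch[k], tiny_encoder.encode(mol), rtol=1e-8)


class TestEncoderContracts:
    def test_unknown_atomic_number_raises(self, tiny_encoder):
        mol = c.Molecule3D([99], [[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="embedding table"):
            tiny_encoder.encode(mol)

    def test_gradients_flow_to_all_parameters(self, tiny_encoder):
        rng = np.random.default_rng(12)
        batch = c.MoleculeBatch.from_molecules([random_molecule(rng) for _ in range(2)])
        out = tiny_encoder(batch).h_G.sum()
        for p in tiny_encoder.parameters():
            p.grad = None
        out.backward()
        for p in tiny_encoder.parameters():
            assert p.grad is not None and np.all(np.isfinite(p.grad))

    def test_parameter_count_closed_form(self):
        for h, L, k, e in [(16, 2, 8, 12), (32, 3, 10, 32)]:
            cfg = c.EncoderConfig(hidden_dim=h, n_layers=L, n_rbf=k, embed_dim=e, n_elements=30)
            enc = c.SchNetEncoder(cfg)
            formula = 30 * h + L * (4 * h * h + k * h + 5 * h) + h * (h // 2) + h // 2 + (h // 2) * e + e
            assert c.count_parameters(enc) == formula

    def test_embedding_table_size_is_product(self):
        cfg = c.EncoderConfig(hidden_dim=128, n_layers=1, n_rbf=2, embed_dim=2, n_elements=100)
        enc = c.SchNetEncoder(cfg)
        assert enc.embedding.data.size == 12800


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, tmp_path, tiny_encoder):
        path = tmp_path / "enc"
        c.save_checkpoint(path, tiny_encoder, metadata={"note": "test"})
        loaded = c.load_checkpoint(path)
        assert loaded.config == tiny_encoder.config
        for a, b in zip(loaded.parameters(), tiny_encoder.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_tampered_weights_detected(self, tmp_path, tiny_encoder):
        path = tmp_path / "enc"
        c.save_checkpoint(path, tiny_encoder)
        data = dict(np.load(path.with_suffix(".npz")))
        data["p0"] = data["p0"] + 1.0
        np.savez(path.with_suffix(".npz"), **data)
        with pytest.raises(ValueError, match="hash"):
            c.load_checkpoint(path)
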