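import math

import networkx as nx
import numpy as np
import pytest

from skinet import (HexCoord, Spectrum, SpectralDataset, TrainingSchedule,
                    find_bmu, init_map, som_update, standardize_dataset,
                    train_som, generate_dataset, map_summary,
                    quantization_error)
from skinet.errors import DimensionError, SkinetError

from conftest import make_map


def labelled(x, k, K, axis=None):
    lab = np.zeros(K)
    lab[k] = 1.0
    axis = np.arange(len(x), dtype=float) if axis is None else axis
    return Spectrum(np.asarray(x, float), axis, lab)


class TestFindBMU:
    def test_exact_match_wins_with_zero_distance(self):
        som = make_map(3, 3, P=4, K=2, seed=1)
        target = som.W[5].copy()
        coord, dist = find_bmu(som, target)
        assert som.index(coord) == 5
        assert dist == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            som = make_map(3, 3, P=6, K=2, seed=int(rng.integers(1000)))
            x = rng.normal(size=6)
            coord, dist = find_bmu(som, x)
            # independent plain-python scan
            best_i, best_d = None, None
            for i in range(9):
                d = math.sqrt(sum((float(xi) - float(wi)) ** 2
                                  for xi, wi in zip(x, som.W[i])))
                if best_d is None or d < best_d:
                    best_i, best_d = i, d
            assert som.index(coord) == best_i
            assert dist == pytest.approx(best_d)

    def test_tie_broken_row_major(self):
        som = make_map(3, 3, P=3, K=2, seed=0)
        x = np.array([0.5, 0.5, 0.5])
        som.W[7] = x
        som.W[2] = x
        coord, dist = find_bmu(som, x)
        assert som.index(coord) == 2 and dist == 0.0

    def test_dimension_mismatch_rejected(self):
        som = make_map(2, 2, P=3, K=2)
        with pytest.raises(DimensionError):
            find_bmu(som, np.zeros(4))


class TestSOMUpdate:
    def test_full_step_lands_on_input(self):
        # alpha0=1 at t=0 makes the BMU scale factor exactly 1
        som = make_map(1, 1, P=3, K=2, alpha0=1.0, T=10)
        s = labelled([0.3, -0.2, 4.0], 1, K=2)
        som_update(som, s, t=0)
        np.testing.assert_array_equal(som.W[0], s.intensities)
        np.testing.assert_array_equal(som.C[0], s.label)

    def test_zero_step_is_identity(self):
        som = make_map(2, 2, P=3, K=2, alpha0=0.5, T=10)
        W0, C0 = som.W.copy(), som.C.copy()
        som_update(som, labelled([1.0, 2.0, 3.0], 0, K=2), t=10)  # alpha(T)=0
        assert np.array_equal(som.W, W0) and np.array_equal(som.C, C0)

    def test_half_step_is_convex_midpoint(self):
        som = make_map(1, 1, P=2, K=2, alpha0=0.5, T=10)
        som.W[0] = [0.0, 0.0]
        som_update(som, labelled([1.0, 1.0], 0, K=2), t=0)
        np.testing.assert_allclose(som.W[0], [0.5, 0.5])

    def test_every_neuron_moves_toward_input(self):
        som = make_map(3, 3, P=4, K=3, alpha0=0.8, T=10, sigma0=2.0)
        x = np.full(4, 10.0)
        before = np.abs(som.W - x).sum(axis=1)
        som_update(som, labelled(x, 2, K=3), t=0)
        after = np.abs(som.W - x).sum(axis=1)
        assert np.all(after < before)

    def test_unlabelled_sample_rejected(self):
        som = make_map(2, 2, P=3, K=2)
        with pytest.raises(SkinetError):
            som_update(som, Spectrum([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]), t=0)

    def test_class_weights_stay_in_unit_interval(self):
        som = make_map(3, 3, P=3, K=3, alpha0=1.0, T=20, sigma0=2.0)
        rng = np.random.default_rng(3)
        for t in range(20):
            x = rng.normal(size=3)
            som_update(som, labelled(x, int(rng.integers(3)), K=3), t=t)
            assert som.C.min() >= 0.0 and som.C.max() <= 1.0

    def test_weights_stay_in_joint_bounding_box(self):
        som = make_map(3, 3, P=3, K=2, alpha0=1.0, T=30, sigma0=2.0)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3)) * 5
        lo = np.minimum(som.W.min(axis=0), X.min(axis=0))
        hi = np.maximum(som.W.max(axis=0), X.max(axis=0))
        for t in range(30):
            k = int(rng.integers(10))
            som_update(som, labelled(X[k], k % 2, K=2), t=t)
            assert np.all(som.W >= lo - 1e-12) and np.all(som.W <= hi + 1e-12)

    def test_displacement_vanishes_as_schedule_ends(self):
        som = make_map(3, 3, P=4, K=2, alpha0=0.9, T=100, sigma0=2.0)
        x = labelled(np.full(4, 3.0), 0, K=2)
        disp = []
        for t in (0, 50, 99):
            W0 = som.W.copy()
            som_update(som, x, t=t)
            disp.append(np.linalg.norm(som.W - W0))
        assert disp[0] > disp[1] > disp[2]


class TestTrainSOM:
    def test_single_sample_converges_to_input(self):
        P, K = 5, 2
        x = np.array([1.0, -2.0, 0.5, 3.0, -0.5])
        ds = SpectralDataset(x[None, :], np.arange(P, dtype=float), [1], ["a", "b"])
        som = init_map(2, 2, P, K, seed=0,
                       schedule=TrainingSchedule(T=200, alpha0=0.5, sigma0=1.5))
        train_som(ds, som, seed=1)
        coord, dist = find_bmu(som, x)
        assert dist < 1e-6
        j = np.zeros(K)
        j[1] = 1.0
        assert np.linalg.norm(som.C[som.index(coord)] - j) < 1e-6

    def test_same_seed_gives_identical_maps(self, separated_config):
        ds = standardize_dataset(generate_dataset(separated_config))
        runs = []
        for _ in range(2):
            som = init_map(4, 4, ds.n_channels, ds.n_classes, seed=5,
                           schedule=TrainingSchedule(T=300, alpha0=0.5,
                                                     sigma0=2.0))
            train_som(ds, som, seed=9)
            runs.append(som)
        assert np.array_equal(runs[0].W, runs[1].W)
        assert np.array_equal(runs[0].C, runs[1].C)

    def test_empty_dataset_rejected(self):
        ds = SpectralDataset(np.empty((0, 3)), np.arange(3, dtype=float), [], ["a"])
        som = make_map(2, 2, P=3, K=1)
        with pytest.raises(SkinetError):
            train_som(ds, som)

    def test_well_separated_classes_occupy_disjoint_connected_regions(self):
        # two classes with distant exclusive bands on a 6x6 map
        from skinet import BandSpec, ClassProfile, SyntheticConfig
        cfg = SyntheticConfig(classes=(
            ClassProfile("p", exclusive=(BandSpec(700.0, width=15.0,
                                                  amplitude=3.0),)),
            ClassProfile("q", exclusive=(BandSpec(1500.0, width=15.0,
                                                  amplitude=3.0),)),
        ), n_channels=150, n_per_class=40, noise_sd=0.05, baseline_scale=0.0,
            gain_sigma=0.0, seed=2)
        ds = standardize_dataset(generate_dataset(cfg))
        som = init_map(6, 6, ds.n_channels, ds.n_classes, seed=1,
                       low=ds.X.min(axis=0), high=ds.X.max(axis=0),
                       schedule=TrainingSchedule(T=2000, alpha0=0.5,
                                                 sigma0=3.0))
        train_som(ds, som, seed=3)
        summary = map_summary(som, ds)
        hit_sets = []
        for k in range(2):
            hit_sets.append({n for n in range(36) if summary.hits[n, k] > 0})
        assert hit_sets[0] and hit_sets[1]
        assert not hit_sets[0] & hit_sets[1]
        # each class's neurons form one connected patch (hex adjacency)
        for hs in hit_sets:
            g = nx.Graph()
            g.add_nodes_from(hs)
            for a in hs:
                for b in hs:
                    if a < b and som.grid_distance(som.coord(a),
                                                   som.coord(b)) == 1:
                        g.add_edge(a, b)
            assert nx.number_connected_components(g) == 1

    def test_quantization_error_decreases_with_training(self, separated_config):
        ds = standardize_dataset(generate_dataset(separated_config))
        som = init_map(5, 5, ds.n_channels, ds.n_classes, seed=7,
                       low=ds.X.min(axis=0), high=ds.X.max(axis=0),
                       schedule=TrainingSchedule(T=1500, alpha0=0.5,
                                                 sigma0=2.5))
        before = quantization_error(som, ds.X)
        train_som(ds, som, seed=8)
        assert quantization_error(som, ds.X) < before

    def test_training_log_written(self, separated_config, tmp_path):
        ds = standardize_dataset(generate_dataset(separated_config))
        som = init_map(3, 3, ds.n_channels, ds.n_classes, seed=0,
                       schedule=TrainingSchedule(T=100, alpha0=0.5, sigma0=1.5))
        log = tmp_path / "train.tsv"
        train_som(ds, som, seed=1, log_path=log, log_every=25)
        lines = log.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["t", "quantization_error",
                                        "learning_rate", "sigma"]
        assert len(lines) >= 4
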