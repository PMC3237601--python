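"""Stage-1 networks, negative sampling and the two-stage ensemble."""

import numpy as np
import pytest
from scipy.special import logit

from pairface.features import FeatureSpec
from pairface.metrics import roc_auc
from pairface.model import (ComplexFeatures, EnsembleModel, PairInterfaceModel,
                            make_feature_grid, predict_complex, predict_pair,
                            sample_negatives, train_ensemble, train_stage1)
from pairface.network import LogisticMLP, NetworkParams


class TestFeatureGrid:
    def test_grid_construction(self):
        grid = make_feature_grid()
        combos = {(s.sparse_window, s.pssm_window) for s in grid}
        assert len(grid) == 24
        assert (0, 7) in combos and (7, 0) in combos
        assert (0, 0) not in combos
        assert combos == {(a, b) for a in (0, 1, 3, 5, 7)
                          for b in (0, 1, 3, 5, 7)} - {(0, 0)}

    def test_grid_order_deterministic(self):
        assert make_feature_grid() == make_feature_grid()


class TestSampleNegatives:
    def test_cap_binds_for_large_pools(self, rng):
        pool = rng.random(100_000)
        assert len(sample_negatives(pool, 0.02, 1000, 1)) == 1000

    def test_fraction_binds_for_small_pools(self, rng):
        pool = rng.random(10_000)
        assert len(sample_negatives(pool, 0.02, 1000, 1)) == 200

    def test_reproducible_and_seed_sensitive(self, rng):
        pool = rng.random(5000)
        a = sample_negatives(pool, 0.02, 1000, 11)
        b = sample_negatives(pool, 0.02, 1000, 11)
        c = sample_negatives(pool, 0.02, 1000, 12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning):
            out = sample_negatives(np.empty(0), 0.02, 1000, 1)
        assert len(out) == 0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives(np.ones(5), 0.0, 1000, 1)


class TestStage1Training:
    def test_separable_toy_set_reaches_perfect_training_auc(self):
        X = np.vstack([np.ones((50, 10)), np.zeros((50, 10))])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        net = train_stage1(X, y, FeatureSpec(1, 0), NetworkParams(epochs=50), seed=0)
        assert roc_auc(net.predict(X), y).auc == 1.0

    def test_zero_epochs_forbidden(self):
        with pytest.raises(ValueError):
            NetworkParams(epochs=0)

    def test_single_class_training_rejected(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_stage1(X, np.ones(10), FeatureSpec(1, 0), NetworkParams(), 0)

    def test_same_seed_reproduces_probe_score(self, rng):
        X = rng.random((60, 8))
        y = (rng.random(60) < 0.5).astype(float)
        y[:2] = [0, 1]
        probe = rng.random((1, 8))
        params = NetworkParams(epochs=20)
        s1 = train_stage1(X, y, FeatureSpec(1, 0), params, 7).predict(probe)
        s2 = train_stage1(X, y, FeatureSpec(1, 0), params, 7).predict(probe)
        assert s1 == s2


def _constant_ensemble(c, use_composition=True):
    """Untrained ensemble whose every member outputs the constant c."""
    params = NetworkParams()
    members = []
    for spec in make_feature_grid(use_composition):
        net = LogisticMLP(spec.pair_length, params, seed=0)
        net.w1[:] = 0.0
        net.w2[:] = 0.0
        net.b2 = float(logit(c))
        members.append((spec, net))
    return EnsembleModel(members, "pair", params, base_seed=0)


def _random_ensemble(seed, use_composition=True):
    params = NetworkParams()
    members = [
        (spec, LogisticMLP(spec.pair_length, params, seed=seed + k))
        for k, spec in enumerate(make_feature_grid(use_composition))
    ]
    return EnsembleModel(members, "pair", params, base_seed=seed)


def _feature_dicts(cfeats, row, side="ligand"):
    get = cfeats.ligand_features if side == "ligand" else cfeats.receptor_features
    return {spec: get(spec)[0][row] for spec in make_feature_grid()}


class TestEnsemblePrediction:
    def test_constant_members_give_constant_score(self, small_fixture_set):
        _, _, tables, pssms = small_fixture_set
        cf = ComplexFeatures(tables[0], pssms)
        model = _constant_ensemble(0.37)
        fi = _feature_dicts(cf, 0, "ligand")
        fj = _feature_dicts(cf, 0, "receptor")
        assert predict_pair(model, fi, fj) == pytest.approx(0.37, abs=1e-12)

    def test_pair_score_symmetric_under_swap(self, small_fixture_set):
        _, _, tables, pssms = small_fixture_set
        cf = ComplexFeatures(tables[0], pssms)
        model = _random_ensemble(3)
        fi = _feature_dicts(cf, 2, "ligand")
        fj = _feature_dicts(cf, 4, "receptor")
        assert predict_pair(model, fi, fj) == predict_pair(model, fj, fi)

    def test_stage2_bounded_by_stage1_range(self, small_fixture_set):
        _, _, tables, pssms = small_fixture_set
        cf = ComplexFeatures(tables[0], pssms)
        model = _random_ensemble(5)
        fi = _feature_dicts(cf, 1, "ligand")
        fj = _feature_dicts(cf, 3, "receptor")
        stage1 = model.stage1_pair_scores(fi, fj)
        stage2 = predict_pair(model, fi, fj)
        assert stage1.min() <= stage2 <= stage1.max()

    def test_complex_matrix_matches_looped_pair_calls(self, small_fixture_set):
        _, _, tables, pssms = small_fixture_set
        cf = ComplexFeatures(tables[1], pssms)
        model = _random_ensemble(9)
        matrix = predict_complex(model, cf)
        m, n = tables[1].labels.shape
        assert matrix.shape == (m, n)
        assert (matrix >= 0).all() and (matrix <= 1).all()
        for i, j in [(0, 0), (3, 7), (m - 1, n - 1)]:
            fi = _feature_dicts(cf, i, "ligand")
            fj = _feature_dicts(cf, j, "receptor")
            assert matrix[i, j] == pytest.approx(predict_pair(model, fi, fj),
                                                 abs=1e-12)


class TestTrainEnsemble:
    @pytest.fixture
    def tiny_params(self):
        return NetworkParams(hidden_units=2, epochs=2)

    def test_returns_24_members_and_is_reproducible(self, small_fixture_set,
                                                    tiny_params):
        _, _, tables, pssms = small_fixture_set
        m1 = train_ensemble(tables[:3], pssms, tiny_params, base_seed=4)
        m2 = train_ensemble(tables[:3], pssms, tiny_params, base_seed=4)
        assert len(m1.members) == 24
        cf = ComplexFeatures(tables[3], pssms)
        assert np.array_equal(predict_complex(m1, cf), predict_complex(m2, cf))

    def test_single_mode_trains_on_residue_patterns(self, small_fixture_set,
                                                    tiny_params):
        from pairface.model import predict_single_residues

        _, _, tables, pssms = small_fixture_set
        m = train_ensemble(tables[:3], pssms, tiny_params, base_seed=4,
                           mode="single")
        assert m.mode == "single"
        cf = ComplexFeatures(tables[3], pssms)
        scores = predict_single_residues(m, cf)
        assert scores.shape == (len(tables[3].ligand_residues)
                                + len(tables[3].receptor_residues),)

    def test_results_save_load_round_trip(self, small_fixture_set, tiny_params,
                                          tmp_path):
        _, _, tables, pssms = small_fixture_set
        model = PairInterfaceModel(tables[:3], pssms=pssms, params=tiny_params)
        results = model.fit(seed=2)
        results.save(tmp_path / "model")
        loaded = EnsembleModel.load(tmp_path / "model")
        cf = ComplexFeatures(tables[3], pssms)
        assert np.array_equal(predict_complex(results.ensemble, cf),
                              predict_complex(loaded, cf))
        assert "pair-trained" in results.summary()
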