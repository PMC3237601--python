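"""Decoy pose scoring, ranking, consensus and hit counting."""

import numpy as np
import pandas as pd
import pytest

from pairface.decoys import (DecoyPose, consensus_rank, count_hits,
                             first_hit_rank, rank_poses, score_pose)
from pairface.metrics import roc_auc
from pairface.simulate import FixtureConfig, generate_complex, generate_decoy_set


def pose(pid, contacts, rank=1, rmsd=10.0):
    return DecoyPose(pid, np.asarray(contacts), rank, rmsd)


class TestScorePose:
    def test_contacts_at_top_predictions_score_one(self, rng):
        scores = rng.random((6, 6))
        contacts = (scores >= np.sort(scores.ravel())[-5]).astype(int)
        assert score_pose(scores, pose("p", contacts)) == 1.0

    def test_random_contacts_score_near_half(self, rng):
        scores = rng.random((10, 10))
        aucs = []
        for _ in range(100):
            flat = rng.choice(100, size=10, replace=False)
            contacts = np.zeros(100, dtype=int)
            contacts[flat] = 1
            aucs.append(score_pose(scores, pose("p", contacts.reshape(10, 10))))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_equals_flattened_roc_auc(self, rng):
        scores = rng.random((8, 5))
        contacts = (rng.random((8, 5)) < 0.3).astype(int)
        contacts[0, 0] = 1
        contacts[1, 1] = 0
        assert score_pose(scores, pose("p", contacts)) == \
            roc_auc(scores.ravel(), contacts.ravel()).auc

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random((6, 6))
        contacts = (rng.random((6, 6)) < 0.4).astype(int)
        contacts.flat[0], contacts.flat[1] = 1, 0
        p = pose("p", contacts)
        assert score_pose(scores, p) == pytest.approx(
            score_pose(np.exp(scores), p), abs=1e-12)

    def test_degenerate_pose_unscorable(self, rng):
        scores = rng.random((3, 3))
        assert np.isnan(score_pose(scores, pose("p", np.zeros((3, 3)))))


class TestRanking:
    def _three_pose_frame(self, rng):
        scores = rng.random((5, 5))
        top5 = (scores >= np.sort(scores.ravel())[-5]).astype(int)
        mid = np.zeros(25, dtype=int)
        mid[np.argsort(scores.ravel())[-10:-5]] = 1  # next-best pairs
        rand = np.zeros(25, dtype=int)
        rand[rng.choice(25, 5, replace=False)] = 1
        poses = [pose("pose1", top5, 2, 1.0),
                 pose("pose2", rand.reshape(5, 5), 1, 12.0),
                 pose("pose3", mid.reshape(5, 5), 3, 8.0)]
        return scores, poses

    def test_descending_auc_order(self, rng):
        scores, poses = self._three_pose_frame(rng)
        ranked = rank_poses(scores, poses)
        assert ranked["auc_score"].is_monotonic_decreasing
        assert ranked.loc[0, "pose_id"] == "pose1"

    def test_ties_broken_by_pose_id(self, rng):
        scores = rng.random((4, 4))
        contacts = (rng.random((4, 4)) < 0.4).astype(int)
        contacts.flat[0], contacts.flat[1] = 1, 0
        ranked = rank_poses(scores, [pose("b", contacts), pose("a", contacts)])
        assert ranked["pose_id"].tolist() == ["a", "b"]

    def test_matches_sort_oracle(self, rng):
        scores, poses = self._three_pose_frame(rng)
        ranked = rank_poses(scores, poses)
        oracle = sorted(poses, key=lambda p: (-score_pose(scores, p), p.pose_id))
        assert ranked["pose_id"].tolist() == [p.pose_id for p in oracle]


class TestConsensus:
    def _frame(self):
        return pd.DataFrame({
            "pose_id": ["a", "b", "c"],
            "external_rank": [1, 2, 3],
            "auc_rank": [3, 1, 2],
            "native_rmsd": [1.0, 12.0, 8.0],
        })

    def test_weighted_average_formula(self):
        out = consensus_rank(self._frame(), weights=(3, 1))
        a = out.set_index("pose_id")
        assert a.loc["a", "consensus_score"] == pytest.approx((3 * 1 + 3) / 4)

    def test_pure_external_weights_reproduce_external_ranking(self):
        out = consensus_rank(self._frame(), weights=(1, 0))
        assert (out["consensus_rank"] == out["external_rank"]).all()

    def test_pure_auc_weights_reproduce_auc_ranking(self):
        out = consensus_rank(self._frame(), weights=(0, 1))
        assert (out["consensus_rank"] == out["auc_rank"]).all()

    def test_identical_rankings_unchanged(self):
        df = self._frame()
        df["auc_rank"] = df["external_rank"]
        out = consensus_rank(df)
        assert (out["consensus_rank"] == out["external_rank"]).all()

    def test_duplicate_pose_ids_rejected(self):
        df = self._frame()
        df.loc[2, "pose_id"] = "a"
        with pytest.raises(ValueError):
            consensus_rank(df)


class TestCountHits:
    def _frame(self, rng, n=50):
        return pd.DataFrame({
            "pose_id": [f"p{i}" for i in range(n)],
            "auc_rank": rng.permutation(n) + 1,
            "native_rmsd": rng.uniform(0, 20, n),
        })

    def test_all_hits_in_window_counted(self):
        df = pd.DataFrame({"pose_id": list("abc"), "auc_rank": [1, 2, 3],
                           "native_rmsd": [1.0, 2.0, 2.4]})
        assert count_hits(df, "auc_rank", top_n=2000) == 3

    def test_empty_window(self, rng):
        assert count_hits(self._frame(rng), "auc_rank", top_n=0) == 0

    def test_matches_filter_and_count(self, rng):
        df = self._frame(rng)
        brute = sum(1 for _, r in df.iterrows()
                    if r["auc_rank"] <= 10 and r["native_rmsd"] < 2.5)
        assert count_hits(df, "auc_rank", top_n=10) == brute

    def test_monotone_in_top_n_and_cutoff(self, rng):
        df = self._frame(rng)
        hits = [count_hits(df, "auc_rank", top_n=k) for k in (0, 10, 25, 50)]
        assert hits == sorted(hits)
        cuts = [count_hits(df, "auc_rank", 50, c) for c in (1.0, 2.5, 5.0)]
        assert cuts == sorted(cuts)

    def test_missing_rmsd_rejected(self, rng):
        df = self._frame(rng)
        df.loc[0, "native_rmsd"] = np.nan
        with pytest.raises(ValueError):
            count_hits(df)


class TestSyntheticDecoys:
    def test_near_native_tops_auc_under_perfect_predictor(self, rng):
        config = FixtureConfig(seed=1)
        _, truth = generate_complex(config, rng)
        poses = generate_decoy_set(truth, 20, rng)
        perfect = truth.labels.astype(float)
        ranked = rank_poses(perfect, poses)
        assert ranked.loc[0, "pose_id"] == "pose0001"
        assert ranked.loc[0, "auc_score"] == 1.0
        assert first_hit_rank(ranked) == 1

    def test_shuffled_decoys_near_half_under_perfect_predictor(self, rng):
        config = FixtureConfig(seed=2)
        _, truth = generate_complex(config, rng)
        poses = generate_decoy_set(truth, 102, rng)
        perfect = truth.labels.astype(float)
        decoy_aucs = [score_pose(perfect, p) for p in poses[1:]]
        assert np.nanmean(decoy_aucs) == pytest.approx(0.5, abs=0.05)

    def test_too_few_poses_rejected(self, rng):
        config = FixtureConfig(seed=3)
        _, truth = generate_complex(config, rng)
        with pytest.raises(ValueError):
            generate_decoy_set(truth, 1, rng)
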