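"""Docking decoy rescoring by agreement with predicted pair scores.

Each rigid-body pose of a complex induces a set of ligand x receptor
contacts (the same 6.0-Å any-atom rule as for native structures).  Treating
the pose's contact labels as the "truth" and the predicted pair-score
matrix as the classifier output, the AUC measures how well the pose agrees
with the sequence-based prediction; the AUC itself is the scoring function,
and poses are ranked by it.  A weighted consensus with an external ranking
(default weight 3:1 in the external ranking's favour) combines the two
signals; quality is summarised as the number of native-like poses
(native/decoy RMSD < 2.5 Å) in the top 2000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import roc_auc

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 2000
DEFAULT_RMSD_CUTOFF = 2.5

__all__ = [
    "DecoyPose", "score_pose", "rank_poses", "consensus_rank", "count_hits",
    "read_pose_table",
]


@dataclass
class DecoyPose:
    """One docking pose: contact labels plus external-rank / RMSD metadata."""

    pose_id: str
    contacts: np.ndarray  # (m, n) 0/1 over the same residue grid as predictions
    external_rank: int
    native_rmsd: float

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=np.int8)
        if not np.isin(self.contacts, (0, 1)).all():
            raise ValueError("pose contacts must be 0/1")
        if self.external_rank < 1:
            raise ValueError("external_rank must be >= 1")

    @property
    def is_hit(self) -> bool:
        return self.native_rmsd < DEFAULT_RMSD_CUTOFF


def score_pose(pair_scores: np.ndarray, pose: DecoyPose) -> float:
    """AUC of the predicted pair scores against the pose's contact labels.

    Returns NaN (unscorable) when the pose has zero or all contacts.
    """
    pair_scores = np.asarray(pair_scores, dtype=float)
    if pair_scores.shape != pose.contacts.shape:
        raise ValueError(
            f"score matrix {pair_scores.shape} and pose contacts "
            f"{pose.contacts.shape} cover different residue sets"
        )
    labels = pose.contacts.ravel()
    if labels.min() == labels.max():
        logger.warning("pose %s has single-class contacts; unscorable", pose.pose_id)
        return float("nan")
    return roc_auc(pair_scores.ravel(), labels).auc


def rank_poses(pair_scores: np.ndarray, poses) -> pd.DataFrame:
    """Rank poses by descending AUC score; ties broken by pose_id.

    Unscorable poses (NaN AUC) sort last.  Returns a frame with auc_score
    and 1-based auc_rank per pose.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("no poses to rank")
    rows = [
        (p.pose_id, score_pose(pair_scores, p), p.external_rank, p.native_rmsd)
        for p in poses
    ]
    df = pd.DataFrame(rows, columns=["pose_id", "auc_score", "external_rank",
                                     "native_rmsd"])
    df = df.sort_values(
        ["auc_score", "pose_id"], ascending=[False, True],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)
    df["auc_rank"] = np.arange(1, len(df) + 1)
    return df


def consensus_rank(ranked: pd.DataFrame, weights=(3.0, 1.0)) -> pd.DataFrame:
    """Weighted-average rank consensus between the external and AUC rankings.

    combined = (w_ext * external_rank + w_auc * auc_rank) / (w_ext + w_auc),
    ascending (default weights 3:1 in the external ranking's favour).
    """
    w_ext, w_auc = weights
    if w_ext < 0 or w_auc < 0 or (w_ext + w_auc) == 0:
        raise ValueError("weights must be non-negative and not both zero")
    required = {"pose_id", "external_rank", "auc_rank"}
    if not required <= set(ranked.columns):
        raise ValueError(f"ranking frame must have columns {sorted(required)}")
    if ranked["pose_id"].duplicated().any():
        raise ValueError("duplicate pose ids")
    df = ranked.copy()
    df["consensus_score"] = (
        w_ext * df["external_rank"] + w_auc * df["auc_rank"]
    ) / (w_ext + w_auc)
    df = df.sort_values(
        ["consensus_score", "pose_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["consensus_rank"] = np.arange(1, len(df) + 1)
    return df


def count_hits(ranking: pd.DataFrame, rank_column: str = "auc_rank",
               top_n: int = DEFAULT_TOP_N,
               rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF) -> int:
    """Native-like poses (RMSD < cutoff) among the top_n of a ranking."""
    if "native_rmsd" not in ranking.columns:
        raise ValueError("ranking frame lacks native_rmsd metadata")
    if ranking["native_rmsd"].isna().any():
        raise ValueError("missing RMSD for one or more poses")
    sel = ranking[ranking[rank_column] <= top_n]
    return int((sel["native_rmsd"] < rmsd_cutoff).sum())


def first_hit_rank(ranking: pd.DataFrame, rank_column: str = "auc_rank",
                   rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF):
    """Rank of the first native-like pose, or None when there is no hit."""
    hits = ranking[ranking["native_rmsd"] < rmsd_cutoff]
    return None if hits.empty else int(hits[rank_column].min())


def read_pose_table(path) -> pd.DataFrame:
    """Read pose metadata TSV (pose_id, external_rank, rmsd)."""
    df = pd.read_csv(path, sep="\t")
    required = {"pose_id", "external_rank", "rmsd"}
    if not required <= set(df.columns):
        raise ValueError(f"pose table must have columns {sorted(required)}")
    return df
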