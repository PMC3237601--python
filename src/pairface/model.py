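"""The two-stage ensemble predictor of interacting residue pairs.

Stage 1 is a grid of 24 small logistic networks, one per combination of
sparse-window and PSSM-window sizes in {0, 1, 3, 5, 7}^2 minus the
featureless (0, 0) cell.  Each network is trained on residue-pair patterns
(both concatenation orders, identical target) with all positives retained
and negatives randomly subsampled — 2% of the pool or 1000, whichever is
smaller — because non-binding pairs outnumber binding pairs by orders of
magnitude.  Stage 2 simply averages the 24 stage-1 scores; training each
member on an independent negative sample lets the averaging cancel noise.

The same machinery trains a partner-unaware variant on single-residue
patterns (pairing information discarded, negative fraction sqrt(0.02)); its
per-residue scores are converted to pair scores downstream for comparison.

``PairInterfaceModel`` / ``PairInterfaceResults`` wrap this in a
model/fit/results interface; the plain functions underneath remain public.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ChainFeatures, FeatureSpec, PSSMProfile, WINDOW_SIZES
from .network import LogisticMLP, NetworkParams
from .structure import ContactTable, pool_single_residue_labels

logger = logging.getLogger(__name__)

PAIR_NEGATIVE_FRACTION = 0.02
SINGLE_NEGATIVE_FRACTION = float(np.sqrt(0.02))
NEGATIVE_CAP = 1000

__all__ = [
    "ComplexFeatures", "EnsembleModel", "PairInterfaceModel",
    "PairInterfaceResults", "make_feature_grid", "sample_negatives",
    "train_stage1", "train_ensemble", "predict_pair", "predict_complex",
    "PAIR_NEGATIVE_FRACTION", "SINGLE_NEGATIVE_FRACTION", "NEGATIVE_CAP",
]


def make_feature_grid(use_composition: bool = True):
    """The 24 window-grid feature specs: {0,1,3,5,7}^2 minus (0, 0)."""
    return [
        FeatureSpec(s, p, use_composition)
        for s in WINDOW_SIZES
        for p in WINDOW_SIZES
        if (s, p) != (0, 0)
    ]


def sample_negatives(negatives, fraction: float, cap: int, rng_seed: int):
    """Uniform without-replacement subsample of the negative pool.

    Sample size is min(round(fraction * N), cap); all positives are kept by
    the caller.  Reproducible under ``rng_seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    negatives = np.asarray(negatives)
    n = len(negatives)
    if n == 0:
        warnings.warn("empty negative pool; returning empty sample")
        return negatives[:0]
    size = min(int(round(fraction * n)), cap)
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n, size=size, replace=False)
    return negatives[np.sort(idx)]


class ComplexFeatures:
    """Feature caches for every chain of one labelled complex.

    Pools the per-chain feature matrices in contact-table residue order so
    that row/column indices of the label matrix line up with feature rows.
    """

    def __init__(self, table: ContactTable, pssms: dict | None = None,
                 use_composition: bool = True, scale: bool = True):
        self.table = table
        self.complex_id = table.complex_id
        pssms = pssms or {}
        self._chains: dict = {}
        for refs in (table.ligand_residues, table.receptor_residues):
            by_chain: dict = {}
            for c, _, aa in refs:
                by_chain.setdefault(c, []).append(aa)
            for c, aas in by_chain.items():
                self._chains[c] = ChainFeatures(
                    "".join(aas), pssms.get(c), scale=scale
                )
        self._lig_index = [(c, i) for c, i, _ in table.ligand_residues]
        self._rec_index = [(c, i) for c, i, _ in table.receptor_residues]
        self.use_composition = use_composition

    def _pooled(self, index, spec: FeatureSpec):
        feats = np.empty((len(index), spec.residue_length))
        valid = np.empty(len(index), dtype=bool)
        mats = {c: cf.matrix(spec) for c, cf in self._chains.items()}
        masks = {c: cf.valid_mask(spec) for c, cf in self._chains.items()}
        for row, (c, i) in enumerate(index):
            feats[row] = mats[c][i - 1]
            valid[row] = masks[c][i - 1]
        return feats, valid

    def ligand_features(self, spec: FeatureSpec):
        return self._pooled(self._lig_index, spec)

    def receptor_features(self, spec: FeatureSpec):
        return self._pooled(self._rec_index, spec)

    def single_features(self, spec: FeatureSpec):
        """Pooled per-residue features over both sides with single labels."""
        lf, lv = self.ligand_features(spec)
        rf, rv = self.receptor_features(spec)
        labels = pool_single_residue_labels(self.table)["label"].to_numpy()
        return np.vstack([lf, rf]), np.concatenate([lv, rv]), labels


def _pair_training_patterns(cfeats, spec: FeatureSpec):
    """Positive and negative both-order pattern pools for one spec."""
    pos_blocks, neg_blocks = [], []
    for cf in cfeats:
        L, vl = cf.ligand_features(spec)
        R, vr = cf.receptor_features(spec)
        eligible = np.outer(vl, vr)
        labels = cf.table.labels.astype(bool)
        for mask, store in ((labels & eligible, pos_blocks),
                            ((~labels) & eligible, neg_blocks)):
            ii, jj = np.nonzero(mask)
            if len(ii):
                store.append(np.hstack([L[ii], R[jj]]))
    dim = 2 * spec.residue_length
    pos = np.vstack(pos_blocks) if pos_blocks else np.empty((0, dim))
    neg = np.vstack(neg_blocks) if neg_blocks else np.empty((0, dim))
    return pos, neg


def _single_training_patterns(cfeats, spec: FeatureSpec):
    pos_blocks, neg_blocks = [], []
    for cf in cfeats:
        X, valid, labels = cf.single_features(spec)
        pos_blocks.append(X[valid & (labels == 1)])
        neg_blocks.append(X[valid & (labels == 0)])
    return np.vstack(pos_blocks), np.vstack(neg_blocks)


def _both_orders(patterns: np.ndarray) -> np.ndarray:
    """Duplicate pair patterns with the two halves swapped."""
    half = patterns.shape[1] // 2
    swapped = np.hstack([patterns[:, half:], patterns[:, :half]])
    return np.vstack([patterns, swapped])


def train_stage1(X: np.ndarray, y: np.ndarray, spec: FeatureSpec,
                 params: NetworkParams, seed: int) -> LogisticMLP:
    """Train one stage-1 network on prepared patterns for a fixed cycle count."""
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("training set must contain both classes")
    net = LogisticMLP(X.shape[1], params, seed)
    return net.fit(X, y)


@dataclass
class EnsembleModel:
    """24 trained stage-1 networks and the stage-2 averaging rule."""

    members: list  # [(FeatureSpec, LogisticMLP), ...]
    mode: str  # "pair" or "single"
    params: NetworkParams
    base_seed: int

    def __post_init__(self) -> None:
        if len(self.members) != 24:
            raise ValueError(f"ensemble must have 24 members, got {len(self.members)}")
        if self.mode not in ("pair", "single"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def stage1_pair_scores(self, features_i, features_j) -> np.ndarray:
        """Per-member order-averaged scores for one residue pair (pair mode)."""
        scores = []
        for spec, net in self.members:
            u = np.concatenate([features_i[spec], features_j[spec]])
            v = np.concatenate([features_j[spec], features_i[spec]])
            s = net.predict(np.vstack([u, v]))
            scores.append((s[0] + s[1]) / 2.0)
        return np.array(scores)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        meta = {"mode": self.mode, "base_seed": self.base_seed,
                "params": vars(self.params).copy(), "members": []}
        for k, (spec, net) in enumerate(self.members):
            meta["members"].append({
                "sparse_window": spec.sparse_window,
                "pssm_window": spec.pssm_window,
                "use_composition": spec.use_composition,
                "n_inputs": net.n_inputs,
            })
            for name, arr in net.state().items():
                arrays[f"m{k}_{name}"] = arr
        np.savez(path / "weights.npz", **arrays)
        (path / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        arrays = np.load(path / "weights.npz")
        params = NetworkParams(**meta["params"])
        members = []
        for k, m in enumerate(meta["members"]):
            spec = FeatureSpec(m["sparse_window"], m["pssm_window"], m["use_composition"])
            state = {name: arrays[f"m{k}_{name}"] for name in ("w1", "b1", "w2", "b2", "seed")}
            members.append((spec, LogisticMLP.from_state(m["n_inputs"], params, state)))
        return cls(members, meta["mode"], params, meta["base_seed"])


def train_ensemble(contact_tables, pssms: dict | None = None,
                   params: NetworkParams | None = None, base_seed: int = 0,
                   mode: str = "pair", negative_fraction: float | None = None,
                   negative_cap: int = NEGATIVE_CAP,
                   use_composition: bool = True) -> EnsembleModel:
    """Train the 24-network ensemble on a set of labelled complexes.

    Each grid member uses an independent negative sample (seed = base_seed +
    grid index) and its own weight-init/shuffle seed, so the whole ensemble
    is reproducible from ``base_seed`` alone.
    """
    params = params or NetworkParams()
    if negative_fraction is None:
        negative_fraction = (
            PAIR_NEGATIVE_FRACTION if mode == "pair" else SINGLE_NEGATIVE_FRACTION
        )
    cfeats = [
        t if isinstance(t, ComplexFeatures)
        else ComplexFeatures(t, pssms, use_composition=use_composition)
        for t in contact_tables
    ]
    members = []
    for k, spec in enumerate(make_feature_grid(use_composition)):
        if mode == "pair":
            pos, neg = _pair_training_patterns(cfeats, spec)
        else:
            pos, neg = _single_training_patterns(cfeats, spec)
        neg_sample = sample_negatives(neg, negative_fraction, negative_cap,
                                      rng_seed=base_seed + k)
        X = np.vstack([pos, neg_sample])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg_sample))])
        if mode == "pair":
            X = _both_orders(X)
            y = np.concatenate([y, y])
        net = train_stage1(X, y, spec, params, seed=base_seed * 1000 + k)
        members.append((spec, net))
        logger.debug("trained member %d (%s): %d pos, %d neg patterns",
                     k, spec, len(pos), len(neg_sample))
    return EnsembleModel(members, mode, params, base_seed)


def predict_pair(model: EnsembleModel, features_i: dict, features_j: dict) -> float:
    """Stage-2 score of one residue pair: mean over members of the
    mean over the two concatenation orders.  Exactly symmetric in (i, j).

    ``features_i`` / ``features_j`` map each member's FeatureSpec to that
    residue's feature vector (termini zero-padded).
    """
    if model.mode != "pair":
        raise ValueError("predict_pair requires a pair-trained ensemble")
    return float(model.stage1_pair_scores(features_i, features_j).mean())


def predict_complex(model: EnsembleModel, cfeats: ComplexFeatures) -> np.ndarray:
    """Complete ligand x receptor pair score matrix for one complex.

    Pair-trained ensembles score every pair in both orders; single-trained
    ensembles score residues and the caller converts downstream.
    """
    if model.mode != "pair":
        raise ValueError("predict_complex requires a pair-trained ensemble")
    m = len(cfeats._lig_index)
    n = len(cfeats._rec_index)
    total = np.zeros((m, n))
    for spec, net in model.members:
        L, _ = cfeats.ligand_features(spec)
        R, _ = cfeats.receptor_features(spec)
        ii = np.repeat(np.arange(m), n)
        jj = np.tile(np.arange(n), m)
        order1 = np.hstack([L[ii], R[jj]])
        order2 = np.hstack([R[jj], L[ii]])
        s = (net.predict(order1) + net.predict(order2)) / 2.0
        total += s.reshape(m, n)
    return total / len(model.members)


def predict_single_residues(model: EnsembleModel, cfeats: ComplexFeatures) -> np.ndarray:
    """Per-residue ensemble scores (ligand pooled first) for a single-trained model."""
    if model.mode != "single":
        raise ValueError("predict_single_residues requires a single-trained ensemble")
    total = None
    for spec, net in model.members:
        X, _, _ = cfeats.single_features(spec)
        s = net.predict(X)
        total = s if total is None else total + s
    return total / len(model.members)


# ---------------------------------------------------------------------------
# Model / Results surface

class PairInterfaceModel:
    """Two-stage interface-pair predictor over a set of labelled complexes.

    Parameters
    ----------
    contact_tables : sequence of ContactTable
        Training complexes with 0/1 labels for every ligand x receptor pair.
    pssms : dict, optional
        chain_id -> PSSMProfile; chains without a profile get zero PSSM blocks.
    mode : {"pair", "single"}
        Train on residue pairs (partner-aware) or on single residues with
        pairing information discarded (partner-unaware baseline).
    params : NetworkParams, optional
    """

    def __init__(self, contact_tables, pssms=None, mode="pair",
                 params=None, use_composition=True,
                 negative_fraction=None, negative_cap=NEGATIVE_CAP):
        self.contact_tables = list(contact_tables)
        self.pssms = pssms
        self.mode = mode
        self.params = params or NetworkParams()
        self.use_composition = use_composition
        self.negative_fraction = negative_fraction
        self.negative_cap = negative_cap
        if not self.contact_tables:
            raise ValueError("no training complexes given")

    def fit(self, seed: int = 0) -> "PairInterfaceResults":
        ensemble = train_ensemble(
            self.contact_tables, self.pssms, self.params, base_seed=seed,
            mode=self.mode, negative_fraction=self.negative_fraction,
            negative_cap=self.negative_cap, use_composition=self.use_composition,
        )
        return PairInterfaceResults(self, ensemble)


@dataclass
class PairInterfaceResults:
    """A fitted ensemble plus prediction and reporting helpers."""

    model: PairInterfaceModel
    ensemble: EnsembleModel

    def _cfeats(self, table) -> ComplexFeatures:
        if isinstance(table, ComplexFeatures):
            return table
        return ComplexFeatures(table, self.model.pssms,
                               use_composition=self.model.use_composition)

    def predict_complex(self, table) -> np.ndarray:
        """Ligand x receptor pair score matrix in [0, 1]."""
        cf = self._cfeats(table)
        if self.ensemble.mode == "pair":
            return predict_complex(self.ensemble, cf)
        from .conversion import single_to_pairs
        res = predict_single_residues(self.ensemble, cf)
        m = len(cf._lig_index)
        return single_to_pairs(res[:m], res[m:])

    def predict_single(self, table) -> np.ndarray:
        """Per-residue scores (pooled ligand residues first, then receptor)."""
        cf = self._cfeats(table)
        if self.ensemble.mode == "single":
            return predict_single_residues(self.ensemble, cf)
        from .conversion import pairs_to_single
        lig, rec = pairs_to_single(predict_complex(self.ensemble, cf))
        return np.concatenate([lig, rec])

    def save(self, path) -> None:
        self.ensemble.save(path)

    def summary(self) -> str:
        p = self.ensemble.params
        lines = [
            "Two-stage interface-pair ensemble",
            f"  mode:            {self.ensemble.mode}-trained",
            f"  stage-1 members: {len(self.ensemble.members)} "
            "(sparse x PSSM window grid {0,1,3,5,7}^2 \\ (0,0))",
            f"  network:         {p.hidden_units} logistic hidden units, "
            f"lr={p.learning_rate}, {p.epochs} cycles, loss={p.loss}",
            f"  base seed:       {self.ensemble.base_seed}",
            f"  training set:    {len(self.model.contact_tables)} complexes",
        ]
        return "\n".join(lines)
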