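"""Leave-one-out evaluation and the pair-trained vs single-trained comparison.

One complex is held out per cycle; an ensemble is trained on all the others
and evaluated on the held-out complex only.  Per-complex AUCs (for both the
residue-pair task and the pooled single-residue task) are averaged
unweighted over complexes, and two training modes are compared with a
paired two-sided t-test over the per-complex values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .conversion import pairs_to_single, single_to_pairs
from .metrics import (aggregate_per_complex, best_f1_point, paired_model_test,
                      roc_auc)
from .model import (ComplexFeatures, NetworkParams, PairInterfaceModel,
                    predict_complex, predict_single_residues)
from .structure import pool_single_residue_labels

logger = logging.getLogger(__name__)

__all__ = ["leave_one_out", "compare_pair_vs_single"]


def _evaluate_heldout(results, cfeat: ComplexFeatures):
    """Pair and single AUC (plus best-F1 stats) on one held-out complex."""
    table = cfeat.table
    pair_labels = table.labels.ravel()
    single_labels = pool_single_residue_labels(table)["label"].to_numpy()
    if pair_labels.min() == pair_labels.max():
        logger.warning("complex %s has single-class pair labels; skipped",
                       table.complex_id)
        return None

    if results.ensemble.mode == "pair":
        matrix = predict_complex(results.ensemble, cfeat)
        lig, rec = pairs_to_single(matrix)
        single_scores = np.concatenate([lig, rec])
    else:
        res = predict_single_residues(results.ensemble, cfeat)
        m = table.labels.shape[0]
        matrix = single_to_pairs(res[:m], res[m:])
        single_scores = res

    pair_scores = matrix.ravel()
    pair_point = best_f1_point(pair_scores, pair_labels)
    return {
        "complex_id": table.complex_id,
        "n_pairs": int(pair_labels.size),
        "n_pos": int(pair_labels.sum()),
        "pair_auc": roc_auc(pair_scores, pair_labels).auc,
        "single_auc": roc_auc(single_scores, single_labels).auc,
        "best_f1": pair_point["f1"],
        "precision": pair_point["precision"],
        "recall": pair_point["recall"],
    }


def leave_one_out(contact_tables, pssms=None, mode: str = "pair",
                  params: NetworkParams | None = None, base_seed: int = 0,
                  use_composition: bool = True) -> pd.DataFrame:
    """Per-complex metrics over leave-one-out cycles for one training mode.

    Cycle c trains on every complex except c (cycle seed = base_seed + 100*c
    so each cycle draws independent negative samples and weights) and
    evaluates on complex c alone.
    """
    tables = list(contact_tables)
    if len(tables) < 2:
        raise ValueError("leave-one-out needs at least two complexes")
    cfeats = [ComplexFeatures(t, pssms, use_composition=use_composition)
              for t in tables]
    rows = []
    for c in range(len(tables)):
        training = [cf for k, cf in enumerate(cfeats) if k != c]
        model = PairInterfaceModel(
            [cf.table for cf in training], pssms=pssms, mode=mode,
            params=params, use_composition=use_composition,
        )
        # reuse the prebuilt feature caches rather than re-deriving them
        model_fit = _fit_with_cached_features(model, training, base_seed + 100 * c)
        row = _evaluate_heldout(model_fit, cfeats[c])
        if row is not None:
            rows.append(row)
        logger.info("LOO cycle %d/%d (%s) done", c + 1, len(tables), mode)
    return pd.DataFrame(rows)


def _fit_with_cached_features(model: PairInterfaceModel, cached, seed: int):
    from .model import PairInterfaceResults, train_ensemble

    ensemble = train_ensemble(
        cached, model.pssms, model.params, base_seed=seed, mode=model.mode,
        negative_fraction=model.negative_fraction,
        negative_cap=model.negative_cap,
        use_composition=model.use_composition,
    )
    return PairInterfaceResults(model, ensemble)


def compare_pair_vs_single(contact_tables, pssms=None,
                           params: NetworkParams | None = None,
                           base_seed: int = 0,
                           use_composition: bool = True) -> dict:
    """Run both training modes through leave-one-out and compare them.

    Returns per-mode per-complex frames, mean AUCs and the paired t-test
    p-values for the pair-prediction and single-prediction tasks.
    """
    pair_df = leave_one_out(contact_tables, pssms, mode="pair", params=params,
                            base_seed=base_seed, use_composition=use_composition)
    single_df = leave_one_out(contact_tables, pssms, mode="single", params=params,
                              base_seed=base_seed, use_composition=use_composition)
    merged = pair_df.merge(single_df, on="complex_id", suffixes=("_pair", "_single"))
    out = {
        "pair_trained": pair_df,
        "single_trained": single_df,
        "mean_pair_auc_pair_trained": aggregate_per_complex(merged["pair_auc_pair"]),
        "mean_pair_auc_single_trained": aggregate_per_complex(merged["pair_auc_single"]),
        "mean_single_auc_pair_trained": aggregate_per_complex(merged["single_auc_pair"]),
        "mean_single_auc_single_trained": aggregate_per_complex(merged["single_auc_single"]),
        "pair_task_test": paired_model_test(merged["pair_auc_pair"],
                                            merged["pair_auc_single"]),
        "single_task_test": paired_model_test(merged["single_auc_pair"],
                                              merged["single_auc_single"]),
        "n_complexes": len(merged),
    }
    return out


# Strong pair-specific signal: contacts drawn almost exclusively from the
# five type pairs most enriched in real interfaces.  Concentrating the
# planted signal keeps the partner-aware vs partner-unaware comparison
# identifiable at a 20-complex scale (at realistic enrichment magnitudes
# ~3x, only a small minority of contacts carry type-pair information and
# even the Bayes-optimal pair AUC sits near 0.55).
STRONG_PAIR_PREFERENCES = {
    ("D", "R"): 400.0,
    ("R", "Y"): 400.0,
    ("N", "Y"): 400.0,
    ("R", "W"): 400.0,
    ("E", "K"): 400.0,
}


def headline_comparison(seed: int = 0) -> dict:
    """The pair-trained vs single-trained benchmark under frozen conditions.

    20 synthetic complexes (one 30-residue chain per side, 12 planted
    contact pairs each, strong pair-type-specific signal), leave-one-out in
    both training modes, networks at 5 hidden units / 100 cycles.  ``seed``
    drives both the fixture set and all training randomness.
    """
    from .simulate import FixtureConfig, generate_fixture_set

    config = FixtureConfig(
        seed=seed, n_complexes=20,
        ligand_length=(30, 30), receptor_length=(30, 30),
        interface_size=(12, 12),
        pair_preferences=dict(STRONG_PAIR_PREFERENCES),
    )
    _, tables, pssms = generate_fixture_set(config)
    params = NetworkParams(hidden_units=5, learning_rate=1.0, epochs=100,
                           batch_size=32, loss="mse")
    return compare_pair_vs_single(tables, pssms, params=params,
                                  base_seed=seed + 1)


def summarize_comparison(result: dict) -> str:
    lines = [
        "Pair-trained vs single-trained (leave-one-out, mean per-complex AUC)",
        f"  complexes compared: {result['n_complexes']}",
        "  residue-pair prediction: "
        f"{100 * result['mean_pair_auc_pair_trained']:.1f}% (pair-trained) vs "
        f"{100 * result['mean_pair_auc_single_trained']:.1f}% (single-trained), "
        f"paired p = {result['pair_task_test']['p']:.3g}",
        "  single-residue prediction: "
        f"{100 * result['mean_single_auc_pair_trained']:.1f}% (pair-trained) vs "
        f"{100 * result['mean_single_auc_single_trained']:.1f}% (single-trained), "
        f"paired p = {result['single_task_test']['p']:.3g}",
    ]
    return "\n".join(lines)
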