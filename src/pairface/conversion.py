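"""Conversions between pair-score matrices and single-residue scores.

Pair -> single: each residue inherits the highest pair score it is involved
in (row maxima for ligand residues, column maxima for receptor residues).
Single -> pair: a pair's score is the average of its two residue scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pairs_to_single", "single_to_pairs", "partner_specific_sites"]


def pairs_to_single(scores: np.ndarray):
    """Row and column maxima of a ligand x receptor pair-score matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.size == 0:
        raise ValueError("need a non-empty 2-D score matrix")
    return scores.max(axis=1), scores.max(axis=0)


def single_to_pairs(scores_ligand, scores_receptor) -> np.ndarray:
    """Pair-score matrix: entry (a, b) = (score_a + score_b) / 2."""
    a = np.asarray(scores_ligand, dtype=float)
    b = np.asarray(scores_receptor, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    return (a[:, None] + b[None, :]) / 2.0


def partner_specific_sites(results, chain_table_by_partner: dict,
                           top_k: int = 30) -> pd.DataFrame:
    """Partner-specific interface residues of one chain with common-site masking.

    For each partner, the pair prediction of the shared chain against that
    partner is converted to per-residue scores; residues appearing in the
    top-k of two or more partners are flagged ``common`` (and can be removed
    to display exclusively partner-specific sites).

    Parameters
    ----------
    results : PairInterfaceResults
        A fitted pair-trained model.
    chain_table_by_partner : dict
        partner_id -> ContactTable whose *ligand* side is the shared chain
        and whose receptor side is that partner.
    top_k : int
        Number of top-scoring residues considered per partner.
    """
    if len(chain_table_by_partner) < 2:
        raise ValueError("need at least two partners to compare interfaces")
    per_partner = {}
    refs = None
    for partner, table in chain_table_by_partner.items():
        matrix = results.predict_complex(table)
        lig_scores, _ = pairs_to_single(matrix)
        per_partner[partner] = lig_scores
        if refs is None:
            refs = table.ligand_residues
        elif [r[2] for r in refs] != [r[2] for r in table.ligand_residues]:
            raise ValueError("shared chain differs between partner tables")

    top_sets = {}
    for partner, s in per_partner.items():
        k = min(top_k, len(s))
        top_sets[partner] = set(np.argsort(-s, kind="stable")[:k])
    counts = np.zeros(len(refs), dtype=int)
    for members in top_sets.values():
        for i in members:
            counts[i] += 1

    rows = []
    for partner, s in per_partner.items():
        for i, ((chain, idx, aa), score) in enumerate(zip(refs, s)):
            in_top = i in top_sets[partner]
            rows.append((partner, chain, idx, aa, float(score), in_top,
                         bool(in_top and counts[i] >= 2)))
    return pd.DataFrame(
        rows, columns=["partner", "chain", "seq_index", "aa",
                       "score", "top_k", "common"]
    )
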