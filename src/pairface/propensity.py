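"""Residue-pair and single-residue interface contact propensities.

For residue types i and j, the pair propensity is the ratio of the observed
number of inter-chain contacts O_ij to the number expected if contacts were
distributed uniformly over all enumerated ligand x receptor residue pairs,

    E_ij = pair_count_ij / total_pairs * total_contacts,
    P_ij = O_ij / E_ij,

where pair_count_ij accumulates, complex by complex, the products of the
side-specific type counts (N_i ligand x N_j receptor), symmetrized over the
unordered type pair.  Overrepresentation is assessed with a chi-squared
statistic (O - E)^2 / E against the 1-degree-of-freedom distribution.

The single-residue propensity of type i is the relative frequency of type i
in the interface divided by the relative frequency of all residues in the
interface; a value above 1 means enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .alphabet import AA_ALPHABET, AA_INDEX, N_AA
from .structure import ContactTable, pool_single_residue_labels

__all__ = [
    "PairCountSummary", "PropensityModel", "PropensityResults",
    "count_pairs", "expected_contacts", "pair_propensity",
    "chi_squared", "chi_squared_pvalue", "single_residue_propensity",
]


@dataclass
class PairCountSummary:
    """Accumulated counts per unordered residue-type pair.

    ``pair_count`` and ``observed`` are symmetric 20x20 matrices holding the
    unordered-pair value in both (i, j) and (j, i); totals sum each unordered
    pair once (upper triangle including the diagonal).
    """

    pair_count: np.ndarray
    observed: np.ndarray
    n_complexes: int = 0

    def __post_init__(self) -> None:
        self.pair_count = np.asarray(self.pair_count, dtype=np.int64)
        self.observed = np.asarray(self.observed, dtype=np.int64)
        for m in (self.pair_count, self.observed):
            if m.shape != (N_AA, N_AA) or (m < 0).any() or not (m == m.T).all():
                raise ValueError("count matrices must be symmetric, non-negative, 20x20")

    @staticmethod
    def _triu_sum(m: np.ndarray) -> int:
        return int(m[np.triu_indices(N_AA)].sum())

    @property
    def total_pairs(self) -> int:
        return self._triu_sum(self.pair_count)

    @property
    def total_contacts(self) -> int:
        return self._triu_sum(self.observed)

    def __add__(self, other: "PairCountSummary") -> "PairCountSummary":
        return PairCountSummary(
            self.pair_count + other.pair_count,
            self.observed + other.observed,
            self.n_complexes + other.n_complexes,
        )


def _type_counts(residues) -> np.ndarray:
    counts = np.zeros(N_AA, dtype=np.int64)
    for _, _, aa in residues:
        if aa not in AA_INDEX:
            raise ValueError(f"unknown residue type {aa!r}")
        counts[AA_INDEX[aa]] += 1
    return counts


def count_pairs(contact_tables) -> PairCountSummary:
    """Accumulate pair counts and observed contacts over complexes.

    Per complex, the ordered product N_i(ligand) x N_j(receptor) is folded
    into the unordered type pair: heterotypic pairs get both orders
    (N_i^L N_j^R + N_j^L N_i^R), homotypic pairs are counted once.
    """
    pair_count = np.zeros((N_AA, N_AA), dtype=np.int64)
    observed = np.zeros((N_AA, N_AA), dtype=np.int64)
    n = 0
    for table in contact_tables:
        n += 1
        nl = _type_counts(table.ligand_residues)
        nr = _type_counts(table.receptor_residues)
        ordered = np.outer(nl, nr)
        sym = ordered + ordered.T
        np.fill_diagonal(sym, np.diag(ordered))
        pair_count += sym

        lig_idx = np.array([AA_INDEX[aa] for _, _, aa in table.ligand_residues])
        rec_idx = np.array([AA_INDEX[aa] for _, _, aa in table.receptor_residues])
        ii, jj = np.nonzero(table.labels)
        obs_ordered = np.zeros((N_AA, N_AA), dtype=np.int64)
        np.add.at(obs_ordered, (lig_idx[ii], rec_idx[jj]), 1)
        obs_sym = obs_ordered + obs_ordered.T
        np.fill_diagonal(obs_sym, np.diag(obs_ordered))
        observed += obs_sym
    return PairCountSummary(pair_count, observed, n)


def expected_contacts(pair_count, total_pairs, total_contacts):
    """Expected contacts under uniform distribution over enumerated pairs."""
    if np.any(np.asarray(total_pairs) <= 0):
        raise ValueError("total_pairs must be positive")
    return np.asarray(pair_count, dtype=float) / total_pairs * total_contacts


def pair_propensity(observed, expected):
    """Observed / expected contact ratio; NaN where expected is zero."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(expected > 0, observed / expected, np.nan)
    return out if out.ndim else float(out)


def chi_squared(observed, expected):
    """(O - E)^2 / E, the 1-df goodness-of-fit statistic per type pair."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    out = (observed - expected) ** 2 / expected
    return out if out.ndim else float(out)


def chi_squared_pvalue(chi2):
    """Upper-tail probability of the chi-squared distribution with 1 df."""
    chi2 = np.asarray(chi2, dtype=float)
    if np.any(chi2 < 0):
        raise ValueError("chi-squared statistic cannot be negative")
    out = _chi2_dist.sf(chi2, df=1)
    return out if out.ndim else float(out)


def single_residue_propensity(contact_tables) -> pd.Series:
    """Per-type interface propensity pooled over both sides of all complexes."""
    total = np.zeros(N_AA, dtype=np.int64)
    interface = np.zeros(N_AA, dtype=np.int64)
    for table in contact_tables:
        labels = pool_single_residue_labels(table)
        for aa, lab in zip(labels["aa"], labels["label"]):
            k = AA_INDEX[aa]
            total[k] += 1
            interface[k] += lab
    if interface.sum() == 0:
        raise ValueError("no interface residues in the pooled data")
    overall = interface.sum() / total.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total > 0, (interface / np.maximum(total, 1)) / overall, np.nan)
    return pd.Series(prop, index=list(AA_ALPHABET), name="propensity")


class PropensityModel:
    """Contact-propensity analysis of a set of labelled complexes.

    Parameters
    ----------
    contact_tables : sequence of ContactTable
        Per-complex binary contact labels over all ligand x receptor pairs.
    """

    def __init__(self, contact_tables):
        self.contact_tables = list(contact_tables)
        if not self.contact_tables:
            raise ValueError("need at least one contact table")

    def fit(self) -> "PropensityResults":
        summary = count_pairs(self.contact_tables)
        single = single_residue_propensity(self.contact_tables)
        return PropensityResults(summary, single)


@dataclass
class PropensityResults:
    """Fitted propensity tables with chi-squared significance."""

    counts: PairCountSummary
    single: pd.Series
    pair_table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        tp, tc = self.counts.total_pairs, self.counts.total_contacts
        rows = []
        for i in range(N_AA):
            for j in range(i, N_AA):
                pc = int(self.counts.pair_count[i, j])
                obs = int(self.counts.observed[i, j])
                if pc == 0:
                    exp = prop = x2 = p = np.nan
                else:
                    exp = expected_contacts(pc, tp, tc)
                    prop = pair_propensity(obs, exp)
                    x2 = chi_squared(obs, exp) if exp > 0 else np.nan
                    p = chi_squared_pvalue(x2) if np.isfinite(x2) else np.nan
                rows.append(
                    (f"{AA_ALPHABET[i]}-{AA_ALPHABET[j]}", pc, prop, obs, exp, x2, p)
                )
        table = pd.DataFrame(
            rows,
            columns=["pair", "pair_count", "propensity", "observed",
                     "expected", "chi2", "p_value"],
        )
        self.pair_table = table.sort_values(
            "p_value", kind="mergesort", na_position="last"
        ).reset_index(drop=True)

    @property
    def total_pairs(self) -> int:
        return self.counts.total_pairs

    @property
    def total_contacts(self) -> int:
        return self.counts.total_contacts

    def to_tsv(self, path) -> None:
        self.pair_table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, top: int = 10) -> str:
        head = self.pair_table.head(top)
        lines = [
            "Contact propensity summary",
            f"  complexes:      {self.counts.n_complexes}",
            f"  residue pairs:  {self.total_pairs}",
            f"  contacts:       {self.total_contacts}",
            "",
            f"Top {top} type pairs by p-value:",
            head.to_string(
                index=False,
                formatters={
                    "propensity": "{:.2f}".format,
                    "expected": "{:.1f}".format,
                    "chi2": "{:.1f}".format,
                    "p_value": "{:.3g}".format,
                },
            ),
        ]
        return "\n".join(lines)
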