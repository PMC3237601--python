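"""Complex structures, chain pooling and inter-chain contact labelling.

A docking-benchmark complex has a *ligand* side and a *receptor* side, each
possibly made of several protein chains.  Residue pairs are enumerated only
across the two sides — contacts within the chains of one side are ignored —
and a pair is labelled as binding when any atom of one residue lies within
``cutoff`` (default 6.0 Å) of any atom of the other.  With m1, m2 residues in
the ligand chains and n1, n2 in the receptor chains, exactly
(m1+m2) x (n1+n2) pairs are labelled.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .alphabet import AA_INDEX, THREE_TO_ONE, check_aa

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0


@dataclass
class ResidueRecord:
    """One residue: chain id, 1-based sequential index, type and atom coords.

    ``seq_index`` is an internal gap-free index per chain, decoupled from the
    author numbering of the source file (kept in ``author_id``); window
    arithmetic in the feature encoder relies on it being contiguous.
    """

    chain_id: str
    seq_index: int
    aa_type: str
    atoms: np.ndarray  # (n_atoms, 3) in Angstrom
    author_id: str = ""

    def __post_init__(self) -> None:
        check_aa(self.aa_type)
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        if self.atoms.shape[0] == 0:
            raise ValueError(
                f"residue {self.chain_id}{self.seq_index} ({self.aa_type}) has no atoms"
            )


Chain = list  # list[ResidueRecord]


@dataclass
class ComplexStructure:
    """Ligand / receptor chain groups; the unit of leave-one-out evaluation."""

    complex_id: str
    ligand_chains: list
    receptor_chains: list

    def __post_init__(self) -> None:
        if not self.ligand_chains or not self.receptor_chains:
            raise ValueError("complex needs at least one chain on each side")
        ids = [c[0].chain_id for c in self.ligand_chains + self.receptor_chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in complex {self.complex_id}: {ids}")

    @property
    def ligand_residues(self) -> list:
        return [r for chain in self.ligand_chains for r in chain]

    @property
    def receptor_residues(self) -> list:
        return [r for chain in self.receptor_chains for r in chain]

    def chain_sequence(self, chain_id: str) -> str:
        for chain in self.ligand_chains + self.receptor_chains:
            if chain[0].chain_id == chain_id:
                return "".join(r.aa_type for r in chain)
        raise KeyError(f"chain {chain_id!r} not in complex {self.complex_id}")

    @property
    def chain_ids(self) -> list:
        return [c[0].chain_id for c in self.ligand_chains + self.receptor_chains]


@dataclass
class ContactTable:
    """Binary labels for every ligand x receptor residue pair of one complex.

    ``labels`` is an (m, n) 0/1 matrix over the pooled ligand residues (rows)
    and pooled receptor residues (columns); ``min_dist`` holds the
    corresponding minimum any-atom distances when derived from coordinates.
    """

    complex_id: str
    ligand_residues: list  # [(chain_id, seq_index, aa_type), ...]
    receptor_residues: list
    labels: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    min_dist: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        m, n = len(self.ligand_residues), len(self.receptor_residues)
        if self.labels.shape != (m, n):
            raise ValueError(
                f"label matrix shape {self.labels.shape} != ({m}, {n})"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_pairs(self) -> int:
        return self.labels.size

    @property
    def n_contacts(self) -> int:
        return int(self.labels.sum())

    def ligand_sequence(self) -> str:
        return "".join(aa for _, _, aa in self.ligand_residues)

    def receptor_sequence(self) -> str:
        return "".join(aa for _, _, aa in self.receptor_residues)

    def transpose(self) -> "ContactTable":
        """Swap the ligand and receptor roles (labels unchanged)."""
        return ContactTable(
            self.complex_id,
            list(self.receptor_residues),
            list(self.ligand_residues),
            self.labels.T.copy(),
            self.cutoff,
            None if self.min_dist is None else self.min_dist.T.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (lc, li, la) in enumerate(self.ligand_residues):
            for j, (rc, ri, ra) in enumerate(self.receptor_residues):
                rows.append(
                    (
                        self.complex_id, lc, li, la, rc, ri, ra,
                        np.nan if self.min_dist is None else self.min_dist[i, j],
                        int(self.labels[i, j]),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "complex_id", "ligand_chain", "ligand_idx", "ligand_aa",
                "receptor_chain", "receptor_idx", "receptor_aa",
                "min_dist", "label",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_contact_table(path) -> ContactTable:
    """Read a ContactTable back from its TSV export."""
    df = pd.read_csv(path, sep="\t")
    lig = list(dict.fromkeys(
        zip(df["ligand_chain"], df["ligand_idx"], df["ligand_aa"])
    ))
    rec = list(dict.fromkeys(
        zip(df["receptor_chain"], df["receptor_idx"], df["receptor_aa"])
    ))
    lig_pos = {r: k for k, r in enumerate(lig)}
    rec_pos = {r: k for k, r in enumerate(rec)}
    labels = np.zeros((len(lig), len(rec)), dtype=np.int8)
    dist = np.full((len(lig), len(rec)), np.nan)
    for row in df.itertuples(index=False):
        i = lig_pos[(row.ligand_chain, row.ligand_idx, row.ligand_aa)]
        j = rec_pos[(row.receptor_chain, row.receptor_idx, row.receptor_aa)]
        labels[i, j] = row.label
        dist[i, j] = row.min_dist
    return ContactTable(
        complex_id=str(df["complex_id"].iloc[0]),
        ligand_residues=lig,
        receptor_residues=rec,
        labels=labels,
        min_dist=None if np.isnan(dist).all() else dist,
    )


def min_atom_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues."""
    return float(cdist(res_a.atoms, res_b.atoms).min())


def read_complex(pdb_source, ligand_chain_ids, receptor_chain_ids,
                 complex_id: str | None = None) -> ComplexStructure:
    """Read a PDB file and pool the requested chains into a complex.

    Only standard amino acids (plus unambiguous modified residues such as
    MSE, mapped to their parent) are kept; waters, heteroatoms and chains not
    listed are dropped.  The first alternate location is used and residues
    are renumbered 1..L per chain in file order.
    """
    from Bio.PDB import PDBParser

    ligand_chain_ids = list(ligand_chain_ids)
    receptor_chain_ids = list(receptor_chain_ids)
    overlap = set(ligand_chain_ids) & set(receptor_chain_ids)
    if overlap:
        raise ValueError(f"chains on both sides: {sorted(overlap)}")

    if complex_id is None:
        complex_id = Path(str(pdb_source)).stem if not hasattr(pdb_source, "read") else "complex"

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if hasattr(pdb_source, "read"):
            model = parser.get_structure(complex_id, pdb_source)[0]
        else:
            model = parser.get_structure(complex_id, str(pdb_source))[0]

    present = {chain.id: chain for chain in model}

    def build(chain_id: str) -> list:
        if chain_id not in present:
            raise KeyError(
                f"chain {chain_id!r} not found in {complex_id} "
                f"(present: {sorted(present)})"
            )
        residues = []
        last_num = None
        for res in present[chain_id]:
            resname = res.get_resname().strip()
            if resname not in THREE_TO_ONE:
                if res.id[0] == " ":
                    logger.warning(
                        "%s/%s: dropping non-standard residue %s %s",
                        complex_id, chain_id, resname, res.id[1],
                    )
                continue
            coords = np.array([a.get_coord() for a in res], dtype=float)
            num = res.id[1]
            if last_num is not None and num > last_num + 1:
                logger.info(
                    "%s/%s: chain break before residue %s (gap of %d); "
                    "treating observed residues as sequence-adjacent",
                    complex_id, chain_id, num, num - last_num - 1,
                )
            last_num = num
            residues.append(
                ResidueRecord(
                    chain_id=chain_id,
                    seq_index=len(residues) + 1,
                    aa_type=THREE_TO_ONE[resname],
                    atoms=coords,
                    author_id=f"{num}{res.id[2].strip()}",
                )
            )
        if not residues:
            raise ValueError(f"chain {chain_id!r} of {complex_id} has no standard residues")
        return residues

    return ComplexStructure(
        complex_id=complex_id,
        ligand_chains=[build(c) for c in ligand_chain_ids],
        receptor_chains=[build(c) for c in receptor_chain_ids],
    )


def residue_index_map(complex: ComplexStructure) -> pd.DataFrame:
    """Mapping table: internal sequential index <-> author PDB numbering."""
    rows = [
        (complex.complex_id, side, r.chain_id, r.seq_index, r.aa_type, r.author_id)
        for side, chains in (
            ("ligand", complex.ligand_chains),
            ("receptor", complex.receptor_chains),
        )
        for chain in chains
        for r in chain
    ]
    return pd.DataFrame(
        rows, columns=["complex_id", "side", "chain", "seq_index", "aa", "author_id"]
    )


def extract_contacts(complex: ComplexStructure,
                     cutoff: float = DEFAULT_CUTOFF) -> ContactTable:
    """Label every ligand x receptor residue pair at the any-atom cutoff.

    A pair is binding (label 1) iff its minimum any-atom distance is <= cutoff;
    the boundary is inclusive.
    """
    lig = complex.ligand_residues
    rec = complex.receptor_residues
    dist = np.empty((len(lig), len(rec)))
    for i, ra in enumerate(lig):
        for j, rb in enumerate(rec):
            dist[i, j] = cdist(ra.atoms, rb.atoms).min()
    labels = (dist <= cutoff).astype(np.int8)
    return ContactTable(
        complex_id=complex.complex_id,
        ligand_residues=[(r.chain_id, r.seq_index, r.aa_type) for r in lig],
        receptor_residues=[(r.chain_id, r.seq_index, r.aa_type) for r in rec],
        labels=labels,
        cutoff=cutoff,
        min_dist=dist,
    )


def pool_single_residue_labels(contacts: ContactTable) -> pd.DataFrame:
    """Per-residue binding labels pooled over both sides of one complex.

    A residue is labelled 1 iff it participates in at least one binding pair.
    Ligand residues come first, in table order, then receptor residues.
    """
    lig_labels = contacts.labels.max(axis=1, initial=0)
    rec_labels = contacts.labels.max(axis=0, initial=0)
    rows = [
        (contacts.complex_id, "ligand", c, i, aa, int(lab))
        for (c, i, aa), lab in zip(contacts.ligand_residues, lig_labels)
    ] + [
        (contacts.complex_id, "receptor", c, i, aa, int(lab))
        for (c, i, aa), lab in zip(contacts.receptor_residues, rec_labels)
    ]
    return pd.DataFrame(
        rows, columns=["complex_id", "side", "chain", "seq_index", "aa", "label"]
    )
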