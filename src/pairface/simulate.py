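"""Synthetic complexes, PSSMs and decoy sets with known ground truth.

The generator emulates the statistical structure of a docking-benchmark
data set: complexes of one or more chains per side, a planted interface in
which contacting residue-type pairs are drawn with configurable enrichment
multipliers over a background composition, profile matrices peaked at the
true residue, and decoy pose sets containing near-native and shuffled
poses.  Geometry is deliberately stylised — one (or a few) dummy atoms per
residue, contact pairs placed at well-separated sites 4 Å apart and
everything else far away — so that the 6.0-Å any-atom extractor recovers
the planted contact table *exactly*.  Every fixture is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_ALPHABET, AA_INDEX, N_AA, ONE_TO_THREE
from .decoys import DecoyPose
from .features import PSSMProfile, write_pssm
from .structure import ComplexStructure, ContactTable, ResidueRecord

__all__ = [
    "FixtureConfig", "generate_complex", "generate_pssm", "generate_decoy_set",
    "generate_fixture_set", "write_pdb", "write_fasta",
    "expected_pair_propensity", "DEFAULT_PAIR_PREFERENCES",
]

# Planted pair-type enrichments: the strongest enriched and depleted
# residue-type pairs seen in real protein-protein interfaces, at their
# observed propensity magnitudes.
DEFAULT_PAIR_PREFERENCES = {
    ("D", "R"): 2.9,
    ("R", "Y"): 3.0,
    ("N", "Y"): 3.0,
    ("R", "W"): 3.6,
    ("E", "K"): 1.9,
    ("A", "V"): 0.3,
    ("A", "L"): 0.5,
    ("L", "V"): 0.5,
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic data set (seed is mandatory)."""

    seed: int
    n_complexes: int = 20
    ligand_length: tuple = (30, 30)
    receptor_length: tuple = (30, 30)
    n_ligand_chains: int = 1
    n_receptor_chains: int = 1
    interface_size: tuple = (10, 10)  # planted contact pairs per complex
    pair_preferences: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_PREFERENCES))
    background_freq: tuple = tuple([1.0 / N_AA] * N_AA)
    pssm_signal: float = 5.0
    pssm_noise: float = 1.0
    contact_distance: float = 4.0
    site_spacing: float = 25.0
    atoms_per_residue: int = 1

    def __post_init__(self) -> None:
        for name in ("ligand_length", "receptor_length", "interface_size"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        if any(m <= 0 for m in self.pair_preferences.values()):
            raise ValueError("pair-preference multipliers must be positive")
        if not np.isclose(sum(self.background_freq), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if self.contact_distance >= 6.0 or self.site_spacing <= 12.0:
            raise ValueError("geometry must keep contacts inside and "
                             "non-contacts outside the 6.0 A cutoff")


def _multiplier_matrix(preferences: dict) -> np.ndarray:
    mult = np.ones((N_AA, N_AA))
    for (a, b), m in preferences.items():
        i, j = AA_INDEX[a], AA_INDEX[b]
        mult[i, j] = mult[j, i] = m
    return mult


def expected_pair_propensity(config: FixtureConfig, aa_i: str, aa_j: str) -> float:
    """Theoretical propensity the planted enrichment induces for one type pair.

    Contacts are drawn with probability proportional to f_i f_j m_ij over
    ordered (ligand, receptor) type pairs, while enumerated pairs follow
    f_i f_j alone, so the observed/expected ratio tends to m_ij / Z with
    Z = sum f_i f_j m_ij the mean multiplier under the background.
    """
    f = np.asarray(config.background_freq)
    mult = _multiplier_matrix(config.pair_preferences)
    z = float(f @ mult @ f)
    return mult[AA_INDEX[aa_i], AA_INDEX[aa_j]] / z


def _draw_int(rng, lo_hi) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def generate_complex(config: FixtureConfig, rng: np.random.Generator,
                     complex_id: str = "synth"):
    """One synthetic complex plus its ground-truth contact table.

    The planted interface is a matching: each contacting ligand residue
    touches exactly one receptor residue at ``contact_distance`` Å inside a
    site separated from all other sites, while every non-contacting
    cross-side pair is hundreds of Å apart.
    """
    lig_lengths = [_draw_int(rng, config.ligand_length)
                   for _ in range(config.n_ligand_chains)]
    rec_lengths = [_draw_int(rng, config.receptor_length)
                   for _ in range(config.n_receptor_chains)]
    m, n = sum(lig_lengths), sum(rec_lengths)
    k = _draw_int(rng, config.interface_size)
    if k > min(m, n):
        raise ValueError(
            f"interface of {k} pairs infeasible for chains of {m} x {n} residues"
        )

    freq = np.asarray(config.background_freq)
    lig_types = rng.choice(N_AA, size=m, p=freq)
    rec_types = rng.choice(N_AA, size=n, p=freq)

    lig_sites = rng.choice(m, size=k, replace=False)
    rec_sites = rng.choice(n, size=k, replace=False)
    mult = _multiplier_matrix(config.pair_preferences)
    pair_prob = np.outer(freq, freq) * mult
    pair_prob /= pair_prob.sum()
    drawn = rng.choice(N_AA * N_AA, size=k, p=pair_prob.ravel())
    for s, (li, ri) in enumerate(zip(lig_sites, rec_sites)):
        lig_types[li] = drawn[s] // N_AA
        rec_types[ri] = drawn[s] % N_AA

    # coordinates: contact sites along x at y=0 / y=contact_distance;
    # everything else on two distant lines
    lig_xyz = np.zeros((m, 3))
    rec_xyz = np.zeros((n, 3))
    far_l = iter(range(m))
    far_r = iter(range(n))
    in_lig = np.zeros(m, dtype=bool)
    in_rec = np.zeros(n, dtype=bool)
    in_lig[lig_sites] = True
    in_rec[rec_sites] = True
    for s, (li, ri) in enumerate(zip(lig_sites, rec_sites)):
        lig_xyz[li] = (config.site_spacing * s, 0.0, 0.0)
        rec_xyz[ri] = (config.site_spacing * s, config.contact_distance, 0.0)
    for li in np.nonzero(~in_lig)[0]:
        lig_xyz[li] = (-500.0 - 10.0 * next(far_l), 0.0, 0.0)
    for ri in np.nonzero(~in_rec)[0]:
        rec_xyz[ri] = (500.0 + 10.0 * next(far_r), 300.0, 0.0)

    def atoms_for(center):
        if config.atoms_per_residue == 1:
            return center[None, :]
        jitter = rng.uniform(-0.4, 0.4, size=(config.atoms_per_residue - 1, 3))
        return np.vstack([center[None, :], center + jitter])

    def build_chains(lengths, types, xyz, chain_ids):
        chains, offset = [], 0
        for cid, L in zip(chain_ids, lengths):
            chain = [
                ResidueRecord(
                    chain_id=cid, seq_index=p + 1,
                    aa_type=AA_ALPHABET[types[offset + p]],
                    atoms=atoms_for(xyz[offset + p]),
                    author_id=str(p + 1),
                )
                for p in range(L)
            ]
            chains.append(chain)
            offset += L
        return chains

    lig_ids = [chr(ord("A") + c) for c in range(config.n_ligand_chains)]
    rec_ids = [chr(ord("R") + c) for c in range(config.n_receptor_chains)]
    structure = ComplexStructure(
        complex_id=complex_id,
        ligand_chains=build_chains(lig_lengths, lig_types, lig_xyz, lig_ids),
        receptor_chains=build_chains(rec_lengths, rec_types, rec_xyz, rec_ids),
    )

    labels = np.zeros((m, n), dtype=np.int8)
    labels[lig_sites, rec_sites] = 1
    truth = ContactTable(
        complex_id=complex_id,
        ligand_residues=[(r.chain_id, r.seq_index, r.aa_type)
                         for r in structure.ligand_residues],
        receptor_residues=[(r.chain_id, r.seq_index, r.aa_type)
                           for r in structure.receptor_residues],
        labels=labels,
    )
    return structure, truth


def generate_pssm(sequence: str, signal: float, noise: float,
                  rng: np.random.Generator, chain_id: str = "") -> PSSMProfile:
    """Profile with log-odds peaked (strength ``signal``) at the true residue.

    Values are rounded to integers, matching the convention of real
    iterative-search profiles, which also makes ASCII round-trips exact.
    """
    L = len(sequence)
    matrix = noise * rng.standard_normal((L, N_AA))
    for pos, aa in enumerate(sequence):
        matrix[pos, AA_INDEX[aa]] += signal
    return PSSMProfile(chain_id=chain_id, matrix=np.round(matrix),
                       sequence=sequence)


def generate_decoy_set(truth: ContactTable, n_poses: int,
                       rng: np.random.Generator, n_near_native: int = 1,
                       rank_noise: float = 2.0):
    """Synthetic decoy poses for one complex.

    Near-native poses keep the true contact set (RMSD drawn below 2.5 Å);
    shuffled decoys place the same number of contacts uniformly at random
    (RMSD 5-20 Å).  External ranks order the poses by RMSD perturbed with
    Gaussian noise of scale ``rank_noise`` positions, emulating an imperfect
    external scoring function.
    """
    if n_poses < 2:
        raise ValueError("need at least 2 poses")
    if not 1 <= n_near_native < n_poses:
        raise ValueError("n_near_native must be in [1, n_poses)")
    m, n = truth.labels.shape
    k = max(int(truth.labels.sum()), 1)
    poses = []
    for p in range(n_poses):
        if p < n_near_native:
            contacts = truth.labels.copy()
            rmsd = float(rng.uniform(0.5, 2.0))
        else:
            flat = rng.choice(m * n, size=k, replace=False)
            contacts = np.zeros(m * n, dtype=np.int8)
            contacts[flat] = 1
            contacts = contacts.reshape(m, n)
            rmsd = float(rng.uniform(5.0, 20.0))
        poses.append((f"pose{p + 1:04d}", contacts, rmsd))
    quality = np.array([r for _, _, r in poses])
    noisy = quality + rank_noise * rng.standard_normal(n_poses)
    order = np.argsort(noisy, kind="stable")
    ranks = np.empty(n_poses, dtype=int)
    ranks[order] = np.arange(1, n_poses + 1)
    return [
        DecoyPose(pose_id=pid, contacts=c, external_rank=int(r), native_rmsd=rmsd)
        for (pid, c, rmsd), r in zip(poses, ranks)
    ]


def generate_fixture_set(config: FixtureConfig):
    """n_complexes synthetic complexes with truth tables and chain PSSMs.

    Returns (structures, truth_tables, pssms) where ``pssms`` maps chain id
    to its profile.  Chain ids are made unique across complexes by prefixing
    the complex id.
    """
    rng = np.random.default_rng(config.seed)
    structures, tables, pssms = [], [], {}
    for c in range(config.n_complexes):
        cid = f"synth{c + 1:03d}"
        structure, truth = generate_complex(config, rng, complex_id=cid)
        structure, truth = _prefix_chain_ids(structure, truth, cid)
        structures.append(structure)
        tables.append(truth)
        for chain_id in structure.chain_ids:
            seq = structure.chain_sequence(chain_id)
            pssms[chain_id] = generate_pssm(
                seq, config.pssm_signal, config.pssm_noise, rng, chain_id=chain_id
            )
    return structures, tables, pssms


def _prefix_chain_ids(structure: ComplexStructure, truth: ContactTable, cid: str):
    def rename(chains):
        return [
            [ResidueRecord(f"{cid}:{r.chain_id}", r.seq_index, r.aa_type,
                           r.atoms, r.author_id) for r in chain]
            for chain in chains
        ]

    new_structure = ComplexStructure(
        cid, rename(structure.ligand_chains), rename(structure.receptor_chains)
    )
    new_truth = ContactTable(
        cid,
        [(f"{cid}:{c}", i, aa) for c, i, aa in truth.ligand_residues],
        [(f"{cid}:{c}", i, aa) for c, i, aa in truth.receptor_residues],
        truth.labels,
        truth.cutoff,
    )
    return new_structure, new_truth


# ---------------------------------------------------------------------------
# File writers (the exact dialects the readers consume)

def write_pdb(structure: ComplexStructure, path) -> None:
    """Write coordinate records; one-letter chain ids only."""
    lines = []
    serial = 1
    atom_names = ["CA", "CB", "CG", "CD", "CE", "CZ", "NH", "OH"]
    for chain in structure.ligand_chains + structure.receptor_chains:
        for res in chain:
            cid = res.chain_id.split(":")[-1]
            for a, xyz in enumerate(res.atoms):
                name = atom_names[a % len(atom_names)]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {ONE_TO_THREE[res.aa_type]} "
                    f"{cid}{res.seq_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(structure: ComplexStructure, path) -> None:
    lines = []
    for chain in structure.ligand_chains + structure.receptor_chains:
        lines.append(f">{chain[0].chain_id}")
        lines.append("".join(r.aa_type for r in chain))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_files(config: FixtureConfig, outdir) -> pd.DataFrame:
    """Write PDB/FASTA/PSSM files plus a ground-truth manifest; returns it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structures, tables, pssms = generate_fixture_set(config)
    manifest_rows = []
    for structure, truth in zip(structures, tables):
        write_pdb(structure, outdir / f"{structure.complex_id}.pdb")
        write_fasta(structure, outdir / f"{structure.complex_id}.fasta")
        truth.to_tsv(outdir / f"{structure.complex_id}.contacts.tsv")
        for chain_id in structure.chain_ids:
            short = chain_id.split(":")[-1]
            write_pssm(pssms[chain_id],
                       outdir / f"{structure.complex_id}_{short}.pssm")
        lig = [c.split(":")[-1] for c in
               dict.fromkeys(c for c, _, _ in truth.ligand_residues)]
        rec = [c.split(":")[-1] for c in
               dict.fromkeys(c for c, _, _ in truth.receptor_residues)]
        manifest_rows.append(
            (structure.complex_id, ",".join(lig), ",".join(rec),
             len(truth.ligand_residues), len(truth.receptor_residues),
             truth.n_contacts)
        )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["complex_id", "ligand_chains", "receptor_chains",
                 "n_ligand", "n_receptor", "n_contacts"],
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
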