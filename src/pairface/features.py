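"""Window features for residues and ordered residue-pair patterns.

Each residue is encoded by a sliding window of sparse (one-hot) residue
identities and/or a window of PSSM log-odds columns squashed to (0, 1),
optionally followed by the global amino-acid composition of its chain.  A
residue pair is encoded by concatenating the two per-residue vectors in both
orders (i,j and j,i), giving two training patterns with the same target; at
prediction time the two order scores are averaged, which makes the final
pair score independent of residue order.

Window sizes are odd (1, 3, 5, 7) or 0 (block absent).  During training,
positions whose largest window would run past a chain terminus are excluded;
at prediction time the missing neighbour slots are zero-padded so every pair
receives a score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_ALPHABET, AA_INDEX, N_AA, check_aa

WINDOW_SIZES = (0, 1, 3, 5, 7)
MAX_WINDOW = 7

__all__ = [
    "PSSMProfile", "FeatureSpec", "ChainFeatures",
    "read_pssm", "write_pssm", "read_fasta",
    "sparse_encode", "scale_pssm", "residue_features", "pair_patterns",
    "PairPattern",
]


@dataclass
class PSSMProfile:
    """Per-position 20-column log-odds profile for one chain."""

    chain_id: str
    matrix: np.ndarray  # (L, 20)
    sequence: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_AA:
            raise ValueError(f"PSSM must be Lx{N_AA}, got {self.matrix.shape}")
        if self.sequence and len(self.sequence) != self.matrix.shape[0]:
            raise ValueError(
                f"PSSM rows ({self.matrix.shape[0]}) != sequence length "
                f"({len(self.sequence)})"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FeatureSpec:
    """One cell of the window grid: sparse and PSSM window sizes."""

    sparse_window: int
    pssm_window: int
    use_composition: bool = True

    def __post_init__(self) -> None:
        for w in (self.sparse_window, self.pssm_window):
            if w not in WINDOW_SIZES:
                raise ValueError(f"window size must be one of {WINDOW_SIZES}, got {w}")
        if self.sparse_window == 0 and self.pssm_window == 0:
            raise ValueError("featureless spec (0, 0) is not allowed")

    @property
    def half_width(self) -> int:
        return max(self.sparse_window, self.pssm_window) // 2

    @property
    def residue_length(self) -> int:
        n = (self.sparse_window + self.pssm_window) * N_AA
        return n + (N_AA if self.use_composition else 0)

    @property
    def pair_length(self) -> int:
        return 2 * self.residue_length


@dataclass
class PairPattern:
    """Feature vector of one ordered residue pair and its 0/1 target."""

    values: np.ndarray
    target: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("pattern contains non-finite values")
        if self.target not in (0, 1):
            raise ValueError("target must be 0 or 1")


def sparse_encode(aa_type: str) -> np.ndarray:
    """One-hot 20-vector for a residue type."""
    vec = np.zeros(N_AA)
    vec[AA_INDEX[check_aa(aa_type)]] = 1.0
    return vec


def scale_pssm(log_odds):
    """Logistic squashing 1 / (1 + exp(-x)) of PSSM log-odds."""
    x = np.asarray(log_odds, dtype=float)
    out = 1.0 / (1.0 + np.exp(-x))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII matrix I/O

_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted, and scaled\n"
)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII matrix dialect (log-odds part)."""
    seq = profile.sequence or "X" * len(profile)
    lines = [_PSSM_HEADER.rstrip("\n"), ""]
    lines.append("           " + "".join(f"{aa:>4}" for aa in AA_ALPHABET))
    for pos, (aa, row) in enumerate(zip(seq, profile.matrix), start=1):
        cells = "".join(
            f"{int(v):4d}" if float(v).is_integer() else f"{v:6.2f}" for v in row
        )
        lines.append(f"{pos:5d} {aa} " + cells)
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm(ascii_source, chain_id: str = "", sequence: str | None = None) -> PSSMProfile:
    """Read a PSI-BLAST ASCII matrix (``-out_ascii_pssm`` style).

    Only the first 20 numeric columns (the log-odds block) are used; trailing
    weighted-percentage columns, if present, are ignored.  When ``sequence``
    is given, the residue column is cross-checked against it.
    """
    if hasattr(ascii_source, "read"):
        text = ascii_source.read()
    else:
        text = Path(ascii_source).read_text()
    rows, seq_letters = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            continue
        pos, aa = int(parts[0]), parts[1]
        values = parts[2:]
        if len(values) < N_AA:
            raise ValueError(
                f"line {lineno}: expected >= {N_AA} score columns, got {len(values)}"
            )
        try:
            row = [float(v) for v in values[:N_AA]]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed score column: {exc}") from exc
        if pos != len(rows) + 1:
            raise ValueError(f"line {lineno}: position {pos} out of order")
        rows.append(row)
        seq_letters.append(aa)
    if not rows:
        raise ValueError("no PSSM rows found")
    seq = "".join(seq_letters)
    if sequence is not None and seq != sequence:
        raise ValueError(
            f"PSSM sequence differs from FASTA sequence "
            f"({seq[:10]}... vs {sequence[:10]}...)"
        )
    return PSSMProfile(chain_id=chain_id, matrix=np.array(rows), sequence=seq)


def read_fasta(path) -> dict:
    """Read a FASTA file into {record id: sequence} (via Bio.SeqIO)."""
    from Bio import SeqIO

    handle = path if hasattr(path, "read") else str(path)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


# ---------------------------------------------------------------------------
# Per-chain feature cache

class ChainFeatures:
    """Precomputed window blocks for one chain, sliceable by FeatureSpec.

    The maximum-width (7-residue) sparse and PSSM window blocks are built
    once with zero padding at the termini; any smaller window is a centred
    column slice of these, so encoding all 24 grid specs costs one pass.
    """

    def __init__(self, sequence: str, pssm: PSSMProfile | None = None,
                 scale: bool = True):
        self.sequence = sequence
        self.length = len(sequence)
        if self.length == 0:
            raise ValueError("empty chain")
        for aa in sequence:
            check_aa(aa)
        one_hot = np.zeros((self.length, N_AA))
        idx = [AA_INDEX[aa] for aa in sequence]
        one_hot[np.arange(self.length), idx] = 1.0
        if pssm is not None:
            if len(pssm) != self.length:
                raise ValueError("PSSM length does not match sequence")
            pssm_mat = scale_pssm(pssm.matrix) if scale else pssm.matrix.astype(float)
        else:
            pssm_mat = np.zeros((self.length, N_AA))
        self._sparse_win = self._stack_window(one_hot)
        self._pssm_win = self._stack_window(pssm_mat)
        counts = one_hot.sum(axis=0)
        self.composition = counts / counts.sum()

    @staticmethod
    def _stack_window(mat: np.ndarray) -> np.ndarray:
        """(L, 20) -> (L, 7, 20): rows are the centred 7-window, zero-padded."""
        L = mat.shape[0]
        half = MAX_WINDOW // 2
        padded = np.zeros((L + 2 * half, N_AA))
        padded[half:half + L] = mat
        out = np.empty((L, MAX_WINDOW, N_AA))
        for k in range(MAX_WINDOW):
            out[:, k, :] = padded[k:k + L]
        return out

    def _block(self, stacked: np.ndarray, window: int) -> np.ndarray:
        if window == 0:
            return np.empty((self.length, 0))
        half = window // 2
        centre = MAX_WINDOW // 2
        sl = stacked[:, centre - half:centre + half + 1, :]
        return sl.reshape(self.length, window * N_AA)

    def matrix(self, spec: FeatureSpec) -> np.ndarray:
        """(L, spec.residue_length) feature matrix, termini zero-padded."""
        blocks = [
            self._block(self._sparse_win, spec.sparse_window),
            self._block(self._pssm_win, spec.pssm_window),
        ]
        if spec.use_composition:
            blocks.append(np.broadcast_to(self.composition, (self.length, N_AA)))
        return np.concatenate(blocks, axis=1)

    def valid_mask(self, spec: FeatureSpec) -> np.ndarray:
        """True where the largest window fits inside the chain (training rule)."""
        half = spec.half_width
        mask = np.ones(self.length, dtype=bool)
        if half:
            mask[:half] = False
            mask[self.length - half:] = False
        return mask

    def residue(self, position: int, spec: FeatureSpec, mode: str = "predict"):
        """Feature vector for a 1-based position, or None (EXCLUDED) in training."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside chain of length {self.length}")
        if mode == "training" and not self.valid_mask(spec)[position - 1]:
            return None
        return self.matrix(spec)[position - 1]


def residue_features(sequence: str, pssm: PSSMProfile | None, position: int,
                     spec: FeatureSpec, mode: str = "predict"):
    """Per-residue feature vector; None means EXCLUDED under the training rule."""
    return ChainFeatures(sequence, pssm).residue(position, spec, mode=mode)


def pair_patterns(features_i: np.ndarray, features_j: np.ndarray, label: int):
    """Both-order concatenated patterns (i,j) and (j,i) with the same target."""
    features_i = np.asarray(features_i, dtype=float)
    features_j = np.asarray(features_j, dtype=float)
    if features_i.shape != features_j.shape:
        raise ValueError(
            f"feature length mismatch: {features_i.shape} vs {features_j.shape}"
        )
    return (
        PairPattern(np.concatenate([features_i, features_j]), label),
        PairPattern(np.concatenate([features_j, features_i]), label),
    )
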