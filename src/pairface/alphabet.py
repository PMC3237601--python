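"""Amino-acid alphabet shared by every module.

The 20-letter alphabet is fixed in the order ``ARNDCQEGHILKMFPSTWYV`` and
recorded in all tabular output headers; every one-hot and PSSM column index
refers to this order.
"""

from __future__ import annotations

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = 20

# Three-letter codes, plus the common unambiguous substitutions seen in
# crystal structures (selenomethionine etc.).  Anything else is dropped.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues with an unambiguous parent
    "MSE": "M", "SEC": "C", "PYL": "K", "CSO": "C", "SEP": "S",
    "TPO": "T", "PTR": "Y", "HYP": "P", "MLY": "K",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def check_aa(aa: str) -> str:
    """Validate a one-letter residue type; returns it or raises ValueError."""
    if aa not in AA_INDEX:
        raise ValueError(f"unknown residue type {aa!r}; expected one of {AA_ALPHABET}")
    return aa
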