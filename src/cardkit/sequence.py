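"""Pairwise sequence identity of domain sequences via global alignment.

Sequences can be pulled from structure chains; identity is computed from a
Needleman–Wunsch global alignment (BLOSUM62, affine gaps) as the number of
identical aligned positions divided by the alignment length.
"""

from __future__ import annotations

from Bio.Align import PairwiseAligner, substitution_matrices

from .structures import Frame

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def chain_sequence(frame: Frame, chain_id: str) -> str:
    """One-letter sequence of a chain, in residue order; unknowns become X."""
    seq = []
    for key in frame.residue_keys():
        if key.chain_id == chain_id:
            seq.append(_THREE_TO_ONE.get(key.res_name, "X"))
    if not seq:
        raise ValueError(f"chain {chain_id!r} not found")
    return "".join(seq)


def global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: PairwiseAligner | None = None) -> float:
    """Fraction of identical positions over the global-alignment length."""
    if aligner is None:
        aligner = global_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return identical / len(a)
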