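"""Genetic-code tables and integer encodings shared across modules.

The standard (NCBI table 1) code is taken from Biopython; sequences are
encoded as small integer arrays so the alignment kernels can run under numba.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

NT_ALPHABET = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
BLOSUM62_ALPHABET = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
AA_INDEX = {a: i for i, a in enumerate(BLOSUM62_ALPHABET)}
BLOSUM62 = np.array(_BLOSUM62, dtype=np.int64)

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)

CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: codon index (16*n1 + 4*n2 + n3, A=0 C=1 G=2 T=3) -> index into the BLOSUM62 alphabet
CODON_AA_IDX = np.empty(64, dtype=np.int8)
for _i, _n1 in enumerate(NT_ALPHABET):
    for _j, _n2 in enumerate(NT_ALPHABET):
        for _k, _n3 in enumerate(NT_ALPHABET):
            CODON_AA_IDX[16 * _i + 4 * _j + _k] = AA_INDEX[CODON_TO_AA[_n1 + _n2 + _n3]]


class SequenceParseError(ValueError):
    """Raised on characters outside the expected nucleotide/protein alphabet."""


def encode_nt(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int8 array; anything else is an error."""
    try:
        return np.array([NT_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise SequenceParseError(f"non-ACGT nucleotide {exc.args[0]!r}") from None


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string into BLOSUM62 alphabet indices ('X' for unknowns)."""
    x = AA_INDEX["X"]
    return np.array([AA_INDEX.get(c, x) for c in seq.upper()], dtype=np.int8)


def translate(seq: str, frame: int = 0) -> str:
    """Translate the maximal run of complete codons starting at ``frame``.

    Stop codons are rendered as ``*``.  ``frame`` must be 0, 1 or 2.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq.upper()
    bad = set(s) - set(NT_ALPHABET)
    if bad:
        raise SequenceParseError(f"non-ACGT nucleotide {sorted(bad)[0]!r}")
    end = frame + 3 * ((len(s) - frame) // 3)
    return "".join(CODON_TO_AA[s[i : i + 3]] for i in range(frame, end, 3))


def codons_of(seq: str) -> list[str]:
    """Split a frame-0 nucleotide string into complete codons (tail dropped)."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def is_valid_cds(seq: str) -> bool:
    """ATG start, stop end, length divisible by 3, no internal in-frame stop."""
    s = seq.upper()
    if len(s) < 6 or len(s) % 3 != 0:
        return False
    if not s.startswith("ATG") or s[-3:] not in STOP_CODONS:
        return False
    return all(s[i : i + 3] not in STOP_CODONS for i in range(3, len(s) - 3, 3))
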