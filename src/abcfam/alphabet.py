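"""Amino-acid alphabet, background composition and sequence encoding.

The 20 standard residues are indexed 0..19 in the order of :data:`AA20`;
the ambiguity character ``X`` maps to index 20 and receives a fixed,
mildly negative match score in every profile column so that runs of
unknown residues can neither seed nor extend an alignment profitably.
"""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = 20
X_SCORE = -1.0  # half-bits, applied uniformly at every profile column

_AA_TO_INDEX = {aa: i for i, aa in enumerate(AA20)}
_AA_TO_INDEX["X"] = X_INDEX

# Robinson & Robinson amino-acid composition (the background model used by
# BLAST's default scoring systems), in AA20 order, renormalised to sum to 1.
BACKGROUND = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode an amino-acid string as an int8 index array (X -> 20)."""
    try:
        return np.array([_AA_TO_INDEX[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


def is_valid_sequence(sequence: str) -> bool:
    return len(sequence) >= 1 and all(c in _AA_TO_INDEX for c in sequence)
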