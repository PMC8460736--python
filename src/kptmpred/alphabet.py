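"""The 21-letter working alphabet for peptide windows.

The 20 standard amino acids plus 'Z', a reserved wildcard used for
nonstandard residues (B, J, O, U, X and anything else unrecognized).
Nonstandard letters are remapped to 'Z' on load so every downstream
encoder works over a closed alphabet.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import AlphabetError

logger = logging.getLogger(__name__)

#: Fixed alphabet order; one-hot and pair encoders index into this string.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYZ"
ALPHABET_SIZE = len(ALPHABET)  # 21
WILDCARD = "Z"

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: The five lysine modification types handled by the predictor.
PTM_TYPES = (
    "acetylation",
    "crotonylation",
    "methylation",
    "succinylation",
    "glutarylation",
)

#: Explicit label standing in for an empty modification set in the metrics.
NULL_LABEL = "non-k-ptm"


def sanitize_sequence(sequence: str, *, context: str = "") -> str:
    """Uppercase a protein sequence and map nonstandard residues to 'Z'.

    Logs one warning per sequence naming the replaced letters.
    """
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in AA_TO_INDEX})
    if bad:
        logger.warning(
            "sequence %s: nonstandard residue(s) %s mapped to wildcard '%s'",
            context or "<unnamed>", ",".join(bad), WILDCARD,
        )
        table = str.maketrans({c: WILDCARD for c in bad})
        seq = seq.translate(table)
    return seq


def window_to_indices(window: str) -> np.ndarray:
    """Map a window string to integer indices into :data:`ALPHABET`.

    Raises
    ------
    AlphabetError
        If a character is outside the 21-letter alphabet (windows are
        expected to have been sanitized on load).
    """
    try:
        return np.fromiter((AA_TO_INDEX[c] for c in window), dtype=np.int64,
                           count=len(window))
    except KeyError as exc:
        raise AlphabetError(
            f"residue {exc.args[0]!r} outside alphabet {ALPHABET!r}"
        ) from None


def windows_to_indices(windows) -> np.ndarray:
    """Vectorize a list of equal-length windows into an (n, width) int array."""
    windows = list(windows)
    if not windows:
        return np.empty((0, 0), dtype=np.int64)
    width = len(windows[0])
    out = np.empty((len(windows), width), dtype=np.int64)
    for i, w in enumerate(windows):
        if len(w) != width:
            raise AlphabetError(
                f"window {i} has length {len(w)}, expected {width}")
        out[i] = window_to_indices(w)
    return out
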