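"""The 20-state amino-acid alphabet in canonical PAML order.

Every matrix, frequency vector and alignment column in this package is
indexed in the fixed order ``A R N D C Q E G H I L K M F P S T W Y V``
(the row/column order of PAML ``.dat`` model files).  Ambiguity codes map
to the subset of residues they permit; gaps and unknowns permit all 20.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used by PAML rate-matrix files.
RESIDUES: str = "ARNDCQEGHILKMFPSTWYV"

N_STATES: int = 20

INDEX: dict[str, int] = {aa: i for i, aa in enumerate(RESIDUES)}

#: Ambiguity codes -> permitted residue subsets.  ``B`` is Asn/Asp,
#: ``Z`` is Gln/Glu, ``J`` is Ile/Leu; gap-like codes permit everything.
AMBIGUITY: dict[str, str] = {
    "B": "ND",
    "Z": "QE",
    "J": "IL",
    "X": RESIDUES,
    "-": RESIDUES,
    "?": RESIDUES,
    ".": RESIDUES,
    "*": RESIDUES,
}


class AlphabetError(ValueError):
    """Raised for characters outside the amino-acid alphabet."""


def indicator(symbol: str) -> np.ndarray:
    """Return the 20-vector of permitted states for one sequence symbol.

    Canonical residues give a one-hot vector; ambiguity codes give the
    indicator of their permitted subset.
    """
    s = symbol.upper()
    vec = np.zeros(N_STATES)
    if s in INDEX:
        vec[INDEX[s]] = 1.0
        return vec
    try:
        allowed = AMBIGUITY[s]
    except KeyError:
        raise AlphabetError(f"unknown amino-acid symbol {symbol!r}") from None
    for aa in allowed:
        vec[INDEX[aa]] = 1.0
    return vec


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as an (L, 20) indicator matrix."""
    return np.stack([indicator(c) for c in sequence])
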