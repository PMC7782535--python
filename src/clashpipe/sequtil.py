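"""Small shared helpers for DNA sequence handling.

All sequences in the package are uppercase DNA strings over {A,C,G,T,N};
RNA input (U) is converted to T at the ingest boundary.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding: A=0 C=1 G=2 T=3 N=4; N never matches anything
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Uppercase and convert U residues to T."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3, anything else=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what}: illegal characters {sorted(bad)} (alphabet is A,C,G,T,N)")
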