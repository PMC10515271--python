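"""Small DNA helpers shared by the simulator and the mapper.

Sequences are handled internally as numpy uint8 arrays with the encoding
A=0, C=1, G=2, T=3; reverse complement is then ``3 - x`` reversed.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string to a uint8 array; non-ACGT characters are rejected."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    enc = _ENCODE[raw]
    if (enc == 255).any():
        bad = chr(raw[int(np.argmax(enc == 255))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return enc


def decode(enc: np.ndarray) -> str:
    return _DECODE[enc].tobytes().decode()


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement each row of an encoded read matrix."""
    return (3 - mat)[:, ::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_matrix(encode(seq)[None, :])[0])


def ga_pattern(length: int, offset: int = 0) -> np.ndarray:
    """Encoded perfect (GA)n dinucleotide repeat of the given length.

    ``offset`` sets the phase: even offsets start on G, odd on A.
    """
    pat = np.empty(length, dtype=np.uint8)
    pat[(np.arange(length) + offset) % 2 == 0] = 2  # G
    pat[(np.arange(length) + offset) % 2 == 1] = 0  # A
    return pat
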