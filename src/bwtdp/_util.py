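"""Shared sequence encoding helpers.

DNA is handled internally as uint8 code arrays: A=0, C=1, G=2, T=3.
Sentinels (one per reference sequence) use code 4 in suffix-array space
but are kept out of the searchable alphabet.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
CODE = {c: i for i, c in enumerate(BASES)}
COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 255, dtype=np.uint8)
for _c, _i in CODE.items():
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string to uint8 codes (N -> 4).

    Raises ValueError naming the first offending position for any other
    character.
    """
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(arr == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    return arr


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT$", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out
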