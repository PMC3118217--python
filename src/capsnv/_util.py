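"""Small shared helpers: base encoding, Phred strings, reporting-style rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

BASES = "ACGT"
#: A,C,G,T,N -> 0..4; everything else is rejected upstream.
BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0..T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def phred_to_string(quals: np.ndarray | list[int]) -> str:
    """Integer Phred scores -> Phred+33 string."""
    arr = np.asarray(quals, dtype=np.int64)
    if (arr < 0).any() or (arr > 93).any():
        raise ValueError("Phred scores must lie in [0, 93]")
    return (arr + 33).astype(np.uint8).tobytes().decode("ascii")


def string_to_phred(qual: str) -> np.ndarray:
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    if (arr < 0).any():
        raise ValueError("quality string contains characters below '!'")
    return arr


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, as printed tables do (97.15 -> 97.2)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
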