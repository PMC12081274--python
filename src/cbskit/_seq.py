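"""Nucleotide encoding helpers shared by the scanning and scoring code.

Bases are encoded A=0, C=1, G=2, T=3; anything else (including N) maps to 4.
Code 4 is scored as -inf by all PWM machinery, which makes windows containing
ambiguous bases drop out of max() reductions without special-casing.
"""
from __future__ import annotations

import numpy as np

N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0..T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    return np.where(codes < 4, 3 - codes, N_CODE).astype(np.uint8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement_codes(codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
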