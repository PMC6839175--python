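"""Reference genome container and nucleotide encoding helpers.

Bases are held as uint8 codes 0..3 = A,C,G,T so that variant injection,
error simulation and pileup comparisons are plain integer array ops.
Transitions are the purine<->purine / pyrimidine<->pyrimidine swaps
(A<->G, C<->T), i.e. ``code ^ 2`` in this encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASE_ALPHABET = "ACGT"
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_ALPHABET):
    _CODE_OF[ord(_b)] = _i
    _CODE_OF[ord(_b.lower())] = _i
_CHAR_OF = np.frombuffer(BASE_ALPHABET.encode(), dtype=np.uint8)

# complement: A<->T (0<->3), C<->G (1<->2)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string into uint8 codes 0..3."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE_OF[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _CHAR_OF[codes].tobytes().decode()


def transition_partner(codes: np.ndarray) -> np.ndarray:
    """A<->G, C<->T (the transition for each base code)."""
    return np.asarray(codes) ^ 2


def is_transition(ref_code: np.ndarray, alt_code: np.ndarray) -> np.ndarray:
    return (np.asarray(ref_code) ^ 2) == np.asarray(alt_code)


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


@dataclass
class ReferenceGenome:
    """A haploid reference: one uint8 code array per chromosome."""

    chrom_names: list[str]
    codes: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.chrom_names) == 0:
            raise ValueError("a reference needs at least one chromosome")
        if len(self.chrom_names) != len(self.codes):
            raise ValueError("chrom_names and codes length mismatch")
        if self.total_length == 0:
            raise ValueError("zero-length genome")

    @property
    def sequences(self) -> list[str]:
        return [decode_seq(c) for c in self.codes]

    @property
    def total_length(self) -> int:
        return int(sum(len(c) for c in self.codes))

    def chrom_index(self, name: str) -> int:
        return self.chrom_names.index(name)

    def chrom_length(self, name: str) -> int:
        return len(self.codes[self.chrom_index(name)])

    def base(self, chrom: str, pos: int) -> str:
        """1-based single-base lookup."""
        return BASE_ALPHABET[int(self.codes[self.chrom_index(chrom)][pos - 1])]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring."""
        return decode_seq(self.codes[self.chrom_index(chrom)][start - 1 : end])
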