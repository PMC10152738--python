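"""Sequence primitives: base encoding, genetic code, reference genome container.

Bases are encoded A=0, C=1, G=2, T=3 so that a trinucleotide maps to
``16*b0 + 4*b1 + b2`` (0..63) and a codon to the same index. Amino acids are
carried as uint8 ASCII codes with ``ord('*')`` for stop, which keeps codon
arithmetic fully vectorisable.
"""

from __future__ import annotations

import numpy as np

from .errors import CoordinateError, DataError

BASE_LETTERS = "ACGT"
_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

#: complement in code space (A<->T, C<->G)
COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

A, C, G, T = 0, 1, 2, 3

STOP = ord("*")

_CODON_WEIGHTS = np.array([16, 4, 1], dtype=np.int64)

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: amino-acid ASCII code per codon index (0..63)
AA_CODE = np.zeros(64, dtype=np.uint8)
for _codon, _aa in _GENETIC_CODE.items():
    _idx = int(_CODON_WEIGHTS @ _CODE[np.frombuffer(_codon.encode(), np.uint8)])
    AA_CODE[_idx] = ord(_aa)

STOP_CODONS = tuple(c for c, aa in _GENETIC_CODE.items() if aa == "*")
NONSTOP_CODON_INDICES = np.array(
    [i for i in range(64) if AA_CODE[i] != STOP], dtype=np.int64
)
ATG_INDEX = int(_CODON_WEIGHTS @ _CODE[np.frombuffer(b"ATG", np.uint8)])


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to base codes; rejects non-ACGT characters."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise DataError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return _BASES_U8[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def codon_indices(codes: np.ndarray) -> np.ndarray:
    """Codon indices (0..63) for a code array whose length is a multiple of 3."""
    if len(codes) % 3 != 0:
        raise DataError(f"sequence length {len(codes)} is not a multiple of 3")
    return codes.reshape(-1, 3).astype(np.int64) @ _CODON_WEIGHTS


def translate_codes(codes: np.ndarray) -> str:
    return AA_CODE[codon_indices(codes)].tobytes().decode("ascii")


def translate(seq: str) -> str:
    return translate_codes(encode(seq))


class Genome:
    """In-memory reference genome keyed by chromosome name.

    Sequences are stored as uint8 base-code arrays. Mutable on purpose: the
    synthetic generator plants coding entities by writing into the array.
    """

    def __init__(self, seqs: dict[str, str | np.ndarray]):
        self._codes: dict[str, np.ndarray] = {}
        for chrom, seq in seqs.items():
            if isinstance(seq, str):
                self._codes[chrom] = encode(seq)
            else:
                self._codes[chrom] = np.asarray(seq, dtype=np.uint8)

    @property
    def chroms(self) -> list[str]:
        return list(self._codes)

    def codes(self, chrom: str) -> np.ndarray:
        try:
            return self._codes[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.codes(chrom))

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        codes = self.codes(chrom)
        if start is None:
            return decode(codes)
        if start < 0 or end is None or end > len(codes) or start > end:
            raise CoordinateError(
                f"span [{start},{end}) outside {chrom} of length {len(codes)}"
            )
        return decode(codes[start:end])

    def set_slice(self, chrom: str, start: int, codes: np.ndarray) -> None:
        target = self.codes(chrom)
        end = start + len(codes)
        if start < 0 or end > len(target):
            raise CoordinateError(f"span [{start},{end}) outside {chrom}")
        target[start:end] = codes

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, codes in self._codes.items():
                fh.write(f">{chrom}\n")
                seq = decode(codes)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
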