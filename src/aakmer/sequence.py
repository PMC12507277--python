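"""Nucleotide and amino-acid sequence primitives.

Codon translation under the standard genetic code, reverse complement,
six-frame translation with stop-frame flagging, overlapping k-mer
extraction, and stop-avoiding reverse translation.

Conventions
-----------
* Nucleotide alphabet is ``{A, C, G, T, N}``; input is upper-cased and
  ``U`` is accepted as ``T``.
* Any codon containing ``N`` translates to ``'X'``; k-mers containing
  ``'X'`` or ``'*'`` are never emitted by :func:`extract_kmers`.
* Frame order is fixed: forward offsets 0, 1, 2, then the same offsets
  on the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Sequence

import numpy as np

__all__ = [
    "CODON_TABLE",
    "CODONS_BY_AA",
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "NucleotideSequence",
    "AminoAcidSequence",
    "SixFrameTranslation",
    "canonicalize_nucleotides",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "extract_kmers",
    "reverse_translate",
]

# Standard genetic code (NCBI table 1; codon->AA identical to table 11).
CODON_TABLE = {
    "AAA": "K", "AAC": "N", "AAG": "K", "AAT": "N", "ACA": "T", "ACC": "T", "ACG": "T", "ACT": "T",
    "AGA": "R", "AGC": "S", "AGG": "R", "AGT": "S", "ATA": "I", "ATC": "I", "ATG": "M", "ATT": "I",
    "CAA": "Q", "CAC": "H", "CAG": "Q", "CAT": "H", "CCA": "P", "CCC": "P", "CCG": "P", "CCT": "P",
    "CGA": "R", "CGC": "R", "CGG": "R", "CGT": "R", "CTA": "L", "CTC": "L", "CTG": "L", "CTT": "L",
    "GAA": "E", "GAC": "D", "GAG": "E", "GAT": "D", "GCA": "A", "GCC": "A", "GCG": "A", "GCT": "A",
    "GGA": "G", "GGC": "G", "GGG": "G", "GGT": "G", "GTA": "V", "GTC": "V", "GTG": "V", "GTT": "V",
    "TAA": "*", "TAC": "Y", "TAG": "*", "TAT": "Y", "TCA": "S", "TCC": "S", "TCG": "S", "TCT": "S",
    "TGA": "*", "TGC": "C", "TGG": "W", "TGT": "C", "TTA": "L", "TTC": "F", "TTG": "L", "TTT": "F",
}

# Synonymous codons per residue, sorted; used for reverse translation.
CODONS_BY_AA = {
    "A": ["GCA", "GCC", "GCG", "GCT"],
    "C": ["TGC", "TGT"],
    "D": ["GAC", "GAT"],
    "E": ["GAA", "GAG"],
    "F": ["TTC", "TTT"],
    "G": ["GGA", "GGC", "GGG", "GGT"],
    "H": ["CAC", "CAT"],
    "I": ["ATA", "ATC", "ATT"],
    "K": ["AAA", "AAG"],
    "L": ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"],
    "M": ["ATG"],
    "N": ["AAC", "AAT"],
    "P": ["CCA", "CCC", "CCG", "CCT"],
    "Q": ["CAA", "CAG"],
    "R": ["AGA", "AGG", "CGA", "CGC", "CGG", "CGT"],
    "S": ["AGC", "AGT", "TCA", "TCC", "TCG", "TCT"],
    "T": ["ACA", "ACC", "ACG", "ACT"],
    "V": ["GTA", "GTC", "GTG", "GTT"],
    "W": ["TGG"],
    "Y": ["TAC", "TAT"],
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset(AMINO_ACIDS)


def canonicalize_nucleotides(seq: str) -> str:
    """Upper-case ``seq``, map U->T, and validate the {A,C,G,T,N} alphabet.

    Raises
    ------
    ValueError
        If a character outside the alphabet is present; the message
        names the first offending position (0-based).
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _NT_ALPHABET:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {i} (alphabet is A/C/G/T/N)"
            )
    return s


@dataclass
class NucleotideSequence:
    """A named nucleotide sequence, canonicalized on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = canonicalize_nucleotides(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AminoAcidSequence:
    """A named amino-acid sequence over the 20 standard one-letter codes."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"non-standard amino acid letter(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SixFrameTranslation:
    """The six translation frames of a read with per-frame validity.

    ``frames[i]`` is valid iff it contains no stop codon; only valid
    frames feed k-mer extraction downstream.
    """

    frames: List[str]
    valid: List[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) != 6:
            raise ValueError("exactly six frames required")
        if not self.valid:
            self.valid = ["*" not in f for f in self.frames]

    def valid_frames(self) -> List[str]:
        return [f for f, ok in zip(self.frames, self.valid) if ok]


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N."""
    s = canonicalize_nucleotides(seq)
    return s.translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, offset: int) -> str:
    """Translate ``seq`` from ``offset`` in codon steps; may contain '*'.

    Codons containing N translate to 'X'; trailing 1-2 nt are dropped.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    s = canonicalize_nucleotides(seq)
    out = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame_translate(read: NucleotideSequence | str) -> SixFrameTranslation:
    """All six translation frames of a read, in the fixed order
    (fwd+0, fwd+1, fwd+2, rev+0, rev+1, rev+2)."""
    seq = read.seq if isinstance(read, NucleotideSequence) else canonicalize_nucleotides(read)
    rc = seq.translate(_COMPLEMENT)[::-1]
    frames = [translate_frame(seq, o) for o in (0, 1, 2)]
    frames += [translate_frame(rc, o) for o in (0, 1, 2)]
    return SixFrameTranslation(frames=frames)


def extract_kmers(seq: str, k: int) -> List[str]:
    """All overlapping length-``k`` windows of ``seq`` in order, skipping
    any window containing 'X' or '*'."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "X" in w or "*" in w:
            continue
        out.append(w)
    return out


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """Lazy variant of :func:`extract_kmers`."""
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "X" not in w and "*" not in w:
            yield w


def reverse_translate(aa: str, rng: int | np.random.Generator) -> str:
    """Map an amino-acid string to nucleotides, picking one synonymous
    codon per residue uniformly at random.

    By construction the result contains no stop codon and translates
    back to ``aa`` in frame 0. Deterministic given the seed.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    codons = []
    for i, res in enumerate(aa):
        try:
            choices = CODONS_BY_AA[res]
        except KeyError:
            raise ValueError(
                f"cannot reverse-translate non-standard letter {res!r} at position {i}"
            ) from None
        codons.append(choices[int(gen.integers(len(choices)))])
    return "".join(codons)


def random_aa_string(length: int, rng: np.random.Generator) -> str:
    """Uniform random amino-acid string (test/simulation helper)."""
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)
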