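"""Average molecular weights of protein fragments and DNA duplexes.

Supports the stoichiometry bookkeeping: the τ_c expected for a
candidate complex needs the total mass of protein plus duplex. Average
(not monoisotopic) masses are used throughout, matching how kDa figures
for unlabelled constructs are conventionally quoted.

Protein: sum of average residue masses plus one water; no terminal
modifications. DNA strands: sum of internal nucleotide-monophosphate
residue masses with the standard synthetic-oligo 5′-OH termini
correction (−61.96 Da per strand), switchable to 5′-phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .exceptions import DataError

__all__ = [
    "AA_RESIDUE_MASS",
    "DNA_RESIDUE_MASS",
    "WATER_MASS",
    "DuplexSpec",
    "protein_mw",
    "strand_mw",
    "duplex_mw",
    "check_complement",
    "reverse_complement",
    "read_fasta_range",
    "PAPER_DUPLEXES",
]

#: average amino-acid residue masses (Da), i.e. monomer minus water
AA_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

#: average internal deoxynucleotide-monophosphate residue masses (Da)
DNA_RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}

#: per-strand terminal correction for synthetic 5'-OH oligos (Da)
FIVE_PRIME_OH_CORRECTION = -61.96
#: mass of the HPO3 group restored by a 5'-phosphate (Da)
HPO3_MASS = 79.98

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def protein_mw(sequence: str) -> float:
    """Average molecular weight (Da) of a protein from one-letter codes."""
    seq = sequence.strip().upper()
    if not seq:
        raise DataError("empty protein sequence")
    try:
        total = sum(AA_RESIDUE_MASS[aa] for aa in seq)
    except KeyError as exc:
        raise DataError(f"invalid amino-acid code: {exc.args[0]!r}") from None
    return total + WATER_MASS


def strand_mw(sequence: str, five_prime: str = "OH") -> float:
    """Average molecular weight (Da) of a single DNA strand (5′→3′)."""
    seq = sequence.strip().upper()
    if not seq:
        raise DataError("empty DNA sequence")
    try:
        total = sum(DNA_RESIDUE_MASS[b] for b in seq)
    except KeyError as exc:
        raise DataError(f"invalid DNA base: {exc.args[0]!r}") from None
    total += FIVE_PRIME_OH_CORRECTION
    if five_prime == "phosphate":
        total += HPO3_MASS
    elif five_prime != "OH":
        raise ValueError(f"unknown 5' terminus: {five_prime!r}")
    return total


def reverse_complement(sequence: str) -> str:
    seq = sequence.strip().upper()
    if set(seq) - set("ACGT"):
        raise DataError(f"invalid DNA sequence: {sequence!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def check_complement(strand1: str, strand2: str) -> bool:
    """True iff the two 5′→3′ strands are exact Watson–Crick complements."""
    s1, s2 = strand1.strip().upper(), strand2.strip().upper()
    if len(s1) != len(s2):
        raise DataError(
            f"strand lengths differ: {len(s1)} vs {len(s2)}"
        )
    return reverse_complement(s1) == s2


@dataclass(frozen=True)
class DuplexSpec:
    """A validated B-DNA duplex given as two 5′→3′ strands."""

    strand1: str
    strand2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand1", self.strand1.strip().upper())
        object.__setattr__(self, "strand2", self.strand2.strip().upper())
        if not check_complement(self.strand1, self.strand2):
            raise DataError(
                f"strands are not complementary: {self.strand1} / {self.strand2}"
            )

    @classmethod
    def from_top_strand(cls, strand1: str) -> "DuplexSpec":
        return cls(strand1, reverse_complement(strand1))

    @property
    def length_bp(self) -> int:
        return len(self.strand1)


def duplex_mw(d: DuplexSpec, five_prime: str = "OH") -> float:
    """Average molecular weight (Da) of a DNA duplex (both strands)."""
    return strand_mw(d.strand1, five_prime) + strand_mw(d.strand2, five_prime)


def read_fasta_range(
    path: str | Path, start: int | None = None, end: int | None = None
) -> str:
    """Read the first FASTA record, optionally slicing residues start..end.

    ``start``/``end`` are 1-based inclusive positions in the record's
    own numbering (author numbering when the record is full length).
    """
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise DataError(f"{path}: no FASTA records") from None
    seq = str(record.seq)
    if start is not None or end is not None:
        start = 1 if start is None else start
        end = len(seq) if end is None else end
        if not (1 <= start <= end <= len(seq)):
            raise DataError(
                f"range {start}..{end} outside sequence of length {len(seq)}"
            )
        seq = seq[start - 1 : end]
    return seq


#: the duplexes used in the study, keyed by length (bp); both strands 5'->3'
PAPER_DUPLEXES: dict[int, tuple[str, str]] = {
    17: ("GGCCCTTTTTTTTCTAG", "CTAGAAAAAAAAGGGCC"),
    12: ("TTTAAAAAGTAA", "TTACTTTTTAAA"),
    11: ("TTTAAAAAGTA", "TACTTTTTAAA"),
    10: ("TTTAAAAAGT", "ACTTTTTAAA"),
    9: ("TTTAAAAAG", "CTTTTTAAA"),
}
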