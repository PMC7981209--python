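"""Genome sequence container and FASTA input/output.

A :class:`GenomeSequence` is the object every downstream stage operates on:
a named string over the unambiguous DNA alphabet ``{A, C, G, T}``.  Real
assemblies may contain ambiguity codes; the simulator never emits them, and
the detectors treat any non-ACGT character as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A named nucleotide sequence.

    Parameters
    ----------
    seq_id:
        Identifier (FASTA header word).
    residues:
        Upper-case DNA string.
    """

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.seq_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    def validate_alphabet(self) -> None:
        """Raise if the sequence contains characters outside A/C/G/T."""
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read all records of a FASTA file."""
    return [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
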