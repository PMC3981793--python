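"""FASTA input/output and sequence normalization.

RNA thermometer candidates are usually distributed as 5' UTR sequences, often
in DNA form. Reading therefore uppercases, strips whitespace and converts
T to U; IUPAC ambiguity codes are rejected outright, because folding a window
containing an ``N`` would silently change the meaning of the prediction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaFormatError, SequenceError

_VALID = set("ACGU")
_ACCEPTED = set("ACGUTacgut \t\r\n")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw sequence string to uppercase RNA over {A,C,G,U}.

    Whitespace is stripped, lowercase accepted, and T converted to U.
    Any other character (including IUPAC ambiguity codes such as N or R)
    raises :class:`SequenceError` naming the first offending position
    (1-based, counted over the non-whitespace residues).
    """
    if not raw or not raw.strip():
        raise SequenceError("empty sequence")
    out = []
    pos = 0
    for ch in raw:
        if ch.isspace():
            continue
        pos += 1
        if ch not in _ACCEPTED:
            raise SequenceError(
                f"invalid residue {ch!r} at position {pos}; only A/C/G/U/T are "
                "accepted — resolve ambiguity codes before folding"
            )
        up = ch.upper()
        out.append("U" if up == "T" else up)
    return "".join(out)


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with a record identifier.

    ``residues`` is guaranteed to be a nonempty string over {A,C,G,U}.
    """

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-RNA residues {sorted(bad)}; "
                "use normalize_sequence() first"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> "RnaSequence":
        """1-based inclusive slice, id annotated with the window coordinates."""
        if not (1 <= start <= end <= self.length):
            raise SequenceError(
                f"window [{start}, {end}] outside sequence of length {self.length}"
            )
        return RnaSequence(f"{self.id}:{start}-{end}", self.residues[start - 1 : end])

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        try:
            return cls(id, normalize_sequence(raw))
        except SequenceError as exc:
            raise SequenceError(f"record {id!r}: {exc}") from exc


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into a list of normalized :class:`RnaSequence`.

    Records are returned in file order. An empty file, or a record with an
    empty sequence, raises :class:`FastaFormatError` naming the record.
    """
    path = Path(path)
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


def write_bed(path: str | Path, chrom: str, start_1based: int, end_1based: int,
              name: str = "thermometer") -> None:
    """Write a single annotation interval as BED (0-based, half-open).

    Internal coordinates are 1-based inclusive; the conversion is
    ``bed_start = start - 1``, ``bed_end = end``.
    """
    if start_1based < 1 or end_1based < start_1based:
        raise SequenceError(
            f"invalid interval [{start_1based}, {end_1based}] for BED output"
        )
    with open(path, "w") as handle:
        handle.write(f"{chrom}\t{start_1based - 1}\t{end_1based}\t{name}\n")
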