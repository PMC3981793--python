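"""The secondary-structure container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import StructureError
from .energy import PAIR_TABLE, encode_sequence


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of given length.

    Pairs are 1-based ``(i, j)`` tuples with ``i < j``. Construction enforces
    the purely combinatorial invariants: indices in range, each index in at
    most one pair, and no two pairs crossing. Sequence-dependent rules
    (canonical pairing, minimum hairpin loop) are checked against a concrete
    sequence by :func:`check_structure`, because dot-bracket strings parsed
    from external engines must not be rejected on those grounds.
    """

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        if self.length < 0:
            raise StructureError("negative length")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i}, {j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise StructureError(f"index reused by pair ({i}, {j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if not (l < j):  # i < k < j, so crossing unless nested
                    raise StructureError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def __str__(self) -> str:
        return self.dotbracket

    @classmethod
    def open_chain(cls, length: int) -> "SecondaryStructure":
        return cls(length=length, pairs=frozenset())


def check_structure(residues: str, s: SecondaryStructure) -> None:
    """Validate sequence-dependent invariants of ``s`` against ``residues``.

    Raises :class:`StructureError` if any pair is non-canonical (outside
    AU/UA/CG/GC/GU/UG) or encloses fewer than 3 bases, or if the lengths
    disagree.
    """
    if len(residues) != s.length:
        raise StructureError(
            f"structure length {s.length} != sequence length {len(residues)}")
    enc = encode_sequence(residues)
    for i, j in s.pairs:
        if j - i - 1 < 3:
            raise StructureError(f"pair ({i},{j}) violates the minimum hairpin loop of 3")
        if PAIR_TABLE[enc[i - 1], enc[j - 1]] < 0:
            raise StructureError(
                f"non-canonical pair {residues[i-1]}{residues[j-1]} at ({i},{j})")
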