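"""Dot-bracket parsing and the base-pair distance between structures.

The base-pair distance — the size of the symmetric difference of two
structures' pair sets — is the measure of structural change between the two
temperatures of a scan. It is a metric on structures of a common length.
"""

from __future__ import annotations

from .errors import DotBracketParseError, StructureError
from .structure import SecondaryStructure


def parse_dotbracket(s: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Only balance is enforced; minimum-loop and canonical-pair rules are not
    checked here, so output from external engines with other conventions is
    accepted as long as the parentheses match. Unbalanced input raises
    :class:`DotBracketParseError` carrying the 1-based position of the first
    violation.
    """
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(s, 1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketParseError(
                    f"unmatched ')' at position {pos}", position=pos)
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise DotBracketParseError(
                f"invalid character {ch!r} at position {pos}", position=pos)
    if stack:
        raise DotBracketParseError(
            f"unclosed '(' at position {stack[-1]}", position=stack[-1])
    return SecondaryStructure(length=len(s), pairs=frozenset(pairs))


def bp_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Base-pair distance: |pairs(a) symmetric-difference pairs(b)|.

    Both structures must describe sequences of the same length; structures
    from different windows are never meaningfully comparable.
    """
    if a.length != b.length:
        raise StructureError(
            f"cannot compare structures of lengths {a.length} and {b.length}")
    return len(a.pairs ^ b.pairs)
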