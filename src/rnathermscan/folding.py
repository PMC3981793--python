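"""Secondary-structure prediction for (windowed) sequences.

Provides, over the reduced thermodynamic model of :mod:`rnathermscan.energy`:

* :func:`score_structure` — the model's energy of a given structure; the
  single definition shared by the dynamic program and the test oracle.
* :func:`enumerate_structures` — exhaustive enumeration of all valid
  structures of a short sequence (the brute-force oracle).
* :func:`fold_mfe` — minimum-free-energy structure by a Zuker-style DP.
* :func:`partition_function` / :func:`centroid_structure` — McCaskill-style
  equilibrium base-pair probabilities and the p > 0.5 centroid.
* :func:`fold` — the engine-dispatching entry point used by the scan; external
  thermodynamic folders register through :mod:`rnathermscan.engines`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import INF, MAX_INTERNAL, MIN_HAIRPIN, mfe_tables, pf_outside_window, pf_tables
from .energy import (GAS_CONSTANT, PAIR_TABLE, PAIR_TYPES, EnergyParams, Temperature,
                     as_temperature, default_params, encode_sequence, loop_energy,
                     stack_energy)
from .errors import EngineError, SequenceError, StructureError
from .seqio import RnaSequence
from .structure import SecondaryStructure, check_structure

__all__ = [
    "FoldResult", "PairProbMatrix", "score_structure", "enumerate_structures",
    "fold_mfe", "partition_function", "centroid_structure", "fold",
]

_ENUM_LIMIT = 20


@dataclass(frozen=True)
class FoldResult:
    """A predicted structure together with its energy and fold settings."""

    structure: SecondaryStructure
    energy: float            # kcal/mol
    temperature: Temperature
    mode: str                # "mfe" | "centroid"
    engine: str = "builtin"


@dataclass(frozen=True)
class PairProbMatrix:
    """Equilibrium base-pair probabilities p(i, j), 1-based, i < j."""

    n: int
    _p: np.ndarray           # dense (n, n), upper triangle holds p

    def get(self, i: int, j: int) -> float:
        if not (1 <= i < j <= self.n):
            raise StructureError(f"invalid pair ({i}, {j}) for length {self.n}")
        return float(self._p[i - 1, j - 1])

    def items(self):
        """Iterate over ((i, j), p) entries with p > 0."""
        ii, jj = np.nonzero(self._p)
        for a, b in zip(ii, jj):
            yield (int(a) + 1, int(b) + 1), float(self._p[a, b])

    def validate(self) -> None:
        if np.any(self._p < -1e-12) or np.any(self._p > 1 + 1e-9):
            raise StructureError("pair probability outside [0, 1]")
        row = self._p.sum(axis=1) + self._p.sum(axis=0)
        if np.any(row > 1 + 1e-6):
            raise StructureError("per-index pairing probability exceeds 1")


# ---------------------------------------------------------------------------
# structure energy (single definition shared by DP and oracle)

def _pair_type(residues: str, i: int, j: int) -> int:
    enc_i = "ACGU".index(residues[i - 1])
    enc_j = "ACGU".index(residues[j - 1])
    return int(PAIR_TABLE[enc_i, enc_j])


def score_structure(seq: RnaSequence, s: SecondaryStructure,
                    t: Temperature | float,
                    params: EnergyParams | None = None) -> float:
    """Energy of structure ``s`` on ``seq`` at temperature ``t`` (kcal/mol).

    Sums stack energies over adjacent stacked pairs, hairpin-loop energies
    and internal/bulge-loop energies. Multibranch loops and exterior bases
    contribute nothing; the open chain scores exactly 0.
    """
    params = params or default_params()
    check_structure(seq.residues, s)
    t = as_temperature(t)
    pairs = sorted(s.pairs)
    pair_set = s.pairs
    total = 0.0
    for i, j in pairs:
        # children: pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            child = next(((a, b) for a, b in pairs if a == k), None)
            if child is not None:
                children.append(child)
                k = child[1] + 1
            else:
                k += 1
        if not children:
            total += loop_energy("hairpin", j - i - 1, t, params)
        elif len(children) == 1:
            (a, b) = children[0]
            unpaired = (a - i - 1) + (j - b - 1)
            if unpaired == 0:
                ctx = (PAIR_TYPES[_pair_type(seq.residues, i, j)],
                       PAIR_TYPES[_pair_type(seq.residues, a, b)])
                total += stack_energy(ctx, t, params)
            else:
                total += loop_energy("internal", unpaired, t, params)
        # multibranch: zero beyond the contributions of its branches
    return total


# ---------------------------------------------------------------------------
# brute-force oracle

def enumerate_structures(seq: RnaSequence) -> list[SecondaryStructure]:
    """Exhaustively enumerate every valid structure of a short sequence.

    Includes the open chain; refuses sequences longer than 20 nt to guard
    against combinatorial blowup. Serves as the independent oracle for the
    dynamic programs.
    """
    n = seq.length
    if n > _ENUM_LIMIT:
        raise SequenceError(
            f"enumeration limited to {_ENUM_LIMIT} nt (got {n})")
    enc = encode_sequence(seq.residues)
    cache: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        # all pair sets over 0-based inclusive interval [i, j]
        if j - i < MIN_HAIRPIN + 1:
            return [frozenset()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out = list(rec(i + 1, j))                     # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):   # i paired with k
            if PAIR_TABLE[enc[i], enc[k]] < 0:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append(inner | outer | {(i, k)})
        cache[key] = out
        return out

    return [
        SecondaryStructure(length=n,
                           pairs=frozenset((i + 1, j + 1) for i, j in ps))
        for ps in rec(0, n - 1)
    ]


# ---------------------------------------------------------------------------
# dynamic programs

def _tables_mfe(seq: RnaSequence, t: Temperature | float,
                params: EnergyParams, span: int):
    enc = encode_sequence(seq.residues)
    stack = params.stack_matrix(t)
    hp, il = params.loop_arrays(t, seq.length)
    return enc, mfe_tables(enc, span, PAIR_TABLE, stack, hp, il)


def traceback_window(tables, s: int, e: int) -> frozenset[tuple[int, int]]:
    """Extract the MFE pair set of interval [s, e] (0-based) from DP tables.

    Pairs are returned in absolute (1-based) sequence coordinates.
    """
    V, VC, VK, VL, M, MK, ML, M2, M2K, F, FK = tables
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("F", s, e)]
    while stack:
        kind, i, j = stack.pop()
        if j <= i:
            continue
        if kind == "F":
            k = FK[i, j]
            if k < 0:
                stack.append(("F", i, j - 1))
            else:
                stack.append(("V", k, j))
                if k > i:
                    stack.append(("F", i, k - 1))
        elif kind == "V":
            pairs.append((i + 1, j + 1))
            c = VC[i, j]
            if c == 1:
                stack.append(("V", VK[i, j], VL[i, j]))
            elif c == 2:
                stack.append(("M2", i + 1, j - 1))
        elif kind == "M2":
            k = M2K[i, j]
            if k == -1:
                stack.append(("M2", i, j - 1))
            else:
                stack.append(("M", i, k - 1))
                stack.append(("V", k, j))
        elif kind == "M":
            k = MK[i, j]
            if k == -1:
                stack.append(("M", i, j - 1))
            else:
                stack.append(("V", k, j))
                if ML[i, j]:
                    stack.append(("M", i, k - 1))
    return frozenset(pairs)


def fold_mfe(seq: RnaSequence, t: Temperature | float,
             params: EnergyParams | None = None) -> FoldResult:
    """Minimum-free-energy structure at temperature ``t``.

    The open chain (energy 0) is always a candidate, so the returned energy
    is never positive. The traceback is deterministic: ties are broken in
    favor of hairpin closure, then stacking, then the smallest interior loop,
    then bifurcations with the smallest split point.
    """
    params = params or default_params()
    t = as_temperature(t)
    _, tables = _tables_mfe(seq, t, params, seq.length)
    F = tables[9]
    energy = float(F[0, seq.length - 1]) if seq.length > 1 else 0.0
    pairs = traceback_window(tables, 0, seq.length - 1)
    structure = SecondaryStructure(length=seq.length, pairs=pairs)
    return FoldResult(structure=structure, energy=energy, temperature=t,
                      mode="mfe")


def partition_function(seq: RnaSequence, t: Temperature | float,
                       params: EnergyParams | None = None
                       ) -> tuple[float, PairProbMatrix]:
    """Partition function Z and base-pair probability matrix at ``t``.

    Z sums exp(-E/RT) over every valid structure (the open chain contributes
    1); probabilities come from an inside-outside computation over the same
    model as :func:`fold_mfe`.
    """
    params = params or default_params()
    t = as_temperature(t)
    n = seq.length
    enc = encode_sequence(seq.residues)
    stack = params.stack_matrix(t)
    hp, il = params.loop_arrays(t, n)
    rt = GAS_CONSTANT * t.kelvin
    Z, Zb, Zm, _ = pf_tables(enc, n, PAIR_TABLE, stack, hp, il, rt)
    p = pf_outside_window(0, n - 1, enc, PAIR_TABLE, stack, il, rt, Z, Zb, Zm)
    return float(Z[0, n]), PairProbMatrix(n=n, _p=p)


def centroid_structure(probs: PairProbMatrix) -> SecondaryStructure:
    """Centroid structure: all pairs with equilibrium probability > 0.5.

    In a pseudoknot-free ensemble no two conflicting pairs can both exceed
    probability 1/2, so the thresholded set is always a valid structure.
    """
    pairs = frozenset((i, j) for (i, j), p in probs.items() if p > 0.5)
    return SecondaryStructure(length=probs.n, pairs=pairs)


# ---------------------------------------------------------------------------
# engine dispatch

def fold(seq: RnaSequence, t: Temperature | float, mode: str = "mfe",
         engine: str = "builtin",
         params: EnergyParams | None = None) -> FoldResult:
    """Fold ``seq`` at temperature ``t`` with the requested engine and mode.

    ``mode`` is ``"mfe"`` or ``"centroid"``. The builtin engine uses the
    reduced model; external engines registered via
    :func:`rnathermscan.engines.register_engine` are called with the same
    (sequence, temperature, mode) contract and their dot-bracket output is
    parsed into a :class:`FoldResult`.
    """
    if mode not in ("mfe", "centroid"):
        raise EngineError(f"unknown fold mode {mode!r}")
    t = as_temperature(t)
    if engine == "builtin":
        if mode == "mfe":
            return fold_mfe(seq, t, params)
        _, probs = partition_function(seq, t, params)
        structure = centroid_structure(probs)
        energy = score_structure(seq, structure, t, params)
        return FoldResult(structure=structure, energy=energy, temperature=t,
                          mode="centroid")
    from .engines import get_engine
    from .structcmp import parse_dotbracket
    engine_fn = get_engine(engine)
    db, energy = engine_fn(seq.residues, t.celsius, mode)
    try:
        structure = parse_dotbracket(db)
    except StructureError as exc:
        raise EngineError(
            f"engine {engine!r} returned unparseable structure: {exc}",
            raw_output=db) from exc
    if structure.length != seq.length:
        raise EngineError(
            f"engine {engine!r} returned structure of length {structure.length} "
            f"for a {seq.length}-nt sequence", raw_output=db)
    return FoldResult(structure=structure, energy=float(energy), temperature=t,
                      mode=mode, engine=engine)
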