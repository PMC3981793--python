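"""Seeded generator of synthetic RNA-thermometer test sequences.

Each record embeds one designed hairpin — a stem-loop whose melting
temperature under the built-in model lies strictly inside a requested
temperature bracket — between low-structure random flanks, with the hairpin
location recorded. Scanning such a record between the bracket temperatures
must light up the annotated interval, while a control record (no hairpin)
must not: the testable analogue of a thermometer-bearing sequence versus a
nearby control sequence.

The melting temperature is defined from the designed structure's total
enthalpy/entropy: the root of dG(T) = sum(stack dH) - T*(sum(stack dS) -
hairpin dG37/310.15), a closed-form surrogate for experimental melting with
no claim of biophysical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (T37_KELVIN, EnergyParams, Temperature, default_params,
                     loop_energy)
from .errors import GenerationError
from .folding import fold_mfe
from .seqio import RnaSequence
from .structure import SecondaryStructure

_PAIR_BASES = {"AU": ("A", "U"), "UA": ("U", "A"), "CG": ("C", "G"),
               "GC": ("G", "C"), "GU": ("G", "U"), "UG": ("U", "G")}
_PARTNER_COUNT_BASE = {"A": "U", "C": "G"}  # loop-base candidates -> partner

_DESIGN_RESTARTS = 300
_DESIGN_STEPS = 120
_FLANK_ATTEMPTS = 1000
_FLANK_MFE_FLOOR = -0.5      # kcal/mol: flanks must be essentially unstructured
#: Flank base sampling weights (A, C, G, U). A-dominant: A pairs only with U,
#: so flanks can neither fold on themselves nor form stackable helices with a
#: stem that carries no adjacent U's on either side (see design_hairpin) —
#: a marginal-stability stem would otherwise lose its bases to strong
#: flank-stem chimeras and the annotated hairpin would vanish from the MFE.
_FLANK_WEIGHTS = (0.92, 0.02, 0.02, 0.04)


@dataclass(frozen=True)
class ThermometerSpec:
    """Design parameters for one synthetic thermometer record.

    ``stem_length`` of 0 is the control sentinel: no hairpin is embedded and
    the record consists of flanks only.
    """

    stem_length: int = 10
    loop_length: int = 4
    tm_low: float = 37.0
    tm_high: float = 42.0
    flank5: int = 88
    flank3: int = 88
    seed: int = 0

    def __post_init__(self):
        if self.stem_length != 0 and self.stem_length < 2:
            raise GenerationError("stem_length must be 0 (control) or >= 2")
        if self.loop_length < 3:
            raise GenerationError("loop_length must be >= 3")
        if not self.tm_low < self.tm_high:
            raise GenerationError("tm_low must be strictly below tm_high")


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated sequence with its thermometer annotation (if any)."""

    sequence: RnaSequence
    thermometer_interval: tuple[int, int] | None   # 1-based inclusive
    predicted_tm: float | None                     # degC under builtin model
    spec: ThermometerSpec


def _hairpin_from_stem(stem: list[str], loop_base: str, loop_length: int
                       ) -> tuple[str, SecondaryStructure]:
    """Assemble sequence and designed structure from a list of pair types."""
    five = "".join(_PAIR_BASES[p][0] for p in stem)
    three = "".join(_PAIR_BASES[p][1] for p in reversed(stem))
    seq = five + loop_base * loop_length + three
    n = len(seq)
    pairs = frozenset((i + 1, n - i) for i in range(len(stem)))
    return seq, SecondaryStructure(length=n, pairs=pairs)


def _melting_temperature(stem: list[str], loop_length: int,
                         params: EnergyParams) -> float:
    """Closed-form Tm (degC) of the designed hairpin under the builtin model."""
    dH = 0.0
    dS = 0.0
    for a, b in zip(stem, stem[1:]):
        dH += params.stack_dH[(a, b)]
        dS += params.stack_dS[(a, b)]
    gh37 = loop_energy("hairpin", loop_length, Temperature(37.0), params)
    denom = dS - gh37 / T37_KELVIN
    if denom >= 0 or dH >= 0:
        return float("-inf")      # never stable: melts at any temperature
    return dH / denom - 273.15


def _loop_base(stem: list[str]) -> str:
    """Loop base from {A, C} with the fewest pairing partners in the stem."""
    bases = "".join(_PAIR_BASES[p][0] + _PAIR_BASES[p][1] for p in stem)
    return min("AC", key=lambda b: bases.count(_PARTNER_COUNT_BASE[b]))


def _repair_u_adjacency(stem: list[str], rng: np.random.Generator) -> bool:
    """Flip pair orientations until no stem side has two adjacent U's.

    Flank-stem chimeric helices need two stackable pairs, which with
    A-dominant flanks requires adjacent U's on one stem side; orientation
    flips (AU<->UA, CG<->GC, GU<->UG) remove that without changing the
    strength class of any pair. Returns False if no repair was found.
    """
    flip = {"AU": "UA", "UA": "AU", "CG": "GC", "GC": "CG", "GU": "UG", "UG": "GU"}
    for _ in range(60):
        bad = None
        for k in range(len(stem) - 1):
            five = _PAIR_BASES[stem[k]][0] + _PAIR_BASES[stem[k + 1]][0]
            three = _PAIR_BASES[stem[k]][1] + _PAIR_BASES[stem[k + 1]][1]
            if five == "UU" or three == "UU":
                bad = k
                break
        if bad is None:
            return True
        pos = bad + int(rng.integers(0, 2))
        stem[pos] = flip[stem[pos]]
    return False


def design_hairpin(spec: ThermometerSpec,
                   params: EnergyParams | None = None
                   ) -> tuple[str, float, SecondaryStructure]:
    """Design a stem-loop whose Tm lies strictly inside (tm_low, tm_high).

    A seeded local search over stem pair compositions: mutate single stem
    positions toward the bracket (stronger pairs if Tm is too low, weaker if
    too high), keep both stem sides free of adjacent U's (so A-dominant
    flanks cannot form stackable helices against the stem), then verify with
    the builtin engine that the hairpin folds to exactly the designed
    structure below the bracket and to the open chain above it.
    Deterministic for a given seed.

    Returns ``(sequence, predicted_tm, designed structure)``; raises
    :class:`GenerationError` (reporting the achievable Tm range) when no
    composition satisfies the bracket.
    """
    params = params or default_params()
    if spec.stem_length == 0:
        raise GenerationError("cannot design a hairpin for a control spec")
    rng = np.random.default_rng(spec.seed)
    weak_to_strong = ["GU", "UG", "AU", "UA", "CG", "GC"]
    seen_tms: list[float] = []

    def verify(stem: list[str]) -> tuple[str, SecondaryStructure] | None:
        loop_base = _loop_base(stem)
        seq_str, designed = _hairpin_from_stem(stem, loop_base, spec.loop_length)
        rna = RnaSequence("hairpin", seq_str)
        for t in (spec.tm_low - 5.0, spec.tm_low):
            if fold_mfe(rna, t, params).structure.pairs != designed.pairs:
                return None
        for t in (spec.tm_high, spec.tm_high + 5.0):
            if fold_mfe(rna, t, params).structure.pairs != frozenset():
                return None
        return seq_str, designed

    for _ in range(_DESIGN_RESTARTS):
        stem = [weak_to_strong[k] for k in rng.integers(0, 6, spec.stem_length)]
        for _ in range(_DESIGN_STEPS):
            if not _repair_u_adjacency(stem, rng):
                break
            tm = _melting_temperature(stem, spec.loop_length, params)
            seen_tms.append(tm)
            if spec.tm_low < tm < spec.tm_high:
                hit = verify(stem)
                if hit is not None:
                    seq_str, designed = hit
                    return seq_str, tm, designed
                break  # composition folds wrong; restart
            pos = int(rng.integers(0, spec.stem_length))
            rank = weak_to_strong.index(stem[pos])
            if rng.random() < 0.4:
                # fine move: flip orientation only, which changes the two
                # adjacent stacking contexts without changing strength class
                new_rank = rank - (rank % 2) + (1 - rank % 2)
            elif tm < spec.tm_low:    # too unstable: strengthen
                new_rank = min(5, rank + int(rng.integers(1, 3)))
                new_rank = new_rank - (new_rank % 2) + int(rng.integers(0, 2))
            else:                     # too stable: weaken
                new_rank = max(0, rank - int(rng.integers(1, 3)))
                new_rank = new_rank - (new_rank % 2) + int(rng.integers(0, 2))
            stem[pos] = weak_to_strong[new_rank]
    finite = [t for t in seen_tms if np.isfinite(t)]
    lo = f"{min(finite):.1f}" if finite else "-inf"
    hi = f"{max(finite):.1f}" if finite else "-inf"
    raise GenerationError(
        f"no stem composition of length {spec.stem_length} reached a Tm inside "
        f"({spec.tm_low}, {spec.tm_high}) degC; explored Tm range [{lo}, {hi}]")


def _sample_flank(rng: np.random.Generator, length: int, tm_low: float,
                  params: EnergyParams) -> str | None:
    """One candidate flank; None if it is too structured at tm_low."""
    if length == 0:
        return ""
    bases = rng.choice(np.array(list("ACGU")), size=length, p=_FLANK_WEIGHTS)
    flank = "".join(bases)
    mfe = fold_mfe(RnaSequence("flank", flank), tm_low, params).energy
    return flank if mfe >= _FLANK_MFE_FLOOR else None


def make_record(spec: ThermometerSpec,
                params: EnergyParams | None = None) -> SyntheticRecord:
    """Generate one synthetic record (or a flanks-only control).

    Flanks are rejection-sampled (A/C-biased) until their standalone MFE at
    ``tm_low`` is above the low-structure floor; for thermometer records the
    assembled sequence is additionally checked to still fold the designed
    stem below the bracket and to lose it above, so flank-hairpin
    interactions cannot silently destroy the embedded signal. Fully
    reproducible from the ThermometerSpec seed.
    """
    params = params or default_params()
    rng = np.random.default_rng(spec.seed)

    if spec.stem_length == 0:
        flanks = []
        for length in (spec.flank5, spec.flank3):
            for attempt in range(_FLANK_ATTEMPTS):
                f = _sample_flank(rng, length, spec.tm_low, params)
                if f is not None:
                    flanks.append(f)
                    break
            else:
                raise GenerationError(
                    f"no low-structure flank of length {length} found in "
                    f"{_FLANK_ATTEMPTS} attempts; try shorter flanks")
        seq = RnaSequence(f"control_seed{spec.seed}", flanks[0] + flanks[1])
        return SyntheticRecord(sequence=seq, thermometer_interval=None,
                               predicted_tm=None, spec=spec)

    hp_seq, tm, designed = design_hairpin(spec, params)
    start = spec.flank5 + 1
    end = spec.flank5 + len(hp_seq)

    for attempt in range(_FLANK_ATTEMPTS):
        f5 = _sample_flank(rng, spec.flank5, spec.tm_low, params)
        if f5 is None:
            continue
        f3 = _sample_flank(rng, spec.flank3, spec.tm_low, params)
        if f3 is None:
            continue
        full = f5 + hp_seq + f3
        # designed pairs in full-sequence coordinates
        shifted = frozenset((i + spec.flank5, j + spec.flank5)
                            for i, j in designed.pairs)
        window = RnaSequence("ctx", full)
        cold = fold_mfe(window, spec.tm_low, params).structure.pairs
        hot = fold_mfe(window, spec.tm_high, params).structure.pairs
        if not shifted <= cold:
            continue
        if shifted & hot:
            continue
        seq = RnaSequence(f"thermometer_seed{spec.seed}", full)
        return SyntheticRecord(sequence=seq, thermometer_interval=(start, end),
                               predicted_tm=tm, spec=spec)
    raise GenerationError(
        f"no flank pair kept the designed hairpin intact in {_FLANK_ATTEMPTS} "
        "attempts; try shorter flanks")
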