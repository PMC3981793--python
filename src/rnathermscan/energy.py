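"""Temperature-dependent energies for the reduced nearest-neighbor model.

The built-in folding engine uses a deliberately small thermodynamic model:

* **Stacks** between adjacent base pairs carry enthalpy and entropy, so their
  free energy is extrapolated to any temperature as ``dG(T) = dH - T*dS``.
  This is what makes hairpins melt as the temperature rises.
* **Hairpin and internal/bulge loops** are tabulated as free energies at
  37 degC and treated as purely entropic, i.e. rescaled linearly with absolute
  temperature: ``dG(T) = (T/310.15) * dG37``. Beyond the tabulated sizes a
  Jacobson-Stockmayer-style logarithmic extrapolation is applied.
* Multibranch loops, dangling ends, terminal-AU penalties and special
  tetraloops contribute nothing. This keeps the dynamic program and the
  brute-force enumeration oracle provably equivalent.

The shipped table (``data/nn_params_v1.tsv``) is a versioned, human-readable
stand-in loosely modeled on published nearest-neighbor magnitudes; no number
in it is claimed to reproduce any published parameter set. Full-accuracy
thermodynamics is available through the external engine adapter instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ParameterError

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 1.98717e-3
#: Reference temperature (37 degC) in kelvin.
T37_KELVIN = 310.15
#: Extrapolation prefactor for loops beyond the tabulated sizes.
_LOOP_EXTRAP = 1.75 * GAS_CONSTANT * T37_KELVIN

#: Canonical pair types, in the fixed index order used by the fold kernels.
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: 4x4 lookup: (base_i, base_j) -> pair-type index, or -1 if not canonical.
PAIR_TABLE = np.full((4, 4), -1, dtype=np.int8)
for _p, _i in PAIR_INDEX.items():
    PAIR_TABLE[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = _i


def encode_sequence(residues: str) -> np.ndarray:
    """Encode an A/C/G/U string as an int8 array (A=0, C=1, G=2, U=3)."""
    return np.fromiter((_BASE_INDEX[c] for c in residues), dtype=np.int8,
                       count=len(residues))


@dataclass(frozen=True)
class Temperature:
    """A temperature given in degrees Celsius on every public interface."""

    celsius: float

    @property
    def kelvin(self) -> float:
        return self.celsius + 273.15

    def __post_init__(self):
        if self.kelvin <= 0:
            raise ParameterError(f"temperature {self.celsius} degC is below 0 K")


def as_temperature(t: "Temperature | float") -> Temperature:
    return t if isinstance(t, Temperature) else Temperature(float(t))


@dataclass(frozen=True)
class EnergyParams:
    """Parsed parameter set for the built-in engine.

    ``stack_dH``/``stack_dS`` are keyed by the ordered stacking context
    ``(outer pair, inner pair)``: for a stack of (i,j) on (i+1,j-1) the outer
    pair is the bases at (i,j) and the inner pair the bases at (i+1,j-1).
    Loop tables are keyed by loop size and hold dG at 37 degC.
    """

    stack_dH: dict[tuple[str, str], float]
    stack_dS: dict[tuple[str, str], float]
    hairpin_dG37: dict[int, float]
    loop_dG37: dict[int, float]
    version: str = "unknown"

    def __post_init__(self):
        for p1 in PAIR_TYPES:
            for p2 in PAIR_TYPES:
                if (p1, p2) not in self.stack_dH or (p1, p2) not in self.stack_dS:
                    raise ParameterError(f"missing stacking context {p1}/{p2}")
        for name, table, lo in (("hairpin", self.hairpin_dG37, 3),
                                ("loop", self.loop_dG37, 1)):
            if not table:
                raise ParameterError(f"empty {name} table")
            sizes = sorted(table)
            if sizes[0] != lo or sizes != list(range(lo, sizes[-1] + 1)):
                raise ParameterError(f"{name} table must cover sizes {lo}..max")
            if any(v < 0 for v in table.values()):
                raise ParameterError(f"{name} table has negative entries")

    # -- file I/O ---------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyParams":
        """Parse the tab-separated parameter format ([STACK]/[HAIRPIN]/[LOOP])."""
        stack_dH: dict[tuple[str, str], float] = {}
        stack_dS: dict[tuple[str, str], float] = {}
        hairpin: dict[int, float] = {}
        loop: dict[int, float] = {}
        version = Path(path).stem
        section = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "version:" in line:
                        version = line.split("version:", 1)[1].strip()
                    continue
                if line.startswith("["):
                    section = line.strip("[]").upper()
                    continue
                fields = line.split("\t")
                try:
                    if section == "STACK":
                        ctx, dh, ds = fields
                        p1, p2 = ctx.split("/")
                        if p1 not in PAIR_INDEX or p2 not in PAIR_INDEX:
                            raise ValueError(f"unknown pair in context {ctx}")
                        stack_dH[(p1, p2)] = float(dh)
                        stack_dS[(p1, p2)] = float(ds)
                    elif section == "HAIRPIN":
                        hairpin[int(fields[0])] = float(fields[1])
                    elif section == "LOOP":
                        loop[int(fields[0])] = float(fields[1])
                    else:
                        raise ValueError("data line outside any section")
                except (ValueError, IndexError) as exc:
                    raise ParameterError(
                        f"{path}:{lineno}: cannot parse {line!r} ({exc})"
                    ) from exc
        return cls(stack_dH, stack_dS, hairpin, loop, version=version)

    @classmethod
    def load_default(cls) -> "EnergyParams":
        """Load the parameter file shipped with the package."""
        ref = resources.files("rnathermscan").joinpath("data/nn_params_v1.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    # -- dense tables for the fold kernels --------------------------------

    def stack_matrix(self, t: "Temperature | float") -> np.ndarray:
        """6x6 array of stack dG(T), indexed by (outer, inner) pair-type index."""
        tk = as_temperature(t).kelvin
        m = np.empty((6, 6))
        for (p1, p2), dh in self.stack_dH.items():
            m[PAIR_INDEX[p1], PAIR_INDEX[p2]] = dh - tk * self.stack_dS[(p1, p2)]
        return m

    def loop_arrays(self, t: "Temperature | float", n: int) -> tuple[np.ndarray, np.ndarray]:
        """Hairpin and internal-loop dG(T) for every size up to ``n``.

        Returns ``(hairpin, internal)`` arrays of length ``n + 1`` indexed by
        loop size; hairpin sizes below 3 are +inf (never formed).
        """
        hp = np.full(n + 1, np.inf)
        il = np.full(n + 1, np.inf)
        temp = as_temperature(t)
        for s in range(3, n + 1):
            hp[s] = loop_energy("hairpin", s, temp, self)
        for s in range(1, n + 1):
            il[s] = loop_energy("internal", s, temp, self)
        return hp, il


_DEFAULT_PARAMS: EnergyParams | None = None


def default_params() -> EnergyParams:
    """Shared instance of the shipped parameter set (loaded once)."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EnergyParams.load_default()
    return _DEFAULT_PARAMS


def stack_energy(ctx: tuple[str, str], t: "Temperature | float",
                 params: EnergyParams) -> float:
    """Free energy of one stack at temperature ``t``: dH - T_kelvin * dS."""
    if ctx not in params.stack_dH:
        raise ParameterError(f"unknown stacking context {ctx!r}")
    tk = as_temperature(t).kelvin
    return params.stack_dH[ctx] - tk * params.stack_dS[ctx]


def loop_energy(kind: str, size: int, t: "Temperature | float",
                params: EnergyParams) -> float:
    """Free energy of a hairpin or internal/bulge loop at temperature ``t``.

    Loops are purely entropic: dG(T) = (T_kelvin / 310.15) * dG37(size), with
    dG37 read from the table, or extrapolated logarithmically beyond it as
    ``dG37(s) = dG37(s_max) + 1.75 * R * 310.15 * ln(s / s_max)``.
    """
    if kind == "hairpin":
        table, lo = params.hairpin_dG37, 3
        if size < 3:
            raise ParameterError(f"hairpin loop of size {size} < minimum 3")
    elif kind in ("internal", "bulge"):
        table, lo = params.loop_dG37, 1
        if size < 1:
            raise ParameterError(f"internal/bulge loop needs >= 1 unpaired base")
    else:
        raise ParameterError(f"unknown loop kind {kind!r}")
    smax = max(table)
    if size <= smax:
        g37 = table[size]
    else:
        g37 = table[smax] + _LOOP_EXTRAP * math.log(size / smax)
    return as_temperature(t).kelvin / T37_KELVIN * g37
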