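"""The sliding-window, two-temperature folding scan.

For every window size in the requested range and every start offset (step
1 nt), the window is folded at a reference temperature and at a shock
temperature; the base-pair distance between the two predictions becomes one
dot at (window start, window end). Dense dark dot clusters mark segments
whose structure responds to the temperature change — putative RNA
thermometers.

For the builtin engine the scan does not re-fold each window from scratch:
all dynamic-programming tables are interval tables, so one banded table set
per temperature (band width = largest window) serves every window. This is
purely an optimization; results are identical to independent per-window
folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import mfe_tables, pf_outside_window, pf_tables
from .energy import (GAS_CONSTANT, PAIR_TABLE, EnergyParams, Temperature,
                     as_temperature, default_params, encode_sequence)
from .errors import ReliabilityWarning, ScanError
from .seqio import RnaSequence
from .folding import fold, traceback_window
from .structcmp import bp_distance, parse_dotbracket
from .structure import SecondaryStructure

#: Window-size envelope outside which energy-minimization predictions on
#: windows are considered less reliable.
RELIABLE_WMIN = 50
RELIABLE_WMAX = 150

TSV_HEADER = "x\ty\twindow\tdistance\tintensity"


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: two temperatures, window-size range, mode, engine."""

    t1: Temperature | float = 37.0
    t2: Temperature | float = 40.0
    wmin: int = 55
    wmax: int = 80
    mode: str = "mfe"
    engine: str = "builtin"

    def __post_init__(self):
        object.__setattr__(self, "t1", as_temperature(self.t1))
        object.__setattr__(self, "t2", as_temperature(self.t2))
        if self.wmin < 1 or self.wmax < self.wmin:
            raise ScanError(
                f"invalid window range [{self.wmin}, {self.wmax}]")
        if self.mode not in ("mfe", "centroid"):
            raise ScanError(f"unknown scan mode {self.mode!r}")

    def warn_if_unreliable(self) -> None:
        if self.wmin < RELIABLE_WMIN or self.wmax > RELIABLE_WMAX:
            warnings.warn(
                f"window range [{self.wmin}, {self.wmax}] extends outside "
                f"[{RELIABLE_WMIN}, {RELIABLE_WMAX}], where window folding "
                "predictions become less reliable", ReliabilityWarning,
                stacklevel=3)
        if self.t1.celsius == self.t2.celsius:
            warnings.warn(
                "both scan temperatures are equal; all distances will be 0",
                UserWarning, stacklevel=3)


@dataclass(frozen=True)
class DotRecord:
    """One dot: window [x, y] (1-based inclusive), its size, distance, intensity."""

    x: int
    y: int
    w: int
    distance: int
    intensity: float = 0.0


@dataclass
class ScanResult:
    """All dots of one scan of one sequence, plus the scan's maximum distance."""

    sequence_id: str
    sequence_length: int
    config: ScanConfig
    dots: list[DotRecord]
    max_distance: int = 0

    def to_tsv(self, path) -> None:
        """Write dots as TSV, deterministic order (ascending window, then x)."""
        with open(path, "w") as fh:
            fh.write(TSV_HEADER + "\n")
            for d in self.dots:
                fh.write(f"{d.x}\t{d.y}\t{d.w}\t{d.distance}\t{d.intensity:.6f}\n")


def expected_dot_count(length: int, wmin: int, wmax: int) -> int:
    """Closed-form dot count: sum over w of max(0, L - w + 1)."""
    return sum(max(0, length - w + 1) for w in range(wmin, wmax + 1))


def normalize_intensities(dots: list[DotRecord], max_distance: int) -> list[DotRecord]:
    """Set intensity = distance / max_distance (all zero when the max is 0)."""
    if max_distance == 0:
        return [replace(d, intensity=0.0) for d in dots]
    return [replace(d, intensity=d.distance / max_distance) for d in dots]


def _window_pairs_builtin(seq: RnaSequence, temp: Temperature, cfg: ScanConfig,
                          params: EnergyParams) -> dict[tuple[int, int], frozenset]:
    """Fold every window at one temperature; pairs in absolute coordinates."""
    n = seq.length
    enc = encode_sequence(seq.residues)
    stack = params.stack_matrix(temp)
    hp, il = params.loop_arrays(temp, n)
    out: dict[tuple[int, int], frozenset] = {}
    if cfg.mode == "mfe":
        tables = mfe_tables(enc, cfg.wmax, PAIR_TABLE, stack, hp, il)
        for w in range(cfg.wmin, cfg.wmax + 1):
            for s in range(0, n - w + 1):
                out[(s + 1, w)] = traceback_window(tables, s, s + w - 1)
    else:
        rt = GAS_CONSTANT * temp.kelvin
        Z, Zb, Zm, _ = pf_tables(enc, cfg.wmax, PAIR_TABLE, stack, hp, il, rt)
        for w in range(cfg.wmin, cfg.wmax + 1):
            for s in range(0, n - w + 1):
                p = pf_outside_window(s, s + w - 1, enc, PAIR_TABLE, stack, il,
                                      rt, Z, Zb, Zm)
                ii, jj = np.nonzero(p > 0.5)
                out[(s + 1, w)] = frozenset(
                    (int(a) + 1, int(b) + 1) for a, b in zip(ii, jj))
    return out


def _window_pairs_external(seq: RnaSequence, temp: Temperature, cfg: ScanConfig
                           ) -> dict[tuple[int, int], frozenset]:
    cache: dict[str, frozenset] = {}
    out: dict[tuple[int, int], frozenset] = {}
    for w in range(cfg.wmin, cfg.wmax + 1):
        for s in range(1, seq.length - w + 2):
            sub = seq.subsequence(s, s + w - 1)
            key = sub.residues
            if key not in cache:
                result = fold(sub, temp, mode=cfg.mode, engine=cfg.engine)
                cache[key] = result.structure.pairs
            # shift window-relative pairs to absolute coordinates
            out[(s, w)] = frozenset((i + s - 1, j + s - 1) for i, j in cache[key])
    return out


def run_scan(seq: RnaSequence, cfg: ScanConfig,
             params: EnergyParams | None = None) -> ScanResult:
    """Scan ``seq`` under ``cfg``: one dot per (window size, start offset).

    Dots are ordered by ascending window size, then ascending start, and
    intensities are normalized by the scan's global maximum distance.
    Raises :class:`ScanError` when the sequence is shorter than the smallest
    window (consider ``--clamp-window``).
    """
    params = params or default_params()
    if seq.length < cfg.wmin:
        raise ScanError(
            f"sequence {seq.id!r} ({seq.length} nt) is shorter than the "
            f"smallest window ({cfg.wmin} nt); use --clamp-window to scan it "
            "as a single full-length window")
    cfg.warn_if_unreliable()

    if cfg.engine == "builtin":
        pairs1 = _window_pairs_builtin(seq, cfg.t1, cfg, params)
        pairs2 = _window_pairs_builtin(seq, cfg.t2, cfg, params)
    else:
        pairs1 = _window_pairs_external(seq, cfg.t1, cfg)
        pairs2 = _window_pairs_external(seq, cfg.t2, cfg)

    dots: list[DotRecord] = []
    for w in range(cfg.wmin, cfg.wmax + 1):
        for x in range(1, seq.length - w + 2):
            a = SecondaryStructure(length=seq.length, pairs=pairs1[(x, w)])
            b = SecondaryStructure(length=seq.length, pairs=pairs2[(x, w)])
            dots.append(DotRecord(x=x, y=x + w - 1, w=w,
                                  distance=bp_distance(a, b)))
    max_distance = max((d.distance for d in dots), default=0)
    dots = normalize_intensities(dots, max_distance)
    return ScanResult(sequence_id=seq.id, sequence_length=seq.length,
                      config=cfg, dots=dots, max_distance=max_distance)


def clamp_config(cfg: ScanConfig, length: int) -> ScanConfig:
    """Replace the window range by the single window = sequence length."""
    return replace(cfg, wmin=length, wmax=length)


def position_profile(result: ScanResult) -> np.ndarray:
    """Per-nucleotide summary: mean dot intensity over all covering windows.

    ``profile[p-1]`` is the mean intensity of every dot whose window covers
    position ``p`` (0 where no window covers it). A convenience summary of
    dot density for localizing the signal along the sequence.
    """
    total = np.zeros(result.sequence_length)
    count = np.zeros(result.sequence_length)
    for d in result.dots:
        total[d.x - 1:d.y] += d.intensity
        count[d.x - 1:d.y] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return profile


def write_profile_tsv(profile: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean_intensity\n")
        for p, v in enumerate(profile, 1):
            fh.write(f"{p}\t{v:.6f}\n")
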