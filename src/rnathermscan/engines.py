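"""External folding-engine registry.

An engine is any callable ``(sequence: str, temperature_celsius: float,
mode: "mfe" | "centroid") -> (dotbracket: str, energy: float)``. Engines are
registered by name and selected with the ``--engine`` flag; the built-in
reduced-model engine is always available and never goes through this
registry.

A ViennaRNA adapter is provided and registered lazily under the name
``"vienna"`` when the ``RNA`` Python bindings are importable. Vienna uses the
full Turner nearest-neighbor model, so its structures are generally *not*
identical to the built-in engine's; only the structural contract is shared.
"""

from __future__ import annotations

from typing import Callable

from .errors import EngineError

EngineFn = Callable[[str, float, str], tuple[str, float]]

_REGISTRY: dict[str, EngineFn] = {}


def register_engine(name: str, fn: EngineFn) -> None:
    """Register an engine callable under ``name`` (overwrites silently)."""
    _REGISTRY[name] = fn


def available_engines() -> list[str]:
    names = {"builtin", *_REGISTRY}
    try:
        import RNA  # noqa: F401
        names.add("vienna")
    except ImportError:
        pass
    return sorted(names)


def get_engine(name: str) -> EngineFn:
    if name in _REGISTRY:
        return _REGISTRY[name]
    if name == "vienna":
        fn = make_vienna_engine()
        register_engine("vienna", fn)
        return fn
    raise EngineError(
        f"unknown engine {name!r}; available: {', '.join(available_engines())}")


def make_vienna_engine(dangles: int | None = None,
                       no_lonely_pairs: bool | None = None) -> EngineFn:
    """Build a ViennaRNA adapter.

    ``dangles`` and ``no_lonely_pairs`` are passed through to the Vienna model
    details untouched when given; otherwise Vienna's own defaults apply.
    """
    try:
        import RNA
    except ImportError as exc:
        raise EngineError(
            "ViennaRNA Python bindings (module 'RNA') are not installed"
        ) from exc

    def vienna(sequence: str, temperature: float, mode: str) -> tuple[str, float]:
        md = RNA.md()
        md.temperature = temperature
        if dangles is not None:
            md.dangles = dangles
        if no_lonely_pairs is not None:
            md.noLP = int(no_lonely_pairs)
        fc = RNA.fold_compound(sequence, md)
        try:
            if mode == "mfe":
                db, energy = fc.mfe()
            elif mode == "centroid":
                fc.pf()
                db, _ = fc.centroid()
                energy = fc.eval_structure(db)
            else:
                raise EngineError(f"unknown fold mode {mode!r}")
        except EngineError:
            raise
        except Exception as exc:  # Vienna raises plain RuntimeErrors
            raise EngineError(f"ViennaRNA failed: {exc}") from exc
        return db, float(energy)

    return vienna
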