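"""Dot-plot rendering.

One scatter marker per nonzero dot at (window start, window end), grayscale
level 1 - intensity on a white background: no structural change is invisible,
the largest change in the scan is black. All window sizes are drawn on the
same axes with a single marker style, which is what produces the vertical
band appearance of a multi-window scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from matplotlib.figure import Figure

from .errors import ThermoScanError
from .scan import ScanResult


@dataclass(frozen=True)
class RenderOptions:
    fmt: str = "png"              # png | svg
    dpi: int = 150
    marker_size: float = 9.0
    axis_labels: bool = True

    def __post_init__(self):
        if self.fmt not in ("png", "svg"):
            raise ThermoScanError(f"unsupported image format {self.fmt!r}")


def render_dotplot(result: ScanResult, opts: RenderOptions,
                   path: str | Path) -> None:
    """Render ``result`` as a dotted x/y plot and save it to ``path``."""
    fig = Figure(figsize=(6.4, 6.4), dpi=opts.dpi)
    ax = fig.add_subplot(111)
    visible = [d for d in result.dots if d.intensity > 0]
    if visible:
        ax.scatter([d.x for d in visible], [d.y for d in visible],
                   s=opts.marker_size,
                   c=[(1 - d.intensity,) * 3 for d in visible],
                   marker="s", edgecolors="none")
    lim = (1, result.sequence_length)
    ax.set_xlim(*lim)
    ax.set_ylim(*lim)
    ax.set_facecolor("white")
    if opts.axis_labels:
        ax.set_xlabel("window start (nt)")
        ax.set_ylabel("window end (nt)")
    cfg = result.config
    ax.set_title(
        f"{result.sequence_id}  {cfg.t1.celsius:g}/{cfg.t2.celsius:g} degC  "
        f"w={cfg.wmin}-{cfg.wmax}  {cfg.mode}", fontsize=10)
    try:
        fig.savefig(path, format=opts.fmt)
    except OSError as exc:
        raise ThermoScanError(f"cannot write image {path}: {exc}") from exc
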