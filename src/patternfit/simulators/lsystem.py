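"""L-system string rewriting and turtle rendering.

Supported symbols: ``F`` (draw one step forward), ``+``/``-`` (turn by the
spec angle), ``[``/``]`` (push/pop turtle state).  Any other symbol is a
no-op placeholder.  The rendered path is auto-scaled to fit the raster
with a 4-pixel margin since the extent grows unpredictably with
iteration count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._common import GRID_SIZE

__all__ = ["LSystemSpec", "rewrite", "generate_l_system"]

_CONTROL = set("F+-[]")


@dataclass(frozen=True)
class LSystemSpec:
    axiom: str = "F"
    productions: dict = field(default_factory=dict)
    iterations: int = 3
    angle: float = 25.0  # degrees
    step: float = 1.0  # nominal step length before auto-scaling

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for rhs in self.productions.values():
            depth = 0
            for ch in rhs:
                depth += (ch == "[") - (ch == "]")
                if depth < 0:
                    raise ValueError(f"unbalanced brackets in production {rhs!r}")
            if depth != 0:
                raise ValueError(f"unbalanced brackets in production {rhs!r}")


def rewrite(spec: LSystemSpec) -> str:
    """Apply the productions to the axiom ``spec.iterations`` times."""
    s = spec.axiom
    for _ in range(spec.iterations):
        s = "".join(spec.productions.get(ch, ch) for ch in s)
    return s


def _trace(spec: LSystemSpec, s: str):
    x = y = 0.0
    heading = math.pi / 2.0  # start pointing up
    stack = []
    segments = []
    turn = math.radians(spec.angle)
    for ch in s:
        if ch == "F":
            nx = x + spec.step * math.cos(heading)
            ny = y + spec.step * math.sin(heading)
            segments.append((x, y, nx, ny))
            x, y = nx, ny
        elif ch == "+":
            heading += turn
        elif ch == "-":
            heading -= turn
        elif ch == "[":
            stack.append((x, y, heading))
        elif ch == "]":
            if not stack:
                raise ValueError("unbalanced brackets in L-system string")
            x, y, heading = stack.pop()
    if stack:
        raise ValueError("unbalanced brackets in L-system string")
    return segments


def generate_l_system(spec: LSystemSpec, size: int = GRID_SIZE,
                      margin: int = 4) -> np.ndarray:
    """Rewrite and render; returns a binary raster (1 on drawn pixels)."""
    segments = _trace(spec, rewrite(spec))
    grid = np.zeros((size, size))
    if not segments:
        return grid
    pts = np.array(segments)  # (n, 4): x0 y0 x1 y1
    xs = np.concatenate([pts[:, 0], pts[:, 2]])
    ys = np.concatenate([pts[:, 1], pts[:, 3]])
    span = max(xs.max() - xs.min(), ys.max() - ys.min(), 1e-9)
    scale = (size - 1 - 2 * margin) / span
    ox = margin + (size - 1 - 2 * margin - (xs.max() - xs.min()) * scale) / 2.0
    oy = margin + (size - 1 - 2 * margin - (ys.max() - ys.min()) * scale) / 2.0
    for x0, y0, x1, y1 in segments:
        px0 = (x0 - xs.min()) * scale + ox
        py0 = (y0 - ys.min()) * scale + oy
        px1 = (x1 - xs.min()) * scale + ox
        py1 = (y1 - ys.min()) * scale + oy
        n = int(max(abs(px1 - px0), abs(py1 - py0))) * 2 + 2
        t = np.linspace(0.0, 1.0, n)
        cols = np.clip(np.round(px0 + (px1 - px0) * t).astype(int), 0, size - 1)
        rows = np.clip(np.round((size - 1) - (py0 + (py1 - py0) * t)).astype(int),
                       0, size - 1)
        grid[rows, cols] = 1.0
    return grid
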