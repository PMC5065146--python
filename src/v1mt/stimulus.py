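"""Moving-bar stimulus generation.

Coordinate convention (used consistently across the package): 0-based pixel
grid, ``x`` increases rightward (array columns), ``y`` increases downward
(array rows).  Direction angles are measured counter-clockwise from +x with
"up" meaning decreasing ``y``; the 8 direction channels are::

    index 0      1         2    3        4     5          6     7
    name  right  up-right  up   up-left  left  down-left  down  down-right
    angle 0      45        90   135      180   225        270   315

A bar is an oriented rectangle rasterised to the nearest pixels on frame 0 and
then translated rigidly by ``speed`` pixels along its motion direction on each
subsequent frame, so the per-frame masks satisfy the translation property
exactly (before any boundary clipping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DIRECTION_NAMES",
    "DIRECTION_VECTORS",
    "direction_index",
    "GridSpec",
    "BarSpec",
    "StimulusSequence",
    "make_bar_stimulus",
    "robustness_battery",
    "save_stimulus",
    "load_stimulus",
    "save_tiff",
]

DIRECTION_NAMES = (
    "right", "up-right", "up", "up-left",
    "left", "down-left", "down", "down-right",
)

#: integer (dx, dy) displacement of each direction at speed 1 (y is downward)
DIRECTION_VECTORS = (
    (1, 0), (1, -1), (0, -1), (-1, -1),
    (-1, 0), (-1, 1), (0, 1), (1, 1),
)

_ALLOWED_ORIENTATIONS = (0, 45, 90, 135)


def direction_index(direction: int | str) -> int:
    """Resolve a direction given by name, channel index, or angle in degrees."""
    if isinstance(direction, str):
        try:
            return DIRECTION_NAMES.index(direction)
        except ValueError:
            raise ValueError(
                f"unknown direction {direction!r}; expected one of {DIRECTION_NAMES}"
            ) from None
    d = int(direction)
    if 0 <= d < 8:
        return d
    if d % 45 == 0:
        return (d // 45) % 8
    raise ValueError(f"direction must be a name, 0..7, or a multiple of 45 deg: {direction}")


@dataclass(frozen=True)
class GridSpec:
    width: int = 64
    height: int = 64

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ValueError("grid must be at least 16x16 (bar + evaluation margin)")


@dataclass(frozen=True)
class BarSpec:
    orientation: int = 45          # degrees, one of 0/45/90/135
    direction: str | int = "right"  # compass name or channel index
    length: int = 9                # pixels along the bar axis
    bar_width: int = 1             # pixels across the bar axis
    speed: int = 1                 # pixels per frame
    n_frames: int = 12
    frame_interval: float = 20.0   # ms

    def __post_init__(self):
        if self.orientation not in _ALLOWED_ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ALLOWED_ORIENTATIONS}")
        if self.length <= self.bar_width:
            raise ValueError("bar length must exceed its width")
        if self.speed < 0 or self.n_frames < 1:
            raise ValueError("speed must be >= 0 and n_frames >= 1")

    @property
    def direction_idx(self) -> int:
        return direction_index(self.direction)

    @property
    def velocity(self) -> tuple[int, int]:
        dx, dy = DIRECTION_VECTORS[self.direction_idx]
        return (dx * self.speed, dy * self.speed)


@dataclass
class StimulusSequence:
    frames: np.ndarray               # (T, H, W) float in [0, 1]
    grid: GridSpec
    bar: BarSpec
    masks: np.ndarray = field(repr=False, default=None)  # (T, H, W) bool

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mask(self, t: int) -> np.ndarray:
        return self.masks[t]


def _bar_footprint(bar: BarSpec, cx: float, cy: float, grid: GridSpec) -> np.ndarray:
    """Rasterise the oriented rectangle centred at (cx, cy) to a boolean grid."""
    ang = np.deg2rad(bar.orientation)
    ux, uy = np.cos(ang), -np.sin(ang)        # bar axis (y downward)
    nx, ny = -uy, ux                          # normal
    ys, xs = np.mgrid[0:grid.height, 0:grid.width]
    rx = xs - cx
    ry = ys - cy
    along = rx * ux + ry * uy
    across = rx * nx + ry * ny
    # nearest-pixel rasterisation: half-open tolerance of half a pixel keeps a
    # width-1 diagonal bar a clean one-pixel staircase
    return (np.abs(along) <= bar.length / 2.0) & (np.abs(across) <= bar.bar_width / 2.0)


def make_bar_stimulus(
    bar: BarSpec,
    grid: GridSpec | None = None,
    *,
    start: tuple[float, float] | None = None,
    bounds: str = "error",
) -> StimulusSequence:
    """Render a drifting-bar sequence of binary luminance frames.

    By default the bar's trajectory is centred on the grid: on the middle frame
    the bar centre coincides with the grid centre.  ``bounds`` controls what
    happens if the bar would leave the grid: ``"error"`` raises, ``"clip"``
    silently crops the footprint at the border.
    """
    grid = grid or GridSpec()
    if bounds not in ("error", "clip"):
        raise ValueError("bounds must be 'error' or 'clip'")
    vx, vy = bar.velocity
    if start is None:
        cx0 = (grid.width - 1) / 2.0 - vx * (bar.n_frames - 1) / 2.0
        cy0 = (grid.height - 1) / 2.0 - vy * (bar.n_frames - 1) / 2.0
    else:
        cx0, cy0 = start

    base = _bar_footprint(bar, cx0, cy0, grid)
    if not base.any():
        raise ValueError("bar footprint is empty (off the grid?)")
    ys, xs = np.nonzero(base)

    masks = np.zeros((bar.n_frames, grid.height, grid.width), dtype=bool)
    for t in range(bar.n_frames):
        px = xs + vx * t
        py = ys + vy * t
        inside = (px >= 0) & (px < grid.width) & (py >= 0) & (py < grid.height)
        if bounds == "error" and not inside.all():
            raise ValueError(
                f"bar leaves the grid at frame {t}; enlarge the grid, shorten "
                "the sequence, or pass bounds='clip'"
            )
        masks[t, py[inside], px[inside]] = True

    frames = masks.astype(np.float64)
    return StimulusSequence(frames=frames, grid=grid, bar=bar, masks=masks)


def robustness_battery(
    *,
    short: int = 9,
    long: int = 21,
    narrow: int = 1,
    wide: int = 3,
    n_frames: int = 12,
    full_cross: bool = False,
) -> list[BarSpec]:
    """The 32-condition battery: 4 motion directions (right/left/up/down) x
    4 orientations (0/45/90/135 deg) x 2 bar sizes, drifting at one pixel per
    frame.  The two sizes pair short with narrow and long with wide (the full
    4-factor cross would be 64 conditions; ``full_cross=True`` gives it)."""
    sizes = [(short, narrow), (long, wide)]
    if full_cross:
        sizes = [(L, W) for L in (short, long) for W in (narrow, wide)]
    battery = []
    for direction in ("right", "left", "up", "down"):
        for orientation in _ALLOWED_ORIENTATIONS:
            for length, width in sizes:
                battery.append(BarSpec(
                    orientation=orientation, direction=direction,
                    length=length, bar_width=width, speed=1,
                    n_frames=n_frames,
                ))
    return battery


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar(stim: StimulusSequence) -> dict:
    return {
        "grid": {"width": stim.grid.width, "height": stim.grid.height},
        "bar": {
            "orientation": stim.bar.orientation,
            "direction": stim.bar.direction if isinstance(stim.bar.direction, str)
            else int(stim.bar.direction),
            "length": stim.bar.length,
            "bar_width": stim.bar.bar_width,
            "speed": stim.bar.speed,
            "n_frames": stim.bar.n_frames,
            "frame_interval": stim.bar.frame_interval,
        },
    }


def save_stimulus(stim: StimulusSequence, path: str | Path) -> None:
    """Write frames (and masks) to a compressed ``.npz`` with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, frames=stim.frames, masks=stim.masks)
    path.with_suffix(".json").write_text(json.dumps(_sidecar(stim), indent=1))


def load_stimulus(path: str | Path) -> StimulusSequence:
    path = Path(path)
    with np.load(path) as z:
        frames = z["frames"]
        masks = z["masks"].astype(bool)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = GridSpec(**meta["grid"])
    bar = BarSpec(**meta["bar"])
    return StimulusSequence(frames=frames, grid=grid, bar=bar, masks=masks)


def save_tiff(stim: StimulusSequence, path: str | Path) -> None:
    """Write the luminance frames as a multi-page 8-bit TIFF."""
    import tifffile

    data = np.clip(stim.frames * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     metadata=_sidecar(stim))
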