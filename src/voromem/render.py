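"""Rendering: Voronoi leaflet maps and 2D time-series plots.

Voronoi maps are rasterized deterministically with Pillow: each cell is
filled by mapping its metric value through a color scale, cell borders are
drawn, user-selected cells are overlaid in blue, inclusion cells use a
reserved neutral grey.  A fixed-size legend (scale bar with vmin/vmax
labels) sits in the top-left corner and the leaflet label in the top-right.
Time-series plots go through matplotlib (Agg).

Color scales: ``rainbow`` (blue-cyan-green-yellow-red), ``locs`` (a
256-entry luminance-optimized scale, black to white through blue, magenta,
orange and yellow with approximately linear luminance), ``heated_object``
(black-red-yellow-white), ``linear_grey`` and ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .metrics import TimeSeries
from .tessellate import INCLUSION, LIPID, Tessellation2D

HIGHLIGHT_COLOR = (60, 100, 230)  # user-selected cells
INCLUSION_COLOR = (150, 150, 150)  # reserved neutral fill for non-lipid cells
BORDER_COLOR = (0, 0, 0)


class RenderError(Exception):
    pass


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear color map over normalized parameter t in [0, 1].

    ``stops`` is an ordered list of (t, (r, g, b)) covering t = 0 and t = 1;
    metric values are clamped to [vmin, vmax] before normalization.
    """

    name: str
    vmin: float
    vmax: float
    stops: tuple[tuple[float, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        if self.vmin >= self.vmax:
            raise RenderError(f"vmin ({self.vmin}) must be < vmax ({self.vmax})")
        ts = [t for t, _ in self.stops]
        if ts[0] != 0.0 or ts[-1] != 1.0 or any(b < a for a, b in zip(ts, ts[1:])):
            raise RenderError("stops must be sorted and cover t=0 and t=1")


def _luminance(rgb: tuple[int, int, int]) -> float:
    r, g, b = rgb
    return (0.299 * r + 0.587 * g + 0.114 * b) / 255.0


# Control points of the luminance-optimized scale: a black-to-white sweep
# through blue, magenta, orange and yellow placed at their own luminances so
# perceived brightness grows linearly with the mapped value.
_LOCS_CONTROL: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (0, 0, 255),
    (255, 0, 255),
    (255, 100, 0),
    (255, 255, 0),
    (255, 255, 255),
)


def _locs_table(n: int = 256) -> tuple[tuple[float, tuple[int, int, int]], ...]:
    ctrl_t = [_luminance(c) for c in _LOCS_CONTROL]
    ctrl = np.array(_LOCS_CONTROL, dtype=float)
    ts = np.linspace(0.0, 1.0, n)
    rgb = np.column_stack([np.interp(ts, ctrl_t, ctrl[:, k]) for k in range(3)])
    return tuple(
        (float(t), tuple(int(np.floor(c + 0.5)) for c in row))
        for t, row in zip(ts, rgb)
    )


_SCALE_STOPS: dict[str, tuple[tuple[float, tuple[int, int, int]], ...]] = {
    "linear_grey": ((0.0, (0, 0, 0)), (1.0, (255, 255, 255))),
    "rainbow": (
        (0.0, (0, 0, 255)),
        (0.25, (0, 255, 255)),
        (0.5, (0, 255, 0)),
        (0.75, (255, 255, 0)),
        (1.0, (255, 0, 0)),
    ),
    "heated_object": (
        (0.0, (0, 0, 0)),
        (1.0 / 3.0, (255, 0, 0)),
        (2.0 / 3.0, (255, 255, 0)),
        (1.0, (255, 255, 255)),
    ),
    "locs": _locs_table(),
    "none": ((0.0, (255, 255, 255)), (1.0, (255, 255, 255))),
}

SCALE_NAMES = tuple(_SCALE_STOPS)


def make_scale(name: str, vmin: float, vmax: float) -> ColorScale:
    if name not in _SCALE_STOPS:
        raise RenderError(f"unknown color scale {name!r}; known: {SCALE_NAMES}")
    return ColorScale(name=name, vmin=vmin, vmax=vmax, stops=_SCALE_STOPS[name])


def normalized_position(value: float, scale: ColorScale) -> float:
    """Clamped normalized parameter t of a metric value on a scale."""
    t = (value - scale.vmin) / (scale.vmax - scale.vmin)
    return min(1.0, max(0.0, t))


def map_color(value: float, scale: ColorScale) -> tuple[int, int, int]:
    """Map a metric value to an RGB triple by piecewise-linear interpolation.

    Values outside [vmin, vmax] clamp to the end colors.  Channel values are
    rounded half-up to integers.
    """
    t = normalized_position(value, scale)
    stops = scale.stops
    for (t0, c0), (t1, c1) in zip(stops, stops[1:]):
        if t <= t1:
            frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            return tuple(
                int(np.floor(a + frac * (b - a) + 0.5)) for a, b in zip(c0, c1)
            )
    return stops[-1][1]  # pragma: no cover


def _draw_legend(
    draw: ImageDraw.ImageDraw, scale: ColorScale, height: int
) -> None:
    # fixed-size vertical scale bar, top-left corner
    x0, y0, bar_w, bar_h = 10, 10, 18, min(160, height - 40)
    for row in range(bar_h):
        t = 1.0 - row / (bar_h - 1)
        value = scale.vmin + t * (scale.vmax - scale.vmin)
        draw.line(
            [(x0, y0 + row), (x0 + bar_w, y0 + row)], fill=map_color(value, scale)
        )
    draw.rectangle([x0, y0, x0 + bar_w, y0 + bar_h - 1], outline=BORDER_COLOR)
    draw.text((x0 + bar_w + 4, y0 - 2), f"{scale.vmax:.3g}", fill=BORDER_COLOR)
    draw.text((x0 + bar_w + 4, y0 + bar_h - 10), f"{scale.vmin:.3g}", fill=BORDER_COLOR)


def render_voronoi_map(
    tess: Tessellation2D,
    values: dict[int, float],
    scale: ColorScale,
    out_path: str | Path,
    highlight: set[int] | None = None,
    leaflet_label: str = "",
    width: int = 1024,
) -> None:
    """Render a leaflet tessellation to a PNG file.

    ``values`` maps lipid ids to the metric being displayed; ``highlight``
    is a set of lipid ids drawn in the selection color.  Output is
    deterministic: identical inputs give byte-identical files.
    """
    highlight = highlight or set()
    lx, ly = tess.box
    height = max(1, int(round(width * ly / lx)))
    sx, sy = width / lx, height / ly

    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)

    def to_px(vertices: np.ndarray) -> list[tuple[float, float]]:
        # y axis flipped so +y points up in the image
        return [(v[0] * sx, height - v[1] * sy) for v in vertices]

    for g in tess.generators:
        cell = tess.cells[g.id]
        if g.kind == INCLUSION:
            fill = INCLUSION_COLOR
        elif g.lipid_id in highlight:
            fill = HIGHLIGHT_COLOR
        else:
            if g.lipid_id not in values:
                raise RenderError(f"no value for lipid generator {g.lipid_id}")
            fill = map_color(values[g.lipid_id], scale)
        # draw the cell and, for periodicity, its 8 shifted images (cheap:
        # off-canvas polygons are clipped by Pillow)
        for dx in (-lx, 0.0, lx):
            for dy in (-ly, 0.0, ly):
                pts = to_px(cell + np.array([dx, dy]))
                draw.polygon(pts, fill=fill, outline=BORDER_COLOR)

    if scale.name != "none":
        _draw_legend(draw, scale, height)
    if leaflet_label:
        draw.text((width - 8 * len(leaflet_label) - 12, 10), leaflet_label,
                  fill=BORDER_COLOR)
    img.save(str(out_path), format="PNG")


def plot_series(
    series: TimeSeries,
    out_path: str | Path,
    title: str = "",
    ylabel: str = "",
) -> None:
    """Line plot of a time series, one line and legend entry per column."""
    if not series.columns or len(series.x) == 0:
        raise RenderError("cannot plot an empty series")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5), dpi=120)
    for name, col in series.columns.items():
        ax.plot(series.x, col, label=name)
    ax.set_xlabel(series.xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(out_path), metadata={"Software": "voromem"})
    plt.close(fig)
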