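"""Polar (radar) diagram of a radius profile.

Vertices start at 12 o'clock and proceed clockwise in registry order; the
radial scale runs 0-10 with a reference ring at the acceptability limit 5.
Negative raw radii plot at the origin (clamped values are used throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import InputValidationError
from .radii import DEFAULT_REGISTRY, R_ACCEPTABLE, R_MAX, RadiusProfile, system_parameter_ids


@dataclass(frozen=True)
class DiagramLayout:
    """Geometry of the radar diagram: axis order, start angle, direction."""

    order: tuple[str, ...]
    start_angle_deg: float = 90.0   # 12 o'clock
    clockwise: bool = True
    r_max: float = R_MAX
    ring: float = R_ACCEPTABLE

    @classmethod
    def for_system(cls, system: str) -> "DiagramLayout":
        return cls(order=system_parameter_ids(system))


def _vertex_angles(n: int, layout: DiagramLayout) -> list[float]:
    sign = -1.0 if layout.clockwise else 1.0
    start = math.radians(layout.start_angle_deg)
    return [start + sign * k * 2 * math.pi / n for k in range(n)]


def polygon_coordinates(
    profile: RadiusProfile, layout: Optional[DiagramLayout] = None
) -> list[tuple[float, float]]:
    """Closed vertex list (first point repeated last) of the profile polygon."""
    layout = layout or DiagramLayout.for_system(profile.system)
    if set(layout.order) != set(profile.parameter_ids):
        raise InputValidationError("layout order does not match the profile's parameters")
    clamped = profile.clamped
    pts = [
        (clamped[pid] * math.cos(a), clamped[pid] * math.sin(a))
        for pid, a in zip(layout.order, _vertex_angles(len(layout.order), layout))
    ]
    return pts + [pts[0]]


def _shoelace(points: list[tuple[float, float]]) -> float:
    area = 0.0
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def shaded_area_ratio(profile: RadiusProfile) -> float:
    """Polygon area over the area of the full-scale (radius 10) circle."""
    pts = polygon_coordinates(profile)[:-1]
    return _shoelace(pts) / (math.pi * R_MAX**2)


def render_svg(
    profile: RadiusProfile,
    path,
    layout: Optional[DiagramLayout] = None,
    size: int = 520,
) -> Path:
    """Write a deterministic standalone SVG radar diagram and return its path."""
    layout = layout or DiagramLayout.for_system(profile.system)
    n = len(layout.order)
    if n == 0:
        raise InputValidationError("cannot render an empty profile")
    cx = cy = size / 2.0
    scale = (size / 2.0 - 60.0) / layout.r_max
    angles = _vertex_angles(n, layout)

    def to_px(r: float, a: float) -> tuple[float, float]:
        return (cx + r * scale * math.cos(a), cy - r * scale * math.sin(a))

    lines: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">',
        f'<rect width="{size}" height="{size}" fill="white"/>',
    ]
    for ring_r, colour in ((layout.r_max, "#888888"), (layout.ring, "#cc3333")):
        lines.append(
            f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{ring_r * scale:.2f}" '
            f'fill="none" stroke="{colour}" stroke-width="1" stroke-dasharray="4 3"/>'
        )
    clamped = profile.clamped
    for pid, a in zip(layout.order, angles):
        ex, ey = to_px(layout.r_max, a)
        lines.append(
            f'<line x1="{cx:.2f}" y1="{cy:.2f}" x2="{ex:.2f}" y2="{ey:.2f}" '
            f'stroke="#cccccc" stroke-width="1"/>'
        )
        lx, ly = to_px(layout.r_max * 1.12, a)
        label = DEFAULT_REGISTRY[pid].id if pid in DEFAULT_REGISTRY else pid
        lines.append(
            f'<text x="{lx:.2f}" y="{ly:.2f}" font-size="11" font-family="sans-serif" '
            f'text-anchor="middle" dominant-baseline="middle" class="axis-label">{label}</text>'
        )
    poly = " ".join(
        f"{x:.3f},{y:.3f}"
        for pid, a in zip(layout.order, angles)
        for x, y in [to_px(clamped[pid], a)]
    )
    lines.append(
        f'<polygon points="{poly}" fill="#4477aa" fill-opacity="0.45" '
        f'stroke="#224466" stroke-width="1.5"/>'
    )
    lines.append(
        f'<text x="{cx:.2f}" y="18" font-size="13" font-family="sans-serif" '
        f'text-anchor="middle">{profile.batch_id} ({profile.system}, n={n})</text>'
    )
    lines.append("</svg>")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def render_png(profile: RadiusProfile, path, layout: Optional[DiagramLayout] = None):
    """Optional raster rendering via matplotlib (not a core dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout = layout or DiagramLayout.for_system(profile.system)
    angles = _vertex_angles(len(layout.order), layout)
    clamped = profile.clamped
    rs = [clamped[pid] for pid in layout.order]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles + angles[:1], rs + rs[:1], color="#224466")
    ax.fill(angles + angles[:1], rs + rs[:1], color="#4477aa", alpha=0.45)
    ax.set_ylim(0, layout.r_max)
    ax.set_xticks(angles)
    ax.set_xticklabels(list(layout.order), fontsize=8)
    ax.set_title(f"{profile.batch_id} ({profile.system})")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
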