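"""Card rendering: deterministic SVG export and PIL rasterization.

A card is a 2 x 3 grid of outline shapes on a 120 x 73.5 (mm) canvas, the
physical aspect of the printed stimulus cards.  Every shape is drawn as a
closed stroke of constant width, centered in its grid cell, after applying
the placement's rotation and scale.  Output is purely a function of its
inputs: the same card yields byte-identical SVG.
"""

from __future__ import annotations

import math
from io import BytesIO

import numpy as np
from PIL import Image, ImageDraw

from .geometry import CardSpec, GeometryError, Quadrilateral, ShapeFamily

__all__ = ["export_card", "render_card", "render_shape", "CARD_W_MM", "CARD_H_MM"]

CARD_W_MM = 120.0
CARD_H_MM = 73.5
_MM_PER_UNIT = 12.0  # drawing scale for a shape with mean pairwise distance 1
_STROKE_MM = 0.8

# Grid cell centers, positions 1..6 reading left-to-right, top-to-bottom.
_CELLS = [
    (CARD_W_MM * (2 * c + 1) / 6.0, CARD_H_MM * (2 * r + 1) / 4.0)
    for r in range(2)
    for c in range(3)
]


def _placed_points(card: CardSpec, families: dict[str, ShapeFamily]) -> list[np.ndarray]:
    """Vertex arrays (mm coordinates, y down as in SVG) per position 1..6."""
    fam = families[card.family]
    deviant = fam.deviants[card.deviant_index - 1]
    out = []
    for p in sorted(card.placements, key=lambda p: p.position):
        if card.disposition == "canonical":
            shape = deviant if p.role == "deviant" else fam.base
        else:
            shape = fam.base if p.role == "reference" else deviant
        q = shape.transformed(rotation_deg=p.rotation, scale=p.scale)
        pts = q.array * _MM_PER_UNIT
        # center on the area centroid within the cell; flip y for screen coords
        from shapely.geometry import Polygon

        c = np.asarray(Polygon(tuple(map(tuple, pts))).centroid.coords[0])
        cx, cy = _CELLS[p.position - 1]
        pts = pts - c
        pts[:, 1] = -pts[:, 1]
        pts = pts + np.array([cx, cy])
        out.append(pts)
    return out


def _check_fit(all_pts: list[np.ndarray]) -> None:
    half_w, half_h = CARD_W_MM / 6.0, CARD_H_MM / 4.0
    for pts, (cx, cy) in zip(all_pts, _CELLS):
        dx = np.max(np.abs(pts[:, 0] - cx)) + _STROKE_MM
        dy = np.max(np.abs(pts[:, 1] - cy)) + _STROKE_MM
        if dx > half_w or dy > half_h:
            raise GeometryError(
                "shape exceeds its grid cell at the requested scale; "
                "reduce the drawing scale"
            )


def export_card(card: CardSpec, families: dict[str, ShapeFamily]) -> str:
    """Render a card to an SVG string (deterministic, byte-stable)."""
    all_pts = _placed_points(card, families)
    _check_fit(all_pts)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {CARD_W_MM:g} {CARD_H_MM:g}" '
        f'width="{CARD_W_MM:g}mm" height="{CARD_H_MM:g}mm">',
        f'<rect width="{CARD_W_MM:g}" height="{CARD_H_MM:g}" fill="white"/>',
    ]
    for pts in all_pts:
        coords = " ".join(f"{x:.4f},{y:.4f}" for x, y in pts)
        parts.append(
            f'<polygon points="{coords}" fill="none" stroke="black" '
            f'stroke-width="{_STROKE_MM:g}" stroke-linejoin="round"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def render_card(
    card: CardSpec, families: dict[str, ShapeFamily], resolution: int = 480
) -> np.ndarray:
    """Rasterize a card to a grayscale float array (0 = white, 1 = ink).

    ``resolution`` is the output width in pixels; height follows the
    physical card aspect.
    """
    scale = resolution / CARD_W_MM
    h = int(round(CARD_H_MM * scale))
    img = Image.new("L", (resolution, h), 255)
    draw = ImageDraw.Draw(img)
    all_pts = _placed_points(card, families)
    _check_fit(all_pts)
    w_px = max(1, int(round(_STROKE_MM * scale)))
    for pts in all_pts:
        poly = [tuple(p) for p in (pts * scale)]
        draw.line(poly + [poly[0]], fill=0, width=w_px, joint="curve")
    return 1.0 - np.asarray(img, dtype=float) / 255.0


def render_shape(
    shape: Quadrilateral,
    rotation: float = 0.0,
    scale: float = 1.0,
    size: int = 64,
    pad: float = 0.12,
) -> np.ndarray:
    """Rasterize a single shape, centered, as a grayscale float array.

    Used as model input: one image per grid position, mimicking a foveated
    view of each shape in turn.  ``pad`` reserves a margin so the largest
    jittered shape still fits.
    """
    q = shape.transformed(rotation_deg=rotation, scale=scale)
    pts = q.array.copy()
    from shapely.geometry import Polygon

    c = np.asarray(Polygon(tuple(map(tuple, pts))).centroid.coords[0])
    pts -= c
    pts[:, 1] = -pts[:, 1]
    # fixed world-to-pixel scale: a shape of mean pairwise distance 1 at the
    # largest jitter scale (1.125) stays inside the frame
    half_extent = 1.35 * 1.125  # conservative circumradius bound, abstract units
    px_per_unit = size * (1 - 2 * pad) / (2 * half_extent)
    pts = pts * px_per_unit + size / 2.0
    img = Image.new("L", (size, size), 255)
    draw = ImageDraw.Draw(img)
    poly = [tuple(p) for p in pts]
    draw.line(poly + [poly[0]], fill=0, width=max(1, size // 48), joint="curve")
    return 1.0 - np.asarray(img, dtype=float) / 255.0
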