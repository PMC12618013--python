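"""Quadrilateral stimulus geometry for the tactile/visual intruder task.

The experiment uses 11 base quadrilaterals spanning the full range of
geometric regularity, from the square (every non-accidental property:
equal sides, equal angles, parallel sides, right angles) down to a fully
irregular quadrilateral (none).  The bases are matched on two constraints:

* the mean of the six pairwise vertex distances is the same for all 11
  shapes (a common overall-size normalizer, here fixed to 1.0), and
* the bottom-edge length is the same across 9 of the 11 shapes; the
  square and the rhombus are exempt because for them the bottom edge is
  tied to the size constraint by their defining properties.

Each base spawns four deviants obtained by displacing the bottom-right
vertex by a fixed fraction (default 30%) of the mean pairwise distance:
two slide it along the bottom edge (shorten / lengthen) and two rotate it
about the bottom-left vertex, preserving the bottom-left distance.

Vertices are stored counterclockwise starting from the top-left corner,
with y increasing upward, the top edge horizontal, and the shape centered
on its area centroid (the default, un-jittered pose).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import spearmanr
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Quadrilateral",
    "ShapeFamily",
    "DeckConfig",
    "Placement",
    "CardSpec",
    "FAMILY_ORDER",
    "mean_pairwise_distance",
    "make_base_shapes",
    "make_deviants",
    "build_deck",
    "sequence_trials",
    "nuisance_check",
]

# Empirical complexity order (rank 1 = easiest / most regular), taken from
# the visual version of the task; used as the x-axis of all analyses.
FAMILY_ORDER: tuple[str, ...] = (
    "square",
    "rectangle",
    "rhombus",
    "parallelogram",
    "right kite",
    "iso-trapezoid",
    "kite",
    "right hinge",
    "hinge",
    "trapezoid",
    "irregular",
)

DEVIANT_KINDS: tuple[str, ...] = ("shorten", "lengthen", "rotate_cw", "rotate_ccw")

# Vertex roles, in storage order (counterclockwise, y up).
TL, BL, BR, TR = 0, 1, 2, 3


class GeometryError(ValueError):
    """Raised when a construction violates a geometric constraint."""


@dataclass(frozen=True)
class Quadrilateral:
    """Four ordered planar vertices: top-left, bottom-left, bottom-right,
    top-right (counterclockwise, y up)."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) != 4:
            raise GeometryError(f"{self.label or 'quadrilateral'}: need 4 vertices")
        arr = self.array
        for i, j in itertools.combinations(range(4), 2):
            if np.allclose(arr[i], arr[j], atol=1e-12):
                raise GeometryError(
                    f"{self.label or 'quadrilateral'}: vertices {i} and {j} coincide"
                )
        if not _ShapelyPolygon(self.vertices).is_valid:
            raise GeometryError(f"{self.label or 'quadrilateral'}: self-intersecting")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    @property
    def bottom_left(self) -> np.ndarray:
        return self.array[BL]

    @property
    def bottom_right(self) -> np.ndarray:
        return self.array[BR]

    def side_lengths(self) -> np.ndarray:
        """Edge lengths in order (left, bottom, right, top)."""
        a = self.array
        return np.array([np.linalg.norm(a[(i + 1) % 4] - a[i]) for i in range(4)])

    def interior_angles(self) -> np.ndarray:
        """Interior angles in degrees at each corner (TL, BL, BR, TR)."""
        a = self.array
        out = np.empty(4)
        for i in range(4):
            p, n = a[(i - 1) % 4] - a[i], a[(i + 1) % 4] - a[i]
            cross = n[0] * p[1] - n[1] * p[0]
            ang = math.degrees(math.atan2(cross, np.dot(n, p)))
            out[i] = ang % 360.0
        return out

    def perimeter(self) -> float:
        return float(self.side_lengths().sum())

    def area(self) -> float:
        return float(_ShapelyPolygon(self.vertices).area)

    def transformed(self, rotation_deg: float = 0.0, scale: float = 1.0) -> "Quadrilateral":
        """Rotate about the area centroid and scale uniformly."""
        c = np.asarray(_ShapelyPolygon(self.vertices).centroid.coords[0])
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        pts = (self.array - c) @ rot.T * scale + c
        return Quadrilateral(tuple(map(tuple, pts)), label=self.label)


def mean_pairwise_distance(q: Quadrilateral) -> float:
    """Mean of the six pairwise vertex distances (the overall-size measure
    on which the 11 bases are matched)."""
    a = q.array
    d = [np.linalg.norm(a[i] - a[j]) for i, j in itertools.combinations(range(4), 2)]
    if min(d) <= 0:
        raise GeometryError("degenerate quadrilateral")
    return float(np.mean(d))


@dataclass(frozen=True)
class ShapeFamily:
    name: str
    base: Quadrilateral
    complexity_rank: int
    deviants: tuple[Quadrilateral, ...] = ()
    deviant_kinds: tuple[str, ...] = ()


@dataclass(frozen=True)
class DeckConfig:
    """Stimulus-generation parameters.

    ``displacement_fraction`` is the deviant vertex displacement as a
    fraction of the mean pairwise vertex distance.  The rotation set
    excludes 0 deg (to prevent alignment cues) and stays within +/-25 deg
    (shapes with rotational symmetry); the intruder is confined to the four
    central rotation/scale values so extreme jitter cannot betray it.
    """

    displacement_fraction: float = 0.30
    rotation_set: tuple[float, ...] = (-25.0, -15.0, -5.0, 5.0, 15.0, 25.0)
    scale_set: tuple[float, ...] = (0.875, 0.925, 0.975, 1.025, 1.075, 1.125)
    intruder_jitter_central_only: bool = True
    balanced_intruder_position: bool = False
    n_miniblocks: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 in self.rotation_set:
            raise ValueError("rotation_set must exclude 0 degrees")

    @property
    def central_rotations(self) -> tuple[float, ...]:
        s = sorted(self.rotation_set)
        return tuple(s[1:-1])

    @property
    def central_scales(self) -> tuple[float, ...]:
        s = sorted(self.scale_set)
        return tuple(s[1:-1])


@dataclass(frozen=True)
class Placement:
    role: str  # "reference" | "deviant"
    rotation: float
    scale: float
    position: int  # grid position 1..6


@dataclass(frozen=True)
class CardSpec:
    card_id: str
    family: str
    deviant_index: int  # 1..4
    disposition: str  # "canonical" | "swapped"
    placements: tuple[Placement, ...]
    intruder_position: int

    def __post_init__(self) -> None:
        if sorted(p.position for p in self.placements) != [1, 2, 3, 4, 5, 6]:
            raise ValueError(f"{self.card_id}: placements must cover positions 1..6")
        roles = [p.role for p in self.placements]
        majority = "reference" if self.disposition == "canonical" else "deviant"
        minority = "deviant" if self.disposition == "canonical" else "reference"
        if roles.count(minority) != 1 or roles.count(majority) != 5:
            raise ValueError(f"{self.card_id}: need exactly one {minority} among five {majority}s")
        (intr,) = [p for p in self.placements if p.role == minority]
        if intr.position != self.intruder_position:
            raise ValueError(f"{self.card_id}: intruder position mismatch")


# --------------------------------------------------------------------------
# Base-shape construction
#
# Each family is built from its defining properties with the bottom edge of
# unit length (except square and rhombus, whose bottom edge is determined by
# the size constraint), leaving one free parameter that is solved so that
# the mean pairwise vertex distance equals 1.  Remaining under-constrained
# degrees of freedom (angles and offsets of the weakly regular families) are
# frozen to the documented constants below, chosen so that no unintended
# non-accidental property holds anywhere near the detection tolerance, for
# the base and for all four of its deviants.

_PARALLELOGRAM_ANGLE = 57.5  # deg, angle at the bottom-left corner
_RHOMBUS_ANGLE = 60.0  # deg
_ISO_TRAPEZOID_TOP = 0.58  # top-edge length (bottom = 1)
_TRAPEZOID_TOP = 0.39
_TRAPEZOID_OFFSET = 0.40  # x of the top-left vertex
_KITE_TIP_RATIO = 1.775  # top-tip height / half-width
_RIGHT_HINGE_TL_X = 0.05  # x of the free top-left vertex
_HINGE_ANGLE = 70.0  # deg, hinge angle at the bottom-right corner
_HINGE_TL_X = 0.10
_IRREGULAR_TL = (0.42, 0.69)
_IRREGULAR_TR_X = 0.88


def _rot2d(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])


def _normalize_pose(pts: np.ndarray, label: str) -> Quadrilateral:
    """Rotate so the top edge (TR -> TL traversal) is horizontal with the
    shape below it, then center on the area centroid."""
    v = pts[TR] - pts[TL]
    ang = math.degrees(math.atan2(v[1], v[0]))
    pts = pts @ _rot2d(-ang).T
    c = np.asarray(_ShapelyPolygon(tuple(map(tuple, pts))).centroid.coords[0])
    return Quadrilateral(tuple(map(tuple, pts - c)), label=label)


def _builder(name):
    """Return f(param) -> vertex array [TL, BL, BR, TR] for the family."""
    if name == "square":

        def f(s):
            return np.array([[0, s], [0, 0], [s, 0], [s, s]], dtype=float)

    elif name == "rectangle":

        def f(h):
            return np.array([[0, h], [0, 0], [1, 0], [1, h]], dtype=float)

    elif name == "rhombus":

        def f(s):
            d = s * math.cos(math.radians(_RHOMBUS_ANGLE))
            h = s * math.sin(math.radians(_RHOMBUS_ANGLE))
            return np.array([[d, h], [0, 0], [s, 0], [s + d, h]], dtype=float)

    elif name == "parallelogram":

        def f(c):
            d = c * math.cos(math.radians(_PARALLELOGRAM_ANGLE))
            h = c * math.sin(math.radians(_PARALLELOGRAM_ANGLE))
            return np.array([[d, h], [0, 0], [1, 0], [1 + d, h]], dtype=float)

    elif name == "iso-trapezoid":
        a = _ISO_TRAPEZOID_TOP

        def f(h):
            return np.array(
                [[(1 - a) / 2, h], [0, 0], [1, 0], [(1 + a) / 2, h]], dtype=float
            )

    elif name == "trapezoid":
        a, x0 = _TRAPEZOID_TOP, _TRAPEZOID_OFFSET

        def f(h):
            return np.array([[x0, h], [0, 0], [1, 0], [x0 + a, h]], dtype=float)

    elif name == "kite":
        # Mirror-symmetric about the T-B diagonal; equal pairs (TL-BL, TR-TL)
        # do not survive relabeling -- roles here: TL=T, BL=L, BR=B, TR=R.
        def f(w):
            t = _KITE_TIP_RATIO * w
            b = math.sqrt(max(1.0 - w * w, 1e-12))  # |LB| = 1 (bottom edge)
            return np.array([[0, t], [-w, 0], [0, -b], [w, 0]], dtype=float)

    elif name == "right kite":
        # Kite with right angles at the two side vertices: w^2 = t*b,
        # with |LB| = sqrt(w^2 + b^2) = 1.
        def f(t):
            b = (-t + math.sqrt(t * t + 4.0)) / 2.0  # solves t*b + b^2 = 1
            w = math.sqrt(t * b)
            return np.array([[0, t], [-w, 0], [0, -b], [w, 0]], dtype=float)

    elif name == "right hinge":
        # Equal adjacent sides (bottom, right) meeting at a right angle at
        # BR, so every deviant (which displaces BR) disturbs both.
        def f(q):
            return np.array(
                [[_RIGHT_HINGE_TL_X, q], [0, 0], [1, 0], [1, 1]], dtype=float
            )

    elif name == "hinge":
        # Equal adjacent sides (bottom, right) at a generic hinge angle at BR.
        trx = 1.0 + math.cos(math.radians(180.0 - _HINGE_ANGLE))
        try_ = math.sin(math.radians(180.0 - _HINGE_ANGLE))

        def f(q):
            return np.array(
                [[_HINGE_TL_X, q], [0, 0], [1, 0], [trx, try_]], dtype=float
            )

    elif name == "irregular":

        def f(q):
            return np.array(
                [list(_IRREGULAR_TL), [0, 0], [1, 0], [_IRREGULAR_TR_X, q]], dtype=float
            )

    else:  # pragma: no cover
        raise KeyError(name)
    return f


_BRACKETS = {
    "square": (0.5, 1.5),
    "rectangle": (0.3, 1.5),
    "rhombus": (0.5, 1.5),
    "parallelogram": (0.3, 0.95),
    "iso-trapezoid": (0.4, 1.6),
    "trapezoid": (0.4, 1.6),
    "kite": (0.2, 0.8),
    "right kite": (0.3, 1.5),
    "right hinge": (0.1, 1.5),
    "hinge": (0.1, 1.5),
    "irregular": (0.3, 1.6),
}


def _make_base(name: str) -> Quadrilateral:
    build = _builder(name)

    def gap(x: float) -> float:
        return mean_pairwise_distance(
            Quadrilateral(tuple(map(tuple, build(x))), label=name)
        ) - 1.0

    lo, hi = _BRACKETS[name]
    try:
        x = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - guarded by tests
        raise GeometryError(f"size constraint unsolvable for family '{name}'") from exc
    return _normalize_pose(build(x), label=name)


def make_base_shapes(config: DeckConfig | None = None) -> list[ShapeFamily]:
    """Construct the 11 matched base quadrilaterals, each with its four
    deviants, ordered by empirical complexity rank (1 = square)."""
    config = config or DeckConfig()
    families = []
    for rank, name in enumerate(FAMILY_ORDER, start=1):
        base = _make_base(name)
        devs, kinds = make_deviants(base, config.displacement_fraction)
        families.append(
            ShapeFamily(
                name=name,
                base=base,
                complexity_rank=rank,
                deviants=tuple(devs),
                deviant_kinds=tuple(kinds),
            )
        )
    return families


def load_base_shapes() -> list[ShapeFamily]:
    """Load the frozen, versioned coordinates shipped with the package
    (identical to ``make_base_shapes()`` at default config; the fixture
    pins downstream results against solver or dependency drift)."""
    import json
    from importlib.resources import files

    data = json.loads(files("geomintruder.data").joinpath("shapes.json").read_text())
    fams = []
    for entry in data["families"]:
        base = Quadrilateral(tuple(map(tuple, entry["base"])), label=entry["name"])
        kinds = tuple(entry["deviants"])
        devs = tuple(
            Quadrilateral(
                tuple(map(tuple, entry["deviants"][k])), label=f"{entry['name']}:{k}"
            )
            for k in kinds
        )
        fams.append(
            ShapeFamily(
                name=entry["name"],
                base=base,
                complexity_rank=entry["complexity_rank"],
                deviants=devs,
                deviant_kinds=kinds,
            )
        )
    return fams


def make_deviants(
    base: Quadrilateral, fraction: float = 0.30
) -> tuple[list[Quadrilateral], list[str]]:
    """Displace the bottom-right vertex by ``fraction`` of the mean pairwise
    distance: along the bottom edge (shorten/lengthen) or around the circle
    centered on the bottom-left vertex (rotate_cw/rotate_ccw)."""
    d = fraction * mean_pairwise_distance(base)
    bl, br = base.bottom_left, base.bottom_right
    edge = br - bl
    r = np.linalg.norm(edge)
    u = edge / r
    if fraction == 0:
        pts = [br] * 4
    else:
        if d / (2 * r) > 1:
            raise GeometryError("rotation deviant impossible: chord exceeds diameter")
        alpha = 2.0 * math.asin(d / (2.0 * r))
        pts = [
            br - d * u,
            br + d * u,
            bl + _rot2d(-math.degrees(alpha)) @ edge,
            bl + _rot2d(math.degrees(alpha)) @ edge,
        ]
    out, kinds = [], []
    for kind, p in zip(DEVIANT_KINDS, pts):
        verts = base.array.copy()
        verts[BR] = p
        try:
            q = Quadrilateral(
                tuple(map(tuple, verts)), label=f"{base.label}:{kind}"
            )
        except GeometryError as exc:
            raise GeometryError(f"deviant '{kind}' of {base.label} invalid: {exc}") from exc
        out.append(q)
        kinds.append(kind)
    return out, kinds


# --------------------------------------------------------------------------
# Deck assembly and trial sequencing


def _draw_placements(
    rng: np.random.Generator, config: DeckConfig, intruder_position: int
) -> list[Placement]:
    rots = rng.choice(config.rotation_set, size=6, replace=False)
    scales = rng.choice(config.scale_set, size=6, replace=True)
    placements = []
    for pos in range(1, 7):
        if pos == intruder_position:
            if config.intruder_jitter_central_only:
                rot = float(rng.choice(config.central_rotations))
                sc = float(rng.choice(config.central_scales))
            else:
                rot = float(rng.choice(config.rotation_set))
                sc = float(rng.choice(config.scale_set))
            placements.append(Placement("intruder", rot, sc, pos))
        else:
            placements.append(
                Placement("majority", float(rots[pos - 1]), float(scales[pos - 1]), pos)
            )
    return placements


def build_deck(families: list[ShapeFamily], config: DeckConfig) -> list[CardSpec]:
    """One card per (family, deviant, disposition): 11 x 4 x 2 = 88 cards.

    Canonical cards show five jittered copies of the base plus one deviant;
    swapped cards show five jittered copies of the deviant plus the base.
    The intruder position is randomized (not balanced) unless
    ``balanced_intruder_position`` is set.
    """
    rng = np.random.default_rng(config.rng_seed)
    cards: list[CardSpec] = []
    combos = [
        (fam, dev_idx, disp)
        for fam in families
        for dev_idx in range(1, 5)
        for disp in ("canonical", "swapped")
    ]
    if config.balanced_intruder_position:
        n_rep = -(-len(combos) // 6)
        pos_pool = list(rng.permutation(np.repeat(np.arange(1, 7), n_rep)))
    for fam, dev_idx, disp in combos:
        pos = int(pos_pool.pop()) if config.balanced_intruder_position else int(
            rng.integers(1, 7)
        )
        raw = _draw_placements(rng, config, pos)
        minority = "deviant" if disp == "canonical" else "reference"
        majority = "reference" if disp == "canonical" else "deviant"
        placements = tuple(
            Placement(minority if p.role == "intruder" else majority, p.rotation, p.scale, p.position)
            for p in raw
        )
        cards.append(
            CardSpec(
                card_id=f"{fam.name.replace(' ', '_')}-d{dev_idx}-{disp}",
                family=fam.name,
                deviant_index=dev_idx,
                disposition=disp,
                placements=placements,
                intruder_position=pos,
            )
        )
    return cards


def sequence_trials(
    deck: list[CardSpec], config: DeckConfig, max_retries: int = 10_000
) -> list[CardSpec]:
    """Order the 88 cards into 8 mini-blocks of 11 such that every family
    appears once per mini-block and no two consecutive trials (including
    across block boundaries) share a family."""
    n_blocks = config.n_miniblocks
    by_family: dict[str, list[CardSpec]] = {}
    for c in deck:
        by_family.setdefault(c.family, []).append(c)
    n_fam = len(by_family)
    if any(len(v) != n_blocks for v in by_family.values()):
        raise ValueError(f"each family needs exactly {n_blocks} cards")
    rng = np.random.default_rng(config.rng_seed + 1)
    # Assign each family's cards to blocks at random, then permute within
    # blocks with rejection at the boundaries.
    assignment = {
        fam: [cards[i] for i in rng.permutation(n_blocks)]
        for fam, cards in by_family.items()
    }
    fams = list(by_family)
    seq: list[CardSpec] = []
    for b in range(n_blocks):
        for _ in range(max_retries):
            order = rng.permutation(n_fam)
            block = [assignment[fams[i]][b] for i in order]
            if seq and seq[-1].family == block[0].family:
                continue
            break
        else:
            raise RuntimeError(
                "could not satisfy sequencing constraints; try another rng_seed"
            )
        seq.extend(block)
    return seq


def nuisance_check(families: list[ShapeFamily]) -> "pandas.DataFrame":  # noqa: F821
    """Per-base perimeter and area, plus their Spearman rank correlation
    with the empirical complexity rank.  The matching constraints equalize
    overall size, not perimeter or area; this table quantifies how much
    either residual feature tracks regularity."""
    import pandas as pd

    rows = [
        {
            "family": f.name,
            "complexity_rank": f.complexity_rank,
            "perimeter": f.base.perimeter(),
            "area": f.base.area(),
        }
        for f in families
    ]
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df.attrs["spearman_perimeter"] = float(
            spearmanr(df["complexity_rank"], df["perimeter"]).statistic
        )
        df.attrs["spearman_area"] = float(
            spearmanr(df["complexity_rank"], df["area"]).statistic
        )
    return df
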