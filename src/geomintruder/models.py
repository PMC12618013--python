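"""Difficulty models for the intruder task.

Two predictors of how hard a deviant is to spot among five copies of a
reference quadrilateral:

* **Symbolic (language-of-thought) model** -- each quadrilateral is coded
  as a binary vector of non-accidental properties (equal sides, equal
  angles, parallel opposite sides, right angles); task ease is predicted
  by the L1 (Manhattan) distance between the reference and deviant codes.
  A deviant that breaks many discrete properties is predicted easy; a
  deviant of the irregular shape breaks none and is predicted hard.

* **Perceptual model** -- each of the six shapes on a card is rendered,
  passed through a feature extractor, and the image whose activation
  vector deviates most (Euclidean, on per-feature standardized
  activations) from the mean of the other five is chosen as the intruder.
  Repeating over jittered cards with additive activation noise yields a
  predicted error rate per (shape, deviant).

The bundled extractor is a fixed bank of oriented edge filters plus
downsampled pixels: deterministic and dependency-light.  Any callable with
the same interface (image -> 1-D vector) can be plugged in instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .geometry import DeckConfig, GeometryError, Quadrilateral, ShapeFamily
from .render import render_shape

__all__ = [
    "PropertyTolerance",
    "SymbolicCode",
    "detect_properties",
    "l1_distance",
    "symbolic_predictions",
    "choose_intruder",
    "FeatureExtractor",
    "EdgeBankExtractor",
    "simulate_perceptual_error",
    "perceptual_predictions",
    "SIDE_PAIRS",
    "ANGLE_PAIRS",
]

SIDE_PAIRS = tuple(itertools.combinations(range(4), 2))  # unordered side pairs
ANGLE_PAIRS = tuple(itertools.combinations(range(4), 2))  # unordered corner pairs


@dataclass(frozen=True)
class PropertyTolerance:
    """Detection tolerances for categorical property perception: relative
    length tolerance for side equality, degrees for everything angular."""

    rel_length: float = 0.01
    angle_deg: float = 1.0


@dataclass(frozen=True)
class SymbolicCode:
    """18-bit non-accidental-property code of a quadrilateral: 6 side-pair
    equality bits, 6 angle-pair equality bits, 2 opposite-side parallelism
    bits, 4 right-angle bits."""

    side_equal: tuple[int, ...]
    angle_equal: tuple[int, ...]
    parallel: tuple[int, ...]
    right_angle: tuple[int, ...]
    tolerance: PropertyTolerance = PropertyTolerance()

    @property
    def bits(self) -> np.ndarray:
        return np.concatenate(
            [self.side_equal, self.angle_equal, self.parallel, self.right_angle]
        ).astype(int)

    @property
    def n_properties(self) -> int:
        return int(self.bits.sum())


def detect_properties(
    q: Quadrilateral, tol: PropertyTolerance = PropertyTolerance()
) -> SymbolicCode:
    """Categorically perceive the non-accidental properties of a shape.

    Invariant under rotation, translation, and uniform scaling: all tests
    compare length ratios and angles only.
    """
    sides = q.side_lengths()
    if np.min(sides) <= 0:
        raise GeometryError("degenerate quadrilateral")
    angles = q.interior_angles()
    side_equal = tuple(
        int(abs(sides[i] - sides[j]) / max(sides[i], sides[j]) <= tol.rel_length)
        for i, j in SIDE_PAIRS
    )
    angle_equal = tuple(
        int(abs(angles[i] - angles[j]) <= tol.angle_deg) for i, j in ANGLE_PAIRS
    )
    a = q.array
    dirs = [a[(i + 1) % 4] - a[i] for i in range(4)]

    def _para(i: int, j: int) -> int:
        di = math.degrees(math.atan2(dirs[i][1], dirs[i][0])) % 180.0
        dj = math.degrees(math.atan2(dirs[j][1], dirs[j][0])) % 180.0
        diff = abs(di - dj)
        return int(min(diff, 180.0 - diff) <= tol.angle_deg)

    parallel = (_para(0, 2), _para(1, 3))
    right_angle = tuple(int(abs(ang - 90.0) <= tol.angle_deg) for ang in angles)
    return SymbolicCode(side_equal, angle_equal, parallel, right_angle, tol)


def l1_distance(a: SymbolicCode, b: SymbolicCode) -> int:
    """Manhattan distance between two property codes (0..18)."""
    if a.tolerance != b.tolerance:
        raise ValueError("codes computed under different tolerances")
    return int(np.abs(a.bits - b.bits).sum())


def symbolic_predictions(
    families: list[ShapeFamily], tol: PropertyTolerance = PropertyTolerance()
) -> pd.DataFrame:
    """Symbolic distance for each of the 44 (family, deviant) conditions.

    Larger distance = more properties broken = predicted easier detection.
    The analysis stage consumes ``-symbolic_distance`` as a difficulty
    score so that both model predictors point in the error direction.
    """
    rows = []
    for fam in families:
        base_code = detect_properties(fam.base, tol)
        for idx, (dev, kind) in enumerate(zip(fam.deviants, fam.deviant_kinds), start=1):
            rows.append(
                {
                    "family": fam.name,
                    "complexity_rank": fam.complexity_rank,
                    "deviant_index": idx,
                    "deviant_kind": kind,
                    "symbolic_distance": l1_distance(
                        base_code, detect_properties(dev, tol)
                    ),
                }
            )
    return pd.DataFrame(rows)


def choose_intruder(vectors: np.ndarray) -> int:
    """Pick the intruder among six activation vectors: the one whose vector
    deviates most (Euclidean) from the mean of the other five.

    Returns a 1-based position.  Exact ties resolve to the lowest position
    with a warning.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[0] != 6:
        raise ValueError("need a 6 x d array of activation vectors")
    total = v.sum(axis=0)
    dev = np.array(
        [np.linalg.norm(v[i] - (total - v[i]) / 5.0) for i in range(6)]
    )
    best = int(np.argmax(dev))
    if np.sum(np.isclose(dev, dev[best], rtol=0, atol=1e-12)) > 1:
        warnings.warn("tie among candidate intruders; choosing lowest position")
    return best + 1


class FeatureExtractor:
    """Interface: a deterministic mapping image -> 1-D activation vector."""

    name: str = "abstract"
    dimensionality: int = 0

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class EdgeBankExtractor(FeatureExtractor):
    """Oriented edge-filter bank with jitter-tolerant pooling.

    Responses of 8-orientation x 2-scale edge filters are globally pooled
    and reduced to their circular-Fourier magnitude over the orientation
    axis, and the ink distribution is summarized by radius-normalized
    radial and pairwise-distance histograms.  All channels are therefore
    approximately invariant to the card's rotation (+/-25 deg) and scale
    (+/-12.5%) jitter while remaining sensitive to the shape change that
    defines the intruder.  Purely spatial poolings (grids of filter
    responses, downsampled pixels) are deliberately absent: they respond
    more to the jitter than to the deviant, driving the choice rule below
    chance.
    """

    name = "edgebank"

    def __init__(
        self,
        orientations: int = 8,
        scales: tuple[int, ...] = (5, 9),
        radial_bins: int = 14,
        dist_bins: int = 14,
    ):
        self._orientations = orientations
        self._kernels: list[list[np.ndarray]] = []
        for k in scales:
            xs = np.arange(k) - (k - 1) / 2.0
            xx, yy = np.meshgrid(xs, xs)
            sigma = k / 3.0
            env = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
            bank = []
            for o in range(orientations):
                th = math.pi * o / orientations
                proj = xx * math.cos(th) + yy * math.sin(th)
                kern = proj * env
                kern -= kern.mean()
                bank.append(kern / np.sqrt((kern**2).sum()))
            self._kernels.append(bank)
        self._radial_bins = radial_bins
        self._dist_bins = dist_bins
        n_fft = orientations // 2 + 1
        self.dimensionality = len(scales) * n_fft + radial_bins + dist_bins

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        total = img.sum()
        if total <= 0:
            raise ValueError("blank image")
        # orientation-energy spectra: global energy per orientation, then
        # circular FFT magnitude over the orientation axis (rotation of the
        # image circularly shifts orientation energy; magnitudes are stable)
        feats = []
        for bank in self._kernels:
            energy = np.array(
                [np.abs(convolve(img, k, mode="constant")).sum() for k in bank]
            )
            feats.append(np.abs(np.fft.rfft(energy / energy.sum())))
        ys, xs = np.nonzero(img > 0.05)
        w = img[ys, xs]
        cx = np.average(xs, weights=w)
        cy = np.average(ys, weights=w)
        r = np.hypot(xs - cx, ys - cy)
        rms = np.sqrt(np.average(r**2, weights=w))
        hist, _ = np.histogram(
            r / rms, bins=self._radial_bins, range=(0.0, 2.2), weights=w
        )
        feats.append(hist / w.sum())
        # pairwise-distance histogram of ink pixels (subsampled, fixed stride)
        step = max(1, len(xs) // 160)
        px, py = xs[::step].astype(float), ys[::step].astype(float)
        d = np.hypot(px[:, None] - px[None, :], py[:, None] - py[None, :])
        iu = np.triu_indices(len(px), k=1)
        dh, _ = np.histogram(d[iu] / rms, bins=self._dist_bins, range=(0.0, 4.4))
        feats.append(dh / max(len(iu[0]), 1))
        return np.concatenate(feats)


def _standardize_rows(acts: np.ndarray) -> np.ndarray:
    """Z-score each feature across the six images (constant features -> 0)."""
    mu = acts.mean(axis=0)
    sd = acts.std(axis=0)
    sd[sd == 0] = 1.0
    return (acts - mu) / sd


def simulate_perceptual_error(
    family: ShapeFamily,
    deviant_index: int,
    extractor: FeatureExtractor,
    config: DeckConfig | None = None,
    n_reps: int = 100,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    image_size: int = 64,
) -> float:
    """Predicted error rate for one (family, deviant) condition.

    Each repetition draws a fresh jittered card (random disposition,
    intruder position, rotations, scales), renders the six shapes, adds
    Gaussian noise of sd ``noise_sd`` to the standardized activations, and
    applies the deviation-from-mean choice rule.  Returns the fraction of
    repetitions in which the chosen position is not the true intruder.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or DeckConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base = family.base
    deviant = family.deviants[deviant_index - 1]
    if np.allclose(base.array, deviant.array):
        warnings.warn(
            "deviant identical to base: intruder undefined, error rate is chance"
        )
    errors = 0
    for _ in range(n_reps):
        disp = "canonical" if rng.random() < 0.5 else "swapped"
        intruder_pos = int(rng.integers(1, 7))
        majority, minority = (
            (base, deviant) if disp == "canonical" else (deviant, base)
        )
        rots = rng.choice(config.rotation_set, size=6, replace=False)
        scales = rng.choice(config.scale_set, size=6, replace=True)
        acts = []
        for pos in range(1, 7):
            if pos == intruder_pos:
                rot = float(rng.choice(config.central_rotations))
                sc = float(rng.choice(config.central_scales))
                shape = minority
            else:
                rot, sc = float(rots[pos - 1]), float(scales[pos - 1])
                shape = majority
            acts.append(extractor(render_shape(shape, rot, sc, size=image_size)))
        acts = _standardize_rows(np.asarray(acts))
        if noise_sd > 0:
            acts = acts + rng.normal(0.0, noise_sd, size=acts.shape)
        if choose_intruder(acts) != intruder_pos:
            errors += 1
    return errors / n_reps


def perceptual_predictions(
    families: list[ShapeFamily],
    extractor: FeatureExtractor | None = None,
    config: DeckConfig | None = None,
    n_reps: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated perceptual error rate for all 44 (family, deviant)
    conditions; the perceptual difficulty score of the analysis stage."""
    extractor = extractor or EdgeBankExtractor()
    rng = np.random.default_rng(seed)
    rows = []
    for fam in families:
        for idx in range(1, 5):
            rows.append(
                {
                    "family": fam.name,
                    "complexity_rank": fam.complexity_rank,
                    "deviant_index": idx,
                    "deviant_kind": fam.deviant_kinds[idx - 1],
                    "perceptual_error_rate": simulate_perceptual_error(
                        fam, idx, extractor, config, n_reps, noise_sd, rng
                    ),
                }
            )
    return pd.DataFrame(rows)


def model_predictions(
    families: list[ShapeFamily],
    tol: PropertyTolerance = PropertyTolerance(),
    extractor: FeatureExtractor | None = None,
    config: DeckConfig | None = None,
    n_reps: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Both model predictions on the 44-condition grid, merged."""
    sym = symbolic_predictions(families, tol)
    perc = perceptual_predictions(families, extractor, config, n_reps, noise_sd, seed)
    return sym.merge(
        perc,
        on=["family", "complexity_rank", "deviant_index", "deviant_kind"],
        validate="one_to_one",
    )
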