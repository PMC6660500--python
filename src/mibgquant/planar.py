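"""Planar cardiac sympathetic-innervation quantification.

Semi-quantitative analysis of anterior planar thoracic count images acquired
after injection of a norepinephrine-analogue tracer: the heart-to-mediastinum
(H/M) count-density ratio at an early (~15 min) and a late (~4 h) time point,
and the decay- and background-corrected myocardial washout between them.

Conventions
-----------
* Images are 2-D integer count matrices indexed ``(row, col)``, 0-based.
* A pixel's center is at its integer index; a polygon ROI selects the pixels
  whose centers fall inside it (even-odd rule). Centers exactly on the
  boundary resolve by a half-open convention: left/top edges are *in*,
  right/bottom edges are *out*.
* The mediastinal reference ROI is a fixed 7x7 pixel square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "PlanarImage",
    "PolygonRoi",
    "SquareRoi",
    "RoiSet",
    "PlanarMetrics",
    "MEDIASTINUM_SIZE",
    "IODINE123_HALF_LIFE_HOURS",
    "DEFAULT_DECAY_FACTOR",
    "mean_counts",
    "hm_ratio",
    "washout",
    "decay_factor",
    "auto_mediastinal_roi",
    "compute_metrics",
]

#: Side length (pixels) of the square mediastinal reference ROI.
MEDIASTINUM_SIZE = 7

#: Physical half-life of iodine-123 in hours.
IODINE123_HALF_LIFE_HOURS = 13.22

#: Conventional decay-correction multiplier for a 3 h 45 min early-to-late
#: interval, used verbatim in the washout formula unless recomputed from the
#: half-life via :func:`decay_factor`.
DEFAULT_DECAY_FACTOR = 1.21

# Sub-pixel nudge implementing the half-open (left/top in) boundary rule.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class PlanarImage:
    """A single planar count image.

    Parameters
    ----------
    counts:
        2-D non-negative integer matrix of detected counts per pixel.
    pixel_size_mm:
        Pixel pitch in millimetres.
    timepoint:
        ``"early"`` or ``"late"``.
    duration_min:
        Acquisition duration in minutes.
    """

    counts: np.ndarray
    pixel_size_mm: float = 4.42
    timepoint: str = "early"
    duration_min: float = 10.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.size == 0:
            raise ValueError("counts must be a non-empty 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.timepoint not in ("early", "late"):
            raise ValueError(f"timepoint must be 'early' or 'late', got {self.timepoint!r}")
        if self.pixel_size_mm <= 0 or self.duration_min <= 0:
            raise ValueError("pixel_size_mm and duration_min must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple:
        return self.counts.shape


@dataclass(frozen=True)
class PolygonRoi:
    """Simple-polygon ROI given as ``(row, col)`` vertices in pixel units."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid or not poly.is_simple or poly.area <= 0:
            raise ValueError("polygon must be simple and non-degenerate")
        object.__setattr__(self, "vertices", verts)

    def mask(self, shape: tuple) -> np.ndarray:
        """Boolean pixel mask of the polygon on an image of ``shape``."""
        nrow, ncol = shape
        rr, cc = np.mgrid[0:nrow, 0:ncol]
        # (x, y) = (col, row); nudge down-right so that centers exactly on a
        # left/top edge land inside and right/bottom edges land outside.
        pts = np.column_stack(
            [cc.ravel() + _BOUNDARY_EPS, rr.ravel() + _BOUNDARY_EPS]
        )
        path = _MplPath(self.vertices[:, ::-1])
        return path.contains_points(pts).reshape(nrow, ncol)

    def bounds_ok(self, shape: tuple) -> bool:
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return bool(
            (r >= 0).all() and (c >= 0).all()
            and (r <= shape[0] - 1).all() and (c <= shape[1] - 1).all()
        )


@dataclass(frozen=True)
class SquareRoi:
    """Axis-aligned square ROI anchored at its top-left pixel."""

    row: int
    col: int
    size: int = MEDIASTINUM_SIZE

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.row < 0 or self.col < 0:
            raise ValueError("anchor must be non-negative")

    def mask(self, shape: tuple) -> np.ndarray:
        if self.row + self.size > shape[0] or self.col + self.size > shape[1]:
            raise ValueError("square ROI exceeds image bounds")
        m = np.zeros(shape, dtype=bool)
        m[self.row : self.row + self.size, self.col : self.col + self.size] = True
        return m


Roi = Union[PolygonRoi, SquareRoi]


@dataclass(frozen=True)
class RoiSet:
    """Heart polygon plus the 7x7 mediastinal reference square."""

    heart: PolygonRoi
    mediastinum: SquareRoi

    def __post_init__(self) -> None:
        if self.mediastinum.size != MEDIASTINUM_SIZE:
            raise ValueError(
                f"mediastinal ROI must be {MEDIASTINUM_SIZE}x{MEDIASTINUM_SIZE} pixels"
            )

    def validate_bounds(self, shape: tuple) -> None:
        if not self.heart.bounds_ok(shape):
            raise ValueError("heart polygon extends outside image bounds")
        self.mediastinum.mask(shape)  # raises if out of bounds


@dataclass(frozen=True)
class PlanarMetrics:
    """Planar summary metrics for one early/late image pair."""

    he: float
    me: float
    hl: float
    ml: float
    early_hm: float
    late_hm: float
    wo_percent: float

    def as_dict(self) -> dict:
        return {
            "He": self.he,
            "Me": self.me,
            "Hl": self.hl,
            "Ml": self.ml,
            "early_hm": self.early_hm,
            "late_hm": self.late_hm,
            "wo_percent": self.wo_percent,
        }


def mean_counts(image: PlanarImage, roi: Roi) -> float:
    """Arithmetic mean of counts over the pixels selected by ``roi``.

    Raises
    ------
    ValueError
        If the ROI selects no pixel or extends outside the image.
    """
    mask = roi.mask(image.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI covers no pixel centers")
    return float(image.counts[mask].mean())


def hm_ratio(image: PlanarImage, heart_roi: Roi, med_roi: Roi) -> float:
    """Heart-to-mediastinum ratio: mean counts/pixel in the heart ROI divided
    by mean counts/pixel in the mediastinal ROI."""
    h = mean_counts(image, heart_roi)
    m = mean_counts(image, med_roi)
    if m <= 0:
        raise ValueError("mediastinal mean counts must be positive for H/M")
    return h / m


def washout(
    he: float,
    me: float,
    hl: float,
    ml: float,
    decay_factor: float = DEFAULT_DECAY_FACTOR,
) -> float:
    """Background- and decay-corrected myocardial washout, in percent.

    ``100 * {(He - Me) - (Hl - Ml) * k} / (He - Me)`` where ``k`` corrects the
    late counts for physical decay of the tracer over the early-to-late
    interval (conventionally 1.21 for 3 h 45 min).

    Raises
    ------
    ValueError
        If ``He <= Me`` (the background-corrected early uptake is not
        positive, so washout is undefined) or the decay factor is not
        positive.
    """
    if decay_factor <= 0:
        raise ValueError("decay_factor must be positive")
    if he <= me:
        raise ValueError("washout undefined: early heart counts must exceed mediastinum")
    return 100.0 * ((he - me) - (hl - ml) * decay_factor) / (he - me)


def decay_factor(
    interval_hours: float, half_life_hours: float = IODINE123_HALF_LIFE_HOURS
) -> float:
    """Physical-decay correction multiplier ``2**(interval/half_life)``."""
    if interval_hours < 0 or half_life_hours <= 0:
        raise ValueError("interval must be >= 0 and half-life > 0")
    return 2.0 ** (interval_hours / half_life_hours)


def auto_mediastinal_roi(
    image: PlanarImage,
    size: int = MEDIASTINUM_SIZE,
    margin: int = 1,
    column_band: tuple = (1.0 / 3.0, 2.0 / 3.0),
    upper_fraction: float = 0.5,
) -> SquareRoi:
    """Place the mediastinal reference square automatically.

    Scans ``size`` x ``size`` windows in the upper part of the image restricted
    to a midline column band and returns the window with the minimal mean
    counts (the mediastinum is the low-count gap between the lung fields).
    Ties resolve deterministically topmost-then-leftmost, and the window never
    touches the outer ``margin`` pixels.
    """
    nrow, ncol = image.shape
    r_lo = margin
    r_hi = int(math.floor(nrow * upper_fraction)) - size  # last valid anchor row
    c_lo = max(margin, int(math.floor(ncol * column_band[0])))
    c_hi = min(ncol - margin - size, int(math.ceil(ncol * column_band[1])) - size)
    if r_hi < r_lo or c_hi < c_lo:
        raise ValueError("image too small for automatic mediastinal ROI placement")

    counts = image.counts.astype(np.float64)
    windows = np.lib.stride_tricks.sliding_window_view(counts, (size, size))
    means = windows.mean(axis=(2, 3))[r_lo : r_hi + 1, c_lo : c_hi + 1]
    # argmin of the row-major flattened array is topmost-then-leftmost.
    i, j = np.unravel_index(int(np.argmin(means)), means.shape)
    return SquareRoi(row=r_lo + int(i), col=c_lo + int(j), size=size)


def compute_metrics(
    early: PlanarImage,
    late: PlanarImage,
    rois_early: RoiSet,
    rois_late: Optional[RoiSet] = None,
    decay: float = DEFAULT_DECAY_FACTOR,
) -> PlanarMetrics:
    """Full planar pipeline: early/late H/M ratios and washout.

    One RoiSet per time point; if ``rois_late`` is omitted, the early set is
    propagated to the late image.
    """
    if early.timepoint != "early" or late.timepoint != "late":
        raise ValueError("compute_metrics expects an (early, late) image pair")
    rois_late = rois_late if rois_late is not None else rois_early
    rois_early.validate_bounds(early.shape)
    rois_late.validate_bounds(late.shape)

    he = mean_counts(early, rois_early.heart)
    me = mean_counts(early, rois_early.mediastinum)
    hl = mean_counts(late, rois_late.heart)
    ml = mean_counts(late, rois_late.mediastinum)
    if me <= 0 or ml <= 0:
        raise ValueError("mediastinal mean counts must be positive")
    return PlanarMetrics(
        he=he,
        me=me,
        hl=hl,
        ml=ml,
        early_hm=he / me,
        late_hm=hl / ml,
        wo_percent=washout(he, me, hl, ml, decay_factor=decay),
    )
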