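"""SPECT 17-segment uptake quantification and defect scoring.

Maps a reconstructed short-axis count volume onto the standard AHA
17-segment division of the left ventricle (6 basal, 6 mid-cavity, 4 apical
sectors plus the apex), expresses each segment's mean counts as a percentage
of the maximum segment, and applies a 5-point defect score per segment:

====================  =====
uptake (% of max)     score
====================  =====
>= 70 (normal)          0
60-69 (mild)            1
50-59 (moderate)        2
40-49 (severe)          3
<= 39 (absent)          4
====================  =====

Summing the 17 scores on the early and late acquisitions yields the early
and late summed scores (ESS, LSS); their difference DSS = ESS - LSS.

Geometry conventions
--------------------
Volumes are indexed ``(slice, row, col)`` with the slice index increasing
from apex to base. In-plane, the anterior wall is at 12 o'clock (the -row
direction) and segment numbering proceeds counter-clockwise in the standard
display (septum on the left): basal/mid rings run anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral in 60-degree sectors;
the apical ring uses four 90-degree sectors (anterior, septal, inferior,
lateral). Myocardial voxels are selected by an annulus (radial band) around
the per-slice long-axis center; the apex is a solid cap. Volumes handled
here are synthetic or pre-segmented, so no edge-detection segmentation is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LVGeometry",
    "ShortAxisVolume",
    "SegmentProfile",
    "SummedScores",
    "ReaderConfig",
    "N_SEGMENTS",
    "MAX_SUMMED_SCORE",
    "slice_rings",
    "segment_labels",
    "segment_uptake",
    "score_segment",
    "score_segments",
    "summed_scores",
    "multi_reader_scores",
]

N_SEGMENTS = 17
MAX_SUMMED_SCORE = 4 * N_SEGMENTS  # 68


@dataclass(frozen=True)
class LVGeometry:
    """Left-ventricular long-axis metadata for a short-axis volume.

    ``centers`` holds the (row, col) long-axis intersection per slice;
    ``apex_slice``/``base_slice`` bound the myocardium (inclusive);
    ``inner_radius``/``outer_radius`` delimit the wall annulus in voxels.
    """

    centers: np.ndarray
    apex_slice: int
    base_slice: int
    inner_radius: float
    outer_radius: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("centers must be (n_slices, 2)")
        if not (0 <= self.apex_slice < self.base_slice < centers.shape[0]):
            raise ValueError("need 0 <= apex_slice < base_slice < n_slices")
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        object.__setattr__(self, "centers", centers)


@dataclass(frozen=True)
class ShortAxisVolume:
    """Reconstructed short-axis count volume plus LV axis metadata."""

    counts: np.ndarray
    geometry: LVGeometry
    voxel_size_mm: float = 6.4

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.size == 0:
            raise ValueError("counts must be a non-empty 3-D array")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        g = self.geometry
        if g.centers.shape[0] != counts.shape[0]:
            raise ValueError("geometry centers must match the number of slices")
        nrow, ncol = counts.shape[1:]
        r, c = g.centers[:, 0], g.centers[:, 1]
        if (r < 0).any() or (c < 0).any() or (r > nrow - 1).any() or (c > ncol - 1).any():
            raise ValueError("slice centers must lie inside slice bounds")
        if (
            (r - g.outer_radius < -0.5).any()
            or (c - g.outer_radius < -0.5).any()
            or (r + g.outer_radius > nrow - 0.5).any()
            or (c + g.outer_radius > ncol - 0.5).any()
        ):
            raise ValueError("wall annulus exceeds volume bounds")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple:
        return self.counts.shape


def slice_rings(apex_slice: int, base_slice: int) -> dict:
    """Partition the myocardial slice range into the four axial rings.

    The apex cap takes ``max(1, n // 6)`` slices at the apex end; the rest is
    split into three near-equal contiguous blocks for the apical, mid and
    basal rings (apex side first). Returns ``{"apex": [...], "apical": [...],
    "mid": [...], "basal": [...]}`` slice-index lists.
    """
    n = base_slice - apex_slice + 1
    if n < 4:
        raise ValueError("need at least 4 myocardial slices for 4 rings")
    n_cap = max(1, n // 6)
    rest = np.arange(apex_slice + n_cap, base_slice + 1)
    apical, mid, basal = np.array_split(rest, 3)
    return {
        "apex": list(range(apex_slice, apex_slice + n_cap)),
        "apical": apical.tolist(),
        "mid": mid.tolist(),
        "basal": basal.tolist(),
    }


def _sector_angles(shape2d: tuple, center: np.ndarray) -> tuple:
    """Per-pixel radius and angle (degrees CCW from anterior) for one slice."""
    rr, cc = np.mgrid[0 : shape2d[0], 0 : shape2d[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    rho = np.hypot(dr, dc)
    # Display frame: x = col (right), y = -row (up). Math angle phi has
    # anterior (up) at 90 deg; theta measures CCW from anterior.
    theta = np.degrees(np.arctan2(-dr, dc)) - 90.0
    return rho, np.mod(theta, 360.0)


def segment_labels(shape: tuple, geometry: LVGeometry) -> np.ndarray:
    """AHA segment label volume: 0 = background, 1..17 = segment ids."""
    labels = np.zeros(shape, dtype=np.int8)
    rings = slice_rings(geometry.apex_slice, geometry.base_slice)
    ring_base_segment = {"basal": 1, "mid": 7}
    for ring_name, slices in rings.items():
        for s in slices:
            rho, theta = _sector_angles(shape[1:], geometry.centers[s])
            if ring_name == "apex":
                labels[s][rho < geometry.outer_radius] = 17
                continue
            wall = (rho >= geometry.inner_radius) & (rho < geometry.outer_radius)
            if ring_name == "apical":
                # four 90-degree sectors centered on anterior/septal/inferior/lateral
                sector = np.floor(np.mod(theta + 45.0, 360.0) / 90.0).astype(np.int8)
                labels[s][wall] = (13 + sector)[wall]
            else:
                # six 60-degree sectors centered on the standard walls
                sector = np.floor(np.mod(theta + 30.0, 360.0) / 60.0).astype(np.int8)
                labels[s][wall] = (ring_base_segment[ring_name] + sector)[wall]
    return labels


def segment_uptake(volume: ShortAxisVolume) -> np.ndarray:
    """Mean counts per AHA segment, normalized so the maximum segment is 100.

    Raises
    ------
    ValueError
        If any segment has no voxels or the myocardium contains no counts.
    """
    labels = segment_labels(volume.shape, volume.geometry)
    counts = volume.counts.astype(np.float64)
    means = np.empty(N_SEGMENTS, dtype=np.float64)
    for seg in range(1, N_SEGMENTS + 1):
        sel = labels == seg
        if not sel.any():
            raise ValueError(f"geometry yields an empty segment {seg}")
        means[seg - 1] = counts[sel].mean()
    peak = means.max()
    if peak <= 0:
        raise ValueError("all-zero myocardium: uptake undefined")
    # clamp the 1-ulp overshoot float division can produce at the peak
    return np.minimum(100.0 * means / peak, 100.0)


def score_segment(uptake_pct: float, strict_gt70: bool = False) -> int:
    """5-point defect score for one segment's uptake percentage.

    The percentage is rounded half-up to the nearest integer first. With the
    default contiguous bins an exact 70 is normal (score 0) and an exact 39
    is absent (score 4); ``strict_gt70`` instead requires uptake strictly
    above 70 for a normal score (an exact 70 then falls in the mild bin).
    """
    if not np.isfinite(uptake_pct) or uptake_pct < 0 or uptake_pct > 100:
        raise ValueError(f"uptake must be in [0, 100], got {uptake_pct!r}")
    u = int(np.floor(uptake_pct + 0.5))  # round half-up
    normal = (u > 70) if strict_gt70 else (u >= 70)
    if normal:
        return 0
    if u >= 60:
        return 1
    if u >= 50:
        return 2
    if u >= 40:
        return 3
    return 4


def score_segments(uptake_pct: Sequence[float], strict_gt70: bool = False) -> np.ndarray:
    arr = np.asarray(uptake_pct, dtype=float)
    return np.array([score_segment(u, strict_gt70=strict_gt70) for u in arr], dtype=np.int64)


@dataclass(frozen=True)
class SegmentProfile:
    """17 per-segment uptake percentages with their defect scores."""

    uptake_pct: np.ndarray
    scores: np.ndarray
    timepoint: str = "early"

    def __post_init__(self) -> None:
        uptake = np.asarray(self.uptake_pct, dtype=float)
        scores = np.asarray(self.scores, dtype=np.int64)
        if uptake.shape != (N_SEGMENTS,) or scores.shape != (N_SEGMENTS,):
            raise ValueError(f"profiles carry exactly {N_SEGMENTS} segments")
        if (uptake < 0).any() or (uptake > 100).any():
            raise ValueError("uptake percentages must lie in [0, 100]")
        if (scores < 0).any() or (scores > 4).any():
            raise ValueError("scores must lie in 0..4")
        if self.timepoint not in ("early", "late"):
            raise ValueError("timepoint must be 'early' or 'late'")
        object.__setattr__(self, "uptake_pct", uptake)
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_uptake(
        cls, uptake_pct: Sequence[float], timepoint: str = "early", strict_gt70: bool = False
    ) -> "SegmentProfile":
        uptake = np.asarray(uptake_pct, dtype=float)
        return cls(
            uptake_pct=uptake,
            scores=score_segments(uptake, strict_gt70=strict_gt70),
            timepoint=timepoint,
        )

    @classmethod
    def from_volume(
        cls, volume: ShortAxisVolume, timepoint: str = "early", strict_gt70: bool = False
    ) -> "SegmentProfile":
        return cls.from_uptake(segment_uptake(volume), timepoint=timepoint, strict_gt70=strict_gt70)

    @property
    def summed(self) -> int:
        return int(self.scores.sum())


@dataclass(frozen=True)
class SummedScores:
    """Early and late summed defect scores and their difference."""

    ess: int
    lss: int
    dss: int

    def __post_init__(self) -> None:
        for name, v in (("ess", self.ess), ("lss", self.lss)):
            if not 0 <= v <= MAX_SUMMED_SCORE:
                raise ValueError(f"{name} must lie in 0..{MAX_SUMMED_SCORE}")
        if self.dss != self.ess - self.lss:
            raise ValueError("dss must equal ess - lss exactly")


def summed_scores(early: SegmentProfile, late: SegmentProfile) -> SummedScores:
    """Sum the 17 segmental scores per time point; DSS = ESS - LSS."""
    if early.timepoint != "early" or late.timepoint != "late":
        raise ValueError("summed_scores expects an (early, late) profile pair")
    ess = early.summed
    lss = late.summed
    return SummedScores(ess=ess, lss=lss, dss=ess - lss)


@dataclass(frozen=True)
class ReaderConfig:
    """Perturbation model of one observer's visual uptake estimation.

    ``bias`` shifts all segment estimates; ``sd`` is the standard deviation
    of independent Gaussian per-segment estimation noise, both in uptake
    percentage points.
    """

    name: str
    bias: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def multi_reader_scores(
    volume: ShortAxisVolume,
    readers: Sequence[ReaderConfig],
    timepoint: str = "early",
    seed: Optional[int] = None,
    strict_gt70: bool = False,
) -> dict:
    """Simulate independent observers scoring the same volume.

    Each reader perceives the computed segment uptake perturbed by their
    bias/noise model (clipped to [0, 100]) and scores it with the standard
    bins; returns ``{reader name: SegmentProfile}``. Feeds inter-observer
    agreement analysis.
    """
    if len(readers) < 2:
        raise ValueError("inter-observer simulation needs >= 2 readers")
    rng = np.random.default_rng(seed)
    uptake = segment_uptake(volume)
    out = {}
    for reader in readers:
        perceived = uptake + reader.bias + rng.normal(0.0, reader.sd, size=N_SEGMENTS)
        perceived = np.clip(perceived, 0.0, 100.0)
        out[reader.name] = SegmentProfile.from_uptake(
            perceived, timepoint=timepoint, strict_gt70=strict_gt70
        )
    return out
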