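"""Synthetic phantoms and cohorts with known ground truth.

Three generators make every downstream stage testable without any image or
patient data:

* :func:`make_planar_pair` — anterior planar count-image pairs with a
  heart-shaped region and a low-count mediastinal band at controllable true
  mean counts, optionally Poisson-noised;
* :func:`make_spect_volume` — short-axis volumes whose annular myocardial
  wall follows the AHA 17-segment layout with per-segment uptake ground
  truth;
* :func:`make_cohort` — a survival cohort whose covariate and imaging-metric
  marginals are calibrated to the published baseline table of a 170-patient
  chronic-heart-failure ICD cohort, and whose event process encodes a
  log-linear early-summed-score (ESS) effect together with a bell-shaped
  late-H/M category effect (piecewise hazard multipliers).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import planar as planar_mod
from . import spect as spect_mod
from .planar import MEDIASTINUM_SIZE, PlanarImage, PolygonRoi, RoiSet, SquareRoi
from .spect import LVGeometry, N_SEGMENTS, ShortAxisVolume, segment_labels
from .stats import EVENT_TYPES, categorize_late_hm

__all__ = [
    "PlanarTruth",
    "PlanarPhantom",
    "make_planar_pair",
    "VolumeTruth",
    "SpectPhantom",
    "make_spect_volume",
    "CohortCalibration",
    "make_cohort",
    "COHORT_COLUMNS",
]


# ---------------------------------------------------------------------------
# planar phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanarTruth:
    """True mean counts/pixel for the planar phantom regions.

    ``he``/``me`` are the early heart and mediastinal means, ``hl``/``ml``
    the late ones. The implied true washout (with the conventional decay
    factor) is available as :attr:`wo_percent`.
    """

    he: float
    me: float
    hl: float
    ml: float
    decay_factor: float = planar_mod.DEFAULT_DECAY_FACTOR

    def __post_init__(self) -> None:
        if not (self.he > self.me >= 0):
            raise ValueError("need he > me >= 0")
        if self.hl < 0 or self.ml < 0:
            raise ValueError("late means must be non-negative")

    @property
    def wo_percent(self) -> float:
        """True washout: the display formula applied to the four true means."""
        return planar_mod.washout(self.he, self.me, self.hl, self.ml, self.decay_factor)

    @property
    def early_hm(self) -> float:
        if self.me <= 0:
            raise ValueError("early H/M undefined for me = 0")
        return self.he / self.me

    @property
    def late_hm(self) -> float:
        if self.ml <= 0:
            raise ValueError("late H/M undefined for ml = 0")
        return self.hl / self.ml


@dataclass(frozen=True)
class PlanarPhantom:
    """Generated early/late planar pair with the ROIs and region masks that
    produced it (masks serve as ground-truth oracles in tests)."""

    early: PlanarImage
    late: PlanarImage
    rois: RoiSet
    heart_mask: np.ndarray
    mediastinum_band_mask: np.ndarray
    truth: PlanarTruth

    def __iter__(self):
        return iter((self.early, self.late, self.rois))


def _heart_polygon(shape: tuple, n_vertices: int = 24) -> np.ndarray:
    """Elliptical heart-shaped polygon in the lower mid-left thorax."""
    nrow, ncol = shape
    cr, cc = 0.60 * (nrow - 1), 0.55 * (ncol - 1)
    a, b = 0.17 * nrow, 0.17 * ncol
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([cr + a * np.cos(t), cc + b * np.sin(t)])


def make_planar_pair(
    truth: PlanarTruth,
    image_shape: tuple = (128, 128),
    noise: bool = False,
    seed: Optional[int] = None,
) -> PlanarPhantom:
    """Generate an early/late planar image pair from region-mean ground truth.

    The image contains a low-count mediastinal band in the upper midline, an
    elliptical heart region in the lower mid-field, and a lung-like
    background between the two region means. Without noise, counts are the
    rounded true means (exact for integer-valued truths); with noise, counts
    are Poisson with the true means as expectations. The returned ``RoiSet``
    marks the generating regions (the heart polygon itself and a 7x7 square
    inside the mediastinal band).
    """
    nrow, ncol = image_shape
    if nrow < 32 or ncol < 32:
        raise ValueError("image_shape must be at least 32 x 32")

    # mediastinal band: upper midline, tall/wide enough to hold the 7x7 square
    band_r0 = max(2, nrow // 16)
    band_r1 = band_r0 + max(9, nrow // 4)  # exclusive
    half_w = max(4, ncol // 16)
    band_c0, band_c1 = ncol // 2 - half_w, ncol // 2 + half_w  # exclusive

    verts = _heart_polygon(image_shape)
    heart_roi = PolygonRoi(verts)
    heart_mask = heart_roi.mask(image_shape)

    band_mask = np.zeros(image_shape, dtype=bool)
    band_mask[band_r0:band_r1, band_c0:band_c1] = True
    if (heart_mask & band_mask).any():
        raise ValueError("phantom geometry overlap: enlarge image_shape")

    med_roi = SquareRoi(row=band_r0 + 1, col=ncol // 2 - MEDIASTINUM_SIZE // 2)
    if (
        med_roi.row + MEDIASTINUM_SIZE > band_r1
        or med_roi.col < band_c0
        or med_roi.col + MEDIASTINUM_SIZE > band_c1
    ):
        raise ValueError("mediastinal square does not fit the band; enlarge image_shape")

    rng = np.random.default_rng(seed)
    images = {}
    for timepoint, h_mean, m_mean in (
        ("early", truth.he, truth.me),
        ("late", truth.hl, truth.ml),
    ):
        # lungs sit between the mediastinal dip and the heart in count density
        background = m_mean + 0.25 * abs(h_mean - m_mean)
        expected = np.full(image_shape, background, dtype=float)
        expected[band_mask] = m_mean
        expected[heart_mask] = h_mean
        if noise:
            counts = rng.poisson(expected)
        else:
            counts = np.rint(expected).astype(np.int64)
        images[timepoint] = PlanarImage(counts=counts, timepoint=timepoint)

    return PlanarPhantom(
        early=images["early"],
        late=images["late"],
        rois=RoiSet(heart=heart_roi, mediastinum=med_roi),
        heart_mask=heart_mask,
        mediastinum_band_mask=band_mask,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# SPECT phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeTruth:
    """Ground truth for a synthetic short-axis volume.

    ``segment_uptake`` holds the 17 per-segment uptake percentages (the
    maximum must be 100 when any myocardium is present); wall geometry is an
    annulus of ``inner_radius``..``outer_radius`` voxels around a fixed
    in-plane center between ``apex_slice`` and ``base_slice``;
    ``peak_counts`` is the voxel mean at 100% uptake and
    ``background_level`` the extra-myocardial count level.
    """

    segment_uptake: np.ndarray
    shape: tuple = (32, 64, 64)
    center: Optional[tuple] = None
    apex_slice: int = 4
    base_slice: int = 27
    inner_radius: float = 8.0
    outer_radius: float = 13.0
    peak_counts: float = 500.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        uptake = np.asarray(self.segment_uptake, dtype=float)
        if uptake.shape != (N_SEGMENTS,):
            raise ValueError(f"segment_uptake must have exactly {N_SEGMENTS} values")
        if (uptake < 0).any() or (uptake > 100).any():
            raise ValueError("segment uptake must lie in [0, 100]")
        if uptake.max() != 100.0:
            raise ValueError("maximum segment uptake must be 100 (% of maximum)")
        if self.background_level < 0 or self.peak_counts <= 0:
            raise ValueError("peak_counts must be > 0 and background_level >= 0")
        center = self.center
        if center is None:
            center = ((self.shape[1] - 1) / 2.0, (self.shape[2] - 1) / 2.0)
        object.__setattr__(self, "segment_uptake", uptake)
        object.__setattr__(self, "center", tuple(float(x) for x in center))
        geometry = self.geometry  # LVGeometry validates radii and slice order
        cr, cc = self.center
        nrow, ncol = self.shape[1], self.shape[2]
        if (
            cr - geometry.outer_radius < -0.5
            or cc - geometry.outer_radius < -0.5
            or cr + geometry.outer_radius > nrow - 0.5
            or cc + geometry.outer_radius > ncol - 0.5
        ):
            raise ValueError("wall annulus exceeds volume bounds")

    @property
    def geometry(self) -> LVGeometry:
        centers = np.tile(np.asarray(self.center, dtype=float), (self.shape[0], 1))
        return LVGeometry(
            centers=centers,
            apex_slice=self.apex_slice,
            base_slice=self.base_slice,
            inner_radius=self.inner_radius,
            outer_radius=self.outer_radius,
        )


@dataclass(frozen=True)
class SpectPhantom:
    """Generated short-axis volume plus its ground-truth segment labels."""

    volume: ShortAxisVolume
    labels: np.ndarray
    truth: VolumeTruth


def make_spect_volume(
    truth: VolumeTruth, noise: bool = False, seed: Optional[int] = None
) -> SpectPhantom:
    """Paint an annular myocardial wall with per-segment uptake ground truth.

    Each AHA sector's voxels get mean counts proportional to its segment
    uptake (``peak_counts`` at 100%); optionally Poisson-noised. The label
    volume marking which voxel belongs to which segment is returned for use
    as an independent oracle.
    """
    geometry = truth.geometry
    labels = segment_labels(truth.shape, geometry)
    expected = np.full(truth.shape, float(truth.background_level))
    for seg in range(1, N_SEGMENTS + 1):
        expected[labels == seg] = truth.peak_counts * truth.segment_uptake[seg - 1] / 100.0
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)
    volume = ShortAxisVolume(counts=counts, geometry=geometry)
    return SpectPhantom(volume=volume, labels=labels, truth=truth)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def _frac(k: int, n: int = 170) -> float:
    return k / n


@dataclass(frozen=True)
class CohortCalibration:
    """Distributional calibration of the synthetic cohort.

    Continuous marginals are (mean, sd) pairs and binary covariates are
    prevalence proportions; the defaults reproduce the published baseline
    table of the 170-patient cohort the generator emulates. The event
    process is an exponential hazard scaled log-linearly by ESS and by a
    piecewise late-H/M category multiplier (the bell shape), with uniform
    administrative censoring over ``censor_window_months``.
    """

    n: int = 170
    # continuous marginals: (mean, sd)
    age: tuple = (64.2, 12.6)
    bmi: tuple = (1.73, 0.59)
    lvef: tuple = (31.1, 9.4)
    early_hm: tuple = (1.62, 0.21)
    late_hm: tuple = (1.53, 0.23)
    wo_percent: tuple = (30.9, 18.4)
    ess: tuple = (31.4, 11.9)
    lss: tuple = (36.2, 12.3)
    # binary prevalences
    p_male: float = _frac(139)
    p_diabetes: float = _frac(61)
    p_hypertension: float = _frac(134)
    p_smoker: float = _frac(65)
    p_dyslipidemia: float = _frac(80)
    p_ischemic: float = _frac(101)
    p_lbbb: float = _frac(43)
    p_nyha3: float = _frac(84)
    p_acei: float = _frac(74)
    p_arb: float = _frac(32)
    p_mra: float = _frac(105)
    p_beta_blocker: float = _frac(162)
    p_amiodarone: float = _frac(38)
    p_statin: float = _frac(98)
    p_diuretic: float = _frac(158)
    p_primary_prevention: float = _frac(156)
    # hazard model
    log_hr_ess: float = math.log(1.028)
    hm_category_multipliers: tuple = (1.0, 2.0, 1.0)  # (low, intermediate, high)
    baseline_hazard: float = 0.0056  # events / month at ESS = 0
    hm_cuts: tuple = (1.2, 1.6)
    event_type_probs: tuple = (25 / 69, 22 / 69, 8 / 69, 14 / 69)  # VT, ICD, arrest, SCD
    censor_window_months: tuple = (1.0, 51.0)
    # cross-correlations of the Gaussian copula (all others default to 0)
    corr_ess_lss: float = 0.8
    corr_late_hm_ess: float = -0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("p_"):
                p = getattr(self, f.name)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{f.name} must lie in [0, 1]")
        for name in ("age", "bmi", "lvef", "early_hm", "late_hm", "wo_percent", "ess", "lss"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} sd must be > 0")
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9 or min(self.event_type_probs) < 0:
            raise ValueError("event_type_probs must be non-negative and sum to 1")
        if any(m < 0 for m in self.hm_category_multipliers):
            raise ValueError("hazard multipliers must be >= 0")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        lo, hi = self.censor_window_months
        if not 0 < lo < hi:
            raise ValueError("censor window must satisfy 0 < lo < hi")
        if not -1 < self.corr_ess_lss < 1 or not -1 < self.corr_late_hm_ess < 1:
            raise ValueError("correlations must lie in (-1, 1)")


# order of the correlated continuous block
_CONTINUOUS = ("age", "bmi", "lvef", "early_hm", "late_hm", "wo_percent", "ess", "lss")

# physical redraw bounds per continuous variable (redraw, not clip, so the
# calibrated means are preserved to first order)
_BOUNDS = {
    "age": (0.0, 110.0),
    "bmi": (0.05, 60.0),
    "lvef": (1.0, 80.0),
    "early_hm": (0.3, 5.0),
    "late_hm": (0.3, 5.0),
    "wo_percent": (-100.0, 100.0),
    "ess": (-0.49, 68.49),  # rounded to integers in [0, 68] afterwards
    "lss": (-0.49, 68.49),
}

#: Cohort CSV column dictionary (also documented in docs/methods.md).
COHORT_COLUMNS = (
    "id", "age", "sex_male", "bmi", "lvef", "nyha_class", "ischemic", "lbbb",
    "diabetes", "hypertension", "smoker", "dyslipidemia", "med_acei",
    "med_arb", "med_mra", "med_beta_blocker", "med_amiodarone", "med_statin",
    "med_diuretic", "prevention", "early_hm", "late_hm", "wo_percent", "ess",
    "lss", "dss", "followup_months", "event_type", "event_month",
)


def _draw_continuous(calib: CohortCalibration, n: int, rng: np.random.Generator) -> dict:
    """Correlated Gaussian draws, redrawing rows outside physical bounds."""
    means = np.array([getattr(calib, v)[0] for v in _CONTINUOUS])
    sds = np.array([getattr(calib, v)[1] for v in _CONTINUOUS])
    k = len(_CONTINUOUS)
    corr = np.eye(k)
    i_hm, i_ess, i_lss = _CONTINUOUS.index("late_hm"), _CONTINUOUS.index("ess"), _CONTINUOUS.index("lss")
    corr[i_ess, i_lss] = corr[i_lss, i_ess] = calib.corr_ess_lss
    corr[i_hm, i_ess] = corr[i_ess, i_hm] = calib.corr_late_hm_ess
    cov = corr * np.outer(sds, sds)
    chol = np.linalg.cholesky(cov)

    lows = np.array([_BOUNDS[v][0] for v in _CONTINUOUS])
    highs = np.array([_BOUNDS[v][1] for v in _CONTINUOUS])

    def draw(m: int) -> np.ndarray:
        return means + rng.standard_normal((m, k)) @ chol.T

    x = draw(n)
    for _ in range(1000):
        bad = ((x < lows) | (x > highs)).any(axis=1)
        if not bad.any():
            break
        x[bad] = draw(int(bad.sum()))
    else:
        raise RuntimeError("redraw loop failed to satisfy physical bounds")
    return {v: x[:, j] for j, v in enumerate(_CONTINUOUS)}


def make_cohort(
    calib: Optional[CohortCalibration] = None,
    seed: Optional[int] = None,
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a patient cohort with known covariate and hazard ground truth.

    Continuous covariates come from a Gaussian copula with the calibrated
    marginals (out-of-range rows redrawn); binary covariates are Bernoulli at
    the calibrated prevalences. Each patient's event hazard is

        h_i = baseline_hazard * exp(log_hr_ess * ESS_i) * m(category(late H/M_i))

    with exponential event times, uniform censoring over the configured
    window (a tie counts as an event), and the arrhythmic event type drawn
    from the calibrated multinomial.
    """
    calib = calib if calib is not None else CohortCalibration()
    n = int(n if n is not None else calib.n)
    if n < 10:
        raise ValueError("n < 10 gives degenerate statistics")
    rng = np.random.default_rng(seed)

    cont = _draw_continuous(calib, n, rng)
    ess = np.floor(cont["ess"] + 0.5).astype(np.int64)
    lss = np.floor(cont["lss"] + 0.5).astype(np.int64)

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "age": cont["age"],
            "sex_male": rng.binomial(1, calib.p_male, n).astype(bool),
            "bmi": cont["bmi"],
            "lvef": cont["lvef"],
            "nyha_class": np.where(rng.binomial(1, calib.p_nyha3, n) == 1, 3, 2),
            "ischemic": rng.binomial(1, calib.p_ischemic, n).astype(bool),
            "lbbb": rng.binomial(1, calib.p_lbbb, n).astype(bool),
            "diabetes": rng.binomial(1, calib.p_diabetes, n).astype(bool),
            "hypertension": rng.binomial(1, calib.p_hypertension, n).astype(bool),
            "smoker": rng.binomial(1, calib.p_smoker, n).astype(bool),
            "dyslipidemia": rng.binomial(1, calib.p_dyslipidemia, n).astype(bool),
            "med_acei": rng.binomial(1, calib.p_acei, n).astype(bool),
            "med_arb": rng.binomial(1, calib.p_arb, n).astype(bool),
            "med_mra": rng.binomial(1, calib.p_mra, n).astype(bool),
            "med_beta_blocker": rng.binomial(1, calib.p_beta_blocker, n).astype(bool),
            "med_amiodarone": rng.binomial(1, calib.p_amiodarone, n).astype(bool),
            "med_statin": rng.binomial(1, calib.p_statin, n).astype(bool),
            "med_diuretic": rng.binomial(1, calib.p_diuretic, n).astype(bool),
            "prevention": np.where(
                rng.binomial(1, calib.p_primary_prevention, n) == 1, "primary", "secondary"
            ),
            "early_hm": cont["early_hm"],
            "late_hm": cont["late_hm"],
            "wo_percent": cont["wo_percent"],
            "ess": ess,
            "lss": lss,
            "dss": ess - lss,
        }
    )

    cats = categorize_late_hm(df["late_hm"].to_numpy(), cuts=calib.hm_cuts)
    mult = np.select(
        [cats == "low", cats == "intermediate", cats == "high"],
        calib.hm_category_multipliers,
    ).astype(float)
    rate = calib.baseline_hazard * np.exp(calib.log_hr_ess * ess) * mult

    # exponential event time; zero hazard -> never an event
    u = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, -np.log(1.0 - u) / np.where(rate > 0, rate, 1.0), np.inf)
    censor = rng.uniform(*calib.censor_window_months, size=n)
    event = t_event <= censor
    followup = np.where(event, t_event, censor)

    type_draw = rng.choice(
        np.array(EVENT_TYPES[1:]), size=n, p=np.asarray(calib.event_type_probs)
    )
    df["followup_months"] = followup
    df["event_type"] = np.where(event, type_draw, "none")
    df["event_month"] = np.where(event, t_event, np.nan)
    return df
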