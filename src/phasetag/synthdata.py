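"""Synthetic micrographs of rod-shaped bacteria with known ground truth.

Every downstream stage (segmentation, condensate calling, time-course
classification) is tested against scenes produced here, so the generator is
first-class, deterministic code.  A scene is a field of non-overlapping
spherocylindrical cells (rectangle capped by half-disks -- the standard 2D
model of an E. coli cell) at uniform cytoplasmic intensity.  A configurable
fraction of cells carries condensates: disks placed on the cell's medial axis
(near a pole by default) whose intensity is the cytoplasm multiplied by the
partition ratio rho >= 1, the condensed/dilute enrichment the analysis is
meant to recover.  The rendered field is blurred by a Gaussian point-spread
function, offset by a uniform background, degraded by Poisson shot noise and
Gaussian read noise, and quantized to the camera bit depth.

The generator also produces synthetic growth/fluorescence tables: optical
density follows a logistic curve and total fluorescence accumulates
proportionally to the optical density times a per-variant expression rate
that decays over time (protein synthesis slows as cultures exhaust
resources), so the fluorescence/OD proxy rises after induction and then
plateaus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import PlacementError
from .micrograph import DEFAULT_PIXEL_SIZE_UM, Micrograph


@dataclass
class SceneParams:
    """Everything needed to render one field of cells, reproducibly.

    Intensities are linear camera units; geometry is in micrometres and
    converted through ``pixel_size``.  ``partition_ratio`` is the true
    condensed/dilute intensity ratio rho >= 1 assigned to condensate-carrying
    cells.  Noise defaults emulate a moderately bright widefield exposure:
    Poisson shot noise (``poisson_gain`` electrons/count) plus Gaussian read
    noise.  Set ``poisson_gain=None`` and ``read_noise_sigma=0`` for
    noise-free renders, and ``psf_sigma=0`` to disable blur.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 40
    cell_length_range: tuple[float, float] = (2.0, 4.0)  # um, pole to pole
    cell_width_range: tuple[float, float] = (0.9, 1.1)  # um
    cytoplasm_intensity: float = 300.0
    background_intensity: float = 20.0
    condensate_fraction: float = 0.5
    partition_ratio: float = 1.8
    condensate_radius_range: tuple[float, float] = (0.25, 0.40)  # um
    foci_per_cell: int = 1
    focus_placement: Literal["polar", "uniform"] = "polar"
    psf_sigma: float = 1.2  # px
    poisson_gain: Optional[float] = 1.0  # None disables shot noise
    read_noise_sigma: float = 3.0  # camera counts; 0 disables
    bit_depth: int = 16
    border_margin_px: int = 8
    min_separation_px: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.partition_ratio < 1:
            raise ValueError(f"partition_ratio must be >= 1, got {self.partition_ratio}")
        if not (0 <= self.condensate_fraction <= 1):
            raise ValueError(f"condensate_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.foci_per_cell < 1:
            raise ValueError("foci_per_cell must be >= 1")
        for name in ("cytoplasm_intensity", "background_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.cell_length_range
        wlo, whi = self.cell_width_range
        if lo > hi or wlo > whi or wlo <= 0:
            raise ValueError("invalid cell geometry ranges")
        if hi <= whi:
            raise ValueError("cell length range must exceed width range")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    label: int
    centroid: tuple[float, float]  # (row, col), px
    orientation: float  # radians, axis direction
    length_um: float
    width_um: float
    axis_endpoints: tuple[tuple[float, float], tuple[float, float]]  # cap centers
    has_condensate: bool
    true_rho: float
    foci: list[tuple[float, float, float]] = field(default_factory=list)  # (r, c, radius_px)


@dataclass
class SceneGroundTruth:
    """Per-cell truth plus a labeled mask image (0 = background)."""

    labels: np.ndarray  # int32, same shape as the image
    cells: list[CellTruth]
    params: SceneParams

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                dict(
                    label=c.label,
                    centroid_row=c.centroid[0],
                    centroid_col=c.centroid[1],
                    orientation=c.orientation,
                    length_um=c.length_um,
                    width_um=c.width_um,
                    has_condensate=c.has_condensate,
                    true_rho=c.true_rho,
                    n_foci=len(c.foci),
                )
            )
        return pd.DataFrame(rows)


def _spherocylinder_mask(
    shape: tuple[int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    half_width: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean mask of points within ``half_width`` of segment p0-p1.

    Returns the local mask and the bounding-box slices into the full frame.
    """
    r0 = int(max(0, math.floor(min(p0[0], p1[0]) - half_width - 1)))
    r1 = int(min(shape[0], math.ceil(max(p0[0], p1[0]) + half_width + 2)))
    c0 = int(max(0, math.floor(min(p0[1], p1[1]) - half_width - 1)))
    c1 = int(min(shape[1], math.ceil(max(p0[1], p1[1]) + half_width + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    return dist <= half_width, (slice(r0, r1), slice(c0, c1))


def _disk_mask(shape, center, radius) -> tuple[np.ndarray, tuple[slice, slice]]:
    return _spherocylinder_mask(shape, np.asarray(center, float), np.asarray(center, float), radius)


def generate_scene(params: SceneParams) -> tuple[Micrograph, SceneGroundTruth]:
    """Render one synthetic field of cells; bit-identical for identical params.

    Raises :class:`~phasetag.errors.PlacementError` if the requested number of
    non-overlapping cells cannot be placed within a bounded number of retries.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    px = params.pixel_size

    img = np.full(shape, float(params.background_intensity))
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    cells: list[CellTruth] = []

    max_attempts = 60 * max(params.n_cells, 1)
    attempts = 0
    sep = params.min_separation_px

    for idx in range(params.n_cells):
        placed = False
        while attempts < max_attempts:
            attempts += 1
            length = rng.uniform(*params.cell_length_range) / px  # px
            width = rng.uniform(*params.cell_width_range) / px
            if length <= width:
                continue
            half_w = width / 2.0
            theta = rng.uniform(0, math.pi)
            axis_len = length - width  # cap-center to cap-center
            margin = params.border_margin_px + length / 2.0 + 1
            if 2 * margin >= min(shape):
                raise PlacementError(
                    "cells too large for the field: reduce cell size or "
                    "enlarge image_shape"
                )
            center = np.array(
                [
                    rng.uniform(margin, shape[0] - margin),
                    rng.uniform(margin, shape[1] - margin),
                ]
            )
            direction = np.array([math.sin(theta), math.cos(theta)])
            p0 = center - direction * axis_len / 2.0
            p1 = center + direction * axis_len / 2.0
            # inflate by the separation margin for the overlap test
            test_mask, test_box = _spherocylinder_mask(shape, p0, p1, half_w + sep)
            if (occupied[test_box] & test_mask).any():
                continue
            mask, box = _spherocylinder_mask(shape, p0, p1, half_w)
            label = idx + 1
            occupied[test_box] |= test_mask
            labels_box = labels[box]
            labels_box[mask] = label
            img_box = img[box]
            img_box[mask] = params.background_intensity + params.cytoplasm_intensity

            carries = bool(rng.random() < params.condensate_fraction)
            rho = params.partition_ratio if carries else 1.0
            foci: list[tuple[float, float, float]] = []
            if carries and rho > 1.0:
                for _ in range(params.foci_per_cell):
                    rf_um = rng.uniform(*params.condensate_radius_range)
                    rf = min(rf_um / px, half_w - 0.5)  # must fit inside the cell
                    rf = max(rf, 1.0)
                    if params.focus_placement == "polar":
                        u = rng.uniform(0.02, 0.18)
                        if rng.random() < 0.5:
                            u = 1.0 - u
                    else:
                        u = rng.uniform(0.0, 1.0)
                    fc = p0 + direction * (u * axis_len)
                    fmask, fbox = _disk_mask(shape, fc, rf)
                    fmask = fmask & (labels[fbox] == label)
                    img_f = img[fbox]
                    img_f[fmask] = params.background_intensity + rho * params.cytoplasm_intensity
                    foci.append((float(fc[0]), float(fc[1]), float(rf)))
            cells.append(
                CellTruth(
                    label=label,
                    centroid=(float(center[0]), float(center[1])),
                    orientation=theta,
                    length_um=length * px,
                    width_um=width * px,
                    axis_endpoints=(
                        (float(p0[0]), float(p0[1])),
                        (float(p1[0]), float(p1[1])),
                    ),
                    has_condensate=bool(carries and rho > 1.0 and foci),
                    true_rho=rho,
                    foci=foci,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placed only {idx} of {params.n_cells} cells after "
                f"{max_attempts} attempts; use fewer or smaller cells, or a "
                "larger image"
            )

    if params.psf_sigma > 0:
        img = gaussian_filter(img, params.psf_sigma, mode="reflect")
    if params.poisson_gain is not None:
        gain = params.poisson_gain
        img = rng.poisson(np.maximum(img, 0) / gain).astype(float) * gain
    if params.read_noise_sigma > 0:
        img = img + rng.normal(0.0, params.read_noise_sigma, size=shape)

    max_val = 2 ** params.bit_depth - 1
    img = np.clip(np.round(img), 0, max_val)
    micro = Micrograph(img, bit_depth=params.bit_depth, pixel_size=px)
    return micro, SceneGroundTruth(labels=labels, cells=cells, params=params)


@dataclass
class LogisticOD:
    """Logistic growth-curve parameters for optical density."""

    od0: float = 0.05
    carrying_capacity: float = 2.0
    growth_rate: float = 0.8  # 1/h

    def __call__(self, t: np.ndarray) -> np.ndarray:
        k, od0, r = self.carrying_capacity, self.od0, self.growth_rate
        if od0 == k:
            return np.full_like(np.asarray(t, float), k)
        a = (k - od0) / od0
        return k / (1.0 + a * np.exp(-r * np.asarray(t, float)))


def generate_growth_table(
    duration_h: float,
    od_params: LogisticOD | None = None,
    expression_rate: float = 100.0,
    expression_decay_h: Optional[float] = 5.0,
    dt_h: float = 0.25,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic (time, od, fluorescence) table for one strain.

    Optical density follows a logistic curve; total fluorescence accumulates
    at ``expression_rate * OD(t) * exp(-t / expression_decay_h)`` so that the
    per-cell proxy (fluorescence / OD) rises after induction and plateaus as
    expression winds down in stationary phase.  ``expression_decay_h=None``
    disables the decay, in which case constant OD gives the closed form
    ``proxy(t) = expression_rate * t``.  ``noise_cv`` adds multiplicative
    log-normal noise of that coefficient of variation to both channels.
    """
    if duration_h <= 0:
        raise ValueError(f"duration must be positive, got {duration_h}")
    if expression_rate <= 0:
        raise ValueError(f"expression_rate must be positive, got {expression_rate}")
    if dt_h <= 0:
        raise ValueError(f"dt_h must be positive, got {dt_h}")
    od_params = od_params or LogisticOD()
    if od_params.growth_rate < 0 or od_params.od0 <= 0 or od_params.carrying_capacity <= 0:
        raise ValueError("growth parameters must be positive")

    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    od = od_params(t)
    decay = np.ones_like(t) if expression_decay_h is None else np.exp(-t / expression_decay_h)
    rate = expression_rate * od * decay
    # cumulative trapezoid of the synthesis rate
    fluor = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(t))])

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        od = od * rng.lognormal(-sigma**2 / 2, sigma, size=t.shape)
        fluor = fluor * rng.lognormal(-sigma**2 / 2, sigma, size=t.shape)

    return pd.DataFrame({"time": t, "od": od, "fluorescence": fluor})


def scenes_for_timecourse(
    base: SceneParams,
    fractions_by_time: dict[float, float],
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[tuple[float, int], SceneParams]:
    """Scene parameters for a (timepoint x replicate) grid of one strain.

    ``fractions_by_time`` maps hours post-induction to the true
    condensate-carrying fraction at that time.  Each cell of the grid gets an
    independent seed derived from ``seed``.
    """
    out = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(fractions_by_time) * n_replicates)
    i = 0
    for t in sorted(fractions_by_time):
        for rep in range(n_replicates):
            out[(t, rep)] = replace(
                base,
                condensate_fraction=fractions_by_time[t],
                seed=int(children[i].generate_state(1)[0] % (2**31)),
            )
            i += 1
    return out
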