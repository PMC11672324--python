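"""Wound-dye influx curves, resealing classification and repair metrics.

A membrane-impermeable dye enters the cell only while the wound is open, so
the wounded cell's dye intensity over time reports resealing: a curve that
saturates to a plateau means the wound closed, a linear rise means it did
not.  The curve is background-corrected against a nearby unwounded cell
(which also absorbs photobleaching) and normalized to the wounded cell's
intensity at the last pre-wound frame.

Classification codifies the plateau-vs-linear distinction as a slope-ratio
rule: the least-squares slope over a late post-wound window divided by the
slope over an early window.  A saturating curve has a late slope far below
its early slope; a linear curve keeps the ratio near 1.

The module also carries the two hydrogel-experiment resealing metrics (the
around-wound influx curve in a 20 µm diameter ROI and the wound-delineation
area fraction) and the scrape-assay repair percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Movie

__all__ = [
    "ResealingCurve",
    "ScrapeCounts",
    "influx_curve",
    "classify_resealing",
    "around_wound_intensity",
    "delineation_area_fraction",
    "scrape_repair_percentage",
]


@dataclass
class ResealingCurve:
    """Background-subtracted, baseline-normalized dye-influx time series.

    ``time`` is seconds post-wound (negative for pre-wound frames);
    ``normalized_intensity`` equals 1 at the reference (last pre-wound)
    frame by construction.  ``classification`` is filled by
    :func:`classify_resealing`.
    """

    time: np.ndarray
    normalized_intensity: np.ndarray
    classification: str = "indeterminate"
    plateau_stats: Optional[tuple[float, float]] = None  # (late slope, early slope)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        self.time = t
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time,
                             "normalized_intensity": self.normalized_intensity})


@dataclass(frozen=True)
class ScrapeCounts:
    """Flow-count table of one scrape-assay sample.

    ``n_wounded``: cells positive for the wound-entry marker (AF488);
    ``n_unrepaired``: the subset of those also positive for the
    viability dye (PI), i.e. wounded and not resealed.
    """

    n_wounded: int
    n_unrepaired: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_unrepaired <= self.n_wounded):
            raise ValueError("unrepaired count must lie in [0, wounded count]")


def _mask_means(movie: Movie, channel: int, mask: np.ndarray) -> np.ndarray:
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    return movie.data[:, channel][:, mask].mean(axis=1)


def influx_curve(movie: Movie, wounded_mask: np.ndarray, unwounded_mask: np.ndarray,
                 channel: int = 0, classify: bool = True, **classify_kwargs
                 ) -> ResealingCurve:
    """Dye-influx curve of the wounded cell, background-corrected.

    Per frame the mean dye intensity over the wounded-cell mask minus the
    mean over a nearby unwounded cell's mask (removing ambient background
    and bleaching), normalized to the corrected intensity at the last
    pre-wound frame.  Raises if the reference intensity is not positive
    (the curve cannot be normalized).
    """
    wounded_mask = np.asarray(wounded_mask, dtype=bool)
    unwounded_mask = np.asarray(unwounded_mask, dtype=bool)
    if (wounded_mask & unwounded_mask).any():
        raise ValueError("wounded and unwounded masks must be disjoint")
    corrected = _mask_means(movie, channel, wounded_mask) - _mask_means(
        movie, channel, unwounded_mask)
    ref_frame = movie.wound_frame - 1
    if ref_frame < 0:
        raise ValueError("no pre-wound frame to normalize against")
    ref = corrected[ref_frame]
    if ref <= 0:
        raise ValueError("non-positive reference intensity — cannot normalize")
    curve = ResealingCurve(time=movie.times(), normalized_intensity=corrected / ref)
    if classify:
        curve.classification = classify_resealing(curve, **classify_kwargs)
    return curve


def classify_resealing(curve: ResealingCurve,
                       early_window: Optional[tuple[float, float]] = None,
                       late_window: Optional[tuple[float, float]] = None,
                       slope_ratio_threshold: float = 0.2) -> str:
    """Plateau-vs-linear verdict on an influx curve.

    Least-squares slopes are fit over an early and a late post-wound
    window (defaults: first and last third of the post-wound record).  A
    late/early slope ratio below ``slope_ratio_threshold`` means the
    influx saturated ("resealed"); a ratio at or above it with a positive
    late slope means sustained influx ("failed").  A flat or negative
    early slope leaves the curve "indeterminate" — there was no influx to
    classify.  The verdict is invariant to adding a constant to the curve.
    """
    post = curve.time >= 0
    t_post = curve.time[post]
    if len(t_post) < 6:
        raise ValueError("too few post-wound samples to classify")
    span = t_post[-1] - t_post[0]
    if early_window is None:
        early_window = (t_post[0], t_post[0] + span / 3.0)
    if late_window is None:
        late_window = (t_post[-1] - span / 3.0, t_post[-1])

    def _slope(window: tuple[float, float]) -> float:
        sel = (curve.time >= window[0]) & (curve.time <= window[1])
        if sel.sum() < 3:
            raise ValueError("classification window holds fewer than 3 samples")
        return float(np.polyfit(curve.time[sel], curve.normalized_intensity[sel], 1)[0])

    early = _slope(early_window)
    late = _slope(late_window)
    curve.plateau_stats = (late, early)

    # no meaningful early influx → nothing to classify
    rise = np.ptp(curve.normalized_intensity[post])
    if early <= 0 or early * span < 0.05 * max(rise, 1e-12):
        return "indeterminate"
    ratio = late / early
    if ratio < slope_ratio_threshold:
        return "resealed"
    if late > 0:
        return "failed"
    return "indeterminate"


def around_wound_intensity(movie: Movie, diameter: float = 20.0, channel: int = 0
                           ) -> ResealingCurve:
    """Dye intensity in a wound-centered disk ROI, whole-cell normalized.

    Mean channel intensity inside a disk of the given diameter (µm) around
    the wound center, per frame, normalized to the mean whole-cell
    intensity at the last pre-wound frame.  Quantifies the local resealing
    delay around the wound.  If the disk misses the cell footprint
    entirely the curve is flagged ``disk_outside_cell``.
    """
    h, w = movie.shape_px
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = movie.wound_center
    d = np.hypot(xx * movie.pixel_size - cx, yy * movie.pixel_size - cy)
    disk = d <= diameter / 2.0
    if not disk.any():
        raise ValueError("around-wound disk lies outside the image")

    flags: tuple[str, ...] = ()
    if movie.cell_mask is not None and not (disk & movie.cell_mask).any():
        flags = ("disk_outside_cell",)

    disk_mean = _mask_means(movie, channel, disk)
    cell = movie.cell_mask if movie.cell_mask is not None else np.ones((h, w), dtype=bool)
    ref_frame = movie.wound_frame - 1
    if ref_frame < 0:
        raise ValueError("no pre-wound frame to normalize against")
    ref = _mask_means(movie, channel, cell)[ref_frame]
    if ref <= 0:
        raise ValueError("non-positive reference intensity — cannot normalize")
    return ResealingCurve(time=movie.times(), normalized_intensity=disk_mean / ref,
                          flags=flags)


def delineation_area_fraction(delineation_mask: np.ndarray, cell_mask: np.ndarray) -> float:
    """Area of the dye-enriched wound delineation as a fraction of the cell.

    Both masks are binary images; the delineation must lie within the
    cell.  Normalizing by the whole-cell area removes the bias from the
    varying cell sizes across substrate conditions.
    """
    delineation_mask = np.asarray(delineation_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("cell mask is empty")
    if (delineation_mask & ~cell_mask).any():
        raise ValueError("delineation mask extends outside the cell mask")
    return float(delineation_mask.sum()) / float(cell_mask.sum())


def scrape_repair_percentage(counts: ScrapeCounts) -> float:
    """Percentage of scrape-wounded cells that resealed.

    100 · (wounded − unrepaired) / wounded, from the flow counts of
    wound-marker-positive cells and the viability-dye-positive subset.
    """
    if counts.n_wounded <= 0:
        raise ValueError("no wounded cells — percentage undefined")
    return 100.0 * (counts.n_wounded - counts.n_unrepaired) / counts.n_wounded
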