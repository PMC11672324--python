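"""Synthetic wound-repair movies, force traces and count tables with ground truth.

No raw imaging data accompany the study this package quantifies, so every
downstream stage is exercised on simulated data whose statistical structure
matches what the analysis assumes:

* a two-channel 512×512 time-lapse with 2 pre-wound frames, a 2.5 µm²
  circular wound, and a ~30 s resealing phase;
* channel 0 (wound dye): membrane-outline baseline plus dye influx —
  saturating ``I₀(1 − e^(−t/τ))`` for a resealing cell, linear for a failed
  one — and a localized accumulation at the wound site;
* channel 1 (event marker): punctae born as an inhomogeneous spatio-temporal
  Poisson process.  A steady birth–death background runs throughout; an
  exocytic burst concentrated near the wound fills the first ~10 s after
  wounding; a delayed endocytic burst follows the resealing phase, each
  endocytic event placed near a previously planted exocytic site with
  probability ``assoc_prob`` (isotropic Gaussian jitter ``assoc_sd``) and
  uniformly over the cell otherwise;
* multiplicative photobleaching and additive Gaussian read noise (optional
  Poisson shot noise) on the rendered frames.

Everything is driven by one integer seed; identical inputs give
bit-identical movies, traces and ground truth.  Positions and times in the
ground truth are physical (µm, s); pixels appear only at rendering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .biophysics import ForceTrace
from .core import Movie
from .rings import build_rings

__all__ = [
    "SimConfig",
    "EventProcessParams",
    "GroundTruth",
    "generate_movie",
    "generate_force_trace",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and wound timing of a simulated movie.

    Defaults mirror the assay being emulated: 512×512 frames, a 2.5 µm²
    circular wound, 2 pre-wound frames followed by 100 post-wound frames,
    and a ~30 s resealing phase.  The frame interval is configurable and
    defaults to 1 s.  The default pixel size (0.25 µm) is chosen so the
    512-pixel field (128 µm) accommodates the full six-ring partition with
    20 µm diameter increments; see the methods note.
    """

    image_shape: tuple[int, int] = (512, 512)  # (height, width) px
    pixel_size: float = 0.25  # µm / px
    n_frames: int = 102  # total, including pre-wound frames
    frame_interval: float = 1.0  # s
    n_prewound_frames: int = 2
    wound_center: Optional[tuple[float, float]] = None  # (x, y) µm; None → image center
    wound_area: float = 2.5  # µm²
    reseal_time: float = 30.0  # s post-wound
    rng_seed: int = 0
    # cell footprint: filled ellipse centered on the image
    cell_axes: Optional[tuple[float, float]] = None  # semi-axes (µm); None → 45 %/38 % of field
    # channel-0 rendering
    membrane_intensity: float = 80.0
    interior_intensity: float = 20.0
    influx_amplitude: float = 100.0
    influx_tau: Optional[float] = None  # s; None → reseal_time / 3
    fail_slope: float = 2.0  # intensity / s for a failed wound
    wound_blob_sigma: float = 2.0  # µm, localized dye accumulation at the wound

    def __post_init__(self) -> None:
        if self.n_prewound_frames < 1:
            raise ValueError("need at least one pre-wound frame")
        if self.n_frames <= self.n_prewound_frames:
            raise ValueError("movie must extend past the wound frame")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.wound_area < 0 or self.reseal_time < 0:
            raise ValueError("rates, sizes and times must be non-negative")
        h, w = self.image_shape
        cx, cy = self.wound_center_um
        if not (0 <= cx <= w * self.pixel_size and 0 <= cy <= h * self.pixel_size):
            raise ValueError("wound_center outside the image")

    @property
    def field_um(self) -> tuple[float, float]:
        h, w = self.image_shape
        return h * self.pixel_size, w * self.pixel_size

    @property
    def wound_center_um(self) -> tuple[float, float]:
        if self.wound_center is not None:
            return self.wound_center
        h_um, w_um = self.field_um
        return (w_um / 2.0, h_um / 2.0)

    @property
    def wound_radius_um(self) -> float:
        return math.sqrt(self.wound_area / math.pi)

    @property
    def wound_frame(self) -> int:
        return self.n_prewound_frames

    def cell_semi_axes(self) -> tuple[float, float]:
        if self.cell_axes is not None:
            return self.cell_axes
        h_um, w_um = self.field_um
        return (0.45 * w_um, 0.38 * h_um)

    def cell_mask(self) -> np.ndarray:
        """Filled-ellipse cell footprint, centered on the image."""
        h, w = self.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        x_um = xx * self.pixel_size
        y_um = yy * self.pixel_size
        h_um, w_um = self.field_um
        a, b = self.cell_semi_axes()
        return ((x_um - w_um / 2) / a) ** 2 + ((y_um - h_um / 2) / b) ** 2 <= 1.0

    def cell_area_um2(self) -> float:
        """Area of the rasterized cell mask in µm²."""
        return float(self.cell_mask().sum()) * self.pixel_size**2


@dataclass(frozen=True)
class EventProcessParams:
    """Intensity and placement rules of the punctae point process.

    ``steady_rate`` is the homogeneous birth rate (events µm⁻² s⁻¹) over
    the cell footprint throughout the movie.  During ``exo_window``
    (seconds post-wound) ring k's birth rate is multiplied by
    ``exo_boost_by_ring[k−1]``; rings follow the analysis geometry with
    ``ring_increment`` µm diameter steps.  Endocytic events run during
    ``(reseal_time, end]`` at ``endo_boost × steady_rate`` over the cell:
    with probability ``assoc_prob`` an event is planted at a uniformly
    chosen earlier exocytic site plus isotropic Gaussian jitter
    (``assoc_sd``), otherwise uniformly over the cell mask.

    Each puncta lives for an exponential lifetime (mean ``lifetime_mean``)
    and is rendered as a Gaussian spot of ``spot_amplitude`` counts and
    ``spot_sigma`` µm.  ``spot_amplitude / noise_sd`` is the nominal SNR.
    """

    steady_rate: float = 2e-3  # events µm⁻² s⁻¹
    exo_boost_by_ring: tuple[float, ...] = (5.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    exo_window: tuple[float, float] = (0.0, 10.0)  # s post-wound, (lo, hi]
    endo_boost: float = 5.0
    assoc_prob: float = 0.9
    assoc_sd: float = 1.0  # µm
    lifetime_mean: float = 4.0  # s
    spot_amplitude: float = 200.0
    spot_sigma: float = 0.3  # µm
    bleach_rate: float = 0.005  # s⁻¹
    noise_sd: float = 20.0
    shot_noise: bool = False
    shot_gain: float = 1.0  # photons per count when shot noise is enabled
    ring_increment: float = 20.0  # µm diameter step of the generator's rings

    def __post_init__(self) -> None:
        if not (0.0 <= self.assoc_prob <= 1.0):
            raise ValueError("assoc_prob must lie in [0, 1]")
        if self.exo_window[0] >= self.exo_window[1]:
            raise ValueError("exo_window must be a non-empty interval")
        for name in ("steady_rate", "endo_boost", "assoc_sd", "lifetime_mean",
                     "spot_amplitude", "spot_sigma", "bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(b < 0 for b in self.exo_boost_by_ring):
            raise ValueError("exo boosts must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth of one simulated dataset.

    ``events`` has one row per planted puncta: ``type`` ∈ {steady, exo,
    endo}, birth ``frame``, position (µm), ``lifetime_s`` and, for
    associated endocytic events, the ``parent_exo_id`` (row index of the
    parent) — null otherwise.
    """

    events: pd.DataFrame
    influx_class: str = "resealed"  # {"resealed", "failed"}
    influx_params: dict = field(default_factory=dict)
    force_gt: Optional[tuple[float, float]] = None  # (peak, plateau) pN
    frame_interval: float = 1.0

    def live_events(self, frame: int) -> pd.DataFrame:
        """Events visible in ``frame`` (born, not yet expired)."""
        e = self.events
        if len(e) == 0:
            return e
        frames_alive = np.maximum(1, np.ceil(e["lifetime_s"] / self.frame_interval))
        alive = (e["frame"] <= frame) & (frame < e["frame"] + frames_alive)
        return e[alive]


def _uniform_in_mask(rng: np.random.Generator, mask: np.ndarray, pixel_size: float,
                     n: int, exclude_center=None, exclude_radius: float = 0.0) -> np.ndarray:
    """n points (x, y) µm uniform over the mask, by rejection sampling."""
    h, w = mask.shape
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(16, 2 * (n - filled))
        x = rng.uniform(0, w * pixel_size, m)
        y = rng.uniform(0, h * pixel_size, m)
        col = np.clip((x / pixel_size).astype(int), 0, w - 1)
        row = np.clip((y / pixel_size).astype(int), 0, h - 1)
        ok = mask[row, col]
        if exclude_center is not None and exclude_radius > 0:
            ok &= np.hypot(x - exclude_center[0], y - exclude_center[1]) > exclude_radius
        xs, ys = x[ok], y[ok]
        take = min(len(xs), n - filled)
        out[filled:filled + take, 0] = xs[:take]
        out[filled:filled + take, 1] = ys[:take]
        filled += take
    return out


def _plant_events(cfg: SimConfig, proc: EventProcessParams,
                  rng: np.random.Generator, mask: np.ndarray) -> pd.DataFrame:
    """Sample the full spatio-temporal point process; returns the event table."""
    dt = cfg.frame_interval
    wound_xy = cfg.wound_center_um
    cell_area = float(mask.sum()) * cfg.pixel_size**2
    rings = build_rings(wound_xy, cfg.wound_area,
                        n_rings=len(proc.exo_boost_by_ring),
                        diameter_increment=proc.ring_increment)

    rows: list[dict] = []

    # -- steady background, whole movie, uniform over the cell
    for f in range(cfg.n_frames):
        n = rng.poisson(proc.steady_rate * cell_area * dt)
        if n == 0:
            continue
        pts = _uniform_in_mask(rng, mask, cfg.pixel_size, n)
        for x, y in pts:
            rows.append(dict(type="steady", frame=f, x_um=x, y_um=y,
                             lifetime_s=rng.exponential(proc.lifetime_mean),
                             parent_exo_id=np.nan))

    # -- exocytic burst: extra events (boost − 1 above background) per ring
    #    during the exo window, placed uniformly within the annulus ∩ cell
    lo, hi = proc.exo_window
    ring_masks = _ring_pixel_masks(cfg, mask, rings)
    for f in range(cfg.wound_frame, cfg.n_frames):
        t = (f - cfg.wound_frame) * dt
        if not (lo < t <= hi):
            continue
        for k, boost in enumerate(proc.exo_boost_by_ring, start=1):
            extra = max(boost - 1.0, 0.0)  # background already covers 1×
            ring_mask = ring_masks[k - 1]
            area_k = float(ring_mask.sum()) * cfg.pixel_size**2
            if extra <= 0 or area_k == 0:
                continue
            n = rng.poisson(extra * proc.steady_rate * area_k * dt)
            if n == 0:
                continue
            pts = _uniform_in_mask(rng, ring_mask, cfg.pixel_size, n)
            for x, y in pts:
                rows.append(dict(type="exo", frame=f, x_um=x, y_um=y,
                                 lifetime_s=rng.exponential(proc.lifetime_mean),
                                 parent_exo_id=np.nan))

    events = pd.DataFrame(rows, columns=["type", "frame", "x_um", "y_um",
                                         "lifetime_s", "parent_exo_id"])

    # -- endocytic burst after the resealing phase, spatially coupled to
    #    previous exocytic sites
    exo_idx = events.index[events["type"] == "exo"].to_numpy()
    endo_rows: list[dict] = []
    for f in range(cfg.wound_frame, cfg.n_frames):
        t = (f - cfg.wound_frame) * dt
        if t <= cfg.reseal_time:
            continue
        n = rng.poisson(proc.endo_boost * proc.steady_rate * cell_area * dt)
        for _ in range(n):
            parent = np.nan
            prior = exo_idx[events.loc[exo_idx, "frame"] < f] if len(exo_idx) else exo_idx
            if len(prior) and rng.random() < proc.assoc_prob:
                parent = int(rng.choice(prior))
                px = events.at[parent, "x_um"] + rng.normal(0, proc.assoc_sd)
                py = events.at[parent, "y_um"] + rng.normal(0, proc.assoc_sd)
            else:
                px, py = _uniform_in_mask(rng, mask, cfg.pixel_size, 1)[0]
            endo_rows.append(dict(type="endo", frame=f, x_um=px, y_um=py,
                                  lifetime_s=rng.exponential(proc.lifetime_mean),
                                  parent_exo_id=parent))
    if endo_rows:
        events = pd.concat([events, pd.DataFrame(endo_rows)], ignore_index=True)
    return events


def _ring_pixel_masks(cfg: SimConfig, cell_mask: np.ndarray, rings) -> list[np.ndarray]:
    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx * cfg.pixel_size - cfg.wound_center_um[0],
                 yy * cfg.pixel_size - cfg.wound_center_um[1])
    radii = np.concatenate([[rings.wound_radius], rings.boundaries])
    return [cell_mask & (d > radii[k]) & (d <= radii[k + 1]) for k in range(rings.n_rings)]


def _render_channel1(cfg: SimConfig, gt: GroundTruth, proc: EventProcessParams,
                     mask: np.ndarray) -> np.ndarray:
    """Event-marker channel: every live puncta as a Gaussian spot, bleached."""
    h, w = cfg.image_shape
    out = np.zeros((cfg.n_frames, h, w), dtype=np.float64)
    sigma_px = proc.spot_sigma / cfg.pixel_size
    r = max(2, int(math.ceil(4 * sigma_px)))
    for f in range(cfg.n_frames):
        frame = out[f]
        live = gt.live_events(f)
        bleach = math.exp(-proc.bleach_rate * f * cfg.frame_interval)
        for x, y in live[["x_um", "y_um"]].to_numpy():
            cx, cy = x / cfg.pixel_size, y / cfg.pixel_size
            c0, c1 = int(max(0, math.floor(cx - r))), int(min(w, math.ceil(cx + r) + 1))
            r0, r1 = int(max(0, math.floor(cy - r))), int(min(h, math.ceil(cy + r) + 1))
            if c0 >= c1 or r0 >= r1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            frame[r0:r1, c0:c1] += proc.spot_amplitude * bleach * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
            )
    return out


def _render_channel0(cfg: SimConfig, resealed: bool, proc: EventProcessParams,
                     mask: np.ndarray) -> tuple[np.ndarray, dict]:
    """Wound-dye channel: membrane outline + interior + influx + wound blob."""
    from scipy import ndimage

    h, w = cfg.image_shape
    outline = mask & ~ndimage.binary_erosion(mask, iterations=2)
    base = np.zeros((h, w))
    base[mask] = cfg.interior_intensity
    base[outline] = cfg.membrane_intensity

    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((xx * cfg.pixel_size - cfg.wound_center_um[0]) ** 2
          + (yy * cfg.pixel_size - cfg.wound_center_um[1]) ** 2)
    blob = np.exp(-d2 / (2 * cfg.wound_blob_sigma**2))

    tau = cfg.influx_tau if cfg.influx_tau is not None else cfg.reseal_time / 3.0
    out = np.zeros((cfg.n_frames, h, w))
    for f in range(cfg.n_frames):
        t = (f - cfg.wound_frame) * cfg.frame_interval
        bleach = math.exp(-proc.bleach_rate * f * cfg.frame_interval)
        frame = base * bleach
        if t >= 0:
            if resealed:
                influx = cfg.influx_amplitude * (1.0 - math.exp(-t / tau))
            else:
                influx = cfg.fail_slope * t
            # dye binds intracellular compartments: whole-cell rise plus a
            # localized accumulation at the wound delineation site
            frame = frame + influx * mask + 0.5 * influx * blob
        out[f] = frame
    params = ({"amplitude": cfg.influx_amplitude, "tau": tau} if resealed
              else {"slope": cfg.fail_slope})
    return out, params


def generate_movie(cfg: SimConfig, proc: EventProcessParams | None = None,
                   resealed: bool = True) -> tuple[Movie, GroundTruth]:
    """Simulate one two-channel wound-repair movie with ground truth.

    Channel 0 carries the wound dye (saturating influx when ``resealed``,
    linear otherwise); channel 1 renders the planted punctae.  The same
    config and seed give bit-identical output.

    Raises
    ------
    ValueError
        If the configured event density is so high that the expected spot
        count exceeds the pixel count of a frame.
    """
    proc = proc or EventProcessParams()
    rng = np.random.default_rng(cfg.rng_seed)
    mask = cfg.cell_mask()
    cell_area = float(mask.sum()) * cfg.pixel_size**2

    max_boost = max([1.0, proc.endo_boost, *proc.exo_boost_by_ring])
    expected_live = (max_boost * proc.steady_rate * cell_area
                     * max(proc.lifetime_mean, cfg.frame_interval))
    if expected_live > mask.size:
        raise ValueError("event density too high: expected spots exceed pixel count")

    events = _plant_events(cfg, proc, rng, mask)
    gt = GroundTruth(events=events,
                     influx_class="resealed" if resealed else "failed",
                     frame_interval=cfg.frame_interval)

    ch1 = _render_channel1(cfg, gt, proc, mask)
    ch0, influx_params = _render_channel0(cfg, resealed, proc, mask)
    gt.influx_params = influx_params

    data = np.stack([ch0, ch1], axis=1)
    if proc.shot_noise:
        data = rng.poisson(np.maximum(data, 0) * proc.shot_gain) / proc.shot_gain
    if proc.noise_sd > 0:
        data = data + rng.normal(0.0, proc.noise_sd, size=data.shape)

    movie = Movie(
        data=data.astype(np.float32),
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
        wound_frame=cfg.wound_frame,
        wound_center=cfg.wound_center_um,
        wound_area=cfg.wound_area,
        cell_mask=mask,
    )
    return movie, gt


def generate_force_trace(peak: float, plateau: float, noise_sd: float = 1.0,
                         n_samples: int = 2000, seed: int = 0,
                         sampling_rate: float = 1000.0) -> tuple[ForceTrace, GroundTruth]:
    """Simulate a tether-pulling force trace.

    Shape: a zero baseline (10 % of samples), a linear rise to ``peak``
    (10 %), a smooth exponential relaxation onto ``plateau`` (clamped to
    reach it exactly, 20 %), then a plateau segment of ≥ ``n_samples``/2
    points, all plus Gaussian noise of ``noise_sd`` pN.

    Raises
    ------
    ValueError
        If ``plateau > peak`` or either is negative.
    """
    if plateau > peak:
        raise ValueError("plateau force cannot exceed peak force")
    if plateau < 0:
        raise ValueError("forces must be non-negative")
    rng = np.random.default_rng(seed)

    n_base = max(1, n_samples // 10)
    n_rise = max(1, n_samples // 10)
    n_decay = max(1, n_samples // 5)
    n_plateau = n_samples - n_base - n_rise - n_decay  # ≥ n_samples / 2

    force = np.empty(n_samples)
    force[:n_base] = 0.0
    force[n_base:n_base + n_rise] = np.linspace(0.0, peak, n_rise, endpoint=False)
    # exponential relaxation pinned to land exactly on the plateau
    s = np.linspace(0.0, 1.0, n_decay)
    shape = (np.exp(-5 * s) - np.exp(-5.0)) / (1.0 - np.exp(-5.0))
    force[n_base + n_rise:n_base + n_rise + n_decay] = plateau + (peak - plateau) * shape
    force[n_base + n_rise + n_decay:] = plateau

    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n_samples)

    time = np.arange(n_samples) / sampling_rate
    trace = ForceTrace(time=time, force=force, sampling_rate=sampling_rate)
    gt = GroundTruth(
        events=pd.DataFrame(columns=["type", "frame", "x_um", "y_um",
                                     "lifetime_s", "parent_exo_id"]),
        force_gt=(peak, plateau),
    )
    return trace, gt


def write_ground_truth(path_prefix: str | Path, gt: GroundTruth) -> tuple[Path, Path]:
    """Write ground truth as an event CSV plus a JSON sidecar of scalars."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    gt.events.to_csv(csv_path, index=False)
    scalars = {
        "influx_class": gt.influx_class,
        "influx_params": gt.influx_params,
        "force_gt": list(gt.force_gt) if gt.force_gt else None,
        "frame_interval": gt.frame_interval,
    }
    json_path = prefix.with_suffix(".gt.json")
    json_path.write_text(json.dumps(scalars, indent=1))
    return csv_path, json_path
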