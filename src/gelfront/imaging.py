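"""Synthetic time-lapse generation and image-based front measurement.

Renders phase-contrast-like frames from simulated fields — a bright circular
ring at the reaction front, on a dim background with optional vignetting and
additive Gaussian noise — and measures front diameters from frames the way
the experiments were measured: bandpass-filter, azimuthally average around
the centre, and take the radius of the peak of the radial intensity profile
with sub-pixel parabolic refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError
from .front_analysis import (
    CORE_FRACTION,
    FrontTrajectory,
    _MIN_POINTS_FOR_FIT,
    production_profile,
    segment_and_fit_velocities,
)
from .kinetics import ModelParameters
from .solver import FieldState, SimulationResult

__all__ = [
    "ImagingNoiseModel",
    "ImageSeries",
    "render_frame",
    "render_series",
    "bandpass_filter",
    "detect_front_diameter",
    "track_image_series",
]

#: Detections jumping outward by more than this many pixels relative to the
#: last accepted detection are discarded (the physical front only moves in).
MAX_OUTWARD_JUMP_PX = 5.0

#: Default synthetic pixel pitch; the experimental optics are not modelled.
DEFAULT_PIXEL_SIZE_UM = 10.0

_MIN_FRAME_SIDE = 64


@dataclass(frozen=True)
class ImagingNoiseModel:
    """Additive-Gaussian imaging noise with vignetting and background."""

    sigma: float = 0.05
    vignetting: float = 0.0
    background: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ContractError("ImagingNoiseModel.sigma must be >= 0")
        if not (0.0 <= self.vignetting < 1.0):
            raise ContractError("ImagingNoiseModel.vignetting must be in [0, 1)")


@dataclass
class ImageSeries:
    """A single-channel time-lapse stack with physical metadata."""

    frames: np.ndarray  # (n_frames, H, W) float
    timestamps: np.ndarray  # s, strictly increasing
    pixel_size_um: float
    center: Tuple[float, float]  # (row, col) in px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ContractError("ImageSeries.frames must be (n, H, W)")
        if len(self.timestamps) != len(self.frames):
            raise ContractError(
                "ImageSeries: one timestamp per frame required"
            )
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ContractError(
                "ImageSeries.timestamps must be strictly increasing"
            )
        if self.pixel_size_um <= 0.0:
            raise ContractError("ImageSeries.pixel_size_um must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def save_tiff(self, path: Union[str, Path]) -> None:
        """Write a multi-page TIFF plus a sidecar metadata JSON."""
        import json

        import tifffile

        path = Path(path)
        tifffile.imwrite(
            path, self.frames.astype(np.float32), photometric="minisblack"
        )
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "timestamps_s": self.timestamps.tolist(),
            "center_row_col_px": list(self.center),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_tiff(cls, path: Union[str, Path]) -> "ImageSeries":
        import json

        import tifffile

        path = Path(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            timestamps=np.asarray(meta["timestamps_s"], dtype=float),
            pixel_size_um=float(meta["pixel_size_um"]),
            center=tuple(meta["center_row_col_px"]),
        )


def _radial_distance_px(shape: Tuple[int, int], center: Tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rows, cols)


def render_frame(
    state: FieldState,
    p: ModelParameters,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise: Optional[ImagingNoiseModel] = None,
    *,
    radii_mm: Optional[np.ndarray] = None,
    shape: Optional[Tuple[int, int]] = None,
    intensity_scale: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one frame: brightness follows the local reaction intensity.

    The radial production profile of ``state`` is interpolated onto the
    pixel-distance map around the frame centre, so the brightest ring sits at
    the front radius.  ``intensity_scale`` fixes the normalisation across a
    series (defaults to this frame's own maximum); a fixed-seed noise model
    makes the output bit-reproducible.
    """
    if pixel_size_um <= 0.0:
        raise ContractError("render_frame: pixel_size_um must be > 0")
    if radii_mm is None:
        raise ContractError(
            "render_frame: radii_mm (node radii of the field state) required"
        )
    noise = noise or ImagingNoiseModel(sigma=0.0)
    prod = production_profile(state, p)
    R0_mm = float(radii_mm[-1])
    px_mm = pixel_size_um * 1e-3
    if shape is None:
        side = int(np.ceil(2.2 * R0_mm / px_mm))
        shape = (side, side)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    dist_mm = _radial_distance_px(shape, center) * px_mm
    signal = np.interp(dist_mm.ravel(), radii_mm, prod, right=0.0).reshape(shape)
    scale = intensity_scale if intensity_scale is not None else float(signal.max())
    if scale > 0.0:
        signal = signal / scale
    frame = noise.background + signal
    if noise.vignetting > 0.0:
        dmax = dist_mm.max()
        frame = frame * (1.0 - noise.vignetting * (dist_mm / dmax) ** 2)
    if noise.sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        frame = frame + rng.normal(0.0, noise.sigma, size=shape)
    return frame


def render_series(
    result: SimulationResult,
    p: Optional[ModelParameters] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise: Optional[ImagingNoiseModel] = None,
    *,
    frame_stride: int = 1,
) -> ImageSeries:
    """Render a whole simulation into a synthetic time-lapse stack.

    All frames share one intensity normalisation (the strongest travelling-
    front production of the run, excluding the rim-attached transient) and a
    single seeded noise stream, so identical seeds give identical stacks.
    """
    p = p or result.params
    noise = noise or ImagingNoiseModel(sigma=0.0)
    rng = np.random.default_rng(noise.seed)
    radii = result.grid.r
    R0 = result.grid.R
    idx = range(0, len(result), frame_stride)

    from .kinetics import _raw_rates

    prod = _raw_rates(
        result.rho_poly, result.rho_ba, result.rho_cross, result.kappa, p
    )[2]
    rev = prod.shape[1] - 1 - np.argmax(prod[:, ::-1], axis=1)
    detached = prod.max(axis=1)[radii[rev] <= 0.95 * R0]
    scale = float(detached.max()) if detached.size else float(prod.max())

    px_mm = pixel_size_um * 1e-3
    side = int(np.ceil(2.2 * R0 / px_mm))
    frames = [
        render_frame(
            result.state(i),
            p,
            pixel_size_um,
            noise,
            radii_mm=radii,
            shape=(side, side),
            intensity_scale=scale,
            rng=rng,
        )
        for i in idx
    ]
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    return ImageSeries(
        frames=np.stack(frames),
        timestamps=result.times[list(idx)],
        pixel_size_um=pixel_size_um,
        center=center,
    )


def bandpass_filter(
    frame: np.ndarray, large_px: float = 50.0, small_px: float = 3.0
) -> np.ndarray:
    """Difference-of-Gaussians bandpass, zero-mean output.

    Approximates the classic FFT bandpass used to enhance low-contrast
    fronts: structure larger than ``large_px`` and smaller than ``small_px``
    is suppressed (sigmas are half the respective cutoffs).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < _MIN_FRAME_SIDE:
        raise ContractError(
            f"bandpass_filter: frame must be 2D and at least "
            f"{_MIN_FRAME_SIDE}x{_MIN_FRAME_SIDE}"
        )
    if large_px <= small_px:
        raise ContractError("bandpass_filter: need large_px > small_px")
    lo = gaussian_filter(frame, sigma=small_px / 2.0)
    hi = gaussian_filter(frame, sigma=large_px / 2.0)
    out = lo - hi
    return out - out.mean()


def _radial_profile(
    frame: np.ndarray, center: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Azimuthal mean binned at 1 px; returns (radii_px, mean_intensity)."""
    dist = _radial_distance_px(frame.shape, center)
    bins = np.rint(dist).astype(int).ravel()
    vals = frame.ravel()
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=vals)
    ok = counts > 0
    prof = sums[ok] / counts[ok]
    return np.nonzero(ok)[0].astype(float), prof


def detect_front_diameter(
    frame: np.ndarray,
    center: Tuple[float, float],
    pixel_size_um: float,
    *,
    apply_bandpass: bool = True,
    min_snr: float = 6.0,
) -> Optional[float]:
    """Measure the front-ring diameter (um) from one frame, or None.

    The frame is bandpass filtered, azimuthally averaged about ``center``,
    and the profile peak is refined to sub-pixel accuracy by parabolic
    interpolation.  A peak whose prominence over the profile median is below
    ``min_snr`` times the robust profile noise counts as not found.
    """
    frame = np.asarray(frame, dtype=float)
    if not (
        0 <= center[0] < frame.shape[0] and 0 <= center[1] < frame.shape[1]
    ):
        raise ContractError("detect_front_diameter: center outside frame")
    work = bandpass_filter(frame) if apply_bandpass else frame
    radii, prof = _radial_profile(work, center)
    if len(prof) < 5:
        return None
    # ignore the outermost bins: corners have few pixels and edge effects
    cut = int(0.95 * len(prof))
    radii, prof = radii[:cut], prof[:cut]
    if np.ptp(prof) == 0.0:
        return None
    med = np.median(prof)
    mad = np.median(np.abs(prof - med)) + 1e-300
    i = int(np.argmax(prof))
    if (prof[i] - med) / (1.4826 * mad) < min_snr:
        return None
    # parabolic sub-pixel refinement
    r_peak = radii[i]
    if 0 < i < len(prof) - 1:
        y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:
            r_peak = r_peak + 0.5 * (y0 - y2) / denom
    return float(2.0 * r_peak * pixel_size_um)


def track_image_series(
    series: ImageSeries,
    *,
    apply_bandpass: bool = True,
    min_snr: float = 6.0,
) -> FrontTrajectory:
    """Measure the front in every frame and assemble a trajectory.

    Detections that jump outward by more than ``MAX_OUTWARD_JUMP_PX`` pixels
    relative to the last accepted detection are dropped (the front only
    travels inward; outward jumps are detection failures).  Gelation time is
    the first timestamp at which the front is lost or has shrunk below 2 % of
    its initial radius.
    """
    if len(series) < 5:
        raise ContractError("track_image_series: need >= 5 frames")
    radii_mm = np.full(len(series), np.nan)
    last_ok: Optional[float] = None
    jump_mm = MAX_OUTWARD_JUMP_PX * series.pixel_size_um * 1e-3
    for i, frame in enumerate(series.frames):
        d_um = detect_front_diameter(
            frame, series.center, series.pixel_size_um,
            apply_bandpass=apply_bandpass, min_snr=min_snr,
        )
        if d_um is None:
            continue
        r_mm = d_um * 1e-3 / 2.0
        if last_ok is not None and r_mm > last_ok + jump_mm:
            continue  # outward jump: discard detection
        radii_mm[i] = r_mm
        last_ok = r_mm
    ok = np.isfinite(radii_mm)
    if not ok.any():
        raise ContractError("track_image_series: no frame yielded a detection")
    R0 = float(radii_mm[ok][0])

    # gelation: the front reaches the core, or is lost for good (a missed
    # detection mid-run is a dropped frame, not the end of the front)
    gel_time: Optional[float] = None
    first = int(np.nonzero(ok)[0][0])
    last = int(np.nonzero(ok)[0][-1])
    for i in range(first + 1, len(series)):
        at_core = ok[i] and radii_mm[i] <= CORE_FRACTION * R0
        lost = not ok[i] and i > last
        if at_core or lost:
            gel_time = float(series.timestamps[i])
            radii_mm[i:] = np.nan
            break

    traj = FrontTrajectory(
        times=series.timestamps.copy(),
        front_radius=radii_mm,
        R0=R0,
        gelation_time=gel_time,
    )
    t, _ = traj.valid_points()
    if t.size >= _MIN_POINTS_FOR_FIT:
        traj.fit = segment_and_fit_velocities(traj)
    return traj
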