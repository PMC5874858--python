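"""Camera-image measurement chain: TIFF stacks to a depth-light profile.

The chain mirrors standard scientific-camera dosimetry practice: subtract
the mean dark frame, median-filter impulse noise, divide by the vignetting
gain field, accumulate the repeated beam-on frames over a fixed region of
interest, extract the central-axis band profile, and undo the perspective
magnification to obtain a calibrated midline depth-light profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import camera_optics
from .camera_optics import CameraModel
from .profiles import DepthProfile


@dataclass
class ImageStack:
    """A stack of same-shaped 2-D count frames from one exposure series."""

    frames: np.ndarray            # (n_frames, rows, cols), counts
    bit_depth: int = 14
    exposure_tag: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if self.frames.min() < 0 or self.frames.max() > 2 ** self.bit_depth - 1:
            raise ValueError("counts outside the sensor's dynamic range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    def mean_frame(self) -> np.ndarray:
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [row_start:row_end, col_start:col_end]."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("ROI must be non-empty")

    def validate(self, shape: tuple) -> None:
        if (self.row_start < 0 or self.col_start < 0
                or self.row_end > shape[0] or self.col_end > shape[1]):
            raise ValueError(f"ROI {self} exceeds frame shape {shape}")

    def slices(self) -> tuple:
        return (slice(self.row_start, self.row_end),
                slice(self.col_start, self.col_end))

    @property
    def n_rows(self) -> int:
        return self.row_end - self.row_start

    @property
    def n_cols(self) -> int:
        return self.col_end - self.col_start


def read_tiff_stack(paths, bit_depth: int = 14, exposure_tag: str = "") -> ImageStack:
    """Load one or more grayscale TIFFs into an :class:`ImageStack`."""
    import tifffile

    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        arr = tifffile.imread(str(p))
        frames.append(arr[None] if arr.ndim == 2 else arr)
    return ImageStack(np.concatenate(frames, axis=0), bit_depth=bit_depth,
                      exposure_tag=exposure_tag)


def write_tiff_stack(stack: ImageStack, directory, prefix: str) -> list:
    """Write each frame as an uncompressed 16-bit grayscale TIFF."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack.frames):
        p = directory / f"{prefix}_{i:03d}.tif"
        tifffile.imwrite(str(p), np.round(frame).astype(np.uint16))
        paths.append(p)
    return paths


def subtract_dark(stack: ImageStack, dark: ImageStack) -> ImageStack:
    """Subtract the mean dark frame from every frame, clipping at zero."""
    if dark.shape != stack.shape:
        raise ValueError(f"dark shape {dark.shape} != stack shape {stack.shape}")
    out = np.clip(stack.frames - dark.mean_frame()[None], 0.0, None)
    return ImageStack(out, bit_depth=stack.bit_depth, exposure_tag=stack.exposure_tag)


def flat_field(stack: ImageStack, vignetting: np.ndarray) -> ImageStack:
    """Divide every frame by the per-pixel vignetting gain field."""
    gain = np.asarray(vignetting, dtype=float)
    if gain.shape != stack.shape:
        raise ValueError("gain field shape mismatch")
    if np.any(gain <= 0) or np.any(gain > 1):
        raise ValueError("gains must lie in (0, 1]")
    out = stack.frames / gain[None]
    # flat-fielding may push counts above the nominal full scale; that is
    # expected and the stack stops enforcing the range here
    s = ImageStack.__new__(ImageStack)
    s.frames = out
    s.bit_depth = stack.bit_depth
    s.exposure_tag = stack.exposure_tag
    return s


def median_filter(stack: ImageStack, kernel: int = 3) -> ImageStack:
    """Per-frame 2-D median filter with an odd square kernel (1 = identity)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    if kernel == 1:
        frames = stack.frames.copy()
    else:
        frames = np.stack([ndimage.median_filter(f, size=kernel)
                           for f in stack.frames])
    s = ImageStack.__new__(ImageStack)
    s.frames = frames
    s.bit_depth = stack.bit_depth
    s.exposure_tag = stack.exposure_tag
    return s


def accumulate_roi(stack: ImageStack, roi: ROI):
    """Sum the frames within the ROI; report mean and sd over ROI pixels.

    Returns ``(image, mean, sd)`` where ``image`` is the per-pixel sum of
    all frames restricted to the ROI.
    """
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    roi.validate(stack.shape)
    image = stack.frames[(slice(None),) + roi.slices()].sum(axis=0)
    return image, float(image.mean()), float(image.std())


def extract_axis_profile(image: np.ndarray, roi: ROI, band_halfwidth: int,
                         beam_axis: str = "cols") -> np.ndarray:
    """Central-axis profile of an accumulated ROI image.

    The beam centre transverse to ``beam_axis`` is located as the
    intensity-weighted centroid, and the profile is the mean over the
    ±``band_halfwidth`` pixels around it, returned as intensity versus
    depth-pixel (ROI-relative).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (roi.n_rows, roi.n_cols):
        raise ValueError("image does not match ROI shape")
    if beam_axis == "cols":
        transverse_len = roi.n_rows
        axis_sum = image.sum(axis=1)
    elif beam_axis == "rows":
        transverse_len = roi.n_cols
        axis_sum = image.sum(axis=0)
    else:
        raise ValueError("beam_axis must be 'rows' or 'cols'")
    if band_halfwidth < 0 or 2 * band_halfwidth + 1 > transverse_len:
        raise ValueError("band exceeds the ROI")
    total = axis_sum.sum()
    if total <= 0:
        center = transverse_len // 2
    else:
        center = int(round(np.average(np.arange(transverse_len), weights=axis_sum)))
    lo = max(center - band_halfwidth, 0)
    hi = min(center + band_halfwidth + 1, transverse_len)
    if beam_axis == "cols":
        return image[lo:hi, :].mean(axis=0)
    return image[:, lo:hi].mean(axis=1)


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs, typically parsed from YAML."""

    cam: CameraModel
    roi: ROI
    median_kernel: int = 3
    band_halfwidth_px: int = 20
    beam_axis: str = "cols"
    field_diameter_mm: float = 25.0
    entrance_px: int = 0          # depth-pixel of the entrance face, ROI-relative
    bin_width_mm: float = 0.125
    dark_paths: list = field(default_factory=list)
    flat_paths: list = field(default_factory=list)
    beam_paths: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig,
                 beam_stack: ImageStack | None = None,
                 dark_stack: ImageStack | None = None,
                 flat_stack: ImageStack | None = None,
                 log: list | None = None) -> DepthProfile:
    """Full measurement chain: stacks in, calibrated depth-light profile out.

    Stage order: dark subtraction → median filter → flat-field →
    ROI accumulation → axis-band extraction → perspective demagnification
    → resample to a uniform depth grid. Stacks may be passed in memory or
    named as TIFF paths in the config. ``log`` (a list) collects one
    entry of summary statistics per stage.
    """
    log = log if log is not None else []

    def _stage(name, **stats):
        log.append({"stage": name, **stats})

    try:
        if beam_stack is None:
            beam_stack = read_tiff_stack(config.beam_paths, exposure_tag="beam")
        if dark_stack is None:
            dark_stack = read_tiff_stack(config.dark_paths, exposure_tag="dark")
        if flat_stack is None and config.flat_paths:
            flat_stack = read_tiff_stack(config.flat_paths, exposure_tag="flat")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    def _run(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    stack = _run("dark", subtract_dark, beam_stack, dark_stack)
    _stage("dark", residual_mean=float(stack.frames.mean()))
    stack = _run("median", median_filter, stack, config.median_kernel)
    _stage("median", kernel=config.median_kernel)

    if flat_stack is not None:
        flat_corr = subtract_dark(flat_stack, dark_stack)
        # median-filter the flat before normalizing: a single hot pixel
        # would otherwise set the maximum and rescale the whole gain field
        flat_smooth = ndimage.median_filter(flat_corr.mean_frame(), size=3)
        gain = camera_optics.normalize_flat(flat_smooth)
        stack = _run("flat", flat_field, stack, gain)
        _stage("flat", gain_min=float(gain.min()))
    cam = config.cam

    image, mean, sd = _run("accumulate", accumulate_roi, stack, config.roi)
    _stage("accumulate", roi_mean=mean, roi_sd=sd, n_frames=stack.n_frames)

    profile_px = _run("extract", extract_axis_profile, image, config.roi,
                      config.band_halfwidth_px, config.beam_axis)
    _stage("extract", n_px=len(profile_px))

    profile_px = profile_px[config.entrance_px:]
    midline = _run("demagnify", camera_optics.demagnify_image_profile,
                   profile_px, cam, config.field_diameter_mm)
    _stage("demagnify", field_diameter_mm=config.field_diameter_mm)

    # uniform scoring grid (bin centres) over the imaged depth span
    span = midline.depths[-1]
    n_bins = int(np.floor(span / config.bin_width_mm))
    grid = (np.arange(n_bins) + 0.5) * config.bin_width_mm
    out = midline.resample(grid)
    out.meta["pipeline_log"] = log
    return out
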