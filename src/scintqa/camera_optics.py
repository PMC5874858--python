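"""Geometric camera model for side-on imaging of a scintillator block.

The camera photographs a three-dimensional light field through the side
face of the block. Each plane of the beam cross-section parallel to the
sensor projects with its own perspective scale: a plane a signed distance
x nearer the camera (x > 0 toward the camera, |x| < r, with r the
camera-to-midline distance) appears brighter by the solid-angle factor
r²/(r−x)² and magnified along depth by (r+x)/r. Summing the projections
over the cylindrical beam cross-section gives the recorded image column;
inverting that sum recovers the midline-equivalent depth-light profile
that can be compared with an ionization chamber scan or a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import DepthProfile, register_profiles  # noqa: F401  (re-export)


@dataclass
class ProjectionGeometry:
    """One off-midline projection plane and its perspective mapping.

    ``r`` is the camera-to-midline distance (mm), ``x`` the signed offset
    of the plane (positive toward the camera), ``y`` a depth coordinate in
    the plane (mm). Derived: ``intensity_factor`` = I'/I and
    ``magnification`` = y'/y.
    """

    r: float
    x: float
    y: float = 0.0
    I: float = 1.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("camera distance r must be positive")
        if abs(self.x) >= self.r:
            raise ValueError("|x| must be smaller than r")

    @property
    def intensity_factor(self) -> float:
        return (self.r / (self.r - self.x)) ** 2

    @property
    def magnification(self) -> float:
        return (self.r + self.x) / self.r

    @property
    def I_prime(self) -> float:
        return self.I * self.intensity_factor

    @property
    def y_prime(self) -> float:
        return self.y * self.magnification


@dataclass
class CameraModel:
    """Camera parameters relevant to profile extraction.

    ``pixel_pitch_mm`` is millimetres per pixel in the midline plane,
    obtained from a ruler image. ``vignetting`` is a 2-D gain field in
    (0, 1] with maximum 1 (None = uniform). ``dark_level`` and
    ``read_noise_sigma`` are in counts; ``bit_depth`` 8–16.
    """

    r: float = 500.0
    pixel_pitch_mm: float | None = None
    vignetting: np.ndarray | None = None
    dark_level: float = 100.0
    read_noise_sigma: float = 2.0
    bit_depth: int = 14

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("camera distance must be positive")
        if self.dark_level < 0:
            raise ValueError("dark level must be non-negative")
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit depth must be within 8..16")
        if self.vignetting is not None:
            v = np.asarray(self.vignetting, dtype=float)
            if not np.isclose(v.max(), 1.0):
                raise ValueError("vignetting field must be normalized to max 1")
            self.vignetting = v

    @property
    def full_scale(self) -> int:
        return 2 ** self.bit_depth - 1


def project_intensity(I, x, r):
    """Perspective intensity of an off-midline plane: I' = I·r²/(r−x)².

    ``x`` is signed, positive toward the camera; near planes subtend a
    larger solid angle and so appear brighter, far planes (x < 0) dimmer.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= r):
        raise ValueError("|x| must be smaller than the camera distance r")
    out = I * (r / (r - x)) ** 2
    return float(out) if out.ndim == 0 else out


def magnify_depth(y, x, r):
    """Perspective depth coordinate of an off-midline plane: y' = y·(r+x)/r.

    Linear in y, identity at x = 0; near planes (x > 0) appear stretched.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= r):
        raise ValueError("|x| must be smaller than the camera distance r")
    out = np.asarray(y, dtype=float) * (r + x) / r
    return float(out) if out.ndim == 0 else out


def projection_kernel(cam: CameraModel, field_diameter: float,
                      n_planes: int = 64):
    """Chord planes of a cylindrical beam with projection weights.

    Returns ``(x, w, c, m)``: plane offsets, chord weights (sum 1),
    intensity factors, and depth magnifications. The cylinder of diameter
    ``field_diameter`` is discretized into ``n_planes`` planes weighted by
    chord length (uniform emission across the cross-section).
    """
    if field_diameter < 0:
        raise ValueError("field diameter must be non-negative")
    if field_diameter == 0:
        return (np.zeros(1), np.ones(1), np.ones(1), np.ones(1))
    a = field_diameter / 2.0
    x = (np.arange(n_planes) + 0.5) / n_planes * field_diameter - a
    w = np.sqrt(np.maximum(1.0 - (x / a) ** 2, 0.0))
    w /= w.sum()
    c = project_intensity(1.0, x, cam.r)
    m = magnify_depth(1.0, x, cam.r)
    return x, w, c, m


def forward_project_profile(midline: DepthProfile, cam: CameraModel,
                            field_diameter: float, n_planes: int = 64,
                            depths: np.ndarray | None = None) -> np.ndarray:
    """Image-plane column profile produced by a midline light profile.

    Sums the perspective projections of every chord plane:
    image(y) = Σ_j w_j c_j L(y / m_j), evaluated at ``depths`` (mm in the
    image plane; defaults to the midline grid).
    """
    _, w, c, m = projection_kernel(cam, field_diameter, n_planes)
    y = midline.depths if depths is None else np.asarray(depths, dtype=float)
    out = np.zeros_like(y)
    for wj, cj, mj in zip(w, c, m):
        out += wj * cj * midline.interp(y / mj)
    return out


def demagnify_image_profile(profile_px: np.ndarray, cam: CameraModel,
                            field_diameter: float, n_planes: int = 64,
                            smoothness: float = 3e-2) -> DepthProfile:
    """Invert the perspective projection of an image-column profile.

    ``profile_px`` is intensity versus depth-pixel with index 0 at the
    beam entrance. The forward model (chord-weighted sum of magnified,
    intensity-scaled copies of the midline profile) is assembled as a
    linear operator on the pixel grid and inverted by Tikhonov least
    squares with a second-difference (curvature) penalty: the forward
    kernel is a depth-proportional smoothing whose bare inverse amplifies
    pixel noise, and the curvature penalty suppresses exactly those
    high-frequency components while leaving the Bragg falloff (widths of
    several pixels) intact. ``smoothness`` scales the penalty relative to
    the operator norm. Reduces to the identity as ``field_diameter → 0``
    or ``r → ∞``.
    """
    if cam.pixel_pitch_mm is None:
        raise ValueError("camera pixel pitch is not calibrated")
    vals = np.asarray(profile_px, dtype=float)
    npx = len(vals)
    pitch = cam.pixel_pitch_mm
    y = (np.arange(npx) + 0.5) * pitch

    _, w, c, m = projection_kernel(cam, field_diameter, n_planes)
    if len(m) == 1 and m[0] == 1.0:
        out = vals.copy()
    else:
        A = np.zeros((npx, npx))
        rows = np.arange(npx)
        for wj, cj, mj in zip(w, c, m):
            # row k samples the midline profile at y_k / m_j
            src = (y / mj - 0.5 * pitch) / pitch   # fractional source index
            i0 = np.clip(np.floor(src).astype(int), 0, npx - 2)
            frac = np.clip(src - i0, 0.0, 1.0)
            A[rows, i0] += wj * cj * (1 - frac)
            A[rows, i0 + 1] += wj * cj * frac
        d2 = np.diff(np.eye(npx), n=2, axis=0)
        lam2 = smoothness**2 * np.trace(A.T @ A) / npx
        out = np.linalg.solve(A.T @ A + lam2 * (d2.T @ d2), A.T @ vals)
    out = np.clip(out, 0.0, None)
    return DepthProfile(y, out, "light")


def calibrate_pixel_pitch(ruler_image: np.ndarray | None,
                          known_length_mm: float,
                          mark_a, mark_b) -> float:
    """Pixel pitch (mm/px) from two user-marked points on a ruler image.

    ``mark_a``/``mark_b`` are pixel coordinates (scalar or (row, col))
    spanning ``known_length_mm``; the result is symmetric in the marks.
    """
    a = np.atleast_1d(np.asarray(mark_a, dtype=float))
    b = np.atleast_1d(np.asarray(mark_b, dtype=float))
    dist = float(np.linalg.norm(a - b))
    if dist == 0:
        raise ValueError("ruler marks coincide")
    if known_length_mm <= 0:
        raise ValueError("known length must be positive")
    return known_length_mm / dist


def normalize_flat(flat: np.ndarray, clip: float = 0.05) -> np.ndarray:
    """Vignetting gain field from a flat white image.

    Divides by the maximum and clips gains below ``clip`` so that
    flat-field division cannot amplify noise at extreme corners.
    """
    flat = np.asarray(flat, dtype=float)
    peak = flat.max()
    if peak <= 0:
        raise ValueError("flat image is empty")
    return np.clip(flat / peak, clip, 1.0)
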