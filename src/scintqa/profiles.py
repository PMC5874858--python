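"""Depth profiles on a uniform grid and their CSV serialization.

A :class:`DepthProfile` is the package's common currency: every module
produces or consumes relative values (dose, track-averaged LET, scintillation
light, or quenching-corrected light) sampled on a strictly increasing uniform
depth grid in millimetres, with z = 0 at the scintillator entrance face.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

VALID_KINDS = ("dose", "let", "light", "corrected")


@dataclass
class DepthProfile:
    """Relative values of one kind on a uniform depth grid.

    Parameters
    ----------
    depths
        Strictly increasing uniform grid, mm, z = 0 at the entrance surface.
    values
        Non-negative relative values; for ``kind="let"`` the units are MeV/mm.
    kind
        One of ``dose``, ``let``, ``light``, ``corrected``.
    """

    depths: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise ValueError("depths and values must be 1-D arrays of equal length")
        if len(self.depths) >= 2:
            steps = np.diff(self.depths)
            if np.any(steps <= 0):
                raise ValueError("depths must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("depth grid must be uniform")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    @property
    def bin_width(self) -> float:
        if len(self.depths) < 2:
            return float("nan")
        return float(self.depths[1] - self.depths[0])

    def interp(self, depths: np.ndarray) -> np.ndarray:
        """Linear interpolation of values at arbitrary depths (0 outside)."""
        return np.interp(np.asarray(depths, dtype=float), self.depths, self.values,
                         left=0.0, right=0.0)

    def resample(self, depths: np.ndarray, kind: str | None = None) -> "DepthProfile":
        depths = np.asarray(depths, dtype=float)
        return DepthProfile(depths, self.interp(depths), kind or self.kind)

    def shifted(self, dz: float) -> "DepthProfile":
        """Profile translated by ``dz`` mm (grid moves, values fixed)."""
        return replace(self, depths=self.depths + dz)

    def normalized(self, mode: str = "max") -> "DepthProfile":
        if mode == "max":
            scale = self.values.max()
        elif mode == "area":
            scale = np.trapezoid(self.values, self.depths)
        else:
            raise ValueError(f"unknown normalization {mode!r}")
        if scale <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return replace(self, values=self.values / scale)


def write_profile_csv(profile: DepthProfile, path: str | Path) -> None:
    """Write a 2-column ``depth_mm,value`` CSV with a ``# kind=`` header."""
    buf = io.StringIO()
    buf.write(f"# kind={profile.kind}\n")
    buf.write("depth_mm,value\n")
    for z, v in zip(profile.depths, profile.values):
        buf.write(f"{z:.6g},{v:.10g}\n")
    Path(path).write_text(buf.getvalue())


def read_profile_csv(path: str | Path, kind: str | None = None) -> DepthProfile:
    """Read a profile CSV written by :func:`write_profile_csv`.

    The ``# kind=`` comment is honoured unless ``kind`` overrides it.
    """
    text = Path(path).read_text()
    file_kind = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("kind="):
                file_kind = body.split("=", 1)[1].strip()
            continue
        if line.lower().startswith("depth"):
            continue
        a, b = line.split(",")[:2]
        rows.append((float(a), float(b)))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.array(rows)
    return DepthProfile(arr[:, 0], arr[:, 1], kind or file_kind or "light")


def distal_crossing(profile: DepthProfile, level: float) -> float:
    """Depth past the peak where the profile first falls to ``level``×max.

    Linear interpolation between the bracketing bins. Raises if the profile
    never crosses the level on the distal side (truncated profile).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    v = profile.values
    z = profile.depths
    i_peak = int(np.argmax(v))
    threshold = level * v[i_peak]
    below = np.nonzero(v[i_peak:] < threshold)[0]
    if len(below) == 0:
        raise ValueError(f"profile never falls below {level:.0%} of max distal to the peak")
    j = i_peak + below[0]
    # linear interpolation between bins j-1 (>= thr) and j (< thr)
    z0, z1, v0, v1 = z[j - 1], z[j], v[j - 1], v[j]
    if v0 == v1:
        return float(z1)
    return float(z0 + (v0 - threshold) / (v0 - v1) * (z1 - z0))


def register_profiles(moving: DepthProfile, reference: DepthProfile,
                      level: float = 0.5) -> DepthProfile:
    """Shift ``moving`` so its distal falloff aligns with ``reference``.

    Alignment is at the distal ``level`` crossing (default 50%), the sharpest
    and least quenching-sensitive feature of a Bragg curve, then resampled
    onto the reference grid.
    """
    dz = distal_crossing(reference, level) - distal_crossing(moving, level)
    shifted = moving.shifted(dz)
    out = shifted.resample(reference.depths)
    out.meta["registration_shift_mm"] = dz
    return out
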