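"""Synthetic labeled CT-like volumes for training and evaluation.

A phantom is a 43x512x512 grid (by default) holding ellipsoidal "organs"
with known ground-truth masks, simple unlabeled distractor structures
(a bright spine-like cylinder, a dim liver-like blob), low-frequency
background texture and additive Gaussian noise.  Intensities live in
[0, 1] so phantoms feed the pipeline without windowing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, Volume

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "PhantomSpec",
    "PhantomSpecError",
    "default_spec",
    "make_phantom",
    "make_cohort",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid; ``label`` is empty for unlabeled distractors."""

    center: tuple[float, float, float]  # (z, y, x) voxels
    semiaxes: tuple[float, float, float]  # (z, y, x) voxels
    intensity: float
    label: str = ""

    def support(self, shape: tuple[int, int, int]) -> np.ndarray:
        # evaluate the quadric only inside the bounding box; outside it the
        # inequality cannot hold
        cz, cy, cx = self.center
        az, ay, ax = self.semiaxes
        lo = [max(int(np.floor(c - a)), 0) for c, a in zip(self.center, self.semiaxes)]
        hi = [min(int(np.ceil(c + a)) + 1, s) for c, a, s in zip(self.center, self.semiaxes, shape)]
        zz = np.arange(lo[0], hi[0], dtype=np.float32)[:, None, None]
        yy = np.arange(lo[1], hi[1], dtype=np.float32)[None, :, None]
        xx = np.arange(lo[2], hi[2], dtype=np.float32)[None, None, :]
        q = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        sup = np.zeros(shape, dtype=bool)
        sup[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = q <= 1.0
        return sup

    def in_bounds(self, shape: tuple[int, int, int]) -> bool:
        return all(
            c - a >= 0 and c + a <= s - 1
            for c, a, s in zip(self.center, self.semiaxes, shape)
        )


@dataclass
class Cylinder:
    """z-aligned cylinder spanning the whole depth (spine-like distractor)."""

    center_yx: tuple[float, float]
    radius: float
    intensity: float
    label: str = ""

    def support(self, shape: tuple[int, int, int]) -> np.ndarray:
        yy = np.arange(shape[1], dtype=np.float32)[:, None]
        xx = np.arange(shape[2], dtype=np.float32)[None, :]
        cy, cx = self.center_yx
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2
        return np.broadcast_to(disk, shape)

    def in_bounds(self, shape: tuple[int, int, int]) -> bool:
        cy, cx = self.center_yx
        r = self.radius
        return cy - r >= 0 and cy + r <= shape[1] - 1 and cx - r >= 0 and cx + r <= shape[2] - 1


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (43, 512, 512)
    organs: list[Ellipsoid] = field(default_factory=list)
    distractors: list = field(default_factory=list)
    background_mean: float = 0.35
    noise_sigma: float = 0.003
    texture_scale: float = 0.16  # amplitude of low-frequency background modulation
    texture_wavelength: float = 32.0  # approximate in-plane period, voxels
    seed: int = 0

    def validate(self) -> None:
        for shp in list(self.organs) + list(self.distractors):
            if not shp.in_bounds(self.shape):
                raise PhantomSpecError(f"shape out of bounds for grid {self.shape}: {shp}")
        for organ in self.organs:
            if not organ.label:
                raise PhantomSpecError("organs must carry a label")
            if abs(organ.intensity - self.background_mean) < 3 * self.noise_sigma:
                raise PhantomSpecError(
                    f"organ {organ.label!r} contrast below 3*noise_sigma; not learnable"
                )


def default_spec(seed: int = 0) -> PhantomSpec:
    """Kidney-in-left-half / spleen-analog-in-right-half phantom.

    Geometry mimics the target problem: one bright contrast-enhanced organ
    per image half, a bright spine-like cylinder near the midline and a dim
    large blob as an extra distractor in the kidney half.  Organ interiors
    are near-uniform while the background carries strong low-frequency
    texture, mirroring the narrow enhanced-organ mode over diverse
    surrounding tissue that the intensity clustering relies on.
    """
    return PhantomSpec(
        organs=[
            Ellipsoid(center=(21, 255, 130), semiaxes=(12, 55, 35), intensity=0.78,
                      label="kidney_right"),
            Ellipsoid(center=(21, 180, 385), semiaxes=(11, 45, 30), intensity=0.76,
                      label="spleen"),
        ],
        distractors=[
            Cylinder(center_yx=(310, 256), radius=24, intensity=0.9),
            Ellipsoid(center=(20, 140, 120), semiaxes=(14, 60, 55), intensity=0.5),
        ],
        seed=seed,
    )


def _texture_field(shape, wavelength, rng) -> np.ndarray:
    """Smooth random field in [-1, 1], generated on a coarse grid and upsampled."""
    coarse = tuple(max(2, int(np.ceil(s / wavelength)) + 1) for s in shape)
    base = rng.standard_normal(coarse).astype(np.float32)
    zoom = [s / c for s, c in zip(shape, coarse)]
    field3d = ndimage.zoom(base, zoom, order=1, mode="nearest", grid_mode=True)
    field3d = field3d[: shape[0], : shape[1], : shape[2]]
    peak = max(float(np.abs(field3d).max()), 1e-6)
    return field3d / peak


def make_phantom(spec: PhantomSpec) -> tuple[Volume, dict[str, BinaryMask]]:
    """Render a phantom volume and its ground-truth organ masks.

    The same seed always yields bit-identical output.  With
    ``noise_sigma=0`` and ``texture_scale=0`` the mean intensity inside
    each organ mask equals the specified organ intensity exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    data = np.full(shape, spec.background_mean, dtype=np.float32)
    if spec.texture_scale > 0:
        data += spec.texture_scale * _texture_field(shape, spec.texture_wavelength, rng)

    masks: dict[str, BinaryMask] = {}
    for shp in list(spec.distractors) + list(spec.organs):
        sup = shp.support(shape)
        data[sup] = shp.intensity
        if shp.label:
            masks[shp.label] = BinaryMask(data=np.ascontiguousarray(sup), label=shp.label)

    if spec.noise_sigma > 0:
        data += spec.noise_sigma * rng.standard_normal(shape).astype(np.float32)
    np.clip(data, 0.0, 1.0, out=data)
    return Volume(data=data, normalized=True), masks


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    spec = copy.deepcopy(base)
    spec.seed = seed
    for shp in list(spec.organs) + list(spec.distractors):
        if isinstance(shp, Ellipsoid):
            dz, dy, dx = rng.uniform([-2, -12, -12], [2, 12, 12])
            shp.center = (shp.center[0] + dz, shp.center[1] + dy, shp.center[2] + dx)
            scale = rng.uniform(0.9, 1.1, size=3)
            shp.semiaxes = tuple(a * s for a, s in zip(shp.semiaxes, scale))
        elif isinstance(shp, Cylinder):
            dy, dx = rng.uniform(-8, 8, size=2)
            shp.center_yx = (shp.center_yx[0] + dy, shp.center_yx[1] + dx)
        shp.intensity = float(np.clip(shp.intensity + rng.uniform(-0.03, 0.03), 0.0, 1.0))
    return spec


def make_cohort(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[Volume, dict[str, BinaryMask]]]:
    """Generate ``n`` phantoms with jittered organ position, size and intensity.

    Jitter is drawn from a generator seeded with ``seed``, so the whole
    cohort is reproducible.  Every organ of the base spec is present in
    every phantom.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base = base_spec if base_spec is not None else default_spec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        spec = _jitter_spec(base, rng, seed=int(rng.integers(0, 2**31)))
        cohort.append(make_phantom(spec))
    return cohort
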