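"""Two-class training-point generation and projection-image extraction.

Organ-class (OC) points are a 50 px grid anchored at the expert-mask
bounding box and kept only inside the mask.  Background-class (BC)
points are a 50 px grid anchored at the image origin, excluding the
disk-dilated mask (radius 60 px) and 20 px-padded horizontal/vertical
strips through the mask bounding box, which guarantees no BC point's
row or column ray intersects the mask.

For every point three projection images are extracted: the sagittal
plane at its x (depth-resampled to 43 rows), the coronal plane at its y
(cropped to the organ's image half, resampled to 43 rows) and the full
axial slice at its z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BinaryMask, Volume, crop_half, resample_depth

__all__ = [
    "SamplePoint",
    "SamplingConfig",
    "SliceTriplet",
    "DatasetBundle",
    "SIDE_FOR_LABEL",
    "organ_points",
    "background_points",
    "extract_triplet",
    "build_dataset",
]

log = logging.getLogger(__name__)

OC, BC = "OC", "BC"

#: Image half holding each organ (radiological convention: the anatomical
#: right kidney appears on the left of the image).
SIDE_FOR_LABEL = {"kidney_right": "left", "kidney_left": "right", "spleen": "right"}


@dataclass(frozen=True)
class SamplePoint:
    x: int
    y: int
    z: int = 0
    label: str = OC


@dataclass
class SamplingConfig:
    grid_spacing: int = 50
    dilation_radius: int = 60
    strip_pad: int = 20
    slice_stride: int = 1  # z-stride over annotated axial slices
    target_depth: int = 43

    def __post_init__(self) -> None:
        for name in ("grid_spacing", "dilation_radius", "strip_pad", "slice_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SliceTriplet:
    """The three projection images associated with one 3D point."""

    img_x: np.ndarray  # (43, Y) sagittal, axes z x y
    img_y: np.ndarray  # (43, X/2) coronal, axes z x x-half
    img_z: np.ndarray  # (Y, X) axial


def _as_bool2d(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if data.ndim != 2:
        raise ValueError(f"expected a 2D mask, got ndim={data.ndim}")
    return data.astype(bool)


def organ_points(mask, cfg: SamplingConfig, z: int = 0) -> list[SamplePoint]:
    """OC grid points: pitch ``grid_spacing``, anchored at the mask bounding
    box top-left corner, intersected with the mask."""
    data = _as_bool2d(mask)
    if not data.any():
        return []
    rows = np.flatnonzero(data.any(axis=1))
    cols = np.flatnonzero(data.any(axis=0))
    ys = np.arange(rows[0], rows[-1] + 1, cfg.grid_spacing)
    xs = np.arange(cols[0], cols[-1] + 1, cfg.grid_spacing)
    pts = [
        SamplePoint(x=int(x), y=int(y), z=z, label=OC)
        for y in ys
        for x in xs
        if data[y, x]
    ]
    return pts


def background_points(mask, cfg: SamplingConfig, z: int = 0) -> list[SamplePoint]:
    """BC grid points: pitch ``grid_spacing`` anchored at the image origin,
    outside the disk-dilated mask and the padded bounding-box strips."""
    data = _as_bool2d(mask)
    h, w = data.shape
    allowed = np.ones((h, w), dtype=bool)
    if data.any():
        # Euclidean-disk dilation of radius r == (distance to mask) <= r
        dist = ndimage.distance_transform_edt(~data)
        allowed &= dist > cfg.dilation_radius
        rows = np.flatnonzero(data.any(axis=1))
        cols = np.flatnonzero(data.any(axis=0))
        pad = cfg.strip_pad
        allowed[max(rows[0] - pad, 0) : rows[-1] + pad + 1, :] = False
        allowed[:, max(cols[0] - pad, 0) : cols[-1] + pad + 1] = False
    ys = np.arange(0, h, cfg.grid_spacing)
    xs = np.arange(0, w, cfg.grid_spacing)
    return [
        SamplePoint(x=int(x), y=int(y), z=z, label=BC)
        for y in ys
        for x in xs
        if allowed[y, x]
    ]


def extract_triplet(
    vol: Volume, p: SamplePoint, side: str = "full", target_depth: int = 43
) -> SliceTriplet:
    """Extract the three projection images for point ``p``.

    ``side`` restricts the coronal (Y) image to one image half; ``full``
    keeps the whole width.  Sagittal and coronal images are depth-resampled
    to ``target_depth`` rows.
    """
    nz, ny, nx = vol.shape
    if not (0 <= p.z < nz and 0 <= p.y < ny and 0 <= p.x < nx):
        raise IndexError(f"point {p} outside volume of shape {vol.shape}")
    img_x = _resample_rows(vol.data[:, :, p.x], vol, target_depth)
    plane_y = vol.data[:, p.y, :]
    if side != "full":
        plane_y = crop_half(plane_y, side)
    img_y = _resample_rows(plane_y, vol, target_depth)
    img_z = vol.data[p.z]
    return SliceTriplet(img_x=img_x, img_y=img_y, img_z=img_z)


def _resample_rows(plane: np.ndarray, vol: Volume, target_depth: int) -> np.ndarray:
    if plane.shape[0] == target_depth:
        return plane
    tmp = Volume(data=plane[:, :, None], spacing=vol.spacing)
    return resample_depth(tmp, target_depth).data[:, :, 0]


@dataclass
class DatasetBundle:
    """Labeled image sets for the three axis networks plus a manifest."""

    images: dict[str, np.ndarray] = field(default_factory=dict)  # axis -> (n, rows, cols)
    labels: dict[str, np.ndarray] = field(default_factory=dict)  # axis -> (n,) 1=organ
    manifest: pd.DataFrame | None = None

    def class_counts(self) -> dict[str, dict[int, int]]:
        return {
            axis: dict(zip(*map(list, np.unique(lab, return_counts=True))))
            for axis, lab in self.labels.items()
        }


def build_dataset(
    cohort,
    organ: str,
    cfg: SamplingConfig | None = None,
    z_stride: int = 1,
    dedupe: bool = False,
) -> DatasetBundle:
    """Build the per-axis training sets from a labeled cohort.

    For every annotated axial slice (stride ``cfg.slice_stride``) OC and BC
    points are generated and their sagittal/coronal images added to the X
    and Y sets.  The Z set holds axial slices (stride ``z_stride``) labeled
    organ when the slice intersects the 3D organ mask.

    ``dedupe`` collapses X/Y images that share (case, coordinate) — the
    projection image depends only on that one coordinate — keeping the
    organ label when any point at the coordinate was organ-class.
    """
    cfg = cfg or SamplingConfig()
    side = SIDE_FOR_LABEL.get(organ, "full")
    xs_imgs, ys_imgs, zs_imgs = [], [], []
    xs_lab, ys_lab, zs_lab = [], [], []
    rows = []
    for case_id, (vol, masks) in enumerate(cohort):
        if organ not in masks:
            log.warning("case %d: organ %r absent; skipped", case_id, organ)
            continue
        mask3d = masks[organ].data
        annotated = np.flatnonzero(mask3d.any(axis=(1, 2)))
        points: list[SamplePoint] = []
        for z in annotated[:: cfg.slice_stride]:
            points += organ_points(mask3d[z], cfg, z=int(z))
            points += background_points(mask3d[z], cfg, z=int(z))
        if dedupe:
            # a projection image depends only on its coordinate, so collapse
            # duplicates; labels are made 3D-consistent (a coordinate is
            # organ-class iff its projection ray intersects the 3D mask),
            # which enforces the construction guarantee that no background
            # point's ray crosses the organ
            x_hit = mask3d.any(axis=(0, 1))
            y_hit = mask3d.any(axis=(0, 2))
            x_lab = {p.x: int(x_hit[p.x]) for p in points}
            y_lab = {p.y: int(y_hit[p.y]) for p in points}
            for x, lab in sorted(x_lab.items()):
                trip = extract_triplet(
                    vol, SamplePoint(x=x, y=0, z=0), side=side, target_depth=cfg.target_depth
                )
                xs_imgs.append(trip.img_x)
                xs_lab.append(lab)
                rows.append((case_id, "X", x, lab))
            for y, lab in sorted(y_lab.items()):
                trip = extract_triplet(
                    vol, SamplePoint(x=0, y=y, z=0), side=side, target_depth=cfg.target_depth
                )
                ys_imgs.append(trip.img_y)
                ys_lab.append(lab)
                rows.append((case_id, "Y", y, lab))
        else:
            for p in points:
                lab = 1 if p.label == OC else 0
                trip = extract_triplet(vol, p, side=side, target_depth=cfg.target_depth)
                xs_imgs.append(trip.img_x)
                xs_lab.append(lab)
                ys_imgs.append(trip.img_y)
                ys_lab.append(lab)
                rows.append((case_id, "X", int(p.x), lab))
                rows.append((case_id, "Y", int(p.y), lab))
        # stride sample of axial slices, plus the organ's boundary slices and
        # their immediate outside neighbors — the z-extent decision hinges on
        # exactly those small-cross-section images
        z_samples = set(range(0, vol.n_slices, z_stride))
        z_samples |= {
            int(np.clip(z, 0, vol.n_slices - 1))
            for z in (annotated[0] - 1, annotated[0], annotated[-1], annotated[-1] + 1)
        }
        for z in sorted(z_samples):
            lab = 1 if mask3d[z].any() else 0
            zs_imgs.append(vol.data[z])
            zs_lab.append(lab)
            rows.append((case_id, "Z", int(z), lab))

    bundle = DatasetBundle()
    for axis, imgs, labs in (("X", xs_imgs, xs_lab), ("Y", ys_imgs, ys_lab), ("Z", zs_imgs, zs_lab)):
        bundle.images[axis] = (
            np.stack(imgs).astype(np.float32) if imgs else np.zeros((0, 0, 0), np.float32)
        )
        bundle.labels[axis] = np.asarray(labs, dtype=np.int64)
    bundle.manifest = pd.DataFrame(rows, columns=["case", "axis", "coord", "label"])
    for axis, counts in bundle.class_counts().items():
        log.info("axis %s class counts: %s", axis, counts)
    return bundle
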