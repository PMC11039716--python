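"""Sample preparation arms: normalize, crop / resample, embed, flip, tokenize.

The three preprocessing arms compared throughout the package are

* ``resample``      — normalize, resample image+label onto a fixed grid
                      covering the native field of view (the conventional
                      shape-harmonization baseline; costs resolution),
* ``crop``          — normalize, random crop of a fixed voxel ROI (keeps
                      native resolution; array position is uninformative),
* ``crop+ppe``      — as ``crop`` plus the physical-coordinate embedding
                      added on the post-crop geometry,
* ``crop+ppe-only`` — as ``crop+ppe`` but the downstream patch-wise
                      (regular) embedding is disabled — the ablation arm.

Order of operations: normalize -> (crop | resample) -> add PPE -> random
flip -> patchify -> tokens.  Normalization precedes the embedding so the
1/S amplitude bound is meaningful against unit-variance intensities.  The
embedding is added after cropping (equivalent to before, by crop
equivariance of the field) but before flips: a flip permutes voxels without
changing their acquisition-time physical positions, so flipping image and
embedding jointly preserves the voxel <-> embedding pairing.  Labels
receive the identical spatial transforms (nearest-neighbour under
resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    ContractError,
    GeometryError,
    ImageGeometry,
    Volume,
    crop_geometry,
    physical_grid,
    resample_geometry,
)
from .ppe import PPEParams, add_ppe, ppe_volume
from .tokens import PatchConfig, TokenBatch, build_tokens, init_patch_pe, patchify, sequence_length

__all__ = [
    "DataError",
    "ARMS",
    "ArmConfig",
    "normalize_per_channel",
    "random_crop",
    "resample_to_shape",
    "random_flip",
    "flip_axes",
    "prepare_volumes",
    "prepare_sample",
]

ARMS = ("resample", "crop", "crop+ppe", "crop+ppe-only")


class DataError(ValueError):
    """Non-finite or otherwise unusable input data."""


@dataclass(frozen=True)
class ArmConfig:
    """One experimental condition: arm name, grid shape and hyperparameters.

    ``shape`` is the crop ROI (crop arms) or the resampling target (resample
    arm), in voxels, and must be divisible by the downstream patch size.
    """

    arm: str
    shape: tuple[int, int, int]
    ppe: Optional[PPEParams] = None
    flip_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise DataError(f"shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        if not 0.0 <= self.flip_p <= 1.0:
            raise DataError(f"flip_p must be in [0, 1], got {self.flip_p}")
        if self.includes_ppe and self.ppe is None:
            object.__setattr__(self, "ppe", PPEParams())

    @property
    def includes_ppe(self) -> bool:
        return self.arm in ("crop+ppe", "crop+ppe-only")

    @property
    def regular_pe_kind(self) -> str:
        """Patch-wise embedding kind implied by the arm."""
        return "none" if self.arm == "crop+ppe-only" else "learnable"


def normalize_per_channel(image: Volume) -> Volume:
    """Standardize every channel to zero mean, unit standard deviation.

    Constant channels (std below 1e-8) map to all zeros with a warning
    rather than dividing by ~0.
    """
    if not np.all(np.isfinite(image.data)):
        raise DataError("image contains NaN or Inf values")
    out = np.empty_like(image.data, dtype=np.float64)
    for c in range(image.channels):
        chan = image.data[c]
        mean = chan.mean()
        std = chan.std()
        if std < 1e-8:
            warnings.warn(
                f"channel {c} is constant (std={std:.2e}); normalized to zeros",
                UserWarning,
                stacklevel=2,
            )
            out[c] = 0.0
        else:
            out[c] = (chan - mean) / std
    return Volume(data=out, geometry=image.geometry)


def random_crop(image: Volume, roi, rng: np.random.Generator) -> Volume:
    """Crop a ``roi``-sized block at a uniformly random valid start.

    The output geometry is the cropped geometry, so physical coordinates of
    the retained voxels are unchanged.
    """
    start = draw_crop_start(image.geometry, roi, rng)
    return crop_volume(image, start, roi)


def draw_crop_start(geom: ImageGeometry, roi, rng: np.random.Generator) -> np.ndarray:
    roi = np.asarray(roi, dtype=int).reshape(3)
    size = np.asarray(geom.size, dtype=int)
    if np.any(roi > size):
        raise GeometryError(f"crop ROI {tuple(roi)} exceeds image size {tuple(size)}")
    # one draw per axis, in axis order, for reproducibility
    return np.array([rng.integers(0, size[k] - roi[k] + 1) for k in range(3)])


def crop_volume(image: Volume, start, roi) -> Volume:
    start = np.asarray(start, dtype=int).reshape(3)
    roi = np.asarray(roi, dtype=int).reshape(3)
    geom = crop_geometry(image.geometry, start, roi)
    sl = tuple(slice(int(s), int(s + r)) for s, r in zip(start, roi))
    return Volume(data=image.data[(slice(None),) + sl].copy(), geometry=geom)


def resample_to_shape(image: Volume, target, order: int = 1) -> Volume:
    """Interpolate onto the same-FOV grid with ``target`` voxel counts.

    ``order=1`` is trilinear (images); ``order=0`` is nearest-neighbour
    (masks).  Interpolation happens in physical space: each new voxel
    center is mapped through the old affine to a fractional index.
    ``target == size`` returns the image unchanged.
    """
    target = tuple(int(t) for t in np.asarray(target).reshape(3))
    new_geom = resample_geometry(image.geometry, target)
    if target == tuple(image.geometry.size):
        return Volume(data=image.data.copy(), geometry=new_geom)
    grid = physical_grid(new_geom)  # (3, h', w', d')
    rel = grid - image.geometry.origin[:, None, None, None]
    idx = np.einsum("ba,bhwd->ahwd", image.geometry.direction, rel)
    idx /= image.geometry.spacing[:, None, None, None]
    out = np.stack(
        [
            map_coordinates(image.data[c], idx, order=order, mode="nearest")
            for c in range(image.channels)
        ]
    )
    return Volume(data=out, geometry=new_geom)


def draw_flips(p: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-axis flip decisions with probability ``p`` each."""
    return rng.random(3) < p


def flip_axes(image: Volume, flips) -> Volume:
    """Reverse the flagged spatial axes of all channels jointly.

    This is intensity augmentation: the array is permuted but the geometry
    is kept, because the voxels' acquisition-time physical positions (and
    any embedding already added to the data) travel with the values.
    """
    flips = np.asarray(flips, dtype=bool).reshape(3)
    axes = tuple(int(a) + 1 for a in np.flatnonzero(flips))  # +1 skips channel axis
    data = np.flip(image.data, axis=axes).copy() if axes else image.data.copy()
    return Volume(data=data, geometry=image.geometry)


def random_flip(image: Volume, p: float, rng: np.random.Generator) -> Volume:
    """Flip each spatial axis independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"flip probability must be in [0, 1], got {p}")
    return flip_axes(image, draw_flips(p, rng))


def prepare_volumes(
    image: Volume,
    arm: ArmConfig,
    rng: np.random.Generator,
    label: Optional[Volume] = None,
    augment: bool = True,
    normalize: bool = True,
):
    """Run the arm's spatial pipeline; returns (image, label) Volumes.

    ``label`` (if given) must share the image grid and receives the same
    crop/resample/flip; it is never normalized and never gets the embedding.
    With ``augment=False`` the random crop becomes a deterministic centered
    crop and flips are disabled (evaluation mode).  ``normalize=False``
    skips standardization for inputs already normalized (normalization is
    deterministic per case, so callers may cache it).
    """
    if label is not None and not label.geometry.isclose(image.geometry):
        raise ContractError("label must share the image sampling grid")
    img = normalize_per_channel(image) if normalize else image
    lab = label
    if arm.arm == "resample":
        img = resample_to_shape(img, arm.shape, order=1)
        if lab is not None:
            lab = resample_to_shape(lab, arm.shape, order=0)
    else:
        if augment:
            start = draw_crop_start(img.geometry, arm.shape, rng)
        else:
            start = (np.asarray(img.geometry.size) - np.asarray(arm.shape)) // 2
        img = crop_volume(img, start, arm.shape)
        if lab is not None:
            lab = crop_volume(lab, start, arm.shape)
    if arm.includes_ppe:
        img = add_ppe(img, ppe_volume(img.geometry, arm.ppe))
    if augment and arm.flip_p > 0:
        flips = draw_flips(arm.flip_p, rng)
        img = flip_axes(img, flips)
        if lab is not None:
            lab = flip_axes(lab, flips)
    assert img.spatial_shape == tuple(img.geometry.size)
    return img, lab


def prepare_sample(
    image: Volume,
    arm: ArmConfig,
    patch_cfg: PatchConfig,
    label: Optional[Volume] = None,
    rng: Optional[np.random.Generator] = None,
    projection: Optional[np.ndarray] = None,
    patch_pe: Optional[np.ndarray] = None,
):
    """Full pipeline to transformer input: returns (TokenBatch, label Volume).

    ``projection`` and ``patch_pe`` default to seed-reproducible
    initializations (the patch-wise embedding kind follows the arm); during
    training these come from the model instead.
    """
    rng = rng if rng is not None else np.random.default_rng(arm.seed)
    img, lab = prepare_volumes(image, arm, rng, label=label)
    seq = patchify(img, patch_cfg.patch)
    n = sequence_length(img.spatial_shape, patch_cfg.patch)
    width = patch_cfg.patch**3 * img.channels
    if projection is None:
        init_rng = np.random.default_rng(arm.seed)
        projection = init_rng.normal(0.0, width**-0.5, size=(width, patch_cfg.dim))
    if patch_pe is None:
        patch_pe = init_patch_pe(n, patch_cfg.dim, kind=arm.regular_pe_kind, seed=arm.seed)
    tokens = build_tokens(seq, projection, patch_pe)
    return tokens, lab
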