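"""Heterogeneous-acquisition phantom generator.

Emulates the statistical structure that a physical-coordinate embedding
exploits in multi-center tomographic data: every case is acquired on its
own grid (spacing, matrix size, origin all vary), while the segmentation
target — one or more spherical "lesions" — lives at a characteristic
location in the *physical* frame, near the device origin.  Array indices
are therefore uninformative about the target's position; physical
coordinates are informative.

Image model per case, on the case's grid:

    image = texture + contrast * soft(lesion) + noise

* ``texture`` — Gaussian-smoothed white noise, smoothing width specified in
  mm so the texture scale is resolution independent, rescaled to unit
  standard deviation;
* ``soft(lesion)`` — the binary sphere indicator softened by a sub-voxel
  Gaussian (partial-volume effect at the lesion edge);
* ``noise`` — white acquisition noise.

The label is exactly the binary rule: voxel = 1 iff its physical center
lies inside a drawn *target* sphere.  In addition the image (not the
label) contains *decoy* spheres with the identical intensity signature,
placed far from the origin-anchored target region — incidental
hyperintensities whose only distinguishing feature is where they sit in
the physical frame.  Intensity alone therefore cannot separate target
from decoy; physical position can.  This is the statistic the benchmark
isolates: a model without access to physical coordinates faces an
irreducible false-positive floor, a model with them does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import (
    GeometryError,
    ImageGeometry,
    Volume,
    affine_from_geometry,
    load_volume,
    physical_grid,
    save_volume,
)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "sample_geometry",
    "generate_phantom",
    "generate_cases",
    "generate_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Distribution of acquisition geometries and lesions.

    Defaults give spacing 1-4 mm, matrix sizes 32/48/64 cubed (all divisible
    by the benchmark patch size 8), field-of-view center jittered within
    +/- 12 mm of the device origin, and a single sphere of radius 5-10 mm
    centered near the origin (sigma 5 mm, clipped at +/- 10 mm).
    """

    spacing_range: tuple[float, float] = (1.0, 4.0)
    isotropic_spacing: bool = True
    matrix_sizes: tuple[tuple[int, int, int], ...] = (
        (32, 32, 32),
        (48, 48, 48),
        (64, 64, 64),
    )
    origin_jitter: float = 12.0
    lesion_center_sigma: float = 5.0
    lesion_center_max: float = 10.0
    lesion_radius_range: tuple[float, float] = (5.0, 10.0)
    lesion_count_range: tuple[int, int] = (1, 1)
    decoy_count_range: tuple[int, int] = (2, 3)
    decoy_min_dist: float = 30.0
    texture_sigma_mm: float = 8.0
    texture_amplitude: float = 1.0
    contrast: float = 3.0
    noise_sigma: float = 0.1
    edge_sigma_vox: float = 0.7
    patch: int = 8
    max_retries: int = 25

    def __post_init__(self) -> None:
        lo, hi = self.spacing_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid spacing range {self.spacing_range}")
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError(f"invalid radius range {self.lesion_radius_range}")
        for size in self.matrix_sizes:
            if any(s % self.patch != 0 for s in size):
                raise ValueError(
                    f"matrix size {size} not divisible by benchmark patch {self.patch}"
                )


@dataclass
class PhantomCase:
    """One generated case: image + label volumes and the drawn lesions."""

    image: Volume
    label: Volume
    lesions: list[tuple[np.ndarray, float]]  # (center mm, radius mm)
    case_id: str = ""


def sample_geometry(
    spec: PhantomSpec, rng: np.random.Generator, random_rotation: bool = False
) -> ImageGeometry:
    """Draw one acquisition geometry from the spec.

    Spacing is uniform over the range — one shared draw per case by default
    (isotropic voxels; set ``isotropic_spacing=False`` for independent
    per-axis draws) — the matrix size is a uniform choice, and the
    field-of-view center is uniform within +/- ``origin_jitter`` of the
    device origin.  Direction is identity unless ``random_rotation`` asks
    for a uniformly random rotation (used by invariance tests).
    """
    if spec.isotropic_spacing:
        spacing = np.full(3, rng.uniform(*spec.spacing_range))
    else:
        spacing = rng.uniform(*spec.spacing_range, size=3)
    size = spec.matrix_sizes[int(rng.integers(len(spec.matrix_sizes)))]
    fov_center = rng.uniform(-spec.origin_jitter, spec.origin_jitter, size=3)
    if random_rotation:
        from scipy.stats import special_ortho_group

        direction = special_ortho_group.rvs(3, random_state=rng)
    else:
        direction = np.eye(3)
    fov = spacing * np.asarray(size, dtype=float)
    # origin (center of voxel 0) = FOV center minus half-FOV plus half-voxel
    origin = fov_center - direction @ (fov / 2.0 - spacing / 2.0)
    return ImageGeometry(origin=origin, spacing=spacing, direction=direction, size=size)


def _draw_lesions(
    geom: ImageGeometry, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[np.ndarray, float]]]:
    """Draw lesions until the label is non-empty (bounded retries)."""
    grid = physical_grid(geom)
    count = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    for _ in range(spec.max_retries):
        lesions = []
        label = np.zeros(geom.size, dtype=bool)
        for _ in range(count):
            center = np.clip(
                rng.normal(0.0, spec.lesion_center_sigma, size=3),
                -spec.lesion_center_max,
                spec.lesion_center_max,
            )
            radius = float(rng.uniform(*spec.lesion_radius_range))
            rel = grid - center[:, None, None, None]
            dist2 = np.einsum("chwd,chwd->hwd", rel, rel)
            label |= dist2 <= radius**2
            lesions.append((center, radius))
        # a lesion can fall between voxel centers on a coarse grid or outside
        # the jittered FOV; redraw in that case
        if label.any():
            return label, lesions
    raise GeometryError(
        f"no lesion intersected the grid after {spec.max_retries} retries "
        f"(FOV {geom.fov}, origin {geom.origin})"
    )


def _draw_decoys(
    geom: ImageGeometry, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unlabeled decoy spheres, centers >= decoy_min_dist from the origin.

    Decoys are drawn uniformly over the field of view (5 mm margin); draws
    closer to the origin than ``decoy_min_dist`` are rejected.  On small
    fields of view that exclude the far periphery, fewer (possibly zero)
    decoys fit — exactly as peripheral findings fall outside a tight
    acquisition window.
    """
    count = int(rng.integers(spec.decoy_count_range[0], spec.decoy_count_range[1] + 1))
    decoy = np.zeros(geom.size, dtype=bool)
    if count == 0:
        return decoy
    grid = physical_grid(geom)
    corner = geom.fov / 2.0 - 5.0
    for _ in range(count):
        for _attempt in range(spec.max_retries):
            center = rng.uniform(-corner, corner)
            if np.linalg.norm(center) >= spec.decoy_min_dist:
                radius = float(rng.uniform(*spec.lesion_radius_range))
                rel = grid - center[:, None, None, None]
                decoy |= np.einsum("chwd,chwd->hwd", rel, rel) <= radius**2
                break
    return decoy


def generate_phantom(
    geom: ImageGeometry, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[Volume, Volume, list[tuple[np.ndarray, float]]]:
    """Render one phantom on ``geom``; returns (image, label, lesions)."""
    label, lesions = _draw_lesions(geom, spec, rng)
    decoy = _draw_decoys(geom, spec, rng)

    sigma_vox = spec.texture_sigma_mm / geom.spacing  # mm -> voxels per axis
    texture = gaussian_filter(rng.standard_normal(geom.size), sigma=sigma_vox)
    std = texture.std()
    if std > 0:
        texture = texture / std * spec.texture_amplitude
    soft = gaussian_filter(
        (label | decoy).astype(np.float64), sigma=spec.edge_sigma_vox
    )
    noise = rng.standard_normal(geom.size) * spec.noise_sigma
    image = texture + spec.contrast * soft + noise

    return (
        Volume(data=image[np.newaxis], geometry=geom),
        Volume(data=label[np.newaxis].astype(np.uint8), geometry=geom),
        lesions,
    )


def generate_cases(
    spec: PhantomSpec, n: int, seed: int, random_rotation: bool = False
) -> list[PhantomCase]:
    """Generate ``n`` cases in memory, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cases = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        geom = sample_geometry(spec, rng, random_rotation=random_rotation)
        image, label, lesions = generate_phantom(geom, spec, rng)
        cases.append(PhantomCase(image=image, label=label, lesions=lesions, case_id=f"case_{i:04d}"))
    return cases


def generate_dataset(spec: PhantomSpec, n: int, seed: int, out_dir) -> pd.DataFrame:
    """Write ``n`` NIfTI image/label pairs plus a manifest CSV.

    The manifest records per-case geometry (origin, spacing, size) and the
    drawn lesions (JSON column), and is returned as a DataFrame.  Re-running
    with the same seed reproduces the arrays exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in generate_cases(spec, n, seed):
        img_path = out_dir / f"{case.case_id}_image.nii"
        lab_path = out_dir / f"{case.case_id}_label.nii"
        save_volume(case.image, img_path, dtype=np.float32)
        save_volume(case.label, lab_path, dtype=np.uint8)
        geom = case.image.geometry
        rows.append(
            {
                "case_id": case.case_id,
                "image": img_path.name,
                "label": lab_path.name,
                "origin": json.dumps([float(v) for v in geom.origin]),
                "spacing": json.dumps([float(v) for v in geom.spacing]),
                "size": json.dumps([int(v) for v in geom.size]),
                "lesions": json.dumps(
                    [
                        {"center": [float(v) for v in c], "radius": float(r)}
                        for c, r in case.lesions
                    ]
                ),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path) -> list[PhantomCase]:
    """Load cases written by :func:`generate_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    cases = []
    for _, row in manifest.iterrows():
        image = load_volume(root / row["image"])
        label = load_volume(root / row["label"])
        lesions = [
            (np.asarray(entry["center"], dtype=float), float(entry["radius"]))
            for entry in json.loads(row["lesions"])
        ]
        cases.append(
            PhantomCase(image=image, label=label, lesions=lesions, case_id=str(row["case_id"]))
        )
    return cases
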