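# geoppe — physical-coordinate positional embedding for tomographic images

Transformer pipelines for volumetric medical images tokenize a fixed array
shape, so datasets with heterogeneous acquisitions (different voxel
spacing, matrix size, origin, field of view) are conventionally resampled
to a common grid — at the cost of spatial resolution. Random cropping
keeps native resolution but discards *where in the scanner* each voxel was
acquired, because standard patch-wise positional embeddings encode array
position only.

`geoppe` implements the alternative: a pixel-wise embedding of each
voxel's physical position, computed from the geometry metadata every
tomographic header carries (origin, spacing, direction cosines) and added
to the image intensities before tokenization:

    PPE(x, y, z) = sin(ω · √(x² + y² + z²)) / S

with angular frequency ω (rad/mm; default 1) and scaling factor S
(default 100) bounding the amplitude so the positional signal does not
dominate normalized intensities. Because the field depends only on
distance from the device origin, its value at a physical point is
independent of the grid sampling it — the property that restores
physical-space awareness across resolutions, and the property the test
suite pins down (with an array-index embedding as the failing negative
control).

The package is aimed at researchers prototyping geometry-aware
tokenization for 3D segmentation: it provides the geometry layer
(NIfTI-affine ↔ origin/spacing/direction, crop- and resample-consistent),
the embedding, ViT-style patch tokenization, the preprocessing arms
(normalize, random crop, resample-to-shape, flips), a synthetic
heterogeneous-acquisition phantom benchmark, the field's standard
evaluation stack (Dice, true-positive-component HD95, exact paired
Wilcoxon with Bonferroni), and a small CPU transformer segmenter with
hand-verified gradients to exercise it all end to end. See
`docs/methods.md` for the model and design details.

## Worked example

```python
import numpy as np
from geoppe import (ImageGeometry, PPEParams, Volume,
                    ppe_volume, add_ppe, normalize_per_channel,
                    patchify, sequence_length)

# two acquisitions of the same physical scene
fine   = ImageGeometry(origin=(5, -3, 2), spacing=(1, 1, 1), size=(8, 8, 8))
coarse = ImageGeometry(origin=(5, -3, 2), spacing=(2, 2, 2), size=(4, 4, 4))

f = ppe_volume(fine, PPEParams(omega=1.0, scale=100.0))
c = ppe_volume(coarse, PPEParams(omega=1.0, scale=100.0))
print(float(np.max(np.abs(f.values[::2, ::2, ::2] - c.values))))
# 0.0   <- same physical points, same embedding values

img = Volume(np.random.default_rng(0).normal(size=(1, 8, 8, 8)), fine)
tokens = patchify(add_ppe(normalize_per_channel(img), f), patch=4)
print(len(tokens), sequence_length((8, 8, 8), 4))
# 8 8
```

The embedding agrees exactly wherever the two grids share voxel centers
(identical physical coordinates flow through the identical float
pipeline), and the augmented volume tokenizes into the N = HWD/P³ patches
the transformer consumes.

The phantom benchmark is one call (this is what the acceptance checks
run; roughly ten minutes on one CPU):

```python
from geoppe import run_benchmark
res = run_benchmark(seeds=(0, 1, 2))
print(res["mean_dice"])
# {'resample': 0.0404, 'crop': 0.2358, 'crop+ppe': 0.2179, 'crop+ppe-only': 0.2282}
print(res["pvalues_bonferroni"]["crop+ppe vs resample"])
# 0.00010582359110087305
```

Cropping preserves resolution and beats resampling by a wide, strongly
significant margin; at this desk scale the embedding-vs-no-embedding
margins are within training noise (see the limitations section of
`docs/methods.md` for why, and for per-run diagnostics showing the
mechanism at work).

A `geoppe` command-line tool wraps the same functionality
(`geoppe phantom`, `geoppe compute-ppe`, `geoppe train-demo`,
`geoppe eval`); run any of them with `--help`.

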