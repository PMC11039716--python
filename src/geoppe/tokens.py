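"""Tokenization: volume -> non-overlapping 3D patches -> transformer tokens.

A (C, H, W, D) volume is divided into non-overlapping cubic patches of side
P, giving a sequence of N = H*W*D / P^3 flattened patches of length P^3*C.
Tokens are the linear projection of the patches plus a patch-wise positional
embedding:  Tokens = Patches @ W + b + PE,  with Tokens in R^(N x K).

Patch scan order is row-major over the (H/P, W/P, D/P) block grid and each
patch row is the C-order flattening of the (P, P, P, C) block; the order is
arbitrary but frozen so a learnable patch embedding is well defined.
Non-divisible shapes are rejected rather than padded: silent padding would
break the voxel <-> physical-coordinate correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ContractError, Volume

__all__ = [
    "ConfigError",
    "PatchConfig",
    "PatchSequence",
    "TokenBatch",
    "sequence_length",
    "patchify",
    "unpatchify",
    "build_tokens",
    "init_patch_pe",
]


class ConfigError(ValueError):
    """Invalid tokenization/model configuration."""


@dataclass(frozen=True)
class PatchConfig:
    """Patch side length P (voxels) and token dimensionality K."""

    patch: int
    dim: int

    def __post_init__(self) -> None:
        if self.patch < 1:
            raise ConfigError(f"patch must be >= 1, got {self.patch}")
        if self.dim < 1:
            raise ConfigError(f"dim must be >= 1, got {self.dim}")


@dataclass
class PatchSequence:
    """N x (P^3 * C) array of flattened patches in frozen scan order."""

    data: np.ndarray
    grid: tuple[int, int, int]  # (H/P, W/P, D/P) block counts
    patch: int
    channels: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        n = int(np.prod(self.grid))
        width = self.patch**3 * self.channels
        if self.data.shape != (n, width):
            raise ContractError(
                f"patch sequence shape {self.data.shape} inconsistent with "
                f"grid {self.grid}, patch {self.patch}, channels {self.channels}"
            )

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class TokenBatch:
    """N x K token array fed to a transformer encoder."""

    tokens: np.ndarray

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens)
        if self.tokens.ndim != 2:
            raise ContractError(f"tokens must be (N, K), got shape {self.tokens.shape}")


def sequence_length(size, patch: int) -> int:
    """Number of tokens N = H*W*D / P^3; every axis must be divisible by P."""
    size = tuple(int(s) for s in size)
    for axis, s in enumerate(size):
        if s % patch != 0:
            suggestion = (s // patch) * patch
            raise ContractError(
                f"axis {axis} (size {s}) is not divisible by patch {patch}; "
                f"crop to {max(suggestion, patch)} or another multiple of {patch}"
            )
    h, w, d = size
    return (h * w * d) // patch**3


def patchify(image: Volume, patch: int) -> PatchSequence:
    """Split a volume into flattened non-overlapping P^3 patches."""
    c, h, w, d = image.data.shape
    n = sequence_length((h, w, d), patch)  # validates divisibility
    grid = (h // patch, w // patch, d // patch)
    # (C,H,W,D) -> (H,W,D,C) -> blocks -> (n_h, n_w, n_d, P, P, P, C) -> (N, P^3*C)
    arr = np.moveaxis(image.data, 0, -1)
    arr = arr.reshape(grid[0], patch, grid[1], patch, grid[2], patch, c)
    arr = arr.transpose(0, 2, 4, 1, 3, 5, 6)
    data = arr.reshape(n, patch**3 * c)
    return PatchSequence(data=data, grid=grid, patch=patch, channels=c)


def unpatchify(seq: PatchSequence, size, channels: int, patch: int) -> np.ndarray:
    """Exact inverse of :func:`patchify`; returns a (C, H, W, D) array."""
    h, w, d = (int(s) for s in size)
    n = sequence_length((h, w, d), patch)
    if len(seq) != n or seq.patch != patch or seq.channels != channels:
        raise ContractError(
            f"sequence (N={len(seq)}, patch={seq.patch}, channels={seq.channels}) "
            f"inconsistent with size {size}, channels {channels}, patch {patch}"
        )
    grid = (h // patch, w // patch, d // patch)
    arr = seq.data.reshape(*grid, patch, patch, patch, channels)
    arr = arr.transpose(0, 3, 1, 4, 2, 5, 6)
    arr = arr.reshape(h, w, d, channels)
    return np.moveaxis(arr, -1, 0)


def build_tokens(seq: PatchSequence, projection, patch_pe: np.ndarray, bias=None) -> TokenBatch:
    """Tokens = Patches @ projection + bias + patch-wise positional embedding."""
    proj = np.asarray(projection)
    pe = np.asarray(patch_pe)
    n, width = seq.data.shape
    if proj.ndim != 2 or proj.shape[0] != width:
        raise ContractError(
            f"projection must be ({width}, K), got {proj.shape} for patch width {width}"
        )
    k = proj.shape[1]
    if pe.shape != (n, k):
        raise ContractError(f"patch_pe must be ({n}, {k}), got {pe.shape}")
    tokens = seq.data @ proj + pe
    if bias is not None:
        bias = np.asarray(bias)
        if bias.shape != (k,):
            raise ContractError(f"bias must be ({k},), got {bias.shape}")
        tokens = tokens + bias
    return TokenBatch(tokens=tokens)


def init_patch_pe(n: int, dim: int, kind: str = "learnable", seed: int = 0) -> np.ndarray:
    """Patch-wise positional embedding of shape (N, K).

    kind="learnable": truncated-normal init (std 0.02, clipped at 2 std),
    seed-reproducible, intended to be trained.
    kind="sinusoidal": fixed interleaved sin/cos bands over the flat patch
    index (the classic transformer table), so row 0 alternates 0, 1, 0, 1...
    kind="none": a zero array — the ablation arm that relies on the
    coordinate embedding alone.
    """
    if n < 1 or dim < 1:
        raise ConfigError(f"n and dim must be >= 1, got n={n}, dim={dim}")
    if kind == "learnable":
        rng = np.random.default_rng(seed)
        pe = rng.normal(0.0, 0.02, size=(n, dim))
        # redraw tail samples so the init is truncated at +/- 2 std
        out = np.abs(pe) > 0.04
        while np.any(out):
            pe[out] = rng.normal(0.0, 0.02, size=int(out.sum()))
            out = np.abs(pe) > 0.04
        return pe
    if kind == "sinusoidal":
        pos = np.arange(n, dtype=np.float64)[:, None]
        i = np.arange(dim, dtype=np.float64)[None, :]
        angle = pos / np.power(10000.0, 2.0 * np.floor(i / 2.0) / dim)
        pe = np.empty((n, dim))
        pe[:, 0::2] = np.sin(angle[:, 0::2])
        pe[:, 1::2] = np.cos(angle[:, 1::2])
        return pe
    if kind == "none":
        return np.zeros((n, dim))
    raise ConfigError(f"unknown patch-PE kind {kind!r}; use learnable|sinusoidal|none")
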