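"""A deliberately small ViT-style 3D segmenter, CPU-only, in numpy.

The model exists to demonstrate the preprocessing comparison (resample vs
random crop vs crop + physical-coordinate embedding, and the embedding with
vs without the regular patch-wise embedding) at desk scale; it is not a
reimplementation of the large encoder-decoder architectures used at GPU
scale.

Architecture: linear patch projection + patch-wise positional embedding,
``depth`` pre-LayerNorm transformer encoder blocks (multi-head
self-attention + GELU MLP), a final LayerNorm, and a per-token linear head
over the token concatenated with its raw input patch (an input-level skip
connection, without which the K-dim token bottleneck could not represent
voxel-level intensity rules), producing P^3 voxel logits per patch,
scattered back to the volume and refined by a fixed separable trilinear
smoothing kernel (0.25, 0.5, 0.25) per axis.  Forward and backward passes are written explicitly; parameters
are trained with Adam on a soft-Dice + binary cross-entropy loss.  All
randomness flows from explicit integer seeds, so runs are bit-reproducible
on a single thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.special import ndtr

from .geometry import ContractError, Volume
from .metrics import SegScore, dice, hd95_tp_components, summarize_scores, wilcoxon_signed_rank, bonferroni
from .phantom import PhantomCase, PhantomSpec, generate_cases
from .pipeline import ARMS, ArmConfig, prepare_volumes
from .ppe import PPEParams
from .tokens import ConfigError, init_patch_pe, sequence_length

__all__ = [
    "TrainingError",
    "DemoModelConfig",
    "DemoSegmenter",
    "build_demo_segmenter",
    "train_demo",
    "evaluate_arm",
    "run_benchmark",
    "BENCHMARK_ARMS",
]

BENCHMARK_ARMS = ("resample", "crop", "crop+ppe", "crop+ppe-only")


class TrainingError(RuntimeError):
    """Optimization diverged (non-finite loss)."""


@dataclass(frozen=True)
class DemoModelConfig:
    """Hyperparameters of the demo segmenter and its training loop.

    Defaults (32^3 ROI, P=8 so N=64 tokens, K=64, depth 2) are sized so a
    full multi-arm, multi-seed benchmark runs on one CPU in minutes.
    """

    patch: int = 8
    dim: int = 64
    depth: int = 2
    heads: int = 4
    mlp_ratio: int = 2
    smooth_passes: int = 1
    lr: float = 3e-3
    steps: int = 1000
    batch: int = 4
    seed: int = 0
    pe_kind: str = "learnable"
    eval_every: int = 200
    dtype: str = "float32"  # float32 halves step cost; float64 for gradient checks

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"dtype must be float32|float64, got {self.dtype}")
        for name in ("patch", "dim", "depth", "heads", "mlp_ratio", "lr", "steps", "batch"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.dim % self.heads != 0:
            raise ConfigError(f"dim {self.dim} must be divisible by heads {self.heads}")
        if self.pe_kind not in ("learnable", "sinusoidal", "none"):
            raise ConfigError(f"unknown pe_kind {self.pe_kind!r}")


# ---------------------------------------------------------------------------
# primitive layers (forward + explicit backward)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    return dx, dg, db


def _gelu_fwd(x):
    phi = ndtr(x)
    return x * phi, (x, phi)


def _gelu_bwd(dy, cache):
    x, phi = cache
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return dy * (phi + x * pdf)


def _softmax(x):
    m = x.max(-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(-1, keepdims=True)


def _batched_patchify(vol: np.ndarray, patch: int) -> np.ndarray:
    """(B, C, H, W, D) -> (B, N, P^3*C), same frozen order as tokens.patchify."""
    b, c, h, w, d = vol.shape
    gh, gw, gd = h // patch, w // patch, d // patch
    arr = np.moveaxis(vol, 1, -1)
    arr = arr.reshape(b, gh, patch, gw, patch, gd, patch, c)
    arr = arr.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return arr.reshape(b, gh * gw * gd, patch**3 * c)


def _batched_scatter(tok: np.ndarray, patch: int, shape) -> np.ndarray:
    """(B, N, P^3) -> (B, H, W, D); inverse of single-channel patchify."""
    b, n, _ = tok.shape
    h, w, d = shape
    gh, gw, gd = h // patch, w // patch, d // patch
    arr = tok.reshape(b, gh, gw, gd, patch, patch, patch)
    arr = arr.transpose(0, 1, 4, 2, 5, 3, 6)
    return arr.reshape(b, h, w, d)


_SMOOTH_KERNEL = np.array([0.25, 0.5, 0.25])


def _smooth(vol: np.ndarray, passes: int) -> np.ndarray:
    # zero-padded symmetric kernel => the operator is self-adjoint, so the
    # backward pass is the same convolution
    for _ in range(passes):
        for axis in (1, 2, 3):
            vol = convolve1d(vol, _SMOOTH_KERNEL, axis=axis, mode="constant", cval=0.0)
    return vol


# ---------------------------------------------------------------------------
# the segmenter
# ---------------------------------------------------------------------------


class DemoSegmenter:
    """Token transformer + per-token voxel head; see module docstring."""

    def __init__(self, cfg: DemoModelConfig, roi, channels: int = 1):
        self.cfg = cfg
        self.roi = tuple(int(s) for s in roi)
        self.channels = int(channels)
        self.n_tokens = sequence_length(self.roi, cfg.patch)
        self.width = cfg.patch**3 * self.channels
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _init_params(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.dim
        p: dict[str, np.ndarray] = {}
        self.params = p
        p["proj_W"] = rng.normal(0.0, self.width**-0.5, (self.width, k))
        p["proj_b"] = np.zeros(k)
        if cfg.pe_kind == "learnable":
            p["patch_pe"] = init_patch_pe(self.n_tokens, k, "learnable", seed=cfg.seed + 1)
            self.fixed_pe = None
        else:
            self.fixed_pe = init_patch_pe(self.n_tokens, k, cfg.pe_kind, seed=cfg.seed + 1)
        for l in range(cfg.depth):
            p[f"ln1_g{l}"] = np.ones(k)
            p[f"ln1_b{l}"] = np.zeros(k)
            p[f"qkv_W{l}"] = rng.normal(0.0, k**-0.5, (k, 3 * k))
            p[f"qkv_b{l}"] = np.zeros(3 * k)
            p[f"att_W{l}"] = rng.normal(0.0, k**-0.5, (k, k))
            p[f"att_b{l}"] = np.zeros(k)
            p[f"ln2_g{l}"] = np.ones(k)
            p[f"ln2_b{l}"] = np.zeros(k)
            hidden = cfg.mlp_ratio * k
            p[f"mlp_W1{l}"] = rng.normal(0.0, k**-0.5, (k, hidden))
            p[f"mlp_b1{l}"] = np.zeros(hidden)
            p[f"mlp_W2{l}"] = rng.normal(0.0, hidden**-0.5, (hidden, k))
            p[f"mlp_b2{l}"] = np.zeros(k)
        p["lnf_g"] = np.ones(k)
        p["lnf_b"] = np.zeros(k)
        # the head also sees the raw patch through an elementwise skip
        # (per-voxel gain on the input), so voxel-level intensity rules are
        # representable despite the K-dim token bottleneck — the role the
        # reference encoder-decoder family's input-level skip plays
        p["head_W"] = rng.normal(0.0, 0.1 * k**-0.5, (k, cfg.patch**3))
        p["head_skip"] = np.zeros(self.width)
        p["head_b"] = np.zeros(cfg.patch**3)
        dtype = np.dtype(cfg.dtype)
        for name in p:
            p[name] = p[name].astype(dtype)
        if self.fixed_pe is not None:
            self.fixed_pe = self.fixed_pe.astype(dtype)

    # -- forward ----------------------------------------------------------

    def forward(self, batch: np.ndarray, want_cache: bool = True):
        """batch (B, C, H, W, D) -> per-voxel logits (B, H, W, D)."""
        cfg, p = self.cfg, self.params
        if batch.shape[1:] != (self.channels, *self.roi):
            raise ContractError(
                f"input shape {batch.shape[1:]} does not match model "
                f"(channels={self.channels}, roi={self.roi})"
            )
        cache: dict = {}
        batch = np.asarray(batch, dtype=p["proj_W"].dtype)
        patches = _batched_patchify(batch, cfg.patch)
        pe = p["patch_pe"] if cfg.pe_kind == "learnable" else self.fixed_pe
        x = patches @ p["proj_W"] + p["proj_b"] + pe
        cache["patches"] = patches
        cache["blocks"] = []
        dh = cfg.dim // cfg.heads
        for l in range(cfg.depth):
            blk: dict = {}
            blk["x_in"] = x
            h1, blk["ln1"] = _ln_fwd(x, p[f"ln1_g{l}"], p[f"ln1_b{l}"])
            blk["h1"] = h1
            qkv = h1 @ p[f"qkv_W{l}"] + p[f"qkv_b{l}"]
            b, n, _ = qkv.shape
            q, kk, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(b, n, cfg.heads, dh).transpose(0, 2, 1, 3)
            kk = kk.reshape(b, n, cfg.heads, dh).transpose(0, 2, 1, 3)
            v = v.reshape(b, n, cfg.heads, dh).transpose(0, 2, 1, 3)
            scores = np.einsum("bhnd,bhmd->bhnm", q, kk) / math.sqrt(dh)
            attn = _softmax(scores)
            out = np.einsum("bhnm,bhmd->bhnd", attn, v)
            merged = out.transpose(0, 2, 1, 3).reshape(b, n, cfg.dim)
            att_out = merged @ p[f"att_W{l}"] + p[f"att_b{l}"]
            blk.update(q=q, k=kk, v=v, attn=attn, merged=merged)
            x = x + att_out
            blk["x_mid"] = x
            h2, blk["ln2"] = _ln_fwd(x, p[f"ln2_g{l}"], p[f"ln2_b{l}"])
            blk["h2"] = h2
            z1 = h2 @ p[f"mlp_W1{l}"] + p[f"mlp_b1{l}"]
            a1, blk["gelu"] = _gelu_fwd(z1)
            blk["a1"] = a1
            x = x + a1 @ p[f"mlp_W2{l}"] + p[f"mlp_b2{l}"]
            cache["blocks"].append(blk)
        y, cache["lnf"] = _ln_fwd(x, p["lnf_g"], p["lnf_b"])
        cache["y"] = y
        # elementwise input skip: per-(voxel, channel) gain, summed over channels
        b_sz, n_tok, _ = patches.shape
        pr = patches.reshape(b_sz, n_tok, cfg.patch**3, self.channels)
        weighted = pr * p["head_skip"].reshape(cfg.patch**3, self.channels)
        tok_logits = y @ p["head_W"] + weighted.sum(-1) + p["head_b"]
        raw = _batched_scatter(tok_logits, cfg.patch, self.roi)
        logits = _smooth(raw, cfg.smooth_passes)
        if not want_cache:
            return logits, None
        return logits, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg, p = self.cfg, self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = np.asarray(dlogits, dtype=p["proj_W"].dtype)
        draw = _smooth(dlogits, cfg.smooth_passes)  # self-adjoint smoothing
        dtok = _batched_patchify(draw[:, None], cfg.patch)  # (B, N, P^3)
        y = cache["y"]
        patches = cache["patches"]
        grads["head_W"] = np.einsum("bnk,bnm->km", y, dtok)
        grads["head_b"] = dtok.sum(axis=(0, 1))
        b_sz, n_tok, _ = patches.shape
        pr = patches.reshape(b_sz, n_tok, cfg.patch**3, self.channels)
        grads["head_skip"] = (pr * dtok[..., None]).sum(axis=(0, 1)).reshape(-1)
        dy = dtok @ p["head_W"].T
        dx, grads["lnf_g"], grads["lnf_b"] = _ln_bwd(dy, cache["lnf"])
        dh_size = cfg.dim // cfg.heads
        for l in reversed(range(cfg.depth)):
            blk = cache["blocks"][l]
            # MLP branch
            da1 = dx @ p[f"mlp_W2{l}"].T
            grads[f"mlp_W2{l}"] = np.einsum("bnh,bnk->hk", blk["a1"], dx)
            grads[f"mlp_b2{l}"] = dx.sum(axis=(0, 1))
            dz1 = _gelu_bwd(da1, blk["gelu"])
            grads[f"mlp_W1{l}"] = np.einsum("bnk,bnh->kh", blk["h2"], dz1)
            grads[f"mlp_b1{l}"] = dz1.sum(axis=(0, 1))
            dh2 = dz1 @ p[f"mlp_W1{l}"].T
            dx_mid, grads[f"ln2_g{l}"], grads[f"ln2_b{l}"] = _ln_bwd(dh2, blk["ln2"])
            dx = dx + dx_mid
            # attention branch
            datt = dx  # residual: gradient w.r.t. att_out equals dx at x_mid
            merged = blk["merged"]
            grads[f"att_W{l}"] = np.einsum("bnk,bnm->km", merged, datt)
            grads[f"att_b{l}"] = datt.sum(axis=(0, 1))
            dmerged = datt @ p[f"att_W{l}"].T
            b, n, _ = dmerged.shape
            dout = dmerged.reshape(b, n, cfg.heads, dh_size).transpose(0, 2, 1, 3)
            attn, q, kk, v = blk["attn"], blk["q"], blk["k"], blk["v"]
            dattn = np.einsum("bhnd,bhmd->bhnm", dout, v)
            dv = np.einsum("bhnm,bhnd->bhmd", attn, dout)
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= math.sqrt(dh_size)
            dq = np.einsum("bhnm,bhmd->bhnd", dscores, kk)
            dk = np.einsum("bhnm,bhnd->bhmd", dscores, q)
            dqkv = np.concatenate(
                [
                    g.transpose(0, 2, 1, 3).reshape(b, n, cfg.dim)
                    for g in (dq, dk, dv)
                ],
                axis=-1,
            )
            grads[f"qkv_W{l}"] = np.einsum("bnk,bnm->km", blk["h1"], dqkv)
            grads[f"qkv_b{l}"] = dqkv.sum(axis=(0, 1))
            dh1 = dqkv @ p[f"qkv_W{l}"].T
            dx_in, grads[f"ln1_g{l}"], grads[f"ln1_b{l}"] = _ln_bwd(dh1, blk["ln1"])
            dx = dx + dx_in
        # projection + patch embedding
        grads["proj_W"] = np.einsum("bnw,bnk->wk", cache["patches"], dx)
        grads["proj_b"] = dx.sum(axis=(0, 1))
        if cfg.pe_kind == "learnable":
            grads["patch_pe"] = dx.sum(axis=0)
        return grads

    def adam_step(self, grads: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        lr = self.cfg.lr
        for name, g in grads.items():
            m = self._adam_m[name] = beta1 * self._adam_m[name] + (1 - beta1) * g
            v = self._adam_v[name] = beta2 * self._adam_v[name] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()

    def predict_proba(self, volume: Volume) -> np.ndarray:
        """Foreground probability (H, W, D) for one prepared volume."""
        logits, _ = self.forward(volume.data[np.newaxis], want_cache=False)
        return 1.0 / (1.0 + np.exp(-logits[0]))


def build_demo_segmenter(cfg: DemoModelConfig, roi=(32, 32, 32), channels: int = 1) -> DemoSegmenter:
    """Construct the demo segmenter for a fixed ROI; seed-reproducible."""
    roi = tuple(int(s) for s in roi)
    for axis, s in enumerate(roi):
        if s % cfg.patch != 0:
            raise ConfigError(f"roi axis {axis} ({s}) not divisible by patch {cfg.patch}")
    return DemoSegmenter(cfg, roi, channels)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def segmentation_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Soft-Dice + binary cross-entropy; returns (loss, dL/dlogits)."""
    b = logits.shape[0]
    z = logits.reshape(b, -1)
    t = targets.reshape(b, -1).astype(np.float64)
    nvox = z.shape[1]
    prob = 1.0 / (1.0 + np.exp(-z))
    # numerically stable BCE
    bce = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    bce_loss = bce.mean()
    dz = (prob - t) / (b * nvox)
    # per-sample soft Dice
    inter = (prob * t).sum(axis=1)
    sums = prob.sum(axis=1) + t.sum(axis=1)
    num = 2.0 * inter + eps
    den = sums + eps
    dice_loss = (1.0 - num / den).mean()
    dnum_dp = 2.0 * t
    dp = -(dnum_dp * den[:, None] - num[:, None]) / (den[:, None] ** 2) / b
    dz = dz + dp * prob * (1.0 - prob)
    loss = bce_loss + dice_loss
    return loss, dz.reshape(logits.shape)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _case_arrays(case: PhantomCase, arm: ArmConfig, rng, augment: bool, normalized: bool = False):
    img, lab = prepare_volumes(
        case.image, arm, rng, label=case.label, augment=augment, normalize=not normalized
    )
    return img, lab


def _prenormalize(cases: Sequence[PhantomCase]) -> list[PhantomCase]:
    """Normalization is deterministic per case; do it once up front."""
    from .pipeline import normalize_per_channel

    return [
        PhantomCase(
            image=normalize_per_channel(c.image),
            label=c.label,
            lesions=c.lesions,
            case_id=c.case_id,
        )
        for c in cases
    ]


def train_demo(
    train_cases: Sequence[PhantomCase],
    val_cases: Sequence[PhantomCase],
    arm: ArmConfig,
    cfg: DemoModelConfig,
    verbose: bool = False,
):
    """Train the demo segmenter under one preprocessing arm.

    Checkpoints the parameter state with the best validation Dice
    (evaluated every ``cfg.eval_every`` steps, deterministic preparation)
    and restores it at the end.  Returns ``(model, history)`` where history
    is a DataFrame of per-step loss and periodic validation Dice.
    """
    if not train_cases or not val_cases:
        raise ContractError("train and validation case lists must be non-empty")
    channels = train_cases[0].image.channels
    model = build_demo_segmenter(cfg, roi=arm.shape, channels=channels)
    # the stream is arm-independent on purpose: arms trained with the same
    # seed see identical batch orders, crop positions and flips, so
    # cross-arm comparisons are paired down to the input transform itself
    rng = np.random.default_rng([cfg.seed, 2654435761 % 2**31])
    records = []
    best = {"dice": -1.0, "state": model.state_copy(), "step": 0}
    train_cases = _prenormalize(train_cases)
    val_cases = _prenormalize(val_cases)

    # validation views are drawn once (two seeded random views per case) and
    # reused at every checkpoint, so best-checkpoint selection compares like
    # with like on a diverse, fixed sample
    val_rng = np.random.default_rng([cfg.seed, 424242])
    val_samples = []
    for case in val_cases:
        for _ in range(2):
            img, lab = _case_arrays(case, arm, val_rng, augment=True, normalized=True)
            val_samples.append((img, lab.data[0] > 0.5))

    def validate() -> float:
        dices = []
        for img, gt in val_samples:
            prob = model.predict_proba(img)
            dices.append(dice(prob >= 0.5, gt))
        return float(np.mean(dices))

    for step in range(1, cfg.steps + 1):
        idx = rng.integers(0, len(train_cases), size=cfg.batch)
        imgs, labs = [], []
        for i in idx:
            img, lab = _case_arrays(train_cases[int(i)], arm, rng, augment=True, normalized=True)
            imgs.append(img.data)
            labs.append(lab.data[0])
        batch = np.stack(imgs)
        targets = np.stack(labs)
        logits, cache = model.forward(batch)
        loss, dlogits = segmentation_loss(logits, targets)
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite loss at step {step} (lr={cfg.lr}, arm={arm.arm}); "
                "lower the learning rate"
            )
        grads = model.backward(dlogits, cache)
        model.adam_step(grads)
        rec = {"step": step, "loss": float(loss), "val_dice": np.nan}
        if step % cfg.eval_every == 0 or step == cfg.steps:
            vd = validate()
            rec["val_dice"] = vd
            if vd > best["dice"]:
                best = {"dice": vd, "state": model.state_copy(), "step": step}
            if verbose:
                print(f"  step {step:4d}  loss {loss:.4f}  val dice {vd:.3f}")
        records.append(rec)
    model.load_state(best["state"])
    history = pd.DataFrame(records)
    history.attrs["best_val_dice"] = best["dice"]
    history.attrs["best_step"] = best["step"]
    return model, history


def evaluate_arm(
    model: Optional[DemoSegmenter],
    test_cases: Sequence[PhantomCase],
    arm: ArmConfig,
    out_csv=None,
):
    """Per-case Dice and true-positive-component HD95 under one arm.

    Preparation is deterministic (centered crop, no flips) so the same
    cases yield paired scores across arms.  ``model=None`` evaluates the
    prepared ground truth against itself (an oracle upper bound).  Returns
    ``(table, summary)``; the table is written as CSV when ``out_csv`` is
    given.
    """
    rng = np.random.default_rng(0)  # unused in deterministic mode
    scores = []
    for case in test_cases:
        img, lab = _case_arrays(case, arm, rng, augment=False)
        gt = lab.data[0] > 0.5
        if model is None:
            pred = gt
        else:
            pred = model.predict_proba(img) >= 0.5
        d = dice(pred, gt)
        if gt.any():
            h = hd95_tp_components(pred, gt, img.geometry.spacing)
        else:
            h = math.nan
        scores.append(SegScore(case_id=case.case_id, dice=d, hd95=h))
    table = pd.DataFrame(
        {
            "case_id": [s.case_id for s in scores],
            "dice": [s.dice for s in scores],
            "hd95_mm": [s.hd95 for s in scores],
        }
    )
    summary = summarize_scores(scores)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False, float_format="%.10g")
    return table, summary


def run_benchmark(
    spec: Optional[PhantomSpec] = None,
    arms: Sequence[str] = BENCHMARK_ARMS,
    seeds: Sequence[int] = (0, 1, 2),
    n_train: int = 48,
    n_val: int = 8,
    n_test: int = 16,
    roi=(32, 32, 32),
    ppe_params: Optional[PPEParams] = None,
    cfg: Optional[DemoModelConfig] = None,
    verbose: bool = False,
):
    """The heterogeneity benchmark: train/evaluate every arm on shared data.

    For each seed one phantom dataset is generated and every arm is trained
    on the identical cases, then evaluated on the identical test cases with
    deterministic preparation, so per-case scores are paired across arms.
    Returns a dict with the pooled per-case table, a per-(arm, seed)
    summary, mean test Dice per arm, and Bonferroni-corrected Wilcoxon
    p-values for the headline comparisons.
    """
    spec = spec if spec is not None else PhantomSpec()
    cfg = cfg if cfg is not None else DemoModelConfig()
    ppe_params = ppe_params if ppe_params is not None else PPEParams()
    per_case_rows = []
    summaries = []
    for seed in seeds:
        cases = generate_cases(spec, n_train + n_val + n_test, seed=int(seed))
        train = cases[:n_train]
        val = cases[n_train : n_train + n_val]
        test = cases[n_train + n_val :]
        for arm_name in arms:
            arm = ArmConfig(
                arm=arm_name, shape=tuple(roi), ppe=ppe_params, flip_p=0.5, seed=int(seed)
            )
            arm_cfg = replace(cfg, seed=int(seed), pe_kind=arm.regular_pe_kind)
            if verbose:
                print(f"[seed {seed}] training arm {arm_name!r}")
            model, history = train_demo(train, val, arm, arm_cfg, verbose=verbose)
            table, summary = evaluate_arm(model, test, arm)
            for _, row in table.iterrows():
                per_case_rows.append(
                    {
                        "seed": int(seed),
                        "arm": arm_name,
                        "case_id": row["case_id"],
                        "dice": row["dice"],
                        "hd95_mm": row["hd95_mm"],
                    }
                )
            summaries.append(
                {
                    "seed": int(seed),
                    "arm": arm_name,
                    "mean_dice": summary["mean_dice"],
                    "mean_hd95_mm": summary["mean_hd95"],
                    "n_hd95_defined": summary["n_hd95_defined"],
                    "best_val_dice": history.attrs["best_val_dice"],
                }
            )
    per_case = pd.DataFrame(per_case_rows)
    summary_df = pd.DataFrame(summaries)
    mean_dice = {
        arm_name: float(per_case.loc[per_case["arm"] == arm_name, "dice"].mean())
        for arm_name in arms
    }

    pvalues: dict[str, float] = {}
    comparisons = []
    if "crop+ppe" in arms:
        for other in ("crop", "resample"):
            if other in arms:
                comparisons.append(("crop+ppe", other))
    if "crop+ppe" in arms and "crop+ppe-only" in arms:
        comparisons.append(("crop+ppe", "crop+ppe-only"))
    raw_ps = []
    for a, bb in comparisons:
        pa = per_case[per_case["arm"] == a].sort_values(["seed", "case_id"])["dice"].to_numpy()
        pb = per_case[per_case["arm"] == bb].sort_values(["seed", "case_id"])["dice"].to_numpy()
        raw_ps.append(wilcoxon_signed_rank(pa, pb))
    for (a, bb), padj in zip(comparisons, bonferroni(raw_ps)):
        pvalues[f"{a} vs {bb}"] = padj

    return {
        "per_case": per_case,
        "summary": summary_df,
        "mean_dice": mean_dice,
        "pvalues_bonferroni": pvalues,
    }
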