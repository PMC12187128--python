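"""WNet3D: a dual 3D U-Net trained end-to-end without labels.

The encoder U-Net maps a single-channel volume to K per-voxel class
probabilities (1x1x1 head + channel softmax); the decoder U-Net maps those
probabilities back to a reconstruction of the input. Training minimizes a
weighted sum of the Soft Normalized Cuts loss on the encoder output and a
reconstruction loss (MSE or BCE) on the decoder output, updated in a single
backward pass. Each U-Net has seven blocks over three resolution levels
(three 2x down/upsampling steps): three descending blocks, a bottleneck, and
three ascending blocks with skip connections concatenating each descending
block's output to its same-resolution ascending block. Group normalization
replaces batch normalization, which suits the small batch sizes typical of
volumetric training.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .io import augment as _augment
from .io import extract_patches, remap_intensity
from .softncuts import AffinityConfig, soft_ncuts_loss_and_grad

__all__ = [
    "WNetArchitectureConfig",
    "TrainConfig",
    "TrainingHistory",
    "WNet3D",
    "build_wnet3d",
    "combined_loss",
    "train_self_supervised",
    "sliding_window_predict",
    "select_foreground_class",
    "save_model",
    "load_model",
    "CheckpointError",
]


class CheckpointError(RuntimeError):
    """Raised when a model checkpoint is corrupt or does not match the config."""


@dataclass(frozen=True)
class WNetArchitectureConfig:
    in_channels: int = 1
    n_classes: int = 2
    features: tuple = (64, 128, 256)  # widths of the three descending blocks
    groups: int = 8  # group-norm groups, clipped to the channel count
    rec_channels: int = 1

    def __post_init__(self):
        if len(self.features) != 3:
            raise ValueError("exactly three resolution levels are required")
        for f in tuple(self.features) + (2 * self.features[-1],):
            g = min(self.groups, f)
            if f % g:
                raise ValueError(f"feature width {f} not divisible by group count {g}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 2
    learning_rate: float = 2e-5  # valid range [2e-5, 2e-3] depending on the data
    w_ncuts: float = 0.5
    # Reconstruction weight, valid range [5e-3, 5e-1] depending on the data.
    # The default sits at the top of the range: with MSE on [0, 100]
    # intensities the reconstruction term must dominate, otherwise the
    # graph-cut term collapses into broad regions of similar brightness.
    w_rec: float = 0.5
    reconstruction_loss: str = "MSE"  # or "BCE"
    affinity: AffinityConfig = field(default_factory=AffinityConfig)
    patch_size: int = 64
    augment: bool = True
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.w_ncuts <= 0 or self.w_rec <= 0:
            raise ValueError("loss weights must be positive")
        if self.reconstruction_loss not in ("MSE", "BCE"):
            raise ValueError("reconstruction_loss must be 'MSE' or 'BCE'")


@dataclass
class TrainingHistory:
    """Per-epoch raw loss terms and their weighted total."""

    ncuts: list = field(default_factory=list)
    reconstruction: list = field(default_factory=list)
    total: list = field(default_factory=list)

    def as_dict(self):
        return {"ncuts": self.ncuts, "reconstruction": self.reconstruction, "total": self.total}

    def loss_balance(self, epoch: int = 0) -> dict:
        """Raw magnitudes of the two loss terms after a warm-up epoch.

        Useful for choosing the weights: the ratio says how strongly the
        reconstruction term dominates (or not) before any rebalancing.
        Nothing is adjusted automatically.
        """
        return {
            "ncuts": self.ncuts[epoch],
            "reconstruction": self.reconstruction[epoch],
            "ratio_rec_over_ncuts": self.reconstruction[epoch] / max(self.ncuts[epoch], 1e-12),
        }


def _groups_for(channels: int, groups: int) -> int:
    return channels if channels < groups else groups


class _Block:
    """Two 3x3x3 convolutions, each followed by ReLU (+ group norm if enabled)."""

    def __init__(self, cin, cout, groups, norm, rng, name):
        self.norm = norm
        self.groups = _groups_for(cout, groups)
        self.name = name
        self.params = {}
        for i, (ci, co) in enumerate(((cin, cout), (cout, cout))):
            std = np.sqrt(2.0 / (ci * 27))
            self.params[f"{name}.conv{i}.w"] = ad.parameter(rng.normal(0.0, std, (co, ci, 3, 3, 3)))
            self.params[f"{name}.conv{i}.b"] = ad.parameter(np.zeros(co))
            if norm:
                self.params[f"{name}.gn{i}.gamma"] = ad.parameter(np.ones(co))
                self.params[f"{name}.gn{i}.beta"] = ad.parameter(np.zeros(co))

    def __call__(self, x):
        for i in range(2):
            x = ad.conv3d(
                x,
                self.params[f"{self.name}.conv{i}.w"],
                self.params[f"{self.name}.conv{i}.b"],
                pad=1,
                pad_mode="reflect",
            )
            x = ad.relu(x)
            if self.norm:
                x = ad.group_norm(
                    x,
                    self.params[f"{self.name}.gn{i}.gamma"],
                    self.params[f"{self.name}.gn{i}.beta"],
                    self.groups,
                )
        return x


class _UNet3D:
    """Seven-block U-Net: 3 descending blocks, bottleneck, 3 ascending blocks.

    Every block is two 3x3x3 convolutions, each followed by ReLU and group
    normalization (normalizing in the outer blocks too keeps the softmax head
    well-scaled for raw-intensity inputs). Descent uses 2x2x2 max pooling, ascent
    2x2x2 transpose convolutions with stride 2; skips concatenate descending
    outputs to the matching ascending inputs.
    """

    def __init__(self, cin, cout, features, groups, rng, softmax_head, name):
        f1, f2, f3 = features
        fb = 2 * f3
        self.softmax_head = softmax_head
        self.params = {}
        self.down = []
        widths = [(cin, f1, True), (f1, f2, True), (f2, f3, True)]
        for i, (ci, co, norm) in enumerate(widths):
            blk = _Block(ci, co, groups, norm, rng, f"{name}.down{i}")
            self.down.append(blk)
            self.params.update(blk.params)
        self.bottleneck = _Block(f3, fb, groups, True, rng, f"{name}.bottleneck")
        self.params.update(self.bottleneck.params)
        self.up = []
        self.upconv = []
        prev = fb
        for i, (fskip, norm) in enumerate(((f3, True), (f2, True), (f1, True))):
            wkey, bkey = f"{name}.up{i}.tconv.w", f"{name}.up{i}.tconv.b"
            std = np.sqrt(2.0 / (prev * 8))
            self.params[wkey] = ad.parameter(rng.normal(0.0, std, (prev, fskip, 2, 2, 2)))
            self.params[bkey] = ad.parameter(np.zeros(fskip))
            self.upconv.append((wkey, bkey))
            blk = _Block(2 * fskip, fskip, groups, norm, rng, f"{name}.up{i}")
            self.up.append(blk)
            self.params.update(blk.params)
            prev = fskip
        std = np.sqrt(2.0 / f1)
        self.params[f"{name}.head.w"] = ad.parameter(rng.normal(0.0, std, (cout, f1, 1, 1, 1)))
        self.params[f"{name}.head.b"] = ad.parameter(np.zeros(cout))
        self.name = name

    def __call__(self, x):
        skips = []
        for i, blk in enumerate(self.down):
            x = blk(x)
            skips.append(x)
            x = ad.maxpool3d_2x(x)
        x = self.bottleneck(x)
        for i, blk in enumerate(self.up):
            wkey, bkey = self.upconv[i]
            x = ad.conv_transpose3d_2x(x, self.params[wkey], self.params[bkey])
            x = ad.concat_channels(skips[-(i + 1)], x)
            x = blk(x)
        x = ad.conv3d(x, self.params[f"{self.name}.head.w"], self.params[f"{self.name}.head.b"], pad=0)
        if self.softmax_head:
            x = ad.softmax_channels(x)
        return x


class WNet3D:
    """Encoder/decoder pair; see the module docstring."""

    def __init__(self, config: WNetArchitectureConfig | None = None, seed: int = 0):
        self.config = config or WNetArchitectureConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.encoder = _UNet3D(c.in_channels, c.n_classes, c.features, c.groups, rng, True, "enc")
        self.decoder = _UNet3D(c.n_classes, c.rec_channels, c.features, c.groups, rng, False, "dec")
        self.params = {**self.encoder.params, **self.decoder.params}

    # -- plumbing ------------------------------------------------------------
    def parameters(self):
        return list(self.params.values())

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @staticmethod
    def _check_divisible(shape):
        for d in shape[-3:]:
            if d % 8:
                raise ValueError(
                    f"spatial dimensions must be divisible by 8 (3 pooling levels), got {shape}"
                )

    @staticmethod
    def _as_batch(vol):
        vol = np.asarray(vol, dtype=np.float64)
        if vol.ndim == 3:
            vol = vol[None, None]
        elif vol.ndim == 4:
            vol = vol[:, None] if vol.shape[1] != 1 else vol[None]
        if vol.ndim != 5:
            raise ValueError(f"expected (Z,Y,X) or (N,1,Z,Y,X) input, got shape {vol.shape}")
        return vol

    # -- forward passes ------------------------------------------------------
    def encode_tensor(self, x: "ad.Tensor") -> "ad.Tensor":
        self._check_divisible(x.shape)
        return self.encoder(x)

    def encode(self, vol: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (K, Z, Y, X) for a single volume."""
        batch = self._as_batch(vol)
        self._check_divisible(batch.shape)
        return self.encoder(ad.constant(batch)).data[0]

    def decode(self, probs: np.ndarray) -> np.ndarray:
        """Reconstruction (C, Z, Y, X) from class probabilities."""
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim == 4:
            probs = probs[None]
        self._check_divisible(probs.shape)
        return self.decoder(ad.constant(probs)).data[0]


def build_wnet3d(cfg: WNetArchitectureConfig | None = None, seed: int = 0) -> WNet3D:
    """Construct a WNet3D with seeded weight initialization."""
    return WNet3D(cfg, seed=seed)


def combined_loss(ncuts: float, rec: float, w_ncuts: float, w_rec: float) -> float:
    """Weighted sum of the two objectives, minimized in a single backward pass."""
    if w_ncuts <= 0 or w_rec <= 0:
        raise ValueError("loss weights must be positive")
    return w_ncuts * ncuts + w_rec * rec


def _ncuts_node(probs: "ad.Tensor", vols: np.ndarray, aff: AffinityConfig) -> "ad.Tensor":
    """Autodiff node for the batch-mean Soft Normalized Cuts loss."""
    n = probs.data.shape[0]
    losses = np.empty(n)
    grads = np.empty_like(probs.data)
    for i in range(n):
        losses[i], grads[i] = soft_ncuts_loss_and_grad(probs.data[i], vols[i, 0], aff)
    out = np.array(losses.mean())

    def bwd(g):
        if probs.requires_grad:
            probs.accumulate(g * grads / n)

    return ad._node(out, (probs,), bwd)


def train_self_supervised(volumes, cfg: TrainConfig | None = None, arch: WNetArchitectureConfig | None = None):
    """Train a WNet3D on raw volumes only; returns (model, TrainingHistory).

    Volumes are remapped to [0, 100], tiled into cubic patches, and (by
    default) augmented with random flips and 90-degree rotations each epoch.
    The reconstruction target is the remapped patch for MSE, or the patch
    rescaled to [0, 1] for BCE.
    """
    cfg = cfg or TrainConfig()
    volumes = [np.asarray(v) for v in volumes]
    if not volumes:
        raise ValueError("at least one training volume is required")
    patches = []
    for vol in volumes:
        remapped = remap_intensity(vol, 0.0, 100.0)
        patches.extend(p for p, _ in extract_patches(remapped, cfg.patch_size))
    # deterministic=False draws a fresh entropy seed; everything else is
    # identical, so the deterministic path is the tested default
    rng = np.random.default_rng(cfg.seed if cfg.deterministic else None)
    model = WNet3D(arch, seed=int(rng.integers(0, 2**31 - 1)))
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    n = len(patches)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_ncuts, ep_rec, ep_total, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = []
            for i in idx:
                p = patches[i]
                if cfg.augment:
                    p, _ = _augment(p, None, mode="selfsup", seed=rng)
                batch.append(p)
            x = np.stack(batch)[:, None].astype(np.float64)
            xt = ad.constant(x)
            probs = model.encoder(xt)
            ncuts = _ncuts_node(probs, x, cfg.affinity)
            rec_out = model.decoder(probs)
            if cfg.reconstruction_loss == "MSE":
                rec = ad.mean_squared_error(rec_out, x)
            else:
                rec = ad.bce_with_logits(rec_out, x / 100.0)
            total = ad.add(ad.scale(ncuts, cfg.w_ncuts), ad.scale(rec, cfg.w_rec))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}: "
                    f"ncuts={float(ncuts.data)}, rec={float(rec.data)}"
                )
            opt.zero_grad()
            ad.backward(total)
            opt.step()
            ep_ncuts += float(ncuts.data)
            ep_rec += float(rec.data)
            ep_total += float(total.data)
            n_batches += 1
        history.ncuts.append(ep_ncuts / n_batches)
        history.reconstruction.append(ep_rec / n_batches)
        history.total.append(ep_total / n_batches)
    return model, history


def _reflect_pad_to(vol, window):
    """Reflect-pad so every axis is >= window and divisible by 8."""
    pads = []
    for d in vol.shape:
        target = max(d, window)
        target = int(np.ceil(target / 8) * 8)
        pads.append((0, target - d))
    return np.pad(vol, pads, mode="reflect"), pads


def sliding_window_predict(model: WNet3D, vol: np.ndarray, window: int = 64, overlap_fraction: float = 0.25, remap: bool = True) -> np.ndarray:
    """Full-volume semantic probabilities by blended windowed inference.

    Overlapping windows are averaged per voxel and the channel distribution
    renormalized; volumes are reflect-padded to a multiple of 8 (and at least
    the window size) and cropped back.
    """
    if window % 8:
        raise ValueError("window must be divisible by 8")
    vol = np.asarray(vol, dtype=np.float64)
    if remap:
        vol = remap_intensity(vol, 0.0, 100.0).astype(np.float64)
    padded, pads = _reflect_pad_to(vol, window)
    stride = max(1, int(round(window * (1.0 - overlap_fraction))))
    k = model.config.n_classes
    acc = np.zeros((k,) + padded.shape)
    cnt = np.zeros(padded.shape)
    starts = []
    for d in padded.shape:
        s = list(range(0, d - window + 1, stride))
        if s[-1] + window < d:
            s.append(d - window)
        starts.append(s)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + window), slice(y0, y0 + window), slice(x0, x0 + window))
                probs = model.encode(padded[sl])
                acc[(slice(None),) + sl] += probs
                cnt[sl] += 1.0
    acc /= cnt
    acc /= acc.sum(axis=0, keepdims=True)
    crop = tuple(slice(0, d) for d in vol.shape)
    return acc[(slice(None),) + crop]


def select_foreground_class(probs: np.ndarray, vol: np.ndarray) -> int:
    """Pick the encoder class acting as foreground.

    Self-supervised training fixes no class identity, so the foreground is
    chosen post hoc as the class whose probability correlates most positively
    with image intensity.
    """
    vol = np.asarray(vol, dtype=np.float64).ravel()
    vc = vol - vol.mean()
    best, best_corr = 0, -np.inf
    for kk in range(probs.shape[0]):
        p = probs[kk].ravel()
        pc = p - p.mean()
        denom = np.sqrt((pc**2).sum() * (vc**2).sum())
        corr = float((pc * vc).sum() / denom) if denom > 0 else 0.0
        if corr > best_corr:
            best, best_corr = kk, corr
    return best


def save_model(model: WNet3D, path, train_config: TrainConfig | None = None) -> None:
    """Write a self-describing checkpoint (weights + configs) as one archive.

    The archive is a deterministic npz (fixed zip timestamps), so identical
    models produce byte-identical checkpoint files.
    """
    import io
    import zipfile

    meta = {
        "arch": dataclasses.asdict(model.config),
        "train": dataclasses.asdict(train_config) if train_config else None,
    }
    arrays = {"meta": np.array(json.dumps(meta))}
    arrays.update({f"param:{k}": v.data for k, v in model.params.items()})
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asanyarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def load_model(path, expected: WNetArchitectureConfig | None = None) -> WNet3D:
    """Load a checkpoint; raises :class:`CheckpointError` on corruption or mismatch."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            arrays = {k[len("param:") :]: npz[k] for k in npz.files if k.startswith("param:")}
    except CheckpointError:
        raise
    except Exception as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    arch_d = meta.get("arch")
    if arch_d is None:
        raise CheckpointError(f"{path}: missing architecture config")
    arch_d["features"] = tuple(arch_d["features"])
    arch = WNetArchitectureConfig(**arch_d)
    if expected is not None and expected != arch:
        raise CheckpointError(f"{path}: checkpoint architecture {arch} does not match expected {expected}")
    model = WNet3D(arch, seed=0)
    if set(arrays) != set(model.params):
        raise CheckpointError(f"{path}: parameter names do not match the architecture")
    for k, v in arrays.items():
        if model.params[k].data.shape != v.shape:
            raise CheckpointError(f"{path}: shape mismatch for {k}")
        model.params[k].data = v.astype(ad.DTYPE)
    return model
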