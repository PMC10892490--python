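"""Stage-2 encoder-decoder CNN segmenter.

A U-shaped network: four encoder blocks (two same-padded convolutions +
ReLU, dropout, 2x2 max-pool), a bottleneck, and four decoder blocks
(2x2 transposed-convolution upsample, skip concatenation, two
convolutions + ReLU), closed by a 1x1 convolution producing 5-class
per-pixel logits.  Trained with Adam on a masked sparse-categorical
cross-entropy: label-0 (unlabeled) pixels contribute no loss, so sparse
polygon labels can supervise full patches.

Two input modes are supported: Method 1 feeds the six raw bands; Method 2
additionally concatenates the five stage-1 class-probability planes
produced by the gradient-boosted pixel classifier (11 channels), the
stacked-ensemble configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from . import nn
from .tiling import make_grid, stitch

__all__ = [
    "CnnConfig",
    "TrainLog",
    "UNet",
    "UNetModel",
    "build_network",
    "make_patches",
    "train_cnn",
    "run_method",
]

N_CLASSES = 5
_DEPTH = 4  # encoder blocks; patch side must divide by 2**_DEPTH


@dataclass(frozen=True)
class CnnConfig:
    """Hyperparameters of the segmentation network.

    Defaults are the tuned optimum of the mapping workflow: 128x128
    patches with 30% overlap, no input filter, 25% held out, an encoder
    ladder 64-128-256-512 with a 1024-wide bottleneck, 3x3 kernels,
    dropout 0.2, Adam at lr 1e-3, batch 25, 400 epochs.  ``scaled("small")``
    returns a desk-scale preset (16-32-64-128/256 ladder, <=50 epochs)
    for testing.
    """

    patch_size: int = 128
    patch_overlap: float = 0.30
    input_filter: tuple | None = None  # ("lowpass", k) | ("gaussian", k)
    test_fraction: float = 0.25
    ladder: tuple[int, ...] = (64, 128, 256, 512)
    bottleneck: int = 1024
    kernel_size: int = 3
    dropout: float = 0.2
    learning_rate: float = 0.001
    batch_size: int = 25
    epochs: int = 400
    seed: int = 0

    def scaled(self, scale: str) -> "CnnConfig":
        if scale == "small":
            return replace(self, ladder=(16, 32, 64, 128), bottleneck=256,
                           epochs=min(self.epochs, 50))
        if scale == "full":
            return self
        raise ValueError(f"unknown scale {scale!r}; use 'small' or 'full'")

    def to_dict(self) -> dict:
        return {
            "patch_size": self.patch_size,
            "patch_overlap": self.patch_overlap,
            "input_filter": list(self.input_filter) if self.input_filter else None,
            "test_fraction": self.test_fraction,
            "ladder": list(self.ladder),
            "bottleneck": self.bottleneck,
            "kernel_size": self.kernel_size,
            "dropout": self.dropout,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CnnConfig":
        d = dict(d)
        if d.get("input_filter"):
            d["input_filter"] = tuple(d["input_filter"])
        if "ladder" in d:
            d["ladder"] = tuple(d["ladder"])
        return cls(**d)


@dataclass
class TrainLog:
    """Per-epoch training/validation loss and accuracy."""

    epochs: list[dict] = field(default_factory=list)

    def last(self) -> dict:
        return self.epochs[-1] if self.epochs else {}


class _ConvBlock:
    """conv-ReLU, conv-ReLU, dropout."""

    def __init__(self, cin, cout, k, dropout, rng, drop_rng):
        self.layers = [
            nn.Conv2d(cin, cout, k, rng),
            nn.ReLU(),
            nn.Conv2d(cout, cout, k, rng),
            nn.ReLU(),
            nn.Dropout(dropout, drop_rng),
        ]

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class UNet:
    """Symmetric encoder-decoder with skip concatenation."""

    def __init__(self, cfg: CnnConfig, in_channels: int, n_classes: int = N_CLASSES):
        if len(cfg.ladder) != _DEPTH:
            raise ValueError(f"encoder ladder must have {_DEPTH} widths; got {cfg.ladder}")
        ss = np.random.SeedSequence(cfg.seed)
        init_rng, self.drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        k, dr = cfg.kernel_size, cfg.dropout
        self.cfg = cfg
        self.in_channels = in_channels
        self.n_classes = n_classes

        self.enc, self.pools = [], []
        cin = in_channels
        for width in cfg.ladder:
            self.enc.append(_ConvBlock(cin, width, k, dr, init_rng, self.drop_rng))
            self.pools.append(nn.MaxPool2())
            cin = width
        self.bottleneck = _ConvBlock(cin, cfg.bottleneck, k, dr, init_rng, self.drop_rng)

        self.ups, self.dec = [], []
        cin = cfg.bottleneck
        for width in reversed(cfg.ladder):
            self.ups.append(nn.ConvTranspose2x2(cin, width, init_rng))
            self.dec.append(_ConvBlock(2 * width, width, k, dr, init_rng, self.drop_rng))
            cin = width
        self.head = nn.Conv2d(cin, n_classes, 1, init_rng)

    @property
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params
        for p in self.pools:
            out += p.params
        out += self.bottleneck.params
        for up, blk in zip(self.ups, self.dec):
            out += up.params + blk.params
        out += self.head.params
        return out

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        if h % (2**_DEPTH) or w % (2**_DEPTH):
            raise ValueError(
                f"patch size {h}x{w} not divisible by {2**_DEPTH}; "
                f"pad the input or change patch_size"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_widths = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_widths.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, blk, wsk in zip(reversed(self.ups), reversed(self.dec),
                                reversed(self._skip_widths)):
            d = blk.backward(d)
            dskips.append(d[:, :wsk])
            d = up.backward(d[:, wsk:])
        d = self.bottleneck.backward(d)
        # dskips were produced decoder-last first, i.e. in encoder order
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)


def build_network(cfg: CnnConfig, in_channels: int) -> UNet:
    """Construct the segmentation network for a given channel count."""
    if cfg.patch_size % (2**_DEPTH):
        raise ValueError(
            f"patch_size {cfg.patch_size} must be divisible by {2**_DEPTH}"
        )
    return UNet(cfg, in_channels)


def _apply_input_filter(channels: np.ndarray, spec: tuple | None) -> np.ndarray:
    if spec is None:
        return channels
    kind, k = spec
    k = int(k)
    if k not in (3, 5, 7):
        raise ValueError(f"filter size must be 3, 5 or 7; got {k}")
    if kind == "lowpass":
        return np.stack([uniform_filter(c, size=k, mode="reflect") for c in channels])
    if kind == "gaussian":
        # sigma chosen so the k x k kernel captures ~2 sigma per side
        return np.stack(
            [gaussian_filter(c, sigma=k / 4.0, truncate=2.0, mode="reflect")
             for c in channels]
        )
    raise ValueError(f"unknown input filter {kind!r}; use lowpass|gaussian")


def make_patches(
    channels: np.ndarray, labels: np.ndarray, cfg: CnnConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int, int]]]:
    """Cut a channel stack + label raster into overlapping training patches.

    Returns (patches, label_patches, windows); patches are raw crops (the
    optional low-pass/Gaussian pre-filter applied, per-channel
    standardization happens later from training patches only).  Patches
    without a single labeled pixel are dropped.
    """
    channels = np.asarray(channels, dtype=np.float64)
    labels = np.asarray(labels)
    h, w = labels.shape
    p = cfg.patch_size
    if h < p or w < p:
        raise ValueError(
            f"raster {h}x{w} smaller than patch {p}; pad the raster or "
            f"reduce patch_size"
        )
    channels = _apply_input_filter(channels, cfg.input_filter)
    grid = make_grid(h, w, p, cfg.patch_overlap)
    xs, ys, windows = [], [], []
    for (r, c, th, tw) in grid.windows:
        lab = labels[r : r + th, c : c + tw]
        if not (lab > 0).any():
            continue  # no loss support
        xs.append(channels[:, r : r + th, c : c + tw])
        ys.append(lab)
        windows.append((r, c, th, tw))
    if not xs:
        raise ValueError("no patch contains a labeled pixel")
    return np.stack(xs), np.stack(ys), windows


class UNetModel:
    """A trained network plus the frozen per-channel standardization."""

    def __init__(self, net: UNet, mu: np.ndarray, sd: np.ndarray, cfg: CnnConfig,
                 log: TrainLog | None = None):
        self.net = net
        self.mu = mu.reshape(-1, 1, 1)
        self.sd = sd.reshape(-1, 1, 1)
        self.cfg = cfg
        self.log = log

    @property
    def in_channels(self) -> int:
        return self.net.in_channels

    def predict_proba_patches(self, patches: np.ndarray, batch: int = 8) -> np.ndarray:
        """Class probabilities for raw (unstandardized) patches."""
        out = []
        for i in range(0, len(patches), batch):
            x = ((patches[i : i + batch] - self.mu) / self.sd).astype(nn.DTYPE)
            logits = self.net.forward(x, train=False)
            out.append(nn.softmax(logits.astype(np.float64), axis=1))
        return np.concatenate(out)

    def segment(self, channels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Tile a full raster, predict every patch, stitch probabilities.

        Returns (hard_labels, soft_probabilities) for the whole raster.
        """
        channels = _apply_input_filter(
            np.asarray(channels, dtype=np.float64), self.cfg.input_filter
        )
        h, w = channels.shape[1:]
        grid = make_grid(h, w, self.cfg.patch_size, self.cfg.patch_overlap)
        tiles = []
        for (r, c, th, tw) in grid.windows:
            crop = channels[None, :, r : r + th, c : c + tw]
            probs = self.predict_proba_patches(crop)[0]
            tiles.append(((r, c, th, tw), probs))
        return stitch(tiles, grid, n_classes=self.net.n_classes)


def train_cnn(
    patches: np.ndarray, labels: np.ndarray, cfg: CnnConfig
) -> tuple[UNetModel, TrainLog]:
    """Train the segmenter on labeled patches.

    Splits patches into train/validation at the patch level using
    ``cfg.test_fraction``, computes per-channel standardization from the
    training patches only, and minimizes the masked cross-entropy with
    Adam.  Fully deterministic given ``cfg.seed``.
    """
    patches = np.asarray(patches, dtype=np.float64)
    labels = np.asarray(labels)
    if not (labels > 0).any():
        raise ValueError("no labeled pixels in any patch")
    n = len(patches)
    ss = np.random.SeedSequence(cfg.seed)
    split_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    order = split_rng.permutation(n)
    n_val = int(round(cfg.test_fraction * n))
    n_val = min(n_val, n - 1) if n > 1 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]

    mu = patches[tr_idx].mean(axis=(0, 2, 3))
    sd = patches[tr_idx].std(axis=(0, 2, 3))
    sd = np.where(sd == 0, 1.0, sd)
    xs = ((patches - mu.reshape(1, -1, 1, 1)) / sd.reshape(1, -1, 1, 1)).astype(nn.DTYPE)

    net = build_network(cfg, in_channels=patches.shape[1])
    opt = nn.Adam(net.params, lr=cfg.learning_rate)
    log = TrainLog()

    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(tr_idx)
        losses, accs = [], []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward(xs[idx], train=True)
            loss, acc, dlogits = nn.masked_cross_entropy(logits, labels[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(acc)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": float(np.mean(accs)),
        }
        if n_val:
            v_loss, v_acc = _eval_patches(net, xs[val_idx], labels[val_idx])
            entry.update(val_loss=v_loss, val_acc=v_acc)
        log.epochs.append(entry)

    model = UNetModel(net, mu, sd, cfg, log=log)
    model.val_idx = val_idx
    model.train_idx = tr_idx
    return model, log


def _eval_patches(net: UNet, xs: np.ndarray, labels: np.ndarray, batch: int = 8):
    losses, accs, weights = [], [], []
    for i in range(0, len(xs), batch):
        logits = net.forward(xs[i : i + batch], train=False)
        loss, acc, _ = nn.masked_cross_entropy(logits, labels[i : i + batch])
        w = int((labels[i : i + batch] > 0).sum())
        losses.append(loss * w)
        accs.append(acc * w)
        weights.append(w)
    tot = sum(weights)
    return float(sum(losses) / tot), float(sum(accs) / tot)


def save_checkpoint(model: UNetModel, path) -> None:
    """Serialize weights, standardization stats and config to one .npz."""
    import json as _json

    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params)}
    arrays["mu"] = model.mu.ravel()
    arrays["sd"] = model.sd.ravel()
    meta = _json.dumps(
        {"cfg": model.cfg.to_dict(), "in_channels": model.net.in_channels,
         "n_classes": model.net.n_classes}
    )
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> UNetModel:
    import json as _json

    data = np.load(path)
    meta = _json.loads(bytes(data["meta"]).decode())
    cfg = CnnConfig.from_dict(meta["cfg"])
    net = UNet(cfg, in_channels=meta["in_channels"], n_classes=meta["n_classes"])
    for i, p in enumerate(net.params):
        p.value = data[f"p{i}"].astype(nn.DTYPE)
    return UNetModel(net, data["mu"], data["sd"], cfg)


def run_method(
    method: int,
    stack,
    labels: np.ndarray,
    cfg: CnnConfig,
    gbm_model=None,
    stage1_probs: np.ndarray | None = None,
    stage1_onehot: bool = False,
):
    """Run the Method 1 / Method 2 segmentation workflow end to end.

    Method 1 trains on the six band channels alone; Method 2 first runs
    the stage-1 pixel classifier over the full raster and concatenates its
    five class-probability planes (11 channels total) — the stacked
    ensemble.  ``stage1_probs`` may supply precomputed probability planes
    in place of ``gbm_model``.  Returns
    ``(hard_labels, soft_probs, model, report)`` where the report scores
    the stitched prediction on the labeled pixels of held-out validation
    patches.
    """
    from .evaluation import evaluate  # local import to avoid a cycle
    from .gbm import predict_gbm

    channels = stack.as_array()
    if method == 2:
        if stage1_probs is None:
            if gbm_model is None:
                raise ValueError("method 2 requires a fitted stage-1 model or its probabilities")
            _, stage1_probs = predict_gbm(gbm_model, stack)
        if stage1_onehot:
            hard = np.argmax(stage1_probs, axis=0)
            stage1_probs = np.eye(stage1_probs.shape[0])[hard].transpose(2, 0, 1)
        channels = np.concatenate([channels, stage1_probs])
    elif method != 1:
        raise ValueError(f"method must be 1 or 2; got {method}")

    patches, lab_patches, windows = make_patches(channels, labels, cfg)
    model, _ = train_cnn(patches, lab_patches, cfg)
    hard, soft = model.segment(channels)

    # score on labeled pixels of validation patches only
    val_mask = np.zeros(labels.shape, dtype=bool)
    for i in model.val_idx:
        r, c, h, w = windows[i]
        val_mask[r : r + h, c : c + w] = True
    truth_val = np.where(val_mask, labels, 0)
    report = evaluate(truth_val, hard)
    return hard, soft, model, report
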