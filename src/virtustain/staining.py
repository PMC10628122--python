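"""pix2pix-style paired image translation: brightfield in, fluorescence out.

The generator is a U-Net: seven 4x4/stride-2 encoder blocks (LeakyReLU,
filters 64,128,256,512,512,512,512 at the full 256 px working size), a
512-filter bottleneck with ReLU, seven decoder blocks with skip connections
and ReLU (filters 512,512,512,512,256,128,64), and a tanh output layer.  The
discriminator scores (source, target) pairs with five 4x4/stride-2
convolutions (filters 64,128,256,512,512) and a sigmoid output; the
spectrally-normalized variant ("pix2pix++") wraps every discriminator
convolution in spectral normalization, bounding its Lipschitz constant by
one.  For smaller working sizes the trailing 512-filter encoder/decoder
blocks are dropped until the bottleneck reaches 1x1.

Training minimizes ``lambda_L1 * L1(G(x), y) + lambda_GAN * BCE(D(x, G(x)), real)``
with alternating Adam updates; images are scaled from [0, 255] to [-1, 1]
for the networks and generated outputs are rescaled to [0, 1] for DFI
quantification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossConfig",
    "TrainConfig",
    "UNetGenerator",
    "PatchDiscriminator",
    "scale_to_model_range",
    "rescale_output",
    "build_generator",
    "build_discriminator",
    "train",
    "stain",
    "save_checkpoint",
    "load_checkpoint",
    "Pix2PixTranslator",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class GeneratorConfig:
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512, 512)
    bottleneck_filters: int = 512
    decoder_filters: tuple[int, ...] = (512, 512, 512, 512, 256, 128, 64)
    leaky_slope: float = 0.2
    norm: bool = True
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError("encoder and decoder must have the same depth")
        if any(f <= 0 for f in (*self.encoder_filters, *self.decoder_filters,
                                self.bottleneck_filters)):
            raise ValueError("filter counts must be positive")


@dataclass(frozen=True)
class DiscriminatorConfig:
    conv_filters: tuple[int, ...] = (64, 128, 256, 512, 512)
    spectral_norm: bool = False
    leaky: bool = False  # stated architecture uses plain ReLU
    norm: bool = True
    n_power_iterations: int = 1

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.conv_filters):
            raise ValueError("filter counts must be positive")


@dataclass(frozen=True)
class LossConfig:
    lambda_l1: float = 100.0
    lambda_gan: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.lambda_gan < 0:
            raise ValueError("loss weights must be >= 0")
        if self.lambda_l1 == 0 and self.lambda_gan == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale defaults; the published protocol used 256 px patches and
    1000 epochs on GPU hardware."""

    epochs: int = 50
    image_size: int = 32
    batch_size: int = 1
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only at the end
    modality: str = "dsdna"


# ---------------------------------------------------------------------------
# scaling


def scale_to_model_range(patch: np.ndarray) -> np.ndarray:
    """Affine map of an 8-bit image from [0, 255] to [-1, 1] (v/127.5 - 1)."""
    patch = np.asarray(patch)
    if patch.size and (patch.min() < 0 or patch.max() > 255):
        raise ValueError("patch values must lie in [0, 255]")
    return patch.astype(np.float64) / 127.5 - 1.0


def rescale_output(gen: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Affine map of generated values from [-1, 1] back to [0, 1]."""
    gen = np.asarray(gen, dtype=np.float64)
    if gen.size and (gen.min() < -1 - tol or gen.max() > 1 + tol):
        raise ValueError(f"generated values outside [-1, 1] beyond tolerance {tol}")
    return (np.clip(gen, -1.0, 1.0) + 1.0) / 2.0


# ---------------------------------------------------------------------------
# models


def _check_size(image_size: int, depth: int) -> int:
    """Validate the working size and return the usable encoder depth."""
    if image_size < 4 or image_size & (image_size - 1):
        raise ValueError(
            f"image_size must be a power of two >= 16, got {image_size} "
            "(minimal valid size 16)"
        )
    max_depth = int(np.log2(image_size)) - 1  # bottleneck stride halves once more
    return min(depth, max_depth)


class UNetGenerator:
    """Encoder/bottleneck/decoder U-Net with per-level skip connections."""

    def __init__(self, cfg: GeneratorConfig, image_size: int, rng: np.random.Generator):
        depth = _check_size(image_size, len(cfg.encoder_filters))
        enc_f = cfg.encoder_filters[:depth]
        dec_f = cfg.decoder_filters[-depth:]
        self.cfg = cfg
        self.image_size = image_size
        self.enc_filters = enc_f
        self.dec_filters = dec_f

        self.enc: list[nn.Sequential] = []
        cin = 1
        for i, f in enumerate(enc_f):
            layers: list[nn.Layer] = [nn.Conv2d(cin, f, rng=rng)]
            if cfg.norm and i > 0:
                layers.append(nn.BatchNorm2d(f))
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
            self.enc.append(nn.Sequential(*layers))
            cin = f
        self.bottleneck = nn.Sequential(
            nn.Conv2d(cin, cfg.bottleneck_filters, rng=rng), nn.ReLU()
        )
        self.dec: list[nn.Sequential] = []
        cin = cfg.bottleneck_filters
        for j, f in enumerate(dec_f):
            layers = [nn.ConvTranspose2d(cin, f, rng=rng)]
            if cfg.norm:
                layers.append(nn.BatchNorm2d(f))
            if cfg.dropout > 0 and j < 3:
                layers.append(nn.Dropout(cfg.dropout, rng=rng))
            layers.append(nn.ReLU())
            self.dec.append(nn.Sequential(*layers))
            cin = f + enc_f[depth - 1 - j]  # concat with the mirrored skip
        self.final = nn.Sequential(nn.ConvTranspose2d(cin, 1, rng=rng), nn.Tanh())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h, train=train)
            skips.append(h)
        h = self.bottleneck.forward(h, train=train)
        for j, blk in enumerate(self.dec):
            h = blk.forward(h, train=train)
            h = np.concatenate([h, skips[len(self.enc) - 1 - j]], axis=1)
        return self.final.forward(h, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.final.backward(gout)
        n_enc = len(self.enc)
        enc_grads: list[np.ndarray | None] = [None] * n_enc
        for j in range(len(self.dec) - 1, -1, -1):
            dec_ch = self.dec_filters[j]
            enc_grads[n_enc - 1 - j] = g[:, dec_ch:]
            g = self.dec[j].backward(g[:, :dec_ch])
        g = self.bottleneck.backward(g)
        for i in range(n_enc - 1, -1, -1):
            g = g + enc_grads[i]
            g = self.enc[i].backward(g)
        return g

    def params(self) -> list[nn.Param]:
        out = []
        for blk in (*self.enc, self.bottleneck, *self.dec, self.final):
            out.extend(blk.params())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the model: parameters plus batch-norm running
        statistics, in a stable order (used for checkpointing)."""
        out = [p.value for p in self.params()]
        for blk in (*self.enc, self.bottleneck, *self.dec, self.final):
            for layer in blk.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    out.append(layer.running_mean)
                    out.append(layer.running_var)
        return out

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class PatchDiscriminator:
    """Strided conv stack scoring concatenated (source, target) pairs.

    Produces a spatial sigmoid score map (1x1 at the minimal working size);
    ``forward_logits`` exposes the pre-sigmoid map used for the numerically
    stable training loss.
    """

    def __init__(self, cfg: DiscriminatorConfig, image_size: int, rng: np.random.Generator):
        if image_size < 2 ** len(cfg.conv_filters):
            raise ValueError(
                f"image_size {image_size} too small for {len(cfg.conv_filters)} "
                f"strided layers (needs >= {2 ** len(cfg.conv_filters)})"
            )
        self.cfg = cfg
        conv_cls = nn.SpectralNormConv2d if cfg.spectral_norm else nn.Conv2d
        kw = dict(rng=rng)
        if cfg.spectral_norm:
            kw["n_power_iterations"] = cfg.n_power_iterations
        act = (lambda: nn.LeakyReLU(0.2)) if cfg.leaky else nn.ReLU
        layers: list[nn.Layer] = []
        cin = 2
        for i, f in enumerate(cfg.conv_filters):
            layers.append(conv_cls(cin, f, **kw))
            if cfg.norm and i > 0:
                layers.append(nn.BatchNorm2d(f))
            layers.append(act())
            cin = f
        layers.append(conv_cls(cin, 1, k=1, stride=1, pad=0, **kw))
        self.body = nn.Sequential(*layers)
        self.sigmoid = nn.Sigmoid()

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.body.forward(x, train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.sigmoid.forward(self.forward_logits(x, train=train))

    def backward_logits(self, gz: np.ndarray) -> np.ndarray:
        return self.body.backward(gz)

    def params(self) -> list[nn.Param]:
        return self.body.params()

    def conv_layers(self) -> list[nn.Conv2d]:
        return [l for l in self.body.layers if isinstance(l, nn.Conv2d)]

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


def build_generator(cfg: GeneratorConfig | None = None, image_size: int = 256,
                    seed: int = 0) -> UNetGenerator:
    return UNetGenerator(cfg or GeneratorConfig(), image_size, np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig | None = None, image_size: int = 256,
                        seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(cfg or DiscriminatorConfig(), image_size, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training


def _as_nchw(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches)
    if patches.ndim == 3:
        patches = patches[:, None]
    if patches.ndim != 4 or patches.shape[1] != 1:
        raise ValueError(f"expected (n, H, W) or (n, 1, H, W) patches, got {patches.shape}")
    return patches


def train(
    src_patches: np.ndarray,
    tgt_patches: np.ndarray,
    gcfg: GeneratorConfig | None = None,
    dcfg: DiscriminatorConfig | None = None,
    lcfg: LossConfig | None = None,
    tcfg: TrainConfig | None = None,
    checkpoint_path: str | Path | None = None,
) -> tuple[UNetGenerator, pd.DataFrame]:
    """Train a generator on paired (brightfield, fluorescence) 8-bit patches.

    Returns the trained generator and a per-epoch loss log with columns
    ``epoch, d_loss, g_gan_loss, g_l1_loss, total``.  Fully seeded; with
    ``lambda_gan == 0`` the discriminator is skipped entirely (pure L1
    regression).  Aborts on NaN loss, naming the epoch and learning rate.
    """
    gcfg = gcfg or GeneratorConfig()
    dcfg = dcfg or DiscriminatorConfig()
    lcfg = lcfg or LossConfig()
    tcfg = tcfg or TrainConfig()

    src = _as_nchw(src_patches)
    tgt = _as_nchw(tgt_patches)
    if src.shape != tgt.shape:
        raise ValueError(f"source/target shapes differ: {src.shape} vs {tgt.shape}")
    n = src.shape[0]
    if n < 1:
        raise ValueError("need at least one paired sample")
    if src.shape[2] != tcfg.image_size or src.shape[3] != tcfg.image_size:
        raise ValueError(
            f"patches are {src.shape[2]}x{src.shape[3]} but image_size={tcfg.image_size}"
        )

    rng = np.random.default_rng(tcfg.seed)
    gen = UNetGenerator(gcfg, tcfg.image_size, rng)
    g_opt = nn.Adam(gen.params(), lr=tcfg.lr, beta1=tcfg.beta1, beta2=tcfg.beta2)
    use_disc = lcfg.lambda_gan > 0
    if use_disc:
        disc = PatchDiscriminator(dcfg, tcfg.image_size, rng)
        d_opt = nn.Adam(disc.params(), lr=tcfg.lr, beta1=tcfg.beta1, beta2=tcfg.beta2)

    src_s = scale_to_model_range(src).astype(nn.DTYPE)
    tgt_s = scale_to_model_range(tgt).astype(nn.DTYPE)

    log_rows = []
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        d_losses, gan_losses, l1_losses = [], [], []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = src_s[idx], tgt_s[idx]
            fake = gen.forward(xb, train=True)

            d_loss = 0.0
            if use_disc:
                d_opt.zero_grad()
                z_real = disc.forward_logits(np.concatenate([xb, yb], axis=1))
                loss_r, dz_r = nn.bce_with_logits(z_real, 1.0)
                disc.backward_logits(0.5 * dz_r)
                z_fake = disc.forward_logits(np.concatenate([xb, fake], axis=1))
                loss_f, dz_f = nn.bce_with_logits(z_fake, 0.0)
                disc.backward_logits(0.5 * dz_f)
                d_loss = 0.5 * (loss_r + loss_f)
                if not np.isfinite(d_loss):
                    raise RuntimeError(
                        f"NaN/inf discriminator loss at epoch {epoch} (lr={tcfg.lr}); "
                        "training aborted"
                    )
                d_opt.step()

            g_opt.zero_grad()
            l1 = float(np.mean(np.abs(fake - yb)))
            if not np.isfinite(l1):
                raise RuntimeError(
                    f"NaN/inf generator loss at epoch {epoch} (lr={tcfg.lr}); "
                    "training aborted"
                )
            g_fake = (lcfg.lambda_l1 / fake.size) * np.sign(fake - yb).astype(nn.DTYPE)
            g_gan = 0.0
            if use_disc:
                d_opt.zero_grad()  # discard discriminator grads from this pass
                z = disc.forward_logits(np.concatenate([xb, fake], axis=1))
                g_gan, dz = nn.bce_with_logits(z, 1.0)
                gin = disc.backward_logits(dz)
                d_opt.zero_grad()
                g_fake = g_fake + lcfg.lambda_gan * gin[:, 1:2]
            gen.backward(g_fake)
            g_opt.step()

            d_losses.append(d_loss)
            gan_losses.append(g_gan)
            l1_losses.append(l1)

        row = dict(
            epoch=epoch,
            d_loss=float(np.mean(d_losses)),
            g_gan_loss=float(np.mean(gan_losses)),
            g_l1_loss=float(np.mean(l1_losses)),
        )
        row["total"] = lcfg.lambda_gan * row["g_gan_loss"] + lcfg.lambda_l1 * row["g_l1_loss"]
        log_rows.append(row)
        if not np.isfinite(row["total"]) or (use_disc and not np.isfinite(row["d_loss"])):
            raise RuntimeError(
                f"NaN/inf loss at epoch {epoch} (lr={tcfg.lr}); training aborted"
            )
        logger.info(
            "epoch %d/%d d=%.4f gan=%.4f l1=%.4f", epoch, tcfg.epochs,
            row["d_loss"], row["g_gan_loss"], row["g_l1_loss"]
        )
        if checkpoint_path and tcfg.checkpoint_every and epoch % tcfg.checkpoint_every == 0:
            save_checkpoint(gen, checkpoint_path, gcfg=gcfg, tcfg=tcfg, epoch=epoch)

    if checkpoint_path:
        save_checkpoint(gen, checkpoint_path, gcfg=gcfg, tcfg=tcfg, epoch=tcfg.epochs)
    return gen, pd.DataFrame(log_rows)


def stain(generator: UNetGenerator, bfi_patches: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Apply a trained generator to 8-bit brightfield patches; returns
    fluorescence patches in [0, 1], shape (n, H, W).  Inference is
    deterministic (no dropout noise)."""
    x = _as_nchw(bfi_patches)
    if x.shape[2] != generator.image_size or x.shape[3] != generator.image_size:
        raise ValueError(
            f"patches are {x.shape[2]}x{x.shape[3]} but the generator was built "
            f"for {generator.image_size}"
        )
    outs = []
    for start in range(0, x.shape[0], batch_size):
        xb = scale_to_model_range(x[start : start + batch_size]).astype(nn.DTYPE)
        outs.append(rescale_output(generator.forward(xb, train=False)))
    return np.concatenate(outs, axis=0)[:, 0]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(generator: UNetGenerator, path: str | Path,
                    gcfg: GeneratorConfig | None = None,
                    tcfg: TrainConfig | None = None, epoch: int | None = None) -> Path:
    """Serialize generator weights (npz) with a JSON sidecar manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": a for i, a in enumerate(generator.state_arrays())}
    np.savez(path, **arrays)
    manifest = dict(
        image_size=generator.image_size,
        generator=asdict(gcfg or generator.cfg),
        train=asdict(tcfg) if tcfg else None,
        epoch=epoch,
        n_params=len(arrays),
    )
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))
    return path


def load_checkpoint(path: str | Path) -> UNetGenerator:
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".json").read_text())
    gdict = manifest["generator"]
    gcfg = GeneratorConfig(
        encoder_filters=tuple(gdict["encoder_filters"]),
        bottleneck_filters=gdict["bottleneck_filters"],
        decoder_filters=tuple(gdict["decoder_filters"]),
        leaky_slope=gdict["leaky_slope"],
        norm=gdict["norm"],
        dropout=gdict["dropout"],
    )
    gen = UNetGenerator(gcfg, manifest["image_size"], np.random.default_rng(0))
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    for i, arr in enumerate(gen.state_arrays()):
        arr[...] = data[f"param_{i}"]
    return gen


# ---------------------------------------------------------------------------
# estimator


class Pix2PixTranslator(BaseEstimator):
    """scikit-learn style paired image-to-image translator.

    ``fit(X, y)`` trains the GAN on 8-bit patch stacks ``(n, H, W)`` (X:
    brightfield, y: fluorescence targets, typically denoised); ``predict(X)``
    returns generated fluorescence in [0, 1].  ``arch='pix2pixpp'`` enables
    spectral normalization in the discriminator.
    """

    def __init__(
        self,
        arch: str = "pix2pix",
        epochs: int = 50,
        image_size: int = 32,
        batch_size: int = 1,
        lambda_l1: float = 100.0,
        lambda_gan: float = 1.0,
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        norm: bool = True,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        self.arch = arch
        self.epochs = epochs
        self.image_size = image_size
        self.batch_size = batch_size
        self.lambda_l1 = lambda_l1
        self.lambda_gan = lambda_gan
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.norm = norm
        self.dropout = dropout
        self.seed = seed

    def fit(self, X, y):
        if self.arch not in ("pix2pix", "pix2pixpp"):
            raise ValueError(f"arch must be 'pix2pix' or 'pix2pixpp', got {self.arch!r}")
        gcfg = GeneratorConfig(norm=self.norm, dropout=self.dropout)
        dcfg = DiscriminatorConfig(spectral_norm=(self.arch == "pix2pixpp"), norm=self.norm)
        lcfg = LossConfig(lambda_l1=self.lambda_l1, lambda_gan=self.lambda_gan)
        tcfg = TrainConfig(
            epochs=self.epochs,
            image_size=self.image_size,
            batch_size=self.batch_size,
            lr=self.lr,
            beta1=self.beta1,
            beta2=self.beta2,
            seed=self.seed,
        )
        self.generator_, self.history_ = train(X, y, gcfg, dcfg, lcfg, tcfg)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "generator_")
        return stain(self.generator_, X)
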