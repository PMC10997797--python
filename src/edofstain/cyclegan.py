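"""Two-step semi-supervised cycle-consistent virtual H&E staining.

Two generators map between the two-channel fluorescence domain X and the
RGB H&E-appearance domain Y (G: X→Y, F: Y→X); patch discriminators D_X and
D_Y score realism; the objective combines least-squares adversarial terms
with an L1 cycle-consistency penalty shared by both generators.

Training is semi-supervised in two steps: step 1 replaces the H&E domain Y
with Beer-Lambert false-colored renderings X̂ of the very same fluorescence
images, so the generators learn the color mapping on exactly co-registered
features; step 2 resumes from those weights on genuinely unpaired (X, Y)
data.  Skipping step 1 is possible only via an explicit flag — pretraining
on the paired surrogate is what anchors nuclear/contextual features and
prevents the unpaired objective from hallucinating structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, no_grad
from .beer_lambert import StainParams, bl_render
from .images import RGBImage, TwoChannelImage

__all__ = ["GANConfig", "StainBundle", "lsgan_generator_loss",
           "lsgan_discriminator_loss", "cycle_loss", "total_generator_loss",
           "train_semisupervised", "stain"]


@dataclass
class GANConfig:
    """Architecture and schedule.  The published profile uses 9-residual-
    block generators, 70x70-receptive-field patch discriminators, instance
    normalization, 512px patches, 5 epochs at learning rate 2e-4."""

    n_blocks: int = 9
    base_width: int = 64
    n_down: int = 2              # stride-2 stages in the generators
    disc_layers: int = 3         # 3 -> 70x70 receptive field
    patch: int = 512
    epochs: int = 5
    lr: float = 2e-4
    cycle_weight: float = 10.0   # λ1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_weight < 0:
            raise ValueError("cycle_weight must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def toy(cls, **kw) -> "GANConfig":
        """Desk-scale profile: 3-block generators, 34x34-receptive-field
        discriminators, 64px patches, a faster learning rate for the small
        nets; the epoch count keeps the published schedule (5)."""
        defaults = dict(n_blocks=3, base_width=8, disc_layers=2, patch=64,
                        lr=1e-3)
        defaults.update(kw)
        return cls(**defaults)


# --------------------------------------------------------------------------- #
# losses
# --------------------------------------------------------------------------- #

def lsgan_generator_loss(d_scores_on_fake) -> Tensor:
    """Least-squares adversarial loss for a generator: mean (D(fake) − 1)².

    Zero iff the discriminator scores every fake patch exactly 1.
    """
    s = as_tensor(d_scores_on_fake)
    if s.size == 0:
        raise ValueError("empty score batch")
    d = s - 1.0
    return (d * d).mean()


def lsgan_discriminator_loss(d_on_fake, d_on_real) -> Tensor:
    """Least-squares discriminator loss: mean D(fake)² + mean (D(real) − 1)²."""
    f = as_tensor(d_on_fake)
    r = as_tensor(d_on_real)
    if f.size == 0 or r.size == 0:
        raise ValueError("empty score batch")
    rd = r - 1.0
    return (f * f).mean() + (rd * rd).mean()


def cycle_loss(x_batch, y_batch, G, F) -> Tensor:
    """Cycle-consistency penalty: mean |F(G(x)) − x|₁ + mean |G(F(y)) − y|₁."""
    x = as_tensor(x_batch)
    y = as_tensor(y_batch)
    return (F(G(x)) - x).abs().mean() + (G(F(y)) - y).abs().mean()


def total_generator_loss(gan_term, cycle_term, cycle_weight: float) -> Tensor:
    """Weighted total: adversarial term + λ1 · (shared) cycle term."""
    if cycle_weight < 0:
        raise ValueError("cycle_weight must be >= 0")
    return as_tensor(gan_term) + as_tensor(cycle_term) * cycle_weight


# --------------------------------------------------------------------------- #
# training
# --------------------------------------------------------------------------- #

@dataclass
class StainBundle:
    """Trained generators/discriminators plus configuration and history."""

    G: nn.ResnetGenerator        # fluorescence (2ch) -> H&E RGB
    F: nn.ResnetGenerator        # H&E RGB -> fluorescence
    DX: nn.PatchDiscriminator
    DY: nn.PatchDiscriminator
    cfg: GANConfig
    bl_params: StainParams
    step: str = "init"           # init | step1 | step2
    history: dict = field(default_factory=lambda: {"gen": [], "disc": []})

    @property
    def trained(self) -> bool:
        return self.step != "init"


def _build_bundle(cfg: GANConfig, bl_params: StainParams) -> StainBundle:
    rng = np.random.default_rng(cfg.seed)
    return StainBundle(
        G=nn.ResnetGenerator(2, 3, n_blocks=cfg.n_blocks, base=cfg.base_width,
                             n_down=cfg.n_down, rng=rng),
        F=nn.ResnetGenerator(3, 2, n_blocks=cfg.n_blocks, base=cfg.base_width,
                             n_down=cfg.n_down, rng=rng),
        DX=nn.PatchDiscriminator(2, base=cfg.base_width, n_layers=cfg.disc_layers, rng=rng),
        DY=nn.PatchDiscriminator(3, base=cfg.base_width, n_layers=cfg.disc_layers, rng=rng),
        cfg=cfg, bl_params=bl_params)


def _as_batches(images, channels: int, patch: int) -> list[np.ndarray]:
    out = []
    for im in images:
        arr = im.values if hasattr(im, "values") else np.asarray(im, dtype=float)
        if arr.shape != (channels, patch, patch):
            raise ValueError(
                f"expected ({channels}, {patch}, {patch}) images, got {arr.shape}")
        out.append(arr[None])  # batch of 1
    return out


def _train_phase(bundle: StainBundle, x_list, y_list, epochs: int,
                 rng: np.random.Generator,
                 opt_gen: nn.Adam, opt_dx: nn.Adam, opt_dy: nn.Adam) -> None:
    cfg = bundle.cfg
    n_iter = max(len(x_list), len(y_list))
    for _ in range(epochs):
        xi = rng.permutation(len(x_list))
        yi = rng.permutation(len(y_list))
        for it in range(n_iter):
            x = Tensor(x_list[xi[it % len(x_list)]])
            y = Tensor(y_list[yi[it % len(y_list)]])
            # generator update (both generators share the cycle term)
            fake_y = bundle.G(x)
            fake_x = bundle.F(y)
            adv = (lsgan_generator_loss(bundle.DY(fake_y))
                   + lsgan_generator_loss(bundle.DX(fake_x)))
            cyc = ((bundle.F(fake_y) - x).abs().mean()
                   + (bundle.G(fake_x) - y).abs().mean())
            gen_loss = total_generator_loss(adv, cyc, cfg.cycle_weight)
            opt_gen.zero_grad()
            gen_loss.backward()
            opt_gen.step()
            # discriminator updates on detached fakes
            fy = Tensor(fake_y.data)
            fx = Tensor(fake_x.data)
            dy_loss = lsgan_discriminator_loss(bundle.DY(fy), bundle.DY(y))
            opt_dy.zero_grad()
            dy_loss.backward()
            opt_dy.step()
            dx_loss = lsgan_discriminator_loss(bundle.DX(fx), bundle.DX(x))
            opt_dx.zero_grad()
            dx_loss.backward()
            opt_dx.step()
            if not np.isfinite(gen_loss.item()):
                raise RuntimeError("GAN training diverged (non-finite loss)")
            bundle.history["gen"].append(gen_loss.item())
            bundle.history["disc"].append(dy_loss.item() + dx_loss.item())


def train_semisupervised(x_images, y_images, bl_params: StainParams | None = None,
                         cfg: GANConfig | None = None,
                         skip_step1: bool = False) -> StainBundle:
    """Train the two-step semi-supervised stain-transfer model.

    ``x_images``: two-channel fluorescence patches.  ``y_images``: RGB H&E
    patches for step 2 (may be None/empty to stop after step 1).  Step 1
    trains the full cycle objective with Y replaced by the Beer-Lambert
    renderings of ``x_images`` (exactly paired by construction); step 2
    resumes all networks, including discriminators, on unpaired (X, Y).
    Deterministic for a fixed seed on one device.
    """
    cfg = cfg or GANConfig()
    bl_params = bl_params or StainParams()
    if not x_images:
        raise ValueError("x_images must be non-empty")
    if skip_step1 and not y_images:
        raise ValueError("skipping step 1 requires step-2 H&E images")
    x_list = _as_batches(x_images, 2, cfg.patch)
    bundle = _build_bundle(cfg, bl_params)
    opt_gen = nn.Adam(bundle.G.parameters() + bundle.F.parameters(), lr=cfg.lr)
    opt_dx = nn.Adam(bundle.DX.parameters(), lr=cfg.lr)
    opt_dy = nn.Adam(bundle.DY.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    if not skip_step1:
        x_hat = [bl_render(x[0], bl_params).values[None] for x in x_list]
        _train_phase(bundle, x_list, x_hat, cfg.epochs, rng, opt_gen, opt_dx, opt_dy)
        bundle.step = "step1"
    if y_images:
        y_list = _as_batches(y_images, 3, cfg.patch)
        _train_phase(bundle, x_list, y_list, cfg.epochs, rng, opt_gen, opt_dx, opt_dy)
        bundle.step = "step2"
    return bundle


# --------------------------------------------------------------------------- #
# inference
# --------------------------------------------------------------------------- #

def _infer_patch(bundle: StainBundle, arr: np.ndarray) -> np.ndarray:
    # reflect-pad to a multiple of 4 (two stride-2 stages)
    h, w = arr.shape[1:]
    ph = (-h) % 4
    pw = (-w) % 4
    padded = np.pad(arr, ((0, 0), (0, ph), (0, pw)), mode="reflect") if ph or pw else arr
    with no_grad():
        out = bundle.G(Tensor(padded[None])).data[0]
    return out[:, :h, :w]


def stain(x, bundle: StainBundle) -> RGBImage:
    """Map a two-channel fluorescence image to H&E appearance with G.

    Deterministic; images larger than the training patch are processed in
    overlapping tiles blended with a linear feather.
    """
    if not bundle.trained:
        raise ValueError("stain called with an untrained bundle")
    arr = x.values if isinstance(x, TwoChannelImage) else np.asarray(x, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError("expected a (2, H, W) fluorescence image")
    tile = bundle.cfg.patch
    h, w = arr.shape[1:]
    if h <= tile and w <= tile:
        return RGBImage(values=np.clip(_infer_patch(bundle, arr), 0.0, 1.0))
    overlap = tile // 4
    step = tile - overlap
    acc = np.zeros((3, h, w))
    weight = np.zeros((h, w))
    ramp = np.minimum(np.arange(1, tile + 1), overlap) / overlap
    feather = np.minimum.outer(np.minimum(ramp, ramp[::-1]),
                               np.minimum(ramp, ramp[::-1]))
    for top in range(0, max(h - overlap, 1), step):
        for left in range(0, max(w - overlap, 1), step):
            b = min(top + tile, h)
            r = min(left + tile, w)
            t0, l0 = max(b - tile, 0), max(r - tile, 0)
            out = _infer_patch(bundle, arr[:, t0:b, l0:r])
            fw = feather[:b - t0, :r - l0]
            acc[:, t0:b, l0:r] += out * fw
            weight[t0:b, l0:r] += fw
    return RGBImage(values=np.clip(acc / np.maximum(weight, 1e-12), 0.0, 1.0))
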