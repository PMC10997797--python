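"""Stain-transfer objective: exact hand-computed loss identities, training
contracts of the two-step semi-supervised schedule, and inference checks."""

import numpy as np
import pytest

from edofstain.autograd import Tensor, default_dtype
from edofstain.beer_lambert import bl_render
from edofstain.cyclegan import (GANConfig, _build_bundle, cycle_loss,
                                lsgan_discriminator_loss, lsgan_generator_loss,
                                stain, total_generator_loss, train_semisupervised)
from edofstain.synthdata import PhantomSpec, gen_nuclei_scene


# --------------------------------------------------------------------------- #
# loss identities (hand arithmetic)
# --------------------------------------------------------------------------- #

@pytest.mark.parametrize("scores,expected", [
    ([1.0, 1.0, 1.0], 0.0),          # perfect fooling
    ([0.0], 1.0),                    # (0-1)²
    ([0.3, 0.7], 0.29),              # (0.49 + 0.09)/2
])
def test_generator_loss_hand_values(scores, expected):
    assert lsgan_generator_loss(np.array(scores)).item() == pytest.approx(expected)


@pytest.mark.parametrize("fake,real,expected", [
    ([0.0], [1.0], 0.0),             # perfect discrimination
    ([0.3], [0.8], 0.13),            # 0.09 + 0.04
    ([0.5], [0.5], 0.5),             # 0.25 + 0.25
])
def test_discriminator_loss_hand_values(fake, real, expected):
    loss = lsgan_discriminator_loss(np.array(fake), np.array(real))
    assert loss.item() == pytest.approx(expected)


def test_loss_empty_batch_rejected():
    with pytest.raises(ValueError):
        lsgan_generator_loss(np.empty(0))
    with pytest.raises(ValueError):
        lsgan_discriminator_loss(np.empty(0), np.array([1.0]))


def test_cycle_loss_identities():
    rng = np.random.default_rng(0)
    x = rng.uniform(size=(2, 1, 4, 4))
    y = rng.uniform(size=(2, 1, 4, 4))
    ident = lambda t: t
    assert cycle_loss(x, y, ident, ident).item() == pytest.approx(0.0)

    # F(G(x)) = x + 0.1 everywhere while G(F(y)) = y: only the forward
    # cycle term contributes -> 0.1.  (cycle_loss evaluates F(G(x)) before
    # G(F(y)), so a one-shot offset isolates the first term.)
    class OneShotPlus:
        def __init__(self):
            self.calls = 0

        def __call__(self, t):
            self.calls += 1
            return t + 0.1 if self.calls == 1 else t

    assert cycle_loss(x, y, ident, OneShotPlus()).item() == pytest.approx(0.1)
    # with plain functions both directions contribute: 0.1 + 0.1
    plus = lambda t: t + 0.1
    assert cycle_loss(x, y, ident, plus).item() == pytest.approx(0.2)
    # invariant to batch permutation
    xp = x[::-1].copy()
    yp = y[::-1].copy()
    noisy = lambda t: t * 0.7 + 0.05
    assert cycle_loss(x, y, noisy, noisy).item() == pytest.approx(
        cycle_loss(xp, yp, noisy, noisy).item())


def test_total_loss_weighting_and_cancellation():
    assert total_generator_loss(0.29, 0.1, 10.0).item() == pytest.approx(1.29)
    assert total_generator_loss(0.7, 0.5, 0.0).item() == pytest.approx(0.7)
    # shared cycle term cancels in the difference of the two totals
    g_gan, f_gan, cyc, lam = 0.4, 0.9, 0.33, 7.0
    diff = (total_generator_loss(g_gan, cyc, lam).item()
            - total_generator_loss(f_gan, cyc, lam).item())
    assert diff == pytest.approx(g_gan - f_gan)
    with pytest.raises(ValueError):
        total_generator_loss(0.1, 0.1, -1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        GANConfig(cycle_weight=-1.0)
    with pytest.raises(ValueError):
        GANConfig(epochs=0)
    assert GANConfig().epochs == 5
    assert GANConfig().lr == 2e-4
    assert GANConfig().n_blocks == 9


# --------------------------------------------------------------------------- #
# training and inference contracts
# --------------------------------------------------------------------------- #

def test_training_requires_data_and_step1():
    with pytest.raises(ValueError, match="non-empty"):
        train_semisupervised([], None)
    with pytest.raises(ValueError, match="step"):
        train_semisupervised([np.zeros((2, 64, 64))], None, skip_step1=True)


def test_untrained_bundle_rejected():
    bundle = _build_bundle(GANConfig.toy(seed=0), None or __import__(
        "edofstain.beer_lambert", fromlist=["StainParams"]).StainParams())
    with pytest.raises(ValueError, match="untrained"):
        stain(np.zeros((2, 64, 64)), bundle)


def test_step1_learns_color_mapping(toy_gan_step1):
    """After step-1 training on the paired Beer-Lambert surrogate domain,
    G(x) is closer to the Beer-Lambert rendering of x than at
    initialization."""
    bundle = toy_gan_step1
    assert bundle.step == "step1"
    init = _build_bundle(bundle.cfg, bundle.bl_params)
    init.step = "step1"  # enable inference on the untrained weights
    maes_tr, maes_init = [], []
    for i in range(3):
        scene, _ = gen_nuclei_scene(PhantomSpec(size=64, n_nuclei=6,
                                                nucleus_radius=4.5, seed=300 + i))
        target = bl_render(scene, bundle.bl_params).values
        maes_tr.append(np.abs(stain(scene, bundle).values - target).mean())
        maes_init.append(np.abs(stain(scene, init).values - target).mean())
    assert np.mean(maes_tr) < np.mean(maes_init)


def _segment_centroids(img_rgb: np.ndarray) -> list:
    import scipy.ndimage as ndi
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.measure import regionprops
    from skimage.segmentation import watershed
    from edofstain.beer_lambert import StainParams
    from edofstain.metrics import _nuclear_signal
    sig = ndi.gaussian_filter(_nuclear_signal(img_rgb, StainParams()), 1.0)
    if sig.max() <= 1e-6 or np.ptp(sig) < 1e-6:
        return []
    mask = sig > threshold_otsu(sig)
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=5, labels=mask,
                           exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros_like(sig, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    return [r.centroid for r in regionprops(labels) if r.area >= 9]


def test_step1_preserves_nuclei_locations(toy_gan_step1):
    """Nuclei segmented in G(x) match the nuclei of the Beer-Lambert
    rendering one-to-one (within one nuclear radius) for >= 90% of
    nuclei, across held-out phantoms."""
    matched, total = 0, 0
    for i in range(4):
        scene, _ = gen_nuclei_scene(PhantomSpec(size=64, n_nuclei=6,
                                                nucleus_radius=4.5, seed=400 + i))
        c_gan = _segment_centroids(stain(scene, toy_gan_step1).values)
        c_bl = _segment_centroids(bl_render(scene).values)
        used = set()
        for cb in c_bl:
            best, bd = None, np.inf
            for j, cg in enumerate(c_gan):
                if j in used:
                    continue
                d = np.hypot(cb[0] - cg[0], cb[1] - cg[1])
                if d < bd:
                    bd, best = d, j
            if best is not None and bd <= 4.5:
                used.add(best)
                matched += 1
        total += len(c_bl)
    assert total > 0
    assert matched / total >= 0.90


def test_stain_contract_shape_determinism_tiling(toy_gan_bundle):
    scene, _ = gen_nuclei_scene(PhantomSpec(size=96, n_nuclei=8, seed=31))
    out = stain(scene, toy_gan_bundle)
    assert out.values.shape == (3, 96, 96)
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0
    again = stain(scene, toy_gan_bundle)
    assert np.array_equal(out.values, again.values)


def test_seed_determinism_of_training(train_scenes):
    xs = [gen_nuclei_scene(PhantomSpec(size=64, n_nuclei=5, seed=40 + i))[0]
          for i in range(3)]
    cfg = GANConfig.toy(epochs=1, seed=7)
    with default_dtype(np.float32):
        a = train_semisupervised(xs, None, cfg=cfg)
        b = train_semisupervised(xs, None, cfg=cfg)
    assert np.allclose(a.history["gen"], b.history["gen"])
    for pa, pb in zip(a.G.parameters(), b.G.parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_nuclei_preserved_through_gan_staining(toy_gan_bundle):
    """Closed-loop phantom check: aggregate nuclear count of the GAN-stained
    images agrees with the phantoms' ground truth within 5%."""
    from edofstain.metrics import count_nuclei
    total_truth, total_gan = 0, 0
    for i in range(6):
        scene, nuclei = gen_nuclei_scene(PhantomSpec(size=64, n_nuclei=6,
                                                     nucleus_radius=4.5,
                                                     seed=400 + i))
        rgb = stain(scene, toy_gan_bundle)
        n, _ = count_nuclei(rgb.values)
        total_truth += len(nuclei)
        total_gan += n
    assert abs(total_gan - total_truth) / total_truth <= 0.05
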