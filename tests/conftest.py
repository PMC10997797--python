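"""Shared fixtures.

Heavy artifacts (the toy-trained extended-DOF system and the toy-trained
stain-transfer bundle) are session-scoped: they are trained once, at a
deliberately reduced desk scale, and reused by unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from edofstain.autograd import default_dtype
from edofstain.optics import compute_psf, toy_optics
from edofstain.recon import ReconNetConfig, train_edof
from edofstain.synthdata import feature_pool, pair_channels

TOY_SEED = 0


@pytest.fixture(scope="session")
def toy_cfg():
    return toy_optics()


@pytest.fixture(scope="session")
def flat_psfs(toy_cfg):
    """Diffraction-limited (no-mask) PSF stack at the toy profile."""
    return compute_psf(toy_cfg)


@pytest.fixture(scope="session")
def train_scenes():
    """Procedural two-channel training scenes, 16 x (2, 64, 64)."""
    pool = feature_pool(32, 64, seed=10)
    return [s.values for s in pair_channels(pool, seed=11, n_samples=16)]


@pytest.fixture(scope="session")
def toy_state(toy_cfg, train_scenes):
    """Toy-profile system trained through both end-to-end steps (float32).

    2000 + 800 iterations (~1/25 of the published 30-40k schedule), four
    resolution levels, and a functional optical learning rate so the joint
    step actually shapes the mask at desk scale."""
    cfg = ReconNetConfig.toy(step1_iterations=2000, step2_iterations=800,
                             levels=4, lr_optical=3e-4,
                             seed=TOY_SEED, batch=2)
    with default_dtype(np.float32):
        return train_edof(train_scenes, cfg, toy_cfg)


@pytest.fixture(scope="session")
def toy_psfs(toy_cfg, toy_state):
    """PSF stack of the trained toy system (learned mask)."""
    return compute_psf(toy_cfg, toy_state.current_mask())


N_GAN_PHANTOMS = 48  # dataset scale: published 5-epoch schedule over a
#                      phantom set sized to give a few hundred iterations


@pytest.fixture(scope="session")
def gan_phantoms():
    from edofstain.synthdata import PhantomSpec, gen_he_scene, gen_nuclei_scene
    xs = [gen_nuclei_scene(PhantomSpec(size=64, n_nuclei=6, nucleus_radius=4.5,
                                       seed=100 + i))[0]
          for i in range(N_GAN_PHANTOMS)]
    ys = [gen_he_scene(PhantomSpec(size=64, n_nuclei=6, nucleus_radius=4.5,
                                   seed=1000 + i))[0]
          for i in range(N_GAN_PHANTOMS)]
    return xs, ys


@pytest.fixture(scope="session")
def toy_gan_step1(gan_phantoms):
    """Step-1-only bundle: cycle objective with Y replaced by the paired
    Beer-Lambert renderings."""
    from edofstain.cyclegan import GANConfig, train_semisupervised
    xs, _ = gan_phantoms
    cfg = GANConfig.toy(seed=TOY_SEED)
    with default_dtype(np.float32):
        return train_semisupervised(xs, None, cfg=cfg)


@pytest.fixture(scope="session")
def toy_gan_bundle(gan_phantoms):
    """Full two-step semi-supervised bundle on nuclei/H&E phantoms."""
    from edofstain.cyclegan import GANConfig, train_semisupervised
    xs, ys = gan_phantoms
    cfg = GANConfig.toy(seed=TOY_SEED)
    with default_dtype(np.float32):
        return train_semisupervised(xs, ys, cfg=cfg)
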