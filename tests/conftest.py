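import numpy as np
import pytest

from dnlseg.network import TEST_PRESET, build_model
from dnlseg.nn import Adam, Tensor
from dnlseg.phantoms import cta_preset, generate_phantom
from dnlseg.training import TrainConfig, combined_loss


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def overfit_setup():
    """A small DNL-Net driven to near-zero loss on one fixed noiseless
    phantom.  Shared across tests that need a model that has actually
    learned something (overfit sanity, CLI prediction quality)."""
    spec = cta_preset(size=(32, 32), seed=7, noise_sigma=0.0, blur_sigma=0.0)
    img, msk = generate_phantom(spec)
    model = build_model(TEST_PRESET, seed=3)
    x = Tensor(img[None, None])
    t = Tensor(msk[None, None].astype(np.float64))
    opt = Adam(model.parameters(), lr=1e-2, betas=(0.5, 0.999))
    cfg = TrainConfig()
    losses = []
    model.train()
    for _ in range(200):
        pred = model(x)
        loss = combined_loss(pred, t, cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        if losses[-1] < 0.02:
            break
    model.eval()
    return model, img, msk, losses
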