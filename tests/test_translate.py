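"""Translation model: architecture traces, loss identities and values,
gradient checks of the training objective on tiny networks, determinism."""

import numpy as np
import pytest

from trabeculagen._autograd import Tensor
from trabeculagen._nets import Conv2d, Generator
from trabeculagen import translate as T


@pytest.fixture(scope="module")
def tiny():
    return T.new_model(T.TrainConfig(base_channels=2, code_dim=8, image_size=16, seed=1))


def img(seed, n=1, size=16):
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(0, 0.5, (n, 1, size, size)), -1, 1).astype(np.float32)


# ---------------------------------------------------------------------------
# architecture traces
# ---------------------------------------------------------------------------

def test_class_label_two_classes():
    assert T.ClassLabel(0).name == "MDCT"
    assert T.ClassLabel(1).name == "MICRO"
    with pytest.raises(ValueError):
        T.ClassLabel(2)


def test_content_code_is_one_eighth(tiny):
    z = T.content_encode(tiny, img(0, size=16))
    assert z.shape[2:] == (2, 2)
    z64 = T.content_encode(T.new_model(T.TrainConfig(base_channels=2, seed=0)),
                           np.zeros((1, 1, 64, 64), np.float32))
    assert z64.shape[2:] == (8, 8)


def test_content_encoder_rejects_indivisible(tiny):
    with pytest.raises(ValueError, match="divisible by 8"):
        T.content_encode(tiny, np.zeros((1, 1, 30, 30), np.float32))


def test_discriminator_map_4x4_with_2_channels():
    st = T.new_model(T.TrainConfig(base_channels=2, seed=0))
    x = Tensor(np.zeros((1, 1, 64, 64), np.float32))
    full = st.discriminator.tail(st.discriminator.features(x))
    assert full.shape == (1, 2, 4, 4)  # S = 2 classes
    assert T.discriminate(st, np.zeros((1, 1, 64, 64), np.float32), 1).shape == (1, 4, 4)


def test_discriminator_too_small_input(tiny):
    with pytest.raises(ValueError, match="at least"):
        T.discriminate(tiny, np.zeros((1, 1, 8, 8), np.float32), 0)


def test_class_encoder_mean_properties(tiny):
    y1, y2 = img(1), img(2)
    c1 = T.class_encode(tiny, [y1]).data
    c_same = T.class_encode(tiny, [y1, y1, y1]).data
    assert np.allclose(c1, c_same, atol=1e-6)  # K copies = K=1
    c12 = T.class_encode(tiny, [y1, y2]).data
    c21 = T.class_encode(tiny, [y2, y1]).data
    assert np.allclose(c12, c21, atol=1e-6)  # permutation invariant
    with pytest.raises(ValueError):
        T.class_encode(tiny, [])


def test_decode_shapes_and_determinism(tiny):
    zx = T.content_encode(tiny, img(3))
    zy = T.class_encode(tiny, [img(4)])
    out1 = T.decode(tiny, zx, zy)
    out2 = T.decode(tiny, zx, zy)
    assert out1.shape == (1, 1, 16, 16)  # back to input resolution
    assert np.array_equal(out1.data, out2.data)


def test_decode_uniform_content_gives_uniform_interior(tiny):
    """A spatially constant content code yields a constant output away from
    the convolutional boundary halo (16x16 code -> 128x128 image; the halo
    penetrates ~50 px, leaving a flat central region)."""
    zx = Tensor(np.ones((1, tiny.generator.content.out_channels, 16, 16), np.float32))
    zy = T.class_encode(tiny, [img(5)])
    out = T.decode(tiny, zx, zy).data[0, 0]
    c = out.shape[0] // 2
    interior = out[c - 6:c + 6, c - 6:c + 6]
    assert interior.std() < 1e-5


def test_generate_composes(tiny):
    x, y = img(6), img(7)
    direct = T.generate(tiny, x, y)
    composed = T.decode(tiny, T.content_encode(tiny, x), T.class_encode(tiny, [y]))
    assert np.allclose(direct.data, composed.data, atol=1e-6)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class IdentityG:
    def __call__(self, x, ys):
        return x


class PlusOneG:
    def __call__(self, x, ys):
        return x + 1.0


def test_reconstruction_loss_identities():
    x = img(8)
    assert T.reconstruction_loss(IdentityG(), x).item() == 0.0
    assert T.reconstruction_loss(PlusOneG(), x).item() == pytest.approx(1.0)
    # arbitrary generator matches elementwise recomputation
    st = T.new_model(T.TrainConfig(base_channels=2, code_dim=8, seed=2, image_size=16))
    xt = Tensor(x)
    val = T.reconstruction_loss(st.generator, x).item()
    ref = np.abs(x - st.generator(xt, [xt]).data).mean()
    assert val == pytest.approx(float(ref), rel=1e-6)


def test_feature_matching_identities(tiny):
    y = img(9)
    assert T.feature_matching_loss(tiny.discriminator.features, y, [y]).item() == 0.0
    xbar = img(10)
    v1 = T.feature_matching_loss(tiny.discriminator.features, xbar, [y]).item()
    v2 = T.feature_matching_loss(tiny.discriminator.features, xbar, [y, y]).item()
    assert v1 == pytest.approx(v2, rel=1e-5)  # K identical targets = K=1
    fa = tiny.discriminator.features(Tensor(xbar)).data
    fb = tiny.discriminator.features(Tensor(y)).data
    assert v1 == pytest.approx(float(np.abs(fa - fb).mean()), rel=1e-5)


def test_gan_loss_at_half_probability(tiny):
    """A discriminator emitting probability 0.5 everywhere scores
    log(0.5) + log(0.5) = 2 log(0.5)."""

    class HalfD:
        def __call__(self, x, c):
            return Tensor(np.zeros((x.shape[0], 4, 4), np.float32))  # logit 0

    d_obj, g_loss = T.gan_loss(HalfD(), Tensor(img(11)), Tensor(img(12)), 0, 1)
    assert d_obj.item() == pytest.approx(2 * np.log(0.5), rel=1e-6)
    assert g_loss.item() == pytest.approx(-np.log(0.5), rel=1e-6)


def test_gan_loss_perfect_discriminator_approaches_zero():
    class PerfectD:
        def __call__(self, x, c):
            v = 50.0 if c == 0 else -50.0  # confident real-cx, fake-cy
            return Tensor(np.full((x.shape[0], 4, 4), v, np.float32))

    d_obj, _ = T.gan_loss(PerfectD(), Tensor(img(13)), Tensor(img(14)), 0, 1)
    assert -1e-5 < d_obj.item() <= 0.0


def test_literal_vs_nonsaturating_flag(tiny):
    xbar, x = Tensor(img(15)), Tensor(img(16))
    _, g_ns = T.gan_loss(tiny.discriminator, xbar, x, 0, 1, literal_g=False)
    d_obj, g_lit = T.gan_loss(tiny.discriminator, xbar, x, 0, 1, literal_g=True)
    p = T.discriminate(tiny, xbar, 1).sigmoid().data.mean()  # sanity direction
    assert g_ns.item() > 0.0
    assert g_lit.item() < 0.0  # log(1-p) is negative


# ---------------------------------------------------------------------------
# gradient checks of the objective on tiny smooth networks
# ---------------------------------------------------------------------------

def fd(f, p, idx, h=1e-3):
    orig = p.data[idx]
    p.data[idx] = orig + h
    fp = f()
    p.data[idx] = orig - h
    fm = f()
    p.data[idx] = orig + h / 2
    fp2 = f()
    p.data[idx] = orig - h / 2
    fm2 = f()
    p.data[idx] = orig
    return (4 * (fp2 - fm2) / h - (fp - fm) / (2 * h)) / 3


class ToyD:
    """Two-convolution smooth patch discriminator (tanh activations),
    promoted to float64 for high-precision finite differences."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.c1 = Conv2d(rng, 1, 3, 3, stride=2, pad=1)
        self.c2 = Conv2d(rng, 3, 2, 3, stride=2, pad=1)
        for p in self.c1.parameters() + self.c2.parameters():
            p.data = p.data.astype(np.float64)

    def features(self, x):
        return self.c1(x).tanh()

    def __call__(self, x, c):
        return self.c2(self.features(x))[:, c]


class ToyG:
    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.c = Conv2d(rng, 1, 1, 3)
        for p in self.c.parameters():
            p.data = p.data.astype(np.float64)

    def __call__(self, x, ys):
        return self.c(x).tanh()

    def parameters(self):
        return self.c.parameters()


@pytest.mark.parametrize("loss_name", ["gan_d", "gan_g", "recon", "featmatch"])
def test_objective_gradients_match_finite_differences(loss_name):
    """Analytic gradients of each training loss agree with central finite
    differences to 1e-4 relative on smooth toy networks."""
    D, G = ToyD(3), ToyG(4)
    # content images offset away from the generator's tanh range so the L1
    # residuals are bounded away from the |.| kink and finite differences
    # are valid
    x = (img(17) + 2.0).astype(np.float64)
    y = (img(18) - 2.0).astype(np.float64)
    rng = np.random.default_rng(5)

    def compute():
        if loss_name == "recon":
            return T.reconstruction_loss(G, x)
        xbar = G(Tensor(x), None)
        if loss_name == "featmatch":
            return T.feature_matching_loss(D.features, xbar, [Tensor(y)])
        d_obj, g_loss = T.gan_loss(D, xbar, Tensor(x), 0, 1)
        return d_obj if loss_name == "gan_d" else g_loss

    params = (D.c1.parameters() + D.c2.parameters()) if loss_name == "gan_d" else G.parameters()
    for p in params:
        p.grad = None
    compute().backward()
    checked = 0
    for p in params:
        idx = tuple(rng.integers(0, s) for s in p.data.shape)
        ag = p.grad[idx] if p.grad is not None else 0.0
        ng = fd(lambda: compute().item(), p, idx)
        assert ag == pytest.approx(ng, rel=1e-4, abs=1e-5), (loss_name, idx)
        checked += 1
    assert checked >= 2


# ---------------------------------------------------------------------------
# training loop behaviour
# ---------------------------------------------------------------------------

def dataset(seed=0, size=16):
    rng = np.random.default_rng(seed)
    return T.TranslationDataset(
        mdct=rng.integers(0, 255, (6, size, size)).astype(np.uint8),
        micro=rng.integers(0, 255, (8, size, size)).astype(np.uint8),
    )


def test_zero_iterations_is_noop():
    st = T.new_model(T.TrainConfig(base_channels=2, code_dim=8, image_size=16, seed=3))
    before = [p.data.copy() for p in st.generator.parameters()]
    T.train(st, dataset(), iterations=0)
    after = st.generator.state_arrays()
    assert all(np.array_equal(a, b) for a, b in zip(before, after))
    assert st.iteration == 0


def test_large_lambda_r_reduces_reconstruction_error():
    cfg = T.TrainConfig(base_channels=2, code_dim=8, image_size=16, seed=4,
                        lambda_r=50.0, lambda_f=0.0, lr=5e-4, log_every=10)
    st = T.new_model(cfg)
    ds = dataset(1)
    x_probe = ds.sample(np.random.default_rng(0), T.MDCT, 4)
    lr_before = T.reconstruction_loss(st.generator, x_probe).item()
    T.train(st, ds, iterations=60)
    lr_after = T.reconstruction_loss(st.generator, x_probe).item()
    assert lr_after < lr_before


def test_checkpoint_roundtrip_bit_identical(tmp_path):
    st = T.new_model(T.TrainConfig(base_channels=2, code_dim=8, image_size=16, seed=5))
    T.train(st, dataset(2), iterations=5)
    x, y = img(20), img(21)
    out1 = T.generate(st, x, y).data
    p = tmp_path / "ckpt.npz"
    T.save_checkpoint(st, p)
    st2 = T.load_checkpoint(p)
    assert st2.iteration == st.iteration
    out2 = T.generate(st2, x, y).data
    assert np.array_equal(out1, out2)
    # resumed training follows the same RNG stream
    T.train(st, dataset(2), iterations=3)
    T.train(st2, dataset(2), iterations=3)
    assert np.array_equal(T.generate(st, x, y).data, T.generate(st2, x, y).data)


def test_translate_stack_preserves_slices(tmp_path, small_mdct):
    st = T.new_model(T.TrainConfig(base_channels=2, code_dim=8, image_size=16, seed=6))
    refs = np.zeros((2, 16, 16), np.uint8) + 128
    sub = small_mdct.data[:4, :32, :32]
    from trabeculagen.core import VoxelVolume
    vol = VoxelVolume(sub, small_mdct.voxel_size)
    out1 = T.translate_stack(st, vol, refs)
    out2 = T.translate_stack(st, vol, refs)
    assert out1.shape[0] == 4
    assert out1.shape[1:] == (16, 16)
    assert np.array_equal(out1.data, out2.data)
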