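"""Unpaired MDCT -> micro-CT-like translation model.

The model is trained adversarially on *unpaired* slices of the two classes
(MDCT-like and micro-CT-like; S = 2).  The generator G(x, y_1..y_K) maps a
content image x toward the class of the target images y_k (K = 1 here: the
micro-CT image is the only target); the patch discriminator D scores each
local patch as real-of-class-c or generated.  Training solves

    min_G max_D  L_GAN(D, G) + lambda_R L_R(G) + lambda_F L_F(G)

with
  L_GAN = E_x[log D^cx(x)] + E_{x,y}[log(1 - D^cy(G(x, y)))],
  L_R   = E_x |x - G(x, x)|_1          (identity reconstruction), and
  L_F   = E |D_f(x_bar) - mean_k D_f(y_k)|_1  (feature matching, where D_f
          is the discriminator without its final layer).

Each training iteration draws a random ordered pair of distinct classes
(cx, cy) and one content image of class cx plus K target images of class
cy, so the discriminator sees real examples of both classes over time.
The generator minimizes the non-saturating surrogate -log D^cy(x_bar) by
default (the literal log(1 - D) form is available behind a flag; the
optimum is unchanged but the literal form stalls early training).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from ._autograd import Tensor
from ._nets import Discriminator, Generator, RMSProp
from .core import VoxelVolume

__all__ = [
    "ClassLabel",
    "TrainConfig",
    "TranslationModelState",
    "TranslationDataset",
    "new_model",
    "generate",
    "gan_loss",
    "reconstruction_loss",
    "feature_matching_loss",
    "train",
    "translate_stack",
    "save_checkpoint",
    "load_checkpoint",
    "build_slice_dataset",
]

MDCT, MICRO = 0, 1
CLASS_NAMES = ("MDCT", "MICRO")
N_CLASSES = 2


@dataclass(frozen=True)
class ClassLabel:
    value: int

    def __post_init__(self):
        if self.value not in (MDCT, MICRO):
            raise ValueError("exactly two classes exist: MDCT (0) and MICRO (1)")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.value]


@dataclass
class TrainConfig:
    iterations: int = 2000
    batch_size: int = 1
    k_targets: int = 1
    image_size: int = 64
    base_channels: int = 6
    code_dim: int = 64
    lambda_r: float = 0.1
    lambda_f: float = 1.0
    lr: float = 1e-4
    eps_clamp: float = 1e-7
    literal_gan: bool = False
    seed: int = 0
    log_every: int = 100


@dataclass
class TranslationModelState:
    """All learnable parameters plus optimizer state and provenance."""

    generator: Generator
    discriminator: Discriminator
    config: TrainConfig
    opt_g: RMSProp
    opt_d: RMSProp
    rng: np.random.Generator
    iteration: int = 0
    history: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.config.k_targets


def new_model(config: TrainConfig | None = None) -> TranslationModelState:
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    g = Generator(rng, base=config.base_channels, code_dim=config.code_dim)
    d = Discriminator(rng, base=config.base_channels, n_classes=N_CLASSES)
    return TranslationModelState(
        generator=g,
        discriminator=d,
        config=config,
        opt_g=RMSProp(g.parameters(), lr=config.lr),
        opt_d=RMSProp(d.parameters(), lr=config.lr),
        rng=rng,
    )


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

def _normalize(images: np.ndarray) -> np.ndarray:
    """uint8 [0,255] -> float32 [-1,1], shape (n, 1, h, w)."""
    a = np.asarray(images, dtype=np.float32)
    if a.ndim == 3:
        a = a[:, None]
    return a / 127.5 - 1.0


def _denormalize(a: np.ndarray) -> np.ndarray:
    return np.clip((a + 1.0) * 127.5, 0, 255).astype(np.uint8)


@dataclass
class TranslationDataset:
    """Slices of both classes on a common pixel grid, plus the known
    ground-truth pairing (mdct index -> micro index) when available."""

    mdct: np.ndarray  # (n, h, w) uint8, upsampled to the micro grid
    micro: np.ndarray  # (m, h, w) uint8
    true_pairs: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if len(self.mdct) == 0 or len(self.micro) == 0:
            raise ValueError("dataset needs slices of both classes")
        if self.mdct.shape[1:] != self.micro.shape[1:]:
            raise ValueError("classes must share one pixel grid")

    def sample(self, rng: np.random.Generator, cls: int, n: int) -> np.ndarray:
        pool = self.mdct if cls == MDCT else self.micro
        idx = rng.integers(0, len(pool), size=n)
        return _normalize(pool[idx])


def build_slice_dataset(items, image_size: int = 64, max_slices_per_item: int | None = None):
    """Cut a paired 2-class slice dataset from rendered phantoms.

    For each (ground truth, micro stack, mdct stack) item, a centred window
    of ``image_size`` micro-CT pixels is cropped from every micro slice, and
    the physically matching window of the MDCT rendering is upsampled
    (bicubic) to the same grid.  The known 2:1 slice correspondence (micro
    slice 2i <-> MDCT slice i) gives ground-truth pairs for evaluation;
    training itself treats the two sets as unpaired.
    """
    mdct_out, micro_out, pairs = [], [], []
    for gt, micro, mdct in items:
        if micro is None or mdct is None:
            raise ValueError("items must carry rendered stacks")
        win_mm = image_size * micro.voxel_size[1]
        cy, cx = (micro.shape[1] // 2, micro.shape[2] // 2)
        half = image_size // 2
        msl = (slice(cy - half, cy + half), slice(cx - half, cx + half))
        # matching physical window on the MDCT grid
        mcy = micro.voxel_size[1] * cy / mdct.voxel_size[1]
        mhalf = win_mm / 2.0 / mdct.voxel_size[1]
        a, b = int(round(mcy - mhalf)), int(round(mcy + mhalf))
        n_micro = micro.shape[0]
        if max_slices_per_item is not None:
            n_micro = min(n_micro, max_slices_per_item)
        base_micro = len(micro_out)
        base_mdct = len(mdct_out)
        n_mdct_used = 0
        for j in range(n_micro):
            i = j // 2
            if i >= mdct.shape[0]:
                break
            micro_out.append(micro.data[j][msl])
            if i >= n_mdct_used:
                up = resize(
                    mdct.data[i][a:b, a:b].astype(np.float32),
                    (image_size, image_size),
                    order=3,
                    anti_aliasing=False,
                )
                mdct_out.append(np.clip(up, 0, 255).astype(np.uint8))
                n_mdct_used += 1
            pairs.append((base_mdct + i, base_micro + j))
    return TranslationDataset(
        mdct=np.stack(mdct_out), micro=np.stack(micro_out), true_pairs=pairs
    )


# ---------------------------------------------------------------------------
# model surface
# ---------------------------------------------------------------------------

def content_encode(state: TranslationModelState, x) -> Tensor:
    return state.generator.content(_as_tensor(x))


def class_encode(state: TranslationModelState, ys) -> Tensor:
    return state.generator.klass([_as_tensor(y) for y in _as_list(ys)])


def decode(state: TranslationModelState, zx: Tensor, zy: Tensor) -> Tensor:
    return state.generator.decoder(zx, zy)


def generate(state: TranslationModelState, x, ys) -> Tensor:
    """x_bar = G(x, y_1..y_K) = decode(content(x), class(y))."""
    return state.generator(_as_tensor(x), [_as_tensor(y) for y in _as_list(ys)])


def discriminate(state: TranslationModelState, img, label: ClassLabel | int) -> Tensor:
    c = label.value if isinstance(label, ClassLabel) else int(label)
    return state.discriminator(_as_tensor(img), c)


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    return Tensor(a)


def _as_list(ys):
    if isinstance(ys, (list, tuple)):
        return list(ys)
    return [ys]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def gan_loss(D: Discriminator, xbar: Tensor, x: Tensor, cx: int, cy: int,
             eps: float = 1e-7, literal_g: bool = False) -> tuple[Tensor, Tensor]:
    """Adversarial objective, averaged over patches.

    Returns ``(d_objective, g_loss)``: the discriminator *maximizes*
    ``E[log D^cx(x)] + E[log(1 - D^cy(x_bar))]`` (so its training loss is
    the negative), while the generator minimizes ``-E[log D^cy(x_bar)]``
    (non-saturating) or, with ``literal_g``, ``E[log(1 - D^cy(x_bar))]``.
    Probabilities are clamped to [eps, 1-eps] inside the logs.
    """
    p_real = D(x, cx).sigmoid().clip(eps, 1.0 - eps)
    p_fake = D(xbar, cy).sigmoid().clip(eps, 1.0 - eps)
    d_obj = p_real.log().mean() + (1.0 - p_fake).log().mean()
    if literal_g:
        g_loss = (1.0 - p_fake).log().mean()
    else:
        g_loss = -(p_fake.log().mean())
    return d_obj, g_loss


def reconstruction_loss(G, x) -> Tensor:
    """L1 reconstruction: mean |x - G(x, x)| with the input itself as the
    K = 1 mapping target; exactly zero for an identity generator."""
    xt = _as_tensor(x)
    return (xt - G(xt, [xt])).abs().mean()


def feature_matching_loss(Df, xbar, ys) -> Tensor:
    """L1 distance between discriminator features of the generated image
    and the mean features of the target images."""
    ys = _as_list(ys)
    f = Df(_as_tensor(ys[0]))
    for y in ys[1:]:
        f = f + Df(_as_tensor(y))
    f = f * np.float32(1.0 / len(ys))
    return (Df(_as_tensor(xbar)) - f).abs().mean()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TrainingDiverged(RuntimeError):
    pass


def train(state: TranslationModelState, dataset: TranslationDataset,
          iterations: int | None = None, callback=None) -> TranslationModelState:
    """Alternating min-max updates; fully driven by the state's RNG.

    Per iteration: draw a random ordered pair of distinct classes (cx, cy),
    a content batch of class cx and K targets of class cy; ascend the
    discriminator on the adversarial objective; then descend the generator
    on g_loss + lambda_R * L_R + lambda_F * L_F.  Aborts with the current
    state attached if any loss becomes non-finite.
    """
    cfg = state.config
    n_iter = cfg.iterations if iterations is None else iterations
    G, D = state.generator, state.discriminator
    rng = state.rng
    for it in range(n_iter):
        cx = int(rng.integers(0, N_CLASSES))
        cy = 1 - cx  # the other class: cx != cy always
        x = Tensor(dataset.sample(rng, cx, cfg.batch_size))
        ys = [Tensor(dataset.sample(rng, cy, cfg.batch_size)) for _ in range(cfg.k_targets)]

        xbar = G(x, ys)

        # discriminator ascent (generator detached)
        state.opt_d.zero_grad()
        d_obj, _ = gan_loss(D, xbar.detach(), x, cx, cy, eps=cfg.eps_clamp)
        d_loss = -d_obj
        d_loss.backward()
        state.opt_d.step()

        # generator descent through the updated discriminator; the patch
        # features of x_bar are computed once and reused for both the
        # adversarial score and the feature-matching term
        state.opt_g.zero_grad()
        state.opt_d.zero_grad()
        f_xbar = D.features(xbar)
        p_fake = D.tail(f_xbar)[:, cy].sigmoid().clip(cfg.eps_clamp, 1.0 - cfg.eps_clamp)
        if cfg.literal_gan:
            g_adv = (1.0 - p_fake).log().mean()
        else:
            g_adv = -(p_fake.log().mean())
        f_y = D.features(ys[0])
        for y in ys[1:]:
            f_y = f_y + D.features(y)
        f_y = f_y * np.float32(1.0 / len(ys))
        l_f = (f_xbar - f_y).abs().mean()
        l_r = reconstruction_loss(G, x)
        g_total = g_adv + np.float32(cfg.lambda_r) * l_r + np.float32(cfg.lambda_f) * l_f
        g_total.backward()
        state.opt_g.step()
        state.opt_d.zero_grad()  # discard discriminator grads from the G pass

        state.iteration += 1
        vals = (d_loss.item(), g_adv.item(), l_r.item(), l_f.item())
        if not all(np.isfinite(v) for v in vals):
            raise TrainingDiverged(
                f"non-finite loss at iteration {state.iteration}: "
                f"d={vals[0]} g={vals[1]} r={vals[2]} f={vals[3]}"
            )
        if state.iteration % cfg.log_every == 0 or it == n_iter - 1:
            state.history.append(
                {"iteration": state.iteration, "d_loss": vals[0],
                 "g_adv": vals[1], "l_r": vals[2], "l_f": vals[3]}
            )
            if callback is not None:
                callback(state.history[-1])
    return state


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def translate_stack(state: TranslationModelState, mdct_stack: VoxelVolume,
                    reference, batch: int = 8) -> VoxelVolume:
    """Slice-wise translation of an MDCT stack to the micro-CT-like class.

    Every slice is upsampled (bicubic) to the micro-CT in-plane pitch
    implied by the reference images' grid, normalized, and passed through
    the generator with the class code of ``reference`` (one or more
    micro-CT-like images).  Slice count is preserved; the output keeps the
    MDCT axial spacing with the micro-CT in-plane pitch.
    """
    ref = np.asarray(reference)
    if ref.ndim == 2:
        ref = ref[None]
    size = ref.shape[-2:]
    # each reference slice is one of the K class images; the resulting class
    # code is a single vector shared by every translated slice
    ref_t = [Tensor(_normalize(r[None])) for r in ref]
    zy = state.generator.klass(ref_t)
    slices = []
    data = mdct_stack.data
    ups = np.stack([
        resize(s.astype(np.float32), size, order=3, anti_aliasing=False)
        for s in data
    ])
    for i in range(0, len(ups), batch):
        chunk = _normalize(ups[i : i + batch])
        zx = state.generator.content(Tensor(chunk))
        # broadcast the single class code across the batch
        zy_b = Tensor(np.broadcast_to(zy.data, (chunk.shape[0], zy.data.shape[1])).copy())
        out = state.generator.decoder(zx, zy_b)
        slices.append(_denormalize(out.data[:, 0]))
    out = np.concatenate(slices)
    dz = mdct_stack.voxel_size[0]
    pitch = mdct_stack.voxel_size[1] * mdct_stack.shape[1] / size[0]
    return VoxelVolume(out, (dz, pitch, pitch), mdct_stack.origin)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: TranslationModelState, path) -> None:
    """Single self-describing archive: config, weights, optimizer state."""
    arrays = {}
    for tag, arrs in (("g", state.generator.state_arrays()),
                      ("d", state.discriminator.state_arrays()),
                      ("mg", state.opt_g.state()),
                      ("md", state.opt_d.state())):
        for i, a in enumerate(arrs):
            arrays[f"{tag}_{i}"] = a
    arrays["rng_state"] = np.frombuffer(
        json.dumps(state.rng.bit_generator.state).encode(), dtype=np.uint8
    )
    arrays["meta"] = np.frombuffer(
        json.dumps({"config": asdict(state.config), "iteration": state.iteration,
                    "history": state.history}).encode(),
        dtype=np.uint8,
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> TranslationModelState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = TrainConfig(**meta["config"])
        state = new_model(cfg)
        count = {"g": 0, "d": 0, "mg": 0, "md": 0}
        for k in z.files:
            tag = k.rsplit("_", 1)[0]
            if tag in count:
                count[tag] += 1
        state.generator.load_arrays([z[f"g_{i}"] for i in range(count["g"])])
        state.discriminator.load_arrays([z[f"d_{i}"] for i in range(count["d"])])
        state.opt_g.load([z[f"mg_{i}"] for i in range(count["mg"])])
        state.opt_d.load([z[f"md_{i}"] for i in range(count["md"])])
        state.rng.bit_generator.state = json.loads(bytes(z["rng_state"]).decode())
        state.iteration = meta["iteration"]
        state.history = meta["history"]
    return state
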