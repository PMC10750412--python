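"""The two skull-reconstruction networks.

Stage 1 — **3-D completion network** (10 table rows): a U-Net-style
encoder-decoder over the low-resolution defective skull. Encoder: one
8-filter conv, then three conv+pool stages (8, 4, 4 filters); a
bottleneck of two dilation-2 convolutions (4 filters) closed by a
residual summation; decoder: three nearest-neighbour-upsample+conv
stages (4, 8, 8 filters) each summed with the encoder conv output at
the same resolution; a sigmoid conv head whose output is added to the
network input (so existing bone is always retained and the conv path
only has to synthesise the missing patch). All kernels are 3x3x3,
stride 1, 'same' padding; pooling is 2x2x2; skips are summations, never
concatenations; no batch normalisation. One skip (the 4-channel
encoder map into the 8-channel decoder stage) needs a declared 3x3x3
projection conv (4->8). Total: 8,269 trainable parameters.

Stage 2 — **resolution-enhancement network** (14 table rows): two
inputs. The low-resolution *completed* skull runs through the same
completion-style encoder/bottleneck/decoder (rows 1-6, 9-11 plus the
projection); the resulting full-low-res 8-channel map is upsampled x2
by parameter-free nearest-neighbour interpolation (row 12). The
high-resolution *defective* skull passes through the **shared** entry
convolution (rows 1 and 7 are the same 1->8 layer, counted once) and a
conv+pool stage (row 8) down to half resolution, where the two streams
merge by summation. One final upsample+conv stage (row 13) with a
U-Net summation skip from the high-resolution stem output, then a
sigmoid conv head (row 14) normalised to [0, 1]. Total: 11,741
trainable parameters. The shared stem and the single parameter-free
upsampling row are the wiring under which the per-layer sums match the
architecture's published parameter totals exactly; ``describe()``
prints the full layer list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import BinaryVolume, ScalarVolume
from .engine import (
    Adadelta,
    Conv3d,
    maxpool2,
    maxpool2_backward,
    relu,
    relu_backward,
    sigmoid,
    upsample2,
    upsample2_backward,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ModelState",
    "CompletionNetwork",
    "EnhancementNetwork",
    "build_completion_network",
    "build_enhancement_network",
    "count_trainable_parameters",
    "forward_completion",
    "forward_enhancement",
    "binarize_prediction",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.45


@dataclass(frozen=True)
class LayerSpec:
    """One declarative network row (3x3x3 kernel, stride 1 throughout)."""

    kind: str  # conv | conv_pool | dilated_conv | upsample_conv | upsample | conv_sigmoid
    channels_out: int
    dilation: int = 1
    activation: str = "relu"
    shares_weights_with: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.dilation == 2 and self.kind != "dilated_conv":
            raise ValueError("dilation 2 is reserved for dilated_conv layers")


@dataclass
class NetworkSpec:
    name: str
    layers: list[LayerSpec]
    skip_pairs: list[tuple[str, str]]
    residual_input_add: bool = False
    second_input_entry: int | None = None
    projections: list[str] = field(default_factory=list)


class _Net:
    """Shared machinery: parameter registry, counting, persistence."""

    def __init__(self) -> None:
        self.convs: dict[str, Conv3d] = {}
        self.init_seed: int | None = None

    def _register(self, conv: Conv3d) -> Conv3d:
        self.convs[conv.name] = conv
        return conv

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, conv in self.convs.items():
            out[name + ".W"] = conv.W
            out[name + ".b"] = conv.b
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for name, conv in self.convs.items():
            conv.W = params[name + ".W"].astype(np.float32)
            conv.b = params[name + ".b"].astype(np.float32)

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters.items()}

    def init(self, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.init_seed = seed
        for conv in self.convs.values():
            conv.init(rng)

    def n_parameters(self) -> int:
        return sum(c.n_params for c in self.convs.values())

    def zero_parameters(self) -> None:
        for c in self.convs.values():
            c.W[...] = 0.0
            c.b[...] = 0.0

    def save(self, path) -> None:
        np.savez(path, **self.parameters)

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_parameters({k: data[k] for k in data.files})


def _check_divisible(dims, by: int, what: str) -> None:
    bad = [d for d in dims if d % by]
    if bad:
        need = tuple((by - d % by) % by for d in dims)
        raise ValueError(
            f"{what} dims {tuple(dims)} must be divisible by {by}; "
            f"pad by {need} voxels"
        )


class CompletionNetwork(_Net):
    """Stage-1 network: low-resolution defective skull -> completed skull."""

    def __init__(self) -> None:
        super().__init__()
        self.c1 = self._register(Conv3d("c1", 1, 8))
        self.c2 = self._register(Conv3d("c2", 8, 8))
        self.c3 = self._register(Conv3d("c3", 8, 4))
        self.c4 = self._register(Conv3d("c4", 4, 4))
        self.c5 = self._register(Conv3d("c5", 4, 4, dilation=2))
        self.c6 = self._register(Conv3d("c6", 4, 4, dilation=2))
        self.c7 = self._register(Conv3d("c7", 4, 4))
        self.c8 = self._register(Conv3d("c8", 4, 8))
        self.proj = self._register(Conv3d("proj", 4, 8))  # skip projection e3 -> decoder
        self.c9 = self._register(Conv3d("c9", 8, 8))
        self.c10 = self._register(Conv3d("c10", 8, 1))

    @property
    def spec(self) -> NetworkSpec:
        rows = [
            LayerSpec("conv", 8),
            LayerSpec("conv_pool", 8),
            LayerSpec("conv_pool", 4),
            LayerSpec("conv_pool", 4),
            LayerSpec("dilated_conv", 4, dilation=2),
            LayerSpec("dilated_conv", 4, dilation=2,
                      note="closed by residual summation with the bottleneck input"),
            LayerSpec("upsample_conv", 4),
            LayerSpec("upsample_conv", 8),
            LayerSpec("upsample_conv", 8),
            LayerSpec("conv_sigmoid", 1, activation="sigmoid"),
        ]
        return NetworkSpec(
            name="completion",
            layers=rows,
            skip_pairs=[("c4", "c7"), ("c3", "c8"), ("c2", "c9")],
            residual_input_add=True,
            projections=["proj: 3x3x3 conv 4->8 on the c3 skip (channel match)"],
        )

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """x: (N, X, Y, Z, 1) float32, dims divisible by 8."""
        _check_divisible(x.shape[1:4], 8, "completion input")
        c = cache if cache is not None else {}
        e1 = relu(self.c1.forward(x, c))
        e2 = relu(self.c2.forward(e1, c))
        p2, i2 = maxpool2(e2)
        e3 = relu(self.c3.forward(p2, c))
        p3, i3 = maxpool2(e3)
        e4 = relu(self.c4.forward(p3, c))
        p4, i4 = maxpool2(e4)
        b1 = relu(self.c5.forward(p4, c))
        r6 = relu(self.c6.forward(b1, c))
        b2 = r6 + p4
        r7 = relu(self.c7.forward(upsample2(b2), c))
        d1 = r7 + e4
        r8 = relu(self.c8.forward(upsample2(d1), c))
        d2 = r8 + self.proj.forward(e3, c)
        r9 = relu(self.c9.forward(upsample2(d2), c))
        d3 = r9 + e2
        y = sigmoid(self.c10.forward(d3, c))
        out = y + x
        if cache is not None:
            cache.update(
                e1=e1, e2=e2, e3=e3, e4=e4, b1=b1, r6=r6, r7=r7, r8=r8, r9=r9,
                y=y, i2=i2, i3=i3, i4=i4,
                shapes=dict(e2=e2.shape, e3=e3.shape, e4=e4.shape),
            )
        return out

    def loss_grad(self, cache: dict, x: np.ndarray, target: np.ndarray,
                  scale: float) -> np.ndarray:
        """d(BCE)/d(head logits), fused with the sigmoid (numerically
        stable at saturation: the gradient is (p - t), never the
        clipped quotient). Voxels already carrying input bone have
        post-residual values >= 1 — clipped to certainty — so they
        contribute no gradient."""
        y = cache["y"]
        return ((y - target) * (x < 0.5) * scale).astype(np.float32)

    def backward(self, cache: dict, gout: np.ndarray,
                 from_logits: bool = False) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        c = cache
        y = c["y"]
        gz = gout if from_logits else gout * y * (1.0 - y)
        gd3 = self.c10.backward(c, gz, grads)
        gu9 = relu_backward(gd3, c["r9"])
        gd2 = upsample2_backward(self.c9.backward(c, gu9, grads))
        ge3_proj = self.proj.backward(c, gd2, grads)
        gu8 = relu_backward(gd2, c["r8"])
        gd1 = upsample2_backward(self.c8.backward(c, gu8, grads))
        gu7 = relu_backward(gd1, c["r7"])
        gb2 = upsample2_backward(self.c7.backward(c, gu7, grads))
        gb1 = self.c6.backward(c, relu_backward(gb2, c["r6"]), grads)
        gp4 = self.c5.backward(c, relu_backward(gb1, c["b1"]), grads) + gb2
        ge4 = maxpool2_backward(gp4, c["i4"], c["shapes"]["e4"]) + gd1
        gp3 = self.c4.backward(c, relu_backward(ge4, c["e4"]), grads)
        ge3 = maxpool2_backward(gp3, c["i3"], c["shapes"]["e3"]) + ge3_proj
        gp2 = self.c3.backward(c, relu_backward(ge3, c["e3"]), grads)
        ge2 = maxpool2_backward(gp2, c["i2"], c["shapes"]["e2"]) + gd3
        ge1 = self.c2.backward(c, relu_backward(ge2, c["e2"]), grads)
        self.c1.backward(c, relu_backward(ge1, c["e1"]), grads)
        return grads


class EnhancementNetwork(_Net):
    """Stage-2 network: (completed low-res, defective high-res) -> completed high-res."""

    def __init__(self) -> None:
        super().__init__()
        self.stem = self._register(Conv3d("stem", 1, 8))  # shared by both inputs
        self.c2 = self._register(Conv3d("c2", 8, 8))
        self.c3 = self._register(Conv3d("c3", 8, 4))
        self.c4 = self._register(Conv3d("c4", 4, 4))
        self.c5 = self._register(Conv3d("c5", 4, 4, dilation=2))
        self.c6 = self._register(Conv3d("c6", 4, 4, dilation=2))
        self.c7 = self._register(Conv3d("c7", 4, 4))
        self.c8 = self._register(Conv3d("c8", 4, 8))
        self.proj = self._register(Conv3d("proj", 4, 8))
        self.c9 = self._register(Conv3d("c9", 8, 8))
        self.cB = self._register(Conv3d("cB", 8, 8))  # high-res branch conv+pool
        self.c13 = self._register(Conv3d("c13", 8, 8))  # post-merge upsample conv
        self.c14 = self._register(Conv3d("c14", 8, 1))

    @property
    def spec(self) -> NetworkSpec:
        rows = [
            LayerSpec("conv", 8, note="entry conv, shared with row 7"),
            LayerSpec("conv_pool", 8),
            LayerSpec("conv_pool", 4),
            LayerSpec("conv_pool", 4),
            LayerSpec("dilated_conv", 4, dilation=2),
            LayerSpec("dilated_conv", 4, dilation=2,
                      note="closed by residual summation with the bottleneck input"),
            LayerSpec("conv", 8, shares_weights_with="row 1",
                      note="high-resolution branch entry (shared stem)"),
            LayerSpec("conv_pool", 8),
            LayerSpec("upsample_conv", 4),
            LayerSpec("upsample_conv", 8),
            LayerSpec("upsample_conv", 8),
            LayerSpec("upsample", 8,
                      note="parameter-free nearest-neighbour x2 to the merge resolution"),
            LayerSpec("upsample_conv", 8, note="post-merge; summed with the stem map"),
            LayerSpec("conv_sigmoid", 1, activation="sigmoid"),
        ]
        return NetworkSpec(
            name="enhancement",
            layers=rows,
            skip_pairs=[("c4", "c7"), ("c3", "c8"), ("c2", "c9"), ("stem", "c13")],
            residual_input_add=False,
            second_input_entry=6,
            projections=["proj: 3x3x3 conv 4->8 on the c3 skip (channel match)"],
        )

    def forward(self, x_low: np.ndarray, x_high: np.ndarray,
                cache: dict | None = None) -> np.ndarray:
        _check_divisible(x_low.shape[1:4], 8, "enhancement low-res input")
        if tuple(x_high.shape[1:4]) != tuple(4 * d for d in x_low.shape[1:4]):
            raise ValueError(
                f"high-res dims {x_high.shape[1:4]} must be 4x the low-res "
                f"dims {x_low.shape[1:4]}"
            )
        c = cache if cache is not None else {}
        a1 = relu(self.stem.forward(x_low, c))
        c["stem_low"] = c.pop("stem")
        a2 = relu(self.c2.forward(a1, c))
        p2, i2 = maxpool2(a2)
        a3 = relu(self.c3.forward(p2, c))
        p3, i3 = maxpool2(a3)
        a4 = relu(self.c4.forward(p3, c))
        p4, i4 = maxpool2(a4)
        b1 = relu(self.c5.forward(p4, c))
        r6 = relu(self.c6.forward(b1, c))
        b2 = r6 + p4
        r7 = relu(self.c7.forward(upsample2(b2), c))
        d1 = r7 + a4
        r8 = relu(self.c8.forward(upsample2(d1), c))
        d2 = r8 + self.proj.forward(a3, c)
        r9 = relu(self.c9.forward(upsample2(d2), c))
        d3 = r9 + a2                     # 8 channels at low resolution
        aup = upsample2(d3)              # parameter-free, to half high-res
        f1 = relu(self.stem.forward(x_high, c))
        c["stem_high"] = c.pop("stem")
        rB = relu(self.cB.forward(f1, c))
        f2, iB = maxpool2(rB)
        m = aup + f2                     # summation merge of the two streams
        r13 = relu(self.c13.forward(upsample2(m), c))
        dd = r13 + f1
        out = sigmoid(self.c14.forward(dd, c))
        if cache is not None:
            cache.update(
                a1=a1, a2=a2, a3=a3, a4=a4, b1=b1, r6=r6, r7=r7, r8=r8, r9=r9,
                f1=f1, rB=rB, r13=r13, out=out, i2=i2, i3=i3, i4=i4, iB=iB,
                shapes=dict(a2=a2.shape, a3=a3.shape, a4=a4.shape, rB=rB.shape),
            )
        return out

    def loss_grad(self, cache: dict, x: np.ndarray, target: np.ndarray,
                  scale: float) -> np.ndarray:
        """d(BCE)/d(head logits): (p - t), stable at saturation."""
        return ((cache["out"] - target) * scale).astype(np.float32)

    def backward(self, cache: dict, gout: np.ndarray,
                 from_logits: bool = False) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        c = cache
        o = c["out"]
        gdd = self.c14.backward(c, gout if from_logits else gout * o * (1.0 - o), grads)
        gm = upsample2_backward(self.c13.backward(c, relu_backward(gdd, c["r13"]), grads))
        # high-res branch
        gf2 = gm
        grB = maxpool2_backward(gf2, c["iB"], c["shapes"]["rB"])
        gf1 = self.cB.backward(c, relu_backward(grB, c["rB"]), grads) + gdd
        c["stem"] = c["stem_high"]
        self.stem.backward(c, relu_backward(gf1, c["f1"]), grads)
        # low-res completion-style branch
        gd3 = upsample2_backward(gm)
        gu9 = relu_backward(gd3, c["r9"])
        gd2 = upsample2_backward(self.c9.backward(c, gu9, grads))
        ga3_proj = self.proj.backward(c, gd2, grads)
        gu8 = relu_backward(gd2, c["r8"])
        gd1 = upsample2_backward(self.c8.backward(c, gu8, grads))
        gu7 = relu_backward(gd1, c["r7"])
        gb2 = upsample2_backward(self.c7.backward(c, gu7, grads))
        gb1 = self.c6.backward(c, relu_backward(gb2, c["r6"]), grads)
        gp4 = self.c5.backward(c, relu_backward(gb1, c["b1"]), grads) + gb2
        ga4 = maxpool2_backward(gp4, c["i4"], c["shapes"]["a4"]) + gd1
        gp3 = self.c4.backward(c, relu_backward(ga4, c["a4"]), grads)
        ga3 = maxpool2_backward(gp3, c["i3"], c["shapes"]["a3"]) + ga3_proj
        gp2 = self.c3.backward(c, relu_backward(ga3, c["a3"]), grads)
        ga2 = maxpool2_backward(gp2, c["i2"], c["shapes"]["a2"]) + gd3
        ga1 = self.c2.backward(c, relu_backward(ga2, c["a2"]), grads)
        # the stem is applied to both inputs; Conv3d.backward accumulates
        c["stem"] = c["stem_low"]
        self.stem.backward(c, relu_backward(ga1, c["a1"]), grads)
        return grads


@dataclass
class ModelState:
    """A built network with its parameters and provenance."""

    net: CompletionNetwork | EnhancementNetwork
    input_dims: tuple[int, int, int]
    high_dims: tuple[int, int, int] | None = None

    @property
    def spec(self) -> NetworkSpec:
        return self.net.spec

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return self.net.parameters

    @property
    def init_seed(self) -> int | None:
        return self.net.init_seed


def build_completion_network(
    input_dims: tuple[int, int, int] = (128, 128, 96), seed: int = 0
) -> ModelState:
    _check_divisible(input_dims, 8, "completion input")
    net = CompletionNetwork()
    net.init(seed)
    return ModelState(net, tuple(input_dims))


def build_enhancement_network(
    low_dims: tuple[int, int, int] = (128, 128, 96),
    high_dims: tuple[int, int, int] = (512, 512, 384),
    seed: int = 0,
) -> ModelState:
    _check_divisible(low_dims, 8, "enhancement low-res input")
    if tuple(high_dims) != tuple(4 * d for d in low_dims):
        raise ValueError(
            f"high_dims {tuple(high_dims)} must be 4x low_dims {tuple(low_dims)}"
        )
    net = EnhancementNetwork()
    net.init(seed)
    return ModelState(net, tuple(low_dims), tuple(high_dims))


def count_trainable_parameters(model: ModelState | _Net) -> int:
    """Sum of element counts over every weight and bias tensor. Shared
    layers are counted once (they are one set of parameters)."""
    net = model.net if isinstance(model, ModelState) else model
    return net.n_parameters()


def _to_tensor(volume: BinaryVolume | ScalarVolume) -> np.ndarray:
    return np.asarray(volume.values, dtype=np.float32)[None, ..., None]


def forward_completion(model: ModelState, defective_low: BinaryVolume) -> ScalarVolume:
    """Run stage 1. Output is real-valued, same dims; values are
    sigmoid(conv path) + input, so they lie in (0, 1) on empty voxels
    and (1, 2) on bone voxels — thresholding handles the range."""
    if tuple(defective_low.shape) != tuple(model.input_dims):
        raise ValueError(
            f"input dims {defective_low.shape} do not match the built "
            f"model dims {model.input_dims}"
        )
    out = model.net.forward(_to_tensor(defective_low))
    return ScalarVolume(
        out[0, ..., 0].astype(np.float64), defective_low.spacing, defective_low.origin
    )


def forward_enhancement(
    model: ModelState, completed_low: BinaryVolume, defective_high: BinaryVolume
) -> ScalarVolume:
    """Run stage 2 on the (binarized) completed low-res model and the
    original high-res defective model; output in [0, 1] at high res."""
    if tuple(defective_high.shape) != tuple(4 * d for d in completed_low.shape):
        raise ValueError(
            f"high-res dims {defective_high.shape} must be 4x the low-res "
            f"dims {completed_low.shape}"
        )
    out = model.net.forward(_to_tensor(completed_low), _to_tensor(defective_high))
    return ScalarVolume(
        out[0, ..., 0].astype(np.float64), defective_high.spacing, defective_high.origin
    )


def binarize_prediction(
    volume: ScalarVolume, threshold: float = DEFAULT_THRESHOLD
) -> BinaryVolume:
    """Threshold a probability volume: voxel = 1 iff value >= threshold."""
    if isinstance(volume, BinaryVolume):
        return volume.copy()
    return BinaryVolume(
        (volume.values >= threshold).astype(np.uint8), volume.spacing, volume.origin
    )
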