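"""Network-layer RSMs and layerwise brain alignment.

Layer activations come either from the built-in untrained convolutional
feature extractor — a seeded, Glorot-initialized stack with the canonical
five convolutional and three fully connected stages (an AlexNet-style
geometry, weights never updated) — or from externally supplied
images-by-features matrices (one per layer) for any pretrained model.
Untrained architectures already impose useful inductive biases, which is
exactly what comparing them against developing visual cortex probes.

Per layer, the model RSM is the Pearson correlation between images'
activation vectors; brain alignment is the bootstrap Spearman correlation
of layer RSM and fMRI RSM upper triangles, excluding the diagonal, and
normalized by the group/ROI noise ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from devgeo.inference import BootstrapResult, bootstrap_statistic, rsa_correlation
from devgeo.rsm import RSM, NoiseCeiling
from devgeo.models import ModelRSM

DEFAULT_LAYERS = ("conv1", "conv2", "conv3", "conv4", "conv5", "fc6", "fc7", "output")

GRAY_BACKGROUND = 128  # compositing level for stimuli on a gray field


@dataclass
class LayerActivations:
    """Ordered per-layer activation matrices (images x features)."""

    layer_names: tuple[str, ...]
    matrices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n_images = None
        for name in self.layer_names:
            m = np.asarray(self.matrices[name], dtype=float)
            if m.ndim != 2 or m.shape[1] < 2:
                raise ValueError(f"layer {name!r} needs an images x features matrix")
            if n_images is None:
                n_images = m.shape[0]
            elif m.shape[0] != n_images:
                raise ValueError("all layers must share the image axis")
            self.matrices[name] = m

    @property
    def n_images(self) -> int:
        return self.matrices[self.layer_names[0]].shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """x: (C, H, W) -> (out_h*out_w, C*k*k) patch matrix."""
    x = np.ascontiguousarray(x)
    c, h, w = x.shape
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError("feature map smaller than the kernel; use a larger input")
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, out_h, out_w, k, k),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2]),
    )
    return (
        patches.transpose(1, 2, 0, 3, 4).reshape(out_h * out_w, c * k * k),
        out_h,
        out_w,
    )


def _maxpool(x: np.ndarray, k: int = 2) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // k, w // k
    return x[:, : h2 * k, : w2 * k].reshape(c, h2, k, w2, k).max(axis=(2, 4))


class UntrainedConvNet:
    """Seeded Glorot-initialized convolutional stack (never trained).

    Five convolution stages (ReLU, with max-pooling after stages 1, 2 and
    5) followed by three fully connected stages, mirroring the classic
    eight-layer object-recognition geometry at a reduced input size for
    CPU-friendly inference. Capture points are post-ReLU, flattened.
    """

    conv_cfg = (  # (out_channels, kernel, stride, pad, pool)
        (32, 7, 2, 0, True),
        (64, 5, 1, 2, True),
        (96, 3, 1, 1, False),
        (96, 3, 1, 1, False),
        (64, 3, 1, 1, True),
    )
    fc_sizes = (256, 128, 64)

    def __init__(self, input_size: int = 128, seed: int | None = 0) -> None:
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.conv_weights = []
        c_in = 3
        side = input_size
        for c_out, k, stride, pad, pool in self.conv_cfg:
            fan_in = c_in * k * k
            fan_out = c_out * k * k
            w = _glorot(rng, fan_in, fan_out, (c_in * k * k, c_out))
            self.conv_weights.append(w)
            side = (side + 2 * pad - k) // stride + 1
            if pool:
                side //= 2
            c_in = c_out
        self.fc_weights = []
        d_in = c_in * side * side
        for d_out in self.fc_sizes:
            self.fc_weights.append(_glorot(rng, d_in, d_out, (d_in, d_out)))
            d_in = d_out

    def forward(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """image: (H, W, 3) float in [0, 1] -> flattened activations per layer."""
        x = np.transpose(image, (2, 0, 1)).astype(float)
        acts: dict[str, np.ndarray] = {}
        for i, ((c_out, k, stride, pad, pool), w) in enumerate(
            zip(self.conv_cfg, self.conv_weights)
        ):
            if pad:
                x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
            cols, oh, ow = _im2col(x, k, stride)
            x = np.maximum(cols @ w, 0.0).T.reshape(c_out, oh, ow)
            if pool:
                x = _maxpool(x)
            acts[f"conv{i + 1}"] = x.ravel().copy()
        flat = x.ravel()
        for name, w in zip(("fc6", "fc7", "output"), self.fc_weights):
            flat = flat @ w
            if name != "output":
                flat = np.maximum(flat, 0.0)
            acts[name] = flat.copy()
        return acts


def composite_on_gray(
    image: np.ndarray, mask: np.ndarray | None = None, level: int = GRAY_BACKGROUND
) -> np.ndarray:
    """Place a stimulus on a uniform gray background, scaled to [0, 1]."""
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    out = np.full_like(img, level / 255.0)
    if mask is None:
        mask = img.sum(axis=-1) > 0
    out[mask] = img[mask]
    return out


def default_activation_provider(
    images: list[np.ndarray],
    seed: int | None = 0,
    masks: list[np.ndarray] | None = None,
    input_size: int = 128,
) -> LayerActivations:
    """Activations of the seeded untrained convolutional stack.

    Stimuli are composited on a gray background, resized to the network
    input size, and passed through the frozen Glorot-initialized stack;
    post-ReLU activations are captured at the eight canonical stages.
    """
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("all images must share the same size")
    net = UntrainedConvNet(input_size=input_size, seed=seed)
    rows: dict[str, list[np.ndarray]] = {name: [] for name in DEFAULT_LAYERS}
    for i, img in enumerate(images):
        gray = composite_on_gray(img, None if masks is None else masks[i])
        small = resize(
            gray, (input_size, input_size, 3), anti_aliasing=True, preserve_range=True
        )
        acts = net.forward(small)
        for name in DEFAULT_LAYERS:
            rows[name].append(acts[name])
    return LayerActivations(
        layer_names=DEFAULT_LAYERS,
        matrices={name: np.stack(rows[name]) for name in DEFAULT_LAYERS},
    )


def layer_rsms(
    activations: LayerActivations, labels: list[str] | None = None
) -> list[ModelRSM]:
    """One Pearson-correlation RSM per layer (diagonal exactly 1)."""
    out = []
    for name in activations.layer_names:
        m = activations.matrices[name]
        sd = m.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(
                f"layer {name!r}: constant activation vector for images {bad}"
            )
        r = np.corrcoef(m)
        np.fill_diagonal(r, 1.0)
        out.append(
            ModelRSM(
                name=name,
                family="dnn-layer",
                rsm=RSM(values=(r + r.T) / 2.0, labels=labels, provenance="model"),
            )
        )
    return out


def layerwise_rsa(
    brain_pair_rsms: list,
    layer_model_rsms: list[ModelRSM],
    ceiling: NoiseCeiling | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    ceiling_floor: float = 0.1,
) -> dict[str, dict]:
    """Layer-resolved brain alignment profile.

    For each layer: bootstrap Spearman correlation between the resampled
    group RSM and the layer RSM (diagonal excluded), expressed as a
    proportion of the noise ceiling when the ceiling is reliable.
    """
    from devgeo.inference import normalize_by_ceiling

    profile: dict[str, dict] = {}
    for k, layer in enumerate(layer_model_rsms):
        model_vals = layer.values

        def stat(mean_rsm: np.ndarray, _m=model_vals) -> float:
            return rsa_correlation(mean_rsm, _m, include_diagonal=False)

        res: BootstrapResult = bootstrap_statistic(
            brain_pair_rsms, stat, n_boot=n_boot, seed=None if seed is None else seed + k
        )
        entry = {
            "rho": res.point,
            "ci": res.ci,
            "result": res,
            "rho_normalized": res.point,
            "ceiling_valid": False,
        }
        if ceiling is not None:
            norm, valid = normalize_by_ceiling(res.point, ceiling, floor=ceiling_floor)
            entry["rho_normalized"] = norm
            entry["ceiling_valid"] = valid
        profile[layer.name] = entry
    return profile
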