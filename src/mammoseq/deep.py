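"""Multi-stage pooled CNN features from mammographic ROIs.

The extraction scheme is backbone-agnostic transfer learning: run a VGG-style
convolutional stack, take the output of every max-pooling stage, globally
average-pool it over the spatial dimensions (one value per channel), and
concatenate the stage vectors.  For the VGG-19 layout the stage widths are
(64, 128, 256, 512, 512), so the concatenated descriptor has 1472 entries.

The forward pass is pure NumPy (3x3 "same" convolutions via im2col matmul,
ReLU, 2x2 max pooling).  Weights are either seeded He-normal random draws --
sufficient for the random-projection flavour of pooled-feature transfer
learning and for every test -- or loaded from an ``.npz`` checkpoint of
pretrained convolutional kernels, which is an optional runtime asset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import ROIPatch
from .radiomics import FeatureVector

# conv-layers-per-stage x channels for the supported layouts
_LAYOUTS = {
    "vgg19": {"convs_per_stage": (2, 2, 4, 4, 4),
              "stage_channels": (64, 128, 256, 512, 512)},
    "tiny-test": {"convs_per_stage": (1, 1), "stage_channels": (8, 16)},
}


@dataclass
class BackboneLayout:
    """Architecture description: per-stage channel widths and conv counts."""

    name: str
    stage_channels: tuple[int, ...]
    convs_per_stage: tuple[int, ...]
    weights: str = "random:0"  # "random:<seed>" or a path to an .npz file
    kernels: list[list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=list)

    @property
    def total_features(self) -> int:
        return int(sum(self.stage_channels))


def backbone_layout(name: str, weights: str = "random:0") -> BackboneLayout:
    """Construct a supported backbone: ``vgg19`` or ``tiny-test``.

    ``weights`` is ``"random:<seed>"`` for seeded He-normal initialization or
    the path of an ``.npz`` file holding arrays ``w_<s>_<k>`` (out, in, 3, 3)
    and ``b_<s>_<k>`` per stage ``s`` / conv ``k``.
    """
    if name not in _LAYOUTS:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(_LAYOUTS)}")
    spec = _LAYOUTS[name]
    layout = BackboneLayout(
        name=name,
        stage_channels=tuple(spec["stage_channels"]),
        convs_per_stage=tuple(spec["convs_per_stage"]),
        weights=weights,
    )
    layout.kernels = _build_kernels(layout)
    return layout


def _build_kernels(layout: BackboneLayout):
    if layout.weights.startswith("random:"):
        seed = int(layout.weights.split(":", 1)[1])
        rng = np.random.default_rng(seed)
        loader = None
    else:
        rng = None
        loader = np.load(layout.weights)
    kernels = []
    c_in = 3
    for s, (n_conv, c_out) in enumerate(
        zip(layout.convs_per_stage, layout.stage_channels)
    ):
        stage = []
        for k in range(n_conv):
            if loader is None:
                fan_in = c_in * 9
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
                b = np.zeros(c_out)
            else:
                try:
                    w = loader[f"w_{s}_{k}"]
                    b = loader[f"b_{s}_{k}"]
                except KeyError as exc:
                    raise ValueError(
                        f"weight file {layout.weights!r} lacks arrays for "
                        f"stage {s} conv {k}"
                    ) from exc
                if w.shape != (c_out, c_in, 3, 3):
                    raise ValueError(
                        f"weight/architecture mismatch at stage {s} conv {k}: "
                        f"expected {(c_out, c_in, 3, 3)}, got {w.shape}"
                    )
            stage.append((w.astype(np.float32), b.astype(np.float32)))
            c_in = c_out
        kernels.append(stage)
    return kernels


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(roi, target_size: int | None = None) -> np.ndarray:
    """ROI -> (3, H, W) float32 input tensor.

    Intensity is min-max rescaled to [0, 1] on the ROI's own range and
    replicated to three identical channels.  ``target_size`` optionally
    resizes (anti-aliased) to the backbone's nominal square input; ``None``
    keeps the native resolution for a fully convolutional pass.  A constant
    ROI maps to all zeros with a warning.
    """
    arr = roi.intensities if isinstance(roi, ROIPatch) else np.asarray(roi, float)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        warnings.warn("constant ROI: deep-feature input is all zeros")
        arr = np.zeros_like(arr)
    if target_size is not None and arr.shape != (target_size, target_size):
        from skimage.transform import resize

        arr = resize(arr, (target_size, target_size), anti_aliasing=True)
    x = arr.astype(np.float32)
    return np.stack([x, x, x])


# ---------------------------------------------------------------------------
# NumPy forward pass
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' 3x3 convolution (cross-correlation) via im2col matmul."""
    c_in, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    # columns: (h*w, c_in*9)
    cols = np.empty((h * wd, c_in * 9), dtype=np.float32)
    idx = 0
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + h, dj : dj + wd]
            cols[:, idx * c_in : (idx + 1) * c_in] = patch.reshape(c_in, -1).T
            idx += 1
    wmat = w.transpose(2, 3, 1, 0).reshape(9 * c_in, -1).astype(np.float32)
    out = cols @ wmat + b.astype(np.float32)
    return out.T.reshape(w.shape[0], h, wd)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def extract_deep(roi, layout: BackboneLayout, target_size: int | None = None) -> FeatureVector:
    """Forward the ROI through the backbone and pool every stage output.

    At each stage: conv(3x3)+ReLU blocks, then 2x2 max pooling; the pooled
    stage output is globally average-pooled over space, giving one value per
    channel.  Stage vectors are concatenated in order; the result has
    ``layout.total_features`` entries and is deterministic given the weights.
    """
    x = preprocess(roi, target_size=target_size)
    pooled = []
    for stage in layout.kernels:
        for w, b in stage:
            x = _conv3x3(x, w, b)
            np.maximum(x, 0.0, out=x)  # ReLU
        x = _maxpool2(x)
        pooled.append(x.mean(axis=(1, 2)))
    values = np.concatenate(pooled).astype(float)
    names = tuple(
        f"{layout.name}_s{s}_c{c}"
        for s, width in enumerate(layout.stage_channels)
        for c in range(width)
    )
    cats = tuple(f"cnn_stage{s}" for s, width in enumerate(layout.stage_channels)
                 for _ in range(width))
    return FeatureVector(values, names, cats)
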