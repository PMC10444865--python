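"""Per-cell preprocessing, convolutional features, and MIL aggregation.

Each nucleus D image is cropped to its mask, min-max normalized to [0, 1],
resized to a fixed input size and pushed through a VGG16-layout stack of
3x3 convolutions with ReLU and 2x2 max pooling.  Per-channel global average
pooling at the final convolution of blocks 2-5 gives a multi-scale cell
descriptor (k = 128+256+512+512 = 1408 at full width); the patient-level
vector is the elementwise mean and sample standard deviation of the cell
descriptors — instance-level multiple-instance aggregation against
patient-level ground truth.

The default ``seeded_random`` weight mode uses He-initialized random filters
(deterministic given the seed): random convolutional projections preserve the
coarse intensity and texture statistics the downstream panel selection needs,
and require no external weight files.  ``pretrained`` loads user-supplied
weights from an .npz archive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "VGG16_BLOCKS",
    "PreprocConfig",
    "BackboneSpec",
    "Backbone",
    "CellFeatures",
    "PatientFeatureVector",
    "preprocess_nucleus",
    "preprocess_nucleus_with_support",
    "make_backbone",
    "extract_cell_features",
    "aggregate_patient",
    "cohort_feature_matrix",
]

#: Channel widths of the five VGG16 convolution blocks.
VGG16_BLOCKS: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256),
    (512, 512, 512),
    (512, 512, 512),
)


@dataclass(frozen=True)
class PreprocConfig:
    """Nucleus preprocessing: crop -> min-max normalize -> resize."""

    target_size: tuple[int, int] = (224, 224)
    background_fill: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BackboneSpec:
    """VGG16-layout conv stacks with taps at the final conv of blocks 2-5.

    ``width_scale`` shrinks every block width (minimum 1 channel) for
    cheaper runs; tap points and layout are fixed.  ``seeded_random`` weights
    are deterministic given ``seed``; ``pretrained`` requires ``weights_path``
    (an .npz with arrays ``W{i}`` of shape (3, 3, c_in, c_out) per conv layer,
    in block order).
    """

    tap_blocks: tuple[int, ...] = (2, 3, 4, 5)
    weights_mode: str = "seeded_random"
    seed: int = 0
    width_scale: float = 1.0
    weights_path: str | None = None
    pooling: str = "masked_gap"
    #: scale of the random per-channel biases (seeded_random mode).  Biases
    #: act as soft activation thresholds, making the pooled channel means
    #: sensitive to the shape (quantiles, skew) of the intensity
    #: distribution, not just its first moments; 0 gives a zero-bias stack.
    bias_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.weights_mode not in ("seeded_random", "pretrained"):
            raise ValueError("weights_mode must be seeded_random or pretrained")
        if self.pooling not in ("masked_gap", "gap", "flatten"):
            raise ValueError("pooling must be masked_gap, gap or flatten")
        if not set(self.tap_blocks) <= {1, 2, 3, 4, 5}:
            raise ValueError("tap_blocks must be within blocks 1-5")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    @property
    def block_widths(self) -> tuple[tuple[int, ...], ...]:
        return tuple(
            tuple(max(1, int(round(c * self.width_scale))) for c in blk)
            for blk in VGG16_BLOCKS
        )

    @property
    def feature_length(self) -> int:
        """k for the pooled modes: sum of tapped final-conv channel counts.

        In ``flatten`` mode the per-cell length additionally scales with the
        tap-resolution pixel counts (input-size dependent, ~1e5-1e6 at full
        width), which is why pooling is the default.
        """
        widths = self.block_widths
        return int(sum(widths[b - 1][-1] for b in self.tap_blocks))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Backbone:
    spec: BackboneSpec
    weights: list  # per conv layer, float32 (3, 3, c_in, c_out)
    biases: list  # per conv layer, float32 (c_out,)


@dataclass
class CellFeatures:
    values: np.ndarray  # (k,)


@dataclass
class PatientFeatureVector:
    values: np.ndarray  # (2k,) = [means, sample stds]
    n_cells: int


def preprocess_nucleus(
    d_image: np.ndarray, mask: np.ndarray, cfg: PreprocConfig | None = None
) -> np.ndarray:
    """Crop to the mask bounding box, min-max normalize, resize bilinearly.

    In-mask values map onto [0, 1]; a constant nucleus maps to 0.5 by
    convention; background pixels take ``background_fill``.
    """
    cfg = cfg or PreprocConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(d_image, dtype=np.float64)
    vals = img[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite in-mask values")
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    crop = img[y0:y1, x0:x1]
    mcrop = mask[y0:y1, x0:x1]
    lo, hi = vals.min(), vals.max()
    out = np.full(crop.shape, cfg.background_fill, dtype=np.float64)
    if hi > lo:
        out[mcrop] = (crop[mcrop] - lo) / (hi - lo)
    else:
        out[mcrop] = 0.5
    resized = resize(
        out, cfg.target_size, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return resized.astype(np.float32)


def preprocess_nucleus_with_support(
    d_image: np.ndarray, mask: np.ndarray, cfg: PreprocConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed image plus the nucleus support resampled to target size.

    The support (mask resized with the same bilinear geometry, thresholded
    at 0.5) is what masked pooling averages over.
    """
    cfg = cfg or PreprocConfig()
    img = preprocess_nucleus(d_image, mask, cfg)
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    crop = mask[ys.min(): ys.max() + 1, xs.min(): xs.max() + 1].astype(np.float64)
    support = resize(
        crop, cfg.target_size, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return img, support >= 0.5


def make_backbone(spec: BackboneSpec) -> Backbone:
    """Instantiate conv weights and biases (He init for seeded_random)."""
    widths = spec.block_widths
    weights: list[np.ndarray] = []
    biases: list[np.ndarray] = []
    if spec.weights_mode == "pretrained":
        if not spec.weights_path:
            raise ValueError(
                "pretrained weights_mode requires weights_path pointing to an "
                ".npz archive of conv kernels (external download; not bundled)"
            )
        archive = np.load(spec.weights_path)
        c_in = 3
        i = 0
        for blk in widths:
            for c_out in blk:
                w = np.asarray(archive[f"W{i}"], dtype=np.float32)
                if w.shape != (3, 3, c_in, c_out):
                    raise ValueError(
                        f"W{i} has shape {w.shape}, expected {(3, 3, c_in, c_out)}"
                    )
                weights.append(w)
                if f"b{i}" in archive:
                    biases.append(np.asarray(archive[f"b{i}"], dtype=np.float32))
                else:
                    biases.append(np.zeros(c_out, dtype=np.float32))
                c_in = c_out
                i += 1
        return Backbone(spec=spec, weights=weights, biases=biases)
    rng = np.random.default_rng(spec.seed)
    c_in = 3
    for blk in widths:
        for c_out in blk:
            std = np.sqrt(2.0 / (9 * c_in))
            weights.append(
                (rng.standard_normal((3, 3, c_in, c_out)) * std).astype(np.float32)
            )
            biases.append(
                (rng.standard_normal(c_out) * spec.bias_scale).astype(np.float32)
            )
            c_in = c_out
    return Backbone(spec=spec, weights=weights, biases=biases)


def _conv3x3_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution + bias + ReLU via im2col GEMM. x: (H, W, C)."""
    h, wd, c = x.shape
    pad = np.zeros((h + 2, wd + 2, c), dtype=np.float32)
    pad[1:-1, 1:-1] = x
    win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3), axis=(0, 1))
    # win: (H, W, C, 3, 3) -> columns (H*W, 3*3*C) matching w reshape order
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, 9 * c)
    out = cols @ w.reshape(9 * w.shape[2], w.shape[3])
    out += b[None, :]
    np.maximum(out, 0.0, out=out)
    return out.reshape(h, wd, w.shape[3])


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    x = x[: h2 * 2, : w2 * 2]
    return x.reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


def extract_cell_features(
    image: np.ndarray, backbone: Backbone, support: np.ndarray | None = None
) -> CellFeatures:
    """Forward pass; per-channel global average pooling at each tap block.

    With ``pooling == "masked_gap"`` (default) and a ``support`` mask, the
    per-channel average is taken over the nucleus support (downsampled to
    each tap resolution) instead of the whole frame, so the pooled features
    reflect chromatin texture rather than the nucleus fill factor, which
    varies with ellipse shape and orientation.  Without a support, or with
    ``pooling == "gap"``, plain frame-wide pooling is used.
    """
    spec = backbone.spec
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    masked = spec.pooling == "masked_gap" and support is not None
    if masked:
        sup = np.asarray(support, dtype=np.float32)
        if sup.shape != img.shape:
            raise ValueError("support must match the image shape")
    # grayscale replicated across the three input channels of the VGG layout
    x = np.repeat(img[:, :, None], 3, axis=2)
    taps: list[np.ndarray] = []
    li = 0
    for b, blk in enumerate(spec.block_widths, start=1):
        for _ in blk:
            x = _conv3x3_relu(x, backbone.weights[li], backbone.biases[li])
            li += 1
        if b in spec.tap_blocks:
            if spec.pooling == "flatten":
                taps.append(x.reshape(-1).astype(np.float64))
            elif masked:
                wsum = float(sup.sum())
                if wsum == 0.0:
                    taps.append(x.mean(axis=(0, 1)))
                else:
                    taps.append(
                        np.tensordot(sup, x, axes=([0, 1], [0, 1])) / wsum
                    )
            else:
                taps.append(x.mean(axis=(0, 1)))
        x = _maxpool2(x)
        if masked:
            sup = _maxpool2(sup[:, :, None])[:, :, 0]
    return CellFeatures(values=np.concatenate(taps).astype(np.float64))


def aggregate_patient(cell_features: list) -> PatientFeatureVector:
    """MIL aggregation: elementwise mean then sample std (ddof=1) across cells."""
    if len(cell_features) < 2:
        raise ValueError("need at least 2 cells for the std block")
    mat = np.stack(
        [cf.values if isinstance(cf, CellFeatures) else np.asarray(cf)
         for cf in cell_features]
    )
    return PatientFeatureVector(
        values=np.concatenate([mat.mean(axis=0), mat.std(axis=0, ddof=1)]),
        n_cells=mat.shape[0],
    )


def cohort_feature_matrix(
    manifest,
    spec,
    backbone_spec: BackboneSpec | None = None,
    preproc: PreprocConfig | None = None,
    qc_config=None,
):
    """Patient feature matrix for an in-memory synthetic cohort.

    Renders each patient's cells, applies QC to the generator masks, and
    aggregates per-patient descriptors.  Returns (X, y, patient_ids) with y
    = 1 for cases.  Patients with < 2 kept cells are dropped.
    """
    from .cohort import render_patient_cells
    from .segmentation import qc_filter

    backbone = make_backbone(backbone_spec or BackboneSpec())
    rows, labels, ids = [], [], []
    for rec in manifest.patients:
        feats = []
        for _, dimg, mask in render_patient_cells(rec, spec):
            if not qc_filter(mask, qc_config).keep:
                continue
            img, support = preprocess_nucleus_with_support(dimg.d, mask, preproc)
            feats.append(extract_cell_features(img, backbone, support))
        if len(feats) < 2:
            continue
        rows.append(aggregate_patient(feats).values)
        labels.append(1 if rec.group == "case" else 0)
        ids.append(rec.patient_id)
    return np.asarray(rows), np.asarray(labels), ids
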