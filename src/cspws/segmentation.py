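"""Nucleus mask handling and cell-level quality control.

The clinical protocol uses manual, blinded nucleus selection; this module
provides an automated surrogate for synthetic images (global Otsu threshold,
hole filling, connected components) and makes the shape-based exclusion of
deformed cells explicit and configurable.  Externally supplied masks (the
manual path) are first-class: ``qc_filter`` operates on any boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["QCConfig", "CellQC", "segment_nuclei", "qc_filter"]


@dataclass(frozen=True)
class QCConfig:
    """Shape thresholds for keeping a cell; defaults match the generator's
    nucleus geometry with comfortable margins."""

    area_min_px: int = 300
    area_max_px: int = 200_000
    eccentricity_max: float = 0.95
    solidity_min: float = 0.90


@dataclass
class CellQC:
    area_px: int
    eccentricity: float
    solidity: float
    touches_border: bool
    keep: bool
    reject_reason: str = ""


def segment_nuclei(image: np.ndarray, min_area_px: int = 100) -> list[np.ndarray]:
    """Otsu threshold + hole filling + connected components.

    NaN background (as written by the cohort generator) is treated as zero.
    Returns one boolean mask per component above ``min_area_px``; an image
    with nothing to segment yields an empty list, not an error.
    """
    img = np.asarray(image, dtype=np.float64)
    img = np.where(np.isfinite(img), img, 0.0)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return []
    thr = threshold_otsu(img)
    binary = img > thr
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)
    labels = label(binary)
    masks = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if int(m.sum()) >= min_area_px:
            masks.append(m)
    return masks


def qc_filter(mask: np.ndarray, config: QCConfig | None = None) -> CellQC:
    """Shape-based keep/reject verdict for one nucleus mask.

    Keep iff area within bounds, eccentricity <= max, solidity >= min and
    the mask does not touch the image border.  A pure function of the mask.
    """
    config = config or QCConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = int(props.area)
    ecc = float(props.eccentricity)
    sol = float(props.solidity)
    border = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    reasons = []
    if border:
        reasons.append("border")
    if not (config.area_min_px <= area <= config.area_max_px):
        reasons.append("area")
    if ecc > config.eccentricity_max:
        reasons.append("eccentricity")
    if sol < config.solidity_min:
        reasons.append("solidity")
    return CellQC(
        area_px=area,
        eccentricity=ecc,
        solidity=sol,
        touches_border=border,
        keep=not reasons,
        reject_reason=";".join(reasons),
    )
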