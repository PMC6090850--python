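"""Nuclear morphometry from two-channel fluorescence images.

Nuclei are segmented from the DNA channel by a global intensity threshold
and connected-component labeling (8-connectivity); components smaller than
a minimum pixel area are discarded as debris.  Dead cells, identified by
their mean intensity in a co-registered viability-stain channel, are
excluded, and pixel areas are converted to square microns with the
microscope's pixel size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledObjects",
    "segment_nuclei",
    "exclude_dead",
    "areas_um2",
    "otsu_threshold",
]

#: default physical pixel size of the imaging setup, microns per pixel
DEFAULT_PIXEL_SIZE_UM = 0.4389


@dataclass
class LabeledObjects:
    """Segmented nuclei: per-object measurements plus the label image."""

    table: pd.DataFrame          # label, area_px, centroid_r, centroid_c [, ...]
    label_image: np.ndarray
    min_area_px: int

    def __len__(self) -> int:
        return len(self.table)


def otsu_threshold(image: np.ndarray) -> float:
    """Automatic global threshold (Otsu); convenience, not part of the
    core procedure, which takes an explicit threshold."""
    return float(threshold_otsu(np.asarray(image)))


def segment_nuclei(
    image: np.ndarray,
    intensity_threshold: float,
    min_area_px: int = 100,
    connectivity: int = 2,
) -> LabeledObjects:
    """Segment nuclei above an intensity threshold, dropping small debris.

    Connected components (8-connected by default) of pixels strictly above
    ``intensity_threshold`` are measured; components with pixel area below
    ``min_area_px`` are discarded (the bound is inclusive: an object of
    exactly ``min_area_px`` pixels is retained).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    mask = image > intensity_threshold
    if not mask.any():
        warnings.warn("threshold above image maximum: no objects", stacklevel=2)
        return LabeledObjects(
            pd.DataFrame(columns=["label", "area_px", "centroid_r", "centroid_c"]),
            np.zeros(image.shape, dtype=int),
            min_area_px,
        )
    labels = measure.label(mask, connectivity=connectivity)
    props = measure.regionprops_table(labels, properties=("label", "area", "centroid"))
    table = pd.DataFrame(props).rename(
        columns={"area": "area_px", "centroid-0": "centroid_r", "centroid-1": "centroid_c"}
    )
    table["area_px"] = table["area_px"].astype(int)
    small = table["area_px"] < min_area_px
    if small.any():
        logger.info("discarded %d objects below %d px", int(small.sum()), min_area_px)
        for lbl in table.loc[small, "label"]:
            labels[labels == lbl] = 0
        table = table[~small].reset_index(drop=True)
    return LabeledObjects(table, labels, min_area_px)


def exclude_dead(
    objects: LabeledObjects,
    viability_image: np.ndarray,
    viability_threshold: float,
) -> LabeledObjects:
    """Remove objects positive for the viability (dead-cell) stain.

    An object is dead if its mean intensity in the co-registered viability
    channel exceeds the threshold.  The returned table carries a ``dead``
    column on the survivors (all False) and the label image keeps only
    live objects.
    """
    viability_image = np.asarray(viability_image)
    if viability_image.shape != objects.label_image.shape:
        raise ValueError("viability image shape does not match the nuclear image")
    table = objects.table.copy()
    if table.empty:
        table["mean_viability"] = pd.Series(dtype=float)
        table["dead"] = pd.Series(dtype=bool)
        return LabeledObjects(table, objects.label_image.copy(), objects.min_area_px)
    means = []
    for lbl in table["label"]:
        means.append(float(viability_image[objects.label_image == lbl].mean()))
    table["mean_viability"] = means
    table["dead"] = table["mean_viability"] > viability_threshold
    labels = objects.label_image.copy()
    for lbl in table.loc[table["dead"], "label"]:
        labels[labels == lbl] = 0
    live = table[~table["dead"]].reset_index(drop=True)
    return LabeledObjects(live, labels, objects.min_area_px)


def areas_um2(
    objects: LabeledObjects | pd.DataFrame,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> pd.Series:
    """Convert per-object pixel areas to square microns."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    table = objects.table if isinstance(objects, LabeledObjects) else objects
    return table["area_px"] * pixel_size_um**2
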