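"""Image-to-table quantification of presynaptic puncta.

Mirrors the standard punctum workflow for two-channel confocal stacks:
maximum-intensity z-projection, automatic (isodata/intermeans) threshold on
the RFP channel, particle analysis of the binary mask (8-connected), an area
floor to reject sub-resolution specks, and per-ROI mean intensities measured
on both channels from the same ROI. Background autofluorescence is estimated
by translating the punctum ROIs to a position adjacent to the synapses on the
GFP channel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .stack import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "PunctumMeasurement",
    "BackgroundEstimate",
    "max_project",
    "isodata_threshold",
    "detect_puncta",
    "estimate_background",
    "quantify_stack",
    "measurements_to_frame",
]


@dataclass
class PunctumMeasurement:
    """One segmented punctum measured on both channels from the same ROI."""

    punctum_id: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y), 0-based pixel origin
    position_norm: float  # 0 = proximal end of the presynaptic region
    mean_rfp: float
    mean_gfp: float

    @property
    def ratio(self) -> float:
        return self.mean_gfp / self.mean_rfp


@dataclass
class BackgroundEstimate:
    """GFP autofluorescence measured in shifted punctum ROIs."""

    mean_gfp_bg: float
    ci95: tuple[float, float]
    n_rois: int
    normalized_value: float | None = None


def max_project(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise maximum over z for each channel -> (rfp_2d, gfp_2d)."""
    if stack.data.shape[1] < 1:
        raise ValueError("stack has no z-planes")
    proj = stack.data.max(axis=1)
    return proj[0], proj[1]


def isodata_threshold(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Iterative-intermeans (isodata) threshold and the strictly-above mask.

    This is the default automatic threshold of common image software: the
    fixed point of t <- (mean below t + mean above t) / 2.
    """
    image = np.asarray(image)
    if np.unique(image).size < 2:
        raise ValueError("no threshold exists: image has a single intensity value")
    t = float(skfilters.threshold_isodata(image))
    return t, image > t


def detect_puncta(
    mask: np.ndarray,
    rfp_img: np.ndarray,
    gfp_img: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.1,
    region_bounds: tuple[float, float] | None = None,
) -> tuple[list[PunctumMeasurement], np.ndarray]:
    """Particle analysis of the RFP-derived mask.

    8-connected components with area strictly below ``min_area_um2`` are
    discarded; each surviving component is measured on both channels using
    the identical ROI. ``region_bounds`` (x_start_um, x_end_um), half-open,
    delimits the presynaptic region for the normalized axial position;
    defaults to the full image width. Returns the measurements and the label
    image of retained components (labels match ``punctum_id``).
    """
    labels = skmeasure.label(mask, connectivity=2)
    px_area = pixel_size_um * pixel_size_um
    if region_bounds is None:
        region_bounds = (0.0, mask.shape[1] * pixel_size_um)
    x0, x1 = region_bounds
    if x1 <= x0:
        raise ValueError("region_bounds must satisfy x_end > x_start")
    keep = np.zeros_like(labels)
    out: list[PunctumMeasurement] = []
    next_id = 0
    for region in skmeasure.regionprops(labels, intensity_image=rfp_img):
        area = region.area * px_area
        if area < min_area_um2:  # strictly-below filter
            continue
        coords = tuple(region.coords.T)
        mean_rfp = float(rfp_img[coords].mean())
        if mean_rfp == 0.0:
            logger.warning("component at %s has zero RFP mean; dropped", region.centroid)
            continue
        mean_gfp = float(gfp_img[coords].mean())
        cy, cx = region.centroid
        cx_um, cy_um = cx * pixel_size_um, cy * pixel_size_um
        pos = min(max((cx_um - x0) / (x1 - x0), 0.0), 1.0)
        next_id += 1
        keep[labels == region.label] = next_id
        out.append(
            PunctumMeasurement(
                punctum_id=next_id,
                area_um2=area,
                centroid_um=(cx_um, cy_um),
                position_norm=pos,
                mean_rfp=mean_rfp,
                mean_gfp=mean_gfp,
            )
        )
    return out, keep


def estimate_background(
    gfp_img: np.ndarray,
    punctum_labels: np.ndarray,
    pixel_size_um: float,
    shift_um: float | None = None,
    normalizer: float | None = None,
) -> BackgroundEstimate:
    """GFP autofluorescence from punctum ROIs shifted off the axon.

    Each punctum ROI is translated perpendicular to the axon axis (+y) by
    ``shift_um`` (default: twice the median punctum diameter). A shifted ROI
    that leaves the image or lands on any punctum pixel is re-shifted once by
    a further ``shift_um``; if that also fails it is excluded with a warning.
    The estimate is the mean of per-ROI means with a 95% t-interval.
    ``normalizer`` (e.g. the control-cohort mean ratio denominator) converts
    the estimate to the normalized-ratio scale.
    """
    ids = [int(i) for i in np.unique(punctum_labels) if i != 0]
    if not ids:
        raise ValueError("no punctum ROIs to shift")
    if shift_um is None:
        areas = [(punctum_labels == i).sum() * pixel_size_um**2 for i in ids]
        diam = 2.0 * math.sqrt(np.median(areas) / math.pi)
        shift_um = 2.0 * diam
    dy = max(1, round(shift_um / pixel_size_um))
    ny = gfp_img.shape[0]
    occupied = punctum_labels > 0
    means = []
    failed = []
    for i in ids:
        ys, xs = np.nonzero(punctum_labels == i)
        placed = False
        for k in (1, 2):  # shift, then one re-shift
            ys2 = ys + k * dy
            if ys2.max() >= ny:
                continue
            if occupied[ys2, xs].any():
                continue
            means.append(float(gfp_img[ys2, xs].mean()))
            placed = True
            break
        if not placed:
            failed.append(i)
    if not means:
        raise ValueError(
            f"all shifted ROIs collide with puncta or leave the image: {failed}"
        )
    if failed:
        logger.warning("background ROIs excluded after re-shift failure: %s", failed)
    means = np.asarray(means)
    m = float(means.mean())
    if means.size > 1 and means.std(ddof=1) > 0:
        half = sps.t.ppf(0.975, means.size - 1) * means.std(ddof=1) / math.sqrt(means.size)
    else:
        half = 0.0
    return BackgroundEstimate(
        mean_gfp_bg=m,
        ci95=(m - half, m + half),
        n_rois=len(means),
        normalized_value=(m / normalizer) if normalizer else None,
    )


def quantify_stack(
    stack: ImageStack,
    min_area_um2: float = 0.1,
    region_bounds: tuple[float, float] | None = None,
) -> tuple[list[PunctumMeasurement], dict]:
    """Project, threshold (RFP), and measure puncta; returns (puncta, QC).

    QC records the threshold used and component counts before/after the
    area filter so every filtering step is auditable.
    """
    rfp, gfp = max_project(stack)
    threshold, mask = isodata_threshold(rfp)
    n_components = int(skmeasure.label(mask, connectivity=2).max())
    puncta, labels = detect_puncta(
        mask, rfp, gfp, stack.pixel_size_um, min_area_um2, region_bounds
    )
    qc = {
        "threshold": threshold,
        "n_components": n_components,
        "n_puncta": len(puncta),
        "min_area_um2": min_area_um2,
    }
    return puncta, qc


def measurements_to_frame(
    puncta: list[PunctumMeasurement],
    animal_id: str,
    neuron_class: str,
    age_days: float,
    treatment: str,
    pulse_age: float | None = None,
) -> pd.DataFrame:
    """Punctum measurements as rows of the shared cohort-table schema."""
    rows = [
        {
            "animal_id": animal_id,
            "neuron_class": neuron_class,
            "age_days": age_days,
            "treatment": treatment,
            "pulse_age": float("nan") if pulse_age is None else pulse_age,
            "punctum_index": p.punctum_id,
            "area_um2": p.area_um2,
            "position_norm": p.position_norm,
            "mean_rfp": p.mean_rfp,
            "mean_gfp": p.mean_gfp,
            "ratio": p.ratio,
        }
        for p in puncta
    ]
    return pd.DataFrame(rows)
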