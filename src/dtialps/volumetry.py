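"""Tumor-compartment volumetry by slice summation and ROI subtraction.

Volumes follow the planimetric convention: per-slice area (pixel count x
in-plane pixel area) times the slice distance (thickness + gap), summed over
slices.  Peritumoral edema is the outer (edema+tumor) region minus the whole
tumor; enhancing tumor is the whole tumor minus the non-enhancing, necrotic
and hemorrhagic subcompartments — both identities hold exactly by
construction of the label scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import TUMOR_LABELS

__all__ = [
    "CompartmentVolumes",
    "slice_volume",
    "compartment_volumes",
    "filter_min_lesion",
    "select_hemisphere",
]

# 8-connectivity in-plane (x, y), face-connectivity across slices (z)
_LESION_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_LESION_STRUCTURE[:, :, 1] = True
_LESION_STRUCTURE[1, 1, :] = True

_TUMOR_VALUES = (
    TUMOR_LABELS["enhancing"],
    TUMOR_LABELS["non_enhancing"],
    TUMOR_LABELS["necrotic"],
    TUMOR_LABELS["hemorrhagic"],
)


@dataclass(frozen=True)
class CompartmentVolumes:
    """Compartment volumes in cm^3."""

    edema_cm3: float
    whole_tumor_cm3: float
    enhancing_cm3: float
    non_enhancing_cm3: float
    necrotic_cm3: float
    hemorrhagic_cm3: float

    def __post_init__(self) -> None:
        for k, v in self.as_dict().items():
            if v < -1e-12:
                raise ValueError(f"{k} is negative ({v})")

    def as_dict(self) -> dict[str, float]:
        return {
            "edema_cm3": self.edema_cm3,
            "whole_tumor_cm3": self.whole_tumor_cm3,
            "enhancing_cm3": self.enhancing_cm3,
            "non_enhancing_cm3": self.non_enhancing_cm3,
            "necrotic_cm3": self.necrotic_cm3,
            "hemorrhagic_cm3": self.hemorrhagic_cm3,
        }

    @property
    def outer_cm3(self) -> float:
        """Edema + whole tumor: the outer envelope volume."""
        return self.edema_cm3 + self.whole_tumor_cm3


def slice_volume(area_mm2: float, slice_thickness_mm: float, slice_gap_mm: float = 0.0) -> float:
    """One slice's ROI volume in mm^3: area x (thickness + gap)."""
    if area_mm2 < 0:
        raise ValueError("area must be >= 0")
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be > 0")
    if slice_gap_mm < 0:
        raise ValueError("slice gap must be >= 0")
    return area_mm2 * (slice_thickness_mm + slice_gap_mm)


def compartment_volumes(
    labels: np.ndarray,
    pixel_size_mm: tuple[float, float] = (2.0, 2.0),
    slice_thickness_mm: float = 2.0,
    slice_gap_mm: float = 0.0,
) -> CompartmentVolumes:
    """Sum per-slice compartment volumes from a nested label volume.

    ``labels`` uses the scheme of :data:`dtialps.phantom.TUMOR_LABELS`, where
    each voxel carries its innermost compartment; nesting is therefore
    guaranteed by representation and only unknown label values can be
    rejected.  Slices are indexed along the last axis.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label volume must be 3-D")
    known = set(TUMOR_LABELS.values())
    present = set(np.unique(labels).tolist())
    if not present <= known:
        raise ValueError(f"unknown label value(s) {sorted(present - known)}")

    px_area = float(pixel_size_mm[0]) * float(pixel_size_mm[1])
    vols_mm3: dict[str, float] = {}
    for name in ("edema", "enhancing", "non_enhancing", "necrotic", "hemorrhagic"):
        val = TUMOR_LABELS[name]
        per_slice_counts = (labels == val).sum(axis=(0, 1))
        vols_mm3[name] = sum(
            slice_volume(int(c) * px_area, slice_thickness_mm, slice_gap_mm)
            for c in per_slice_counts
        )
    whole = (
        vols_mm3["enhancing"]
        + vols_mm3["non_enhancing"]
        + vols_mm3["necrotic"]
        + vols_mm3["hemorrhagic"]
    )
    return CompartmentVolumes(
        edema_cm3=vols_mm3["edema"] / 1000.0,
        whole_tumor_cm3=whole / 1000.0,
        enhancing_cm3=vols_mm3["enhancing"] / 1000.0,
        non_enhancing_cm3=vols_mm3["non_enhancing"] / 1000.0,
        necrotic_cm3=vols_mm3["necrotic"] / 1000.0,
        hemorrhagic_cm3=vols_mm3["hemorrhagic"] / 1000.0,
    )


def filter_min_lesion(
    labels: np.ndarray,
    min_area_cm2: float = 1.0,
    pixel_size_mm: tuple[float, float] = (2.0, 2.0),
) -> np.ndarray:
    """Drop lesions no larger than ``min_area_cm2`` in any single slice.

    A lesion is a connected component of non-background labels (8-connected
    in-plane, face-connected across slices).  A component is retained only if
    its maximal in-plane area on some slice is strictly greater than the
    threshold ("larger than 1 x 1 cm"), and removed (set to background)
    otherwise.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    fg = labels > 0
    comp, n = ndimage.label(fg, structure=_LESION_STRUCTURE)
    px_area_cm2 = float(pixel_size_mm[0]) * float(pixel_size_mm[1]) / 100.0
    for ci in range(1, n + 1):
        mask = comp == ci
        max_area = mask.sum(axis=(0, 1)).max() * px_area_cm2
        if not max_area > min_area_cm2:
            out[mask] = 0
    return out


def select_hemisphere(labels: np.ndarray, midline_x: int | None = None) -> str:
    """Hemisphere carrying the larger tumor: 'left' (x < midline) or 'right'.

    Ties go to 'left' with a warning (the choice is arbitrary).  Raises if no
    tumor voxels are present.
    """
    labels = np.asarray(labels)
    if midline_x is None:
        midline_x = labels.shape[0] // 2
    tumor = np.isin(labels, _TUMOR_VALUES)
    if not tumor.any():
        raise ValueError("no tumor voxels in label volume")
    xs = np.nonzero(tumor)[0]
    n_left = int((xs < midline_x).sum())
    n_right = int((xs >= midline_x).sum())
    if n_left == n_right:
        warnings.warn("equal tumor volume in both hemispheres; choosing left", stacklevel=2)
        return "left"
    return "left" if n_left > n_right else "right"
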