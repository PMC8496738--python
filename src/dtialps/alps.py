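"""The ALPS index: diffusivity along perivascular spaces, normalized.

At the level of the lateral-ventricle body, perivascular spaces of the
medullary veins run left-right (x), perpendicular both to the adjacent
projection fibers (craniocaudal, z) and to the association fibers lateral to
them (anterior-posterior, y).  The index is the ratio

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

of the mean x-axis diffusivity in the two fiber ROIs to the mean diffusivity
perpendicular to both the x-axis and each fiber's own axis.  Unity means no
preferential perivascular diffusion; glymphatic impairment lowers the index.

All diffusivities are raw tensor-diagonal elements (Dxx/Dyy/Dzz), not
eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tensorfit import TensorVolume

__all__ = [
    "ALPSMeasurement",
    "roi_diffusivities",
    "compute_alps",
    "measure_alps",
    "merge_observers",
    "mean_of_indices",
    "suggest_rois",
]


@dataclass(frozen=True)
class ALPSMeasurement:
    """The four ROI-mean axis diffusivities (mm^2/s) and their ALPS ratio."""

    d_x_proj: float
    d_x_assoc: float
    d_y_proj: float
    d_z_assoc: float
    alps_index: float
    roi_size_proj: int  # voxels
    roi_size_assoc: int
    side: str = "left"
    slice_index: int = -1

    def __post_init__(self) -> None:
        vals = (self.d_x_proj, self.d_x_assoc, self.d_y_proj, self.d_z_assoc)
        if any(not (v > 0) for v in vals):
            raise ValueError(f"all four diffusivities must be positive, got {vals}")
        if self.roi_size_proj <= 0 or self.roi_size_assoc <= 0:
            raise ValueError("ROI sizes must be positive")
        expect = compute_alps(*vals)
        if not np.isclose(self.alps_index, expect, rtol=1e-12, atol=0):
            raise ValueError(
                f"alps_index {self.alps_index} inconsistent with diffusivities ({expect})"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


def compute_alps(
    d_x_proj: float, d_x_assoc: float, d_y_proj: float, d_z_assoc: float
) -> float:
    """mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc); inputs must be > 0."""
    vals = (d_x_proj, d_x_assoc, d_y_proj, d_z_assoc)
    if any(not (v > 0) for v in vals):
        raise ValueError(
            f"non-positive diffusivity {vals}: upstream tensor fit likely failed"
        )
    return (d_x_proj + d_x_assoc) / (d_y_proj + d_z_assoc)


def roi_diffusivities(
    tv: TensorVolume, proj_roi: np.ndarray, assoc_roi: np.ndarray
) -> tuple[float, float, float, float]:
    """ROI-mean (Dx_proj, Dx_assoc, Dy_proj, Dz_assoc), invalid voxels excluded.

    The ROIs must live on the tensor grid, be nonempty and be disjoint.
    Voxels invalid in the tensor volume (failed/unmasked fits) are dropped
    from the means; an ROI left empty by that exclusion is an error naming
    the ROI.
    """
    proj_roi = np.asarray(proj_roi, dtype=bool)
    assoc_roi = np.asarray(assoc_roi, dtype=bool)
    for name, roi in (("projection", proj_roi), ("association", assoc_roi)):
        if roi.shape != tv.grid_shape:
            raise ValueError(f"{name} ROI shape {roi.shape} != tensor grid {tv.grid_shape}")
        if not roi.any():
            raise ValueError(f"{name} ROI is empty")
    if (proj_roi & assoc_roi).any():
        raise ValueError("projection and association ROIs overlap")

    out = []
    for name, roi in (("projection", proj_roi), ("association", assoc_roi)):
        valid = roi & tv.mask
        n_dropped = int(roi.sum() - valid.sum())
        if n_dropped:
            warnings.warn(
                f"{name} ROI: excluded {n_dropped} invalid voxel(s)", stacklevel=2
            )
        if not valid.any():
            raise ValueError(f"{name} ROI has no valid tensor voxels")
        out.append(valid)
    proj_v, assoc_v = out
    return (
        float(tv.dxx[proj_v].mean()),
        float(tv.dxx[assoc_v].mean()),
        float(tv.dyy[proj_v].mean()),
        float(tv.dzz[assoc_v].mean()),
    )


def _single_slice_index(roi: np.ndarray, name: str, allow_multislice: bool) -> int:
    zs = np.unique(np.nonzero(roi)[2])
    if len(zs) > 1:
        msg = f"{name} ROI spans {len(zs)} slices; ALPS ROIs are drawn on a single slice"
        if not allow_multislice:
            raise ValueError(msg + " (pass allow_multislice=True to override)")
        warnings.warn(msg, stacklevel=3)
    return int(zs[0])


def measure_alps(
    tv: TensorVolume,
    proj_roi: np.ndarray,
    assoc_roi: np.ndarray,
    side: str = "left",
    allow_multislice: bool = False,
) -> ALPSMeasurement:
    """ROI means + index in one step, enforcing the single-slice convention."""
    z = _single_slice_index(proj_roi, "projection", allow_multislice)
    _single_slice_index(assoc_roi, "association", allow_multislice)
    dxp, dxa, dyp, dza = roi_diffusivities(tv, proj_roi, assoc_roi)
    return ALPSMeasurement(
        d_x_proj=dxp,
        d_x_assoc=dxa,
        d_y_proj=dyp,
        d_z_assoc=dza,
        alps_index=compute_alps(dxp, dxa, dyp, dza),
        roi_size_proj=int(np.asarray(proj_roi, bool).sum()),
        roi_size_assoc=int(np.asarray(assoc_roi, bool).sum()),
        side=side,
        slice_index=z,
    )


def merge_observers(m1: ALPSMeasurement, m2: ALPSMeasurement) -> ALPSMeasurement:
    """Merge two observers' measurements of the same subject and side.

    Averages the four diffusivities element-wise and recomputes the index
    from the averaged diffusivities.  Note the ratio of averaged
    diffusivities generally differs from the average of the two ratios
    (ratio-of-means != mean-of-ratios); :func:`mean_of_indices` exposes the
    other convention.
    """
    if m1.side != m2.side:
        raise ValueError(f"cannot merge measurements from different sides ({m1.side} vs {m2.side})")
    d = {
        k: (getattr(m1, k) + getattr(m2, k)) / 2
        for k in ("d_x_proj", "d_x_assoc", "d_y_proj", "d_z_assoc")
    }
    return ALPSMeasurement(
        **d,
        alps_index=compute_alps(**d),
        roi_size_proj=round((m1.roi_size_proj + m2.roi_size_proj) / 2),
        roi_size_assoc=round((m1.roi_size_assoc + m2.roi_size_assoc) / 2),
        side=m1.side,
        slice_index=m1.slice_index,
    )


def mean_of_indices(m1: ALPSMeasurement, m2: ALPSMeasurement) -> float:
    """Plain average of the two observers' ALPS ratios."""
    return (m1.alps_index + m2.alps_index) / 2


def _dominant_axis(dec_slice: np.ndarray, min_dec: float) -> np.ndarray:
    """Per-pixel dominant channel of a DEC slice; -1 where the map is too
    dim (low anisotropy) to call a direction."""
    dom = np.argmax(dec_slice, axis=-1)
    dom[dec_slice.max(axis=-1) < min_dec] = -1
    return dom


def suggest_rois(
    dec: np.ndarray,
    ventricle_mask: np.ndarray,
    side: str = "left",
    target_size_proj: int = 9,
    target_size_assoc: int = 8,
    slice_index: int | None = None,
    min_dec: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic automatic ROI placement on a DEC map.

    Picks the slice where the ventricle is largest (its "body"), restricts to
    the requested hemisphere (left = x below the grid midline), then grows
    the projection ROI from z-dominant pixels bordering the ventricle and the
    association ROI from y-dominant pixels lateral (farther from the
    ventricle along x) to the projection ROI, each to the target voxel count.
    Default target sizes correspond to ~35 and ~30 mm^2 at 2x2 mm pixels.

    Raises if no qualifying pixels exist (fall back to manual ROIs).
    """
    dec = np.asarray(dec, dtype=float)
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if dec.shape[:3] != ventricle_mask.shape:
        raise ValueError("DEC map and ventricle mask grids differ")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not ventricle_mask.any():
        raise ValueError("ventricle mask is empty")

    nx, ny, nz = ventricle_mask.shape
    midline = nx // 2
    if slice_index is None:
        per_slice = ventricle_mask.reshape(-1, nz).sum(axis=0)
        slice_index = int(np.argmax(per_slice))
    vent = ventricle_mask[:, :, slice_index]
    dom = _dominant_axis(dec[:, :, slice_index], min_dec)
    hemi = np.zeros((nx, ny), dtype=bool)
    if side == "left":
        hemi[:midline] = True
    else:
        hemi[midline:] = True

    vx, vy = np.nonzero(vent)
    if len(vx) == 0:
        raise ValueError(f"ventricle absent on slice {slice_index}")

    def grow(candidates: np.ndarray, seeds: list[tuple[int, int]], target: int) -> np.ndarray:
        """8-connected nearest-first growth from seed pixels."""
        roi = np.zeros_like(candidates)
        frontier = sorted(seeds)
        while frontier and roi.sum() < target:
            frontier.sort()
            x, y = frontier.pop(0)
            if roi[x, y]:
                continue
            roi[x, y] = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    xx, yy = x + dx, y + dy
                    if 0 <= xx < nx and 0 <= yy < ny and candidates[xx, yy] and not roi[xx, yy]:
                        frontier.append((xx, yy))
        return roi

    # projection: z-dominant, in hemisphere, 8-adjacent to the ventricle
    proj_cand = (dom == 2) & hemi & ~vent
    seeds = []
    for x, y in zip(*np.nonzero(proj_cand)):
        if vent[max(0, x - 1) : x + 2, max(0, y - 1) : y + 2].any():
            seeds.append((int(x), int(y)))
    if not seeds:
        raise ValueError(
            "no z-dominant pixels adjacent to the ventricle on the chosen slice; "
            "draw the projection ROI manually"
        )
    proj2d = grow(proj_cand, seeds, target_size_proj)

    # association: y-dominant, lateral to (farther from ventricle than) the
    # projection ROI along x
    vent_cx = vx.mean()
    px = np.nonzero(proj2d)[0]
    lateral_edge = px.min() if px.mean() < vent_cx else px.max()
    assoc_cand = (dom == 1) & hemi & ~vent & ~proj2d
    if px.mean() < vent_cx:
        assoc_cand[lateral_edge:] = False  # ROI block is at lower x than ventricle
    else:
        assoc_cand[: lateral_edge + 1] = False
    seeds = []
    for x, y in zip(*np.nonzero(assoc_cand)):
        if proj2d[max(0, x - 1) : x + 2, max(0, y - 1) : y + 2].any():
            seeds.append((int(x), int(y)))
    if not seeds:
        seeds = sorted(
            ((int(x), int(y)) for x, y in zip(*np.nonzero(assoc_cand))),
            key=lambda p: (abs(p[0] - lateral_edge), p[1]),
        )[:1]
    if not seeds:
        raise ValueError(
            "no y-dominant pixels lateral to the projection ROI; "
            "draw the association ROI manually"
        )
    assoc2d = grow(assoc_cand, seeds, target_size_assoc)

    proj = np.zeros_like(ventricle_mask)
    assoc = np.zeros_like(ventricle_mask)
    proj[:, :, slice_index] = proj2d
    assoc[:, :, slice_index] = assoc2d
    if not proj.any() or not assoc.any():
        raise ValueError("automatic ROI placement found no voxels; draw ROIs manually")
    return proj, assoc
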