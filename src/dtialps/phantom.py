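"""Synthetic DWI phantoms and tumor label masks with known ground truth.

The phantom emulates the periventricular geometry the ALPS method relies on:
a CSF-filled ventricle block, a projection-fiber block (corona radiata,
fibers along the craniocaudal z-axis) adjacent to it, and an
association-fiber block (superior longitudinal fasciculus, fibers along the
anterior-posterior y-axis) lateral to that.  Perivascular spaces of the
medullary veins run left-right (x-axis) through both fiber blocks, modelled
as an additive increment ``perivascular_delta`` to Dxx there.

Signals follow the Stejskal-Tanner forward model at b = 0 and 1000 s/mm^2
over 20 encoding directions; magnitude (Rician) noise is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable, default_gradient_table
from .tensorfit import TensorVolume, forward_signal

__all__ = [
    "PhantomSpec",
    "TumorLabelSpec",
    "make_phantom",
    "make_tumor_labels",
    "add_rician_noise",
    "LABELS",
    "TUMOR_LABELS",
]

#: fiber/ventricle label scheme written by make_phantom
LABELS = {"background": 0, "ventricle": 1, "projection": 2, "association": 3}

#: nested tumor-compartment label scheme written by make_tumor_labels.
#: A voxel carries its innermost compartment: enhancing tumor is the part of
#: the whole tumor not claimed by a subcompartment, and peritumoral edema is
#: the outer (edema+tumor) region outside the whole tumor.
TUMOR_LABELS = {
    "background": 0,
    "edema": 1,
    "enhancing": 2,
    "non_enhancing": 3,
    "necrotic": 4,
    "hemorrhagic": 5,
}

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open per axis


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)  # type: ignore[return-value]


def _box_count(box: Box) -> int:
    return int(np.prod([hi - lo for lo, hi in box]))


def _boxes_disjoint(a: Box, b: Box) -> bool:
    return any(a[i][1] <= b[i][0] or b[i][1] <= a[i][0] for i in range(3))


def _box_inside(inner: Box, outer: Box) -> bool:
    return all(outer[i][0] <= inner[i][0] and inner[i][1] <= outer[i][1] for i in range(3))


def _default_tensors() -> dict[str, np.ndarray]:
    """Plausible brain diffusivities (mm^2/s): fiber lambda_par = 1.4e-3,
    lambda_perp = 0.4e-3; CSF 3.0e-3 isotropic; background 0.8e-3 isotropic."""
    lam_par, lam_perp = 1.4e-3, 0.4e-3
    return {
        "background": np.eye(3) * 0.8e-3,
        "ventricle": np.eye(3) * 3.0e-3,
        "projection": np.diag([lam_perp, lam_perp, lam_par]),
        "association": np.diag([lam_perp, lam_par, lam_perp]),
    }


def _default_regions(grid: tuple[int, int, int]) -> dict[str, Box]:
    """Left-hemisphere periventricular strip at mid-height of the grid."""
    nx, ny, nz = grid
    midline = nx // 2
    y0, y1 = ny // 4, 3 * ny // 4
    w = max(2, nx // 8)
    vent = ((midline - w, midline), (y0, y1), (0, nz))
    proj = ((midline - 2 * w, midline - w), (y0, y1), (0, nz))
    assoc = ((midline - 3 * w, midline - 2 * w), (y0, y1), (0, nz))
    return {"ventricle": vent, "projection": proj, "association": assoc}


@dataclass
class PhantomSpec:
    """Geometry, ground-truth tensors and acquisition of a DWI phantom.

    ``perivascular_delta`` (mm^2/s) is added to Dxx inside both fiber blocks;
    the ground-truth ALPS ratio of the default phantom is therefore
    ``(lambda_perp + delta) / lambda_perp``.  The default delta of 1.488e-4
    puts that ratio at 1.372, the midpoint of reported glioma cohorts.
    ``snr`` is S0 over the Gaussian channel noise sigma; ``inf`` disables
    noise entirely.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    slice_gap: float = 0.0
    regions: dict[str, Box] = field(default_factory=dict)
    region_tensors: dict[str, np.ndarray] = field(default_factory=_default_tensors)
    perivascular_delta: float = 1.488e-4
    s0: float = 1000.0
    snr: float = 30.0
    bval: float = 1000.0
    n_b0: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = _default_regions(tuple(self.grid_shape))
        self.validate()

    def validate(self) -> None:
        if self.perivascular_delta < 0:
            raise ValueError("perivascular_delta must be >= 0")
        if not (self.snr > 0):
            raise ValueError("snr must be > 0 (use inf for noiseless)")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        nx, ny, nz = self.grid_shape
        for name, box in self.regions.items():
            if name not in self.region_tensors:
                raise ValueError(f"no ground-truth tensor for region {name!r}")
            for (lo, hi), n in zip(box, (nx, ny, nz)):
                if not (0 <= lo < hi <= n):
                    raise ValueError(f"region {name!r} box {box} outside grid {self.grid_shape}")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if not _boxes_disjoint(self.regions[a], self.regions[b]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")
        for name, D in self.region_tensors.items():
            D = np.asarray(D, dtype=float)
            if D.shape != (3, 3) or not np.allclose(D, D.T):
                raise ValueError(f"region tensor {name!r} must be symmetric 3x3")
            if np.linalg.eigvalsh(D).min() < -1e-15:
                raise ValueError(f"region tensor {name!r} is not positive semi-definite")

    def truth_tensor(self, region: str) -> np.ndarray:
        """Generating tensor for a region, including the perivascular term."""
        D = np.asarray(self.region_tensors[region], dtype=float).copy()
        if region in ("projection", "association"):
            D[0, 0] += self.perivascular_delta
        return D

    @property
    def truth_alps(self) -> float:
        """Ground-truth ALPS ratio implied by the region tensors."""
        p = self.truth_tensor("projection")
        a = self.truth_tensor("association")
        return ((p[0, 0] + a[0, 0]) / 2) / ((p[1, 1] + a[2, 2]) / 2)


def delta_for_alps(target: float, lambda_perp: float = 0.4e-3) -> float:
    """Perivascular Dxx increment giving a ground-truth ALPS of ``target``."""
    if target < 1:
        raise ValueError("target ALPS below 1 would need a negative delta")
    return (target - 1.0) * lambda_perp


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + N(0, sigma), N(0, sigma)) — standard MRI
    magnitude-noise construction."""
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def make_phantom(
    spec: PhantomSpec, gtab: GradientTable | None = None
) -> tuple[np.ndarray, GradientTable, np.ndarray, TensorVolume]:
    """Simulate a DWI phantom.

    Returns ``(dwi, gtab, labels, truth)``: the 4-D signal volume, the
    gradient table used, the region label volume (see ``LABELS``) and the
    per-voxel generating tensors as a :class:`TensorVolume`.  Identical
    ``(spec, gtab)`` pairs produce bit-identical output (the noise stream is
    seeded from ``spec.seed``).
    """
    spec.validate()
    if gtab is None:
        gtab = default_gradient_table(b=spec.bval, n_b0=spec.n_b0)
    grid = tuple(spec.grid_shape)
    labels = np.zeros(grid, dtype=np.int16)
    tensors = np.empty(grid + (3, 3))
    tensors[...] = spec.truth_tensor("background") if "background" in spec.region_tensors else np.nan
    for name, box in spec.regions.items():
        sl = _box_slices(box)
        labels[sl] = LABELS.get(name, max(LABELS.values()) + 1)
        tensors[sl] = spec.truth_tensor(name)

    s0 = np.full(grid, spec.s0)
    dwi = forward_signal(tensors, s0, gtab)
    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        dwi = add_rician_noise(dwi, spec.s0 / spec.snr, rng)
    truth = TensorVolume(
        tensor=tensors,
        s0=s0,
        mask=np.ones(grid, dtype=bool),
        voxel_size=tuple(spec.voxel_size),
        slice_gap=spec.slice_gap,
    )
    return dwi, gtab, labels, truth


@dataclass
class TumorLabelSpec:
    """Nested cuboid tumor compartments on a voxel grid.

    ``outer`` is the edema+tumor envelope; ``tumor`` (the whole tumor) must
    nest inside it, and the three subcompartments must nest inside ``tumor``
    and be mutually disjoint.  Everything is an axis-aligned half-open box,
    so per-slice areas and volumes are exactly computable from the spec.
    """

    grid_shape: tuple[int, int, int]
    outer: Box
    tumor: Box | None = None
    non_enhancing: Box | None = None
    necrotic: Box | None = None
    hemorrhagic: Box | None = None
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    slice_thickness: float | None = None  # default: voxel_size[2]
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.slice_thickness is None:
            self.slice_thickness = float(self.voxel_size[2])
        self.validate()

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        for name, box in self._boxes().items():
            for (lo, hi), n in zip(box, (nx, ny, nz)):
                if not (0 <= lo < hi <= n):
                    raise ValueError(f"{name} box {box} outside grid {self.grid_shape}")
        if self.tumor is not None and not _box_inside(self.tumor, self.outer):
            raise ValueError("tumor compartment must nest inside the outer (edema+tumor) region")
        subs = {
            k: b
            for k, b in (
                ("non_enhancing", self.non_enhancing),
                ("necrotic", self.necrotic),
                ("hemorrhagic", self.hemorrhagic),
            )
            if b is not None
        }
        if subs and self.tumor is None:
            raise ValueError("subcompartments given without a tumor compartment")
        for name, box in subs.items():
            if not _box_inside(box, self.tumor):  # type: ignore[arg-type]
                raise ValueError(f"{name} compartment must nest inside the whole tumor")
        keys = list(subs)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if not _boxes_disjoint(subs[a], subs[b]):
                    raise ValueError(f"compartments {a!r} and {b!r} overlap but are not nested")

    def _boxes(self) -> dict[str, Box]:
        out = {"outer": self.outer}
        for k in ("tumor", "non_enhancing", "necrotic", "hemorrhagic"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out

    def expected_voxel_counts(self) -> dict[str, int]:
        """Analytic voxel count per label, straight from the box arithmetic."""
        n_sub = sum(
            _box_count(b)
            for b in (self.non_enhancing, self.necrotic, self.hemorrhagic)
            if b is not None
        )
        n_tumor = _box_count(self.tumor) if self.tumor is not None else 0
        return {
            "edema": _box_count(self.outer) - n_tumor,
            "enhancing": n_tumor - n_sub,
            "non_enhancing": _box_count(self.non_enhancing) if self.non_enhancing else 0,
            "necrotic": _box_count(self.necrotic) if self.necrotic else 0,
            "hemorrhagic": _box_count(self.hemorrhagic) if self.hemorrhagic else 0,
        }

    def expected_volumes_cm3(self) -> dict[str, float]:
        """Analytic compartment volumes by the slice-summation rule:
        per-slice area x (slice thickness + gap), summed over slices."""
        px_area = self.voxel_size[0] * self.voxel_size[1]
        dist = self.slice_thickness + self.slice_gap
        counts = self.expected_voxel_counts()
        vols = {k: n * px_area * dist / 1000.0 for k, n in counts.items()}
        vols["whole_tumor"] = (
            vols["enhancing"] + vols["non_enhancing"] + vols["necrotic"] + vols["hemorrhagic"]
        )
        return vols


def make_tumor_labels(spec: TumorLabelSpec) -> np.ndarray:
    """Paint the nested compartments into an integer label volume.

    Inner compartments overwrite outer ones, so each voxel carries its
    innermost label (see ``TUMOR_LABELS``).
    """
    spec.validate()
    labels = np.zeros(tuple(spec.grid_shape), dtype=np.int16)
    labels[_box_slices(spec.outer)] = TUMOR_LABELS["edema"]
    if spec.tumor is not None:
        labels[_box_slices(spec.tumor)] = TUMOR_LABELS["enhancing"]
        for name in ("non_enhancing", "necrotic", "hemorrhagic"):
            box = getattr(spec, name)
            if box is not None:
                labels[_box_slices(box)] = TUMOR_LABELS[name]
    return labels
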