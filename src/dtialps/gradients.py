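"""Diffusion gradient tables (b-values + unit directions, FSL text dialect)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["GradientTable", "default_directions", "read_bvals_bvecs", "write_bvals_bvecs"]

_UNIT_TOL = 1e-3


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions for a DWI series.

    ``bvecs`` rows are unit vectors in the image coordinate frame of the
    accompanying NIfTI affine (the FSL text dialect does not pin the frame;
    this package fixes it to the image frame).  A zero vector marks a b=0
    volume.
    """

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        self._validate()

    def _validate(self) -> None:
        dw = self.bvals > 0
        if not np.any(~dw):
            raise ValueError("gradient table needs at least one b=0 volume")
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError(
                "non-unit gradient direction(s) where b > 0 "
                f"(worst |norm-1| = {np.abs(norms - 1).max():.3g})"
            )
        if n_noncollinear(self.bvecs[dw]) < 6:
            raise ValueError("need at least 6 non-collinear diffusion directions")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def __len__(self) -> int:
        return self.bvals.shape[0]


def n_noncollinear(vecs: np.ndarray, tol: float = 1e-6) -> int:
    """Count directions that are pairwise non-collinear (antipodes collapse)."""
    kept: list[np.ndarray] = []
    for v in np.asarray(vecs, dtype=float):
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        u = v / nv
        if all(abs(abs(u @ k)) < 1 - tol for k in kept):
            kept.append(u)
    return len(kept)


def default_directions() -> np.ndarray:
    """The package's 20-direction electrostatic-repulsion gradient set."""
    with resources.files("dtialps.data").joinpath("directions20.txt").open() as fh:
        return np.loadtxt(fh)


def default_gradient_table(b: float = 1000.0, n_b0: int = 4) -> GradientTable:
    """b=0 (x ``n_b0``) followed by 20 directions at ``b`` s/mm^2.

    Mirrors a clinical single-shell scheme (b = 0, 1000 s/mm^2 over 20
    encoding directions) with the four signal averages modelled as four b=0
    repeats.
    """
    dirs = default_directions()
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(dirs), b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-dialect bval/bvec text files.

    bval: one whitespace-separated row of b-values.  bvec: three rows holding
    the x, y, z components.  Near-unit directions (|norm - 1| <= 1e-3) are
    renormalized with a warning; worse deviations are rejected.
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous 3x3; FSL convention is 3 rows of components
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"{bvec_path}: {bvecs.shape[0]} directions but {bvals.shape[0]} b-values"
        )
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    off = np.abs(norms - 1.0)
    if np.any((off > 1e-6) & (off <= _UNIT_TOL)):
        warnings.warn("renormalizing near-unit gradient directions", stacklevel=2)
        bvecs = bvecs.copy()
        bvecs[dw] = bvecs[dw] / norms[:, None]
    return GradientTable(bvals, bvecs)


def write_bvals_bvecs(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.10f")
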