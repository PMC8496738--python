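"""Per-voxel diffusion tensor estimation and derived maps.

The single-tensor model relates the diffusion-weighted signal in a voxel to a
symmetric 3x3 tensor ``D`` (mm^2/s) via the Stejskal-Tanner equation

    S_i = S0 * exp(-b_i * g_i^T D g_i)

Taking logs gives a linear system in the 6 unique tensor elements plus
``ln S0``, solved here by ordinary (LLS) or signal-weighted (WLLS) least
squares — the standard log-linear estimator used by clinical DTI pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable

__all__ = ["TensorVolume", "fit_tensor", "design_matrix", "dec_map", "forward_signal"]

#: signals below this fraction of the voxel's S0 are floored before the log
SIGNAL_FLOOR_FRACTION = 1e-6

# index pairs of the 6 unique tensor elements in the design/parameter order
_TENSOR_ELEMENTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors plus derived scalar maps.

    ``tensor`` has shape ``grid + (3, 3)`` in mm^2/s; voxels where ``mask`` is
    False (outside the fit mask, or marked invalid) hold NaN.  The
    eigensystem is computed lazily: eigenvalues are sorted descending and
    clamped at zero *for the derived metrics only* — the raw tensor diagonal
    (``dxx``/``dyy``/``dzz``) is kept untouched because the ALPS index is
    defined on axis diffusivities, not eigenvalues.
    """

    tensor: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    slice_gap: float = 0.0
    n_floored: int = 0
    _eig: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape[-2:] != (3, 3):
            raise ValueError("tensor field must have trailing shape (3, 3)")
        self.mask = np.asarray(self.mask, dtype=bool)
        # non-finite tensors are invalid voxels
        bad = ~np.isfinite(self.tensor).all(axis=(-2, -1))
        self.mask = self.mask & ~bad

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.tensor.shape[:-2]

    @property
    def dxx(self) -> np.ndarray:
        return self.tensor[..., 0, 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensor[..., 1, 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensor[..., 2, 2]

    def _eigensystem(self) -> dict:
        if not self._eig:
            self._eig = eigensystem(self)
        return self._eig

    @property
    def eigvals(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return self._eigensystem()["eigvals"]

    @property
    def eigvecs(self) -> np.ndarray:
        """Matching orthonormal eigenvectors; column i pairs with eigval i."""
        return self._eigensystem()["eigvecs"]

    @property
    def fa(self) -> np.ndarray:
        return self._eigensystem()["fa"]

    @property
    def md(self) -> np.ndarray:
        return self._eigensystem()["md"]


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear design: columns (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0)."""
    b = gtab.bvals
    g = gtab.bvecs
    cols = [
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ]
    return np.stack(cols, axis=1)


def params_to_tensor(params: np.ndarray) -> np.ndarray:
    """(..., 7) parameter vectors -> (..., 3, 3) symmetric tensors."""
    out = np.zeros(params.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_TENSOR_ELEMENTS):
        out[..., i, j] = params[..., k]
        out[..., j, i] = params[..., k]
    return out


def forward_signal(tensor: np.ndarray, s0: np.ndarray, gtab: GradientTable) -> np.ndarray:
    """Noiseless Stejskal-Tanner signal for every gradient-table entry."""
    quad = np.einsum("nj,...jk,nk->...n", gtab.bvecs, tensor, gtab.bvecs)
    return np.asarray(s0)[..., None] * np.exp(-gtab.bvals * quad)


def _average_b0(dwi: np.ndarray, gtab: GradientTable) -> tuple[np.ndarray, GradientTable]:
    """Average b=0 repeats into one volume; leave DW volumes in order."""
    b0 = gtab.b0_mask
    if b0.sum() <= 1:
        return dwi, gtab
    mean_b0 = dwi[..., b0].mean(axis=-1, keepdims=True)
    data = np.concatenate([mean_b0, dwi[..., ~b0]], axis=-1)
    gt = GradientTable(
        np.concatenate([[0.0], gtab.bvals[~b0]]),
        np.vstack([np.zeros(3), gtab.bvecs[~b0]]),
    )
    return data, gt


def fit_tensor(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    method: str = "lls",
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    slice_gap: float = 0.0,
) -> TensorVolume:
    """Fit the diffusion tensor in every masked voxel.

    Parameters
    ----------
    dwi
        4-D array, last axis indexing the gradient-table entries.
    gtab
        Diffusion encoding; must contain >= 1 b=0 volume and >= 6
        non-collinear directions (validated on construction).
    mask
        Boolean volume restricting the fit; default all voxels.
    method
        ``"lls"`` (default) or ``"wlls"`` — weighted refit with weights equal
        to the squared LLS-predicted signals.

    Non-positive (or tiny) signals are floored at ``1e-6 * S0`` before the
    log; the number of floored samples is reported on the result and via a
    warning.  A rank-deficient design (collinear directions) is rejected.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (x, y, z, volume)")
    if dwi.shape[-1] != len(gtab):
        raise ValueError(
            f"dwi has {dwi.shape[-1]} volumes but gradient table has {len(gtab)}"
        )
    if method not in ("lls", "wlls"):
        raise ValueError(f"unknown fit method {method!r}")
    grid = dwi.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match dwi grid")

    data, gt = _average_b0(dwi, gtab)
    A = design_matrix(gt)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError(
            "rank-deficient tensor design: gradient directions are collinear "
            "or too few — need >= 6 non-collinear directions plus b=0"
        )

    sig = data[mask]  # (v, m)
    s0_est = sig[:, gt.b0_mask].mean(axis=1)
    s0_est = np.where(s0_est > 0, s0_est, 1.0)
    floor = SIGNAL_FLOOR_FRACTION * s0_est[:, None]
    n_floored = int(np.count_nonzero(sig < floor))
    if n_floored:
        warnings.warn(
            f"floored {n_floored} non-positive/tiny signal sample(s) before log",
            stacklevel=2,
        )
    sig = np.maximum(sig, floor)

    y = np.log(sig)  # (v, m)
    pinv = np.linalg.pinv(A)  # (7, m)
    params = y @ pinv.T  # (v, 7)

    if method == "wlls":
        # weights: squared predicted signals from the first (LLS) pass
        w = np.exp(A @ params.T).T ** 2  # (v, m)
        lhs = np.einsum("vm,mi,mj->vij", w, A, A)
        rhs = np.einsum("vm,mi,vm->vi", w, A, y)
        params = np.linalg.solve(lhs, rhs[..., None])[..., 0]

    tensor = np.full(grid + (3, 3), np.nan)
    s0 = np.full(grid, np.nan)
    tensor[mask] = params_to_tensor(params[:, :6])
    s0[mask] = np.exp(params[:, 6])
    return TensorVolume(
        tensor=tensor,
        s0=s0,
        mask=mask,
        voxel_size=tuple(voxel_size),
        slice_gap=slice_gap,
        n_floored=n_floored,
    )


def eigensystem(tv: TensorVolume) -> dict:
    """Eigendecomposition with descending sort, plus FA and MD maps.

    Negative eigenvalues (noise can push the smallest below zero) are clamped
    to 0 before FA/MD.  FA uses the standard normalized-deviation form
    sqrt(3/2) * ||lambda - <lambda>|| / ||lambda||; an all-zero tensor maps
    to FA = 0.
    """
    grid = tv.grid_shape
    eigvals = np.full(grid + (3,), np.nan)
    eigvecs = np.full(grid + (3, 3), np.nan)
    fa = np.full(grid, np.nan)
    md = np.full(grid, np.nan)
    m = tv.mask
    if m.any():
        w, v = np.linalg.eigh(tv.tensor[m])  # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        wc = np.clip(w, 0.0, None)
        eigvals[m] = wc
        eigvecs[m] = v
        mdv = wc.mean(axis=1)
        num = np.linalg.norm(wc - mdv[:, None], axis=1)
        den = np.linalg.norm(wc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fav = np.sqrt(1.5) * num / den
        fav[den == 0] = 0.0
        fa[m] = np.clip(fav, 0.0, 1.0)
        md[m] = mdv
    return {"eigvals": eigvals, "eigvecs": eigvecs, "fa": fa, "md": md}


def dec_map(tv: TensorVolume) -> np.ndarray:
    """Directionally encoded color volume: channel c = FA * |v1_c|, in [0,1].

    Red/green/blue encode left-right (x), anterior-posterior (y) and
    craniocaudal (z) orientation of the principal eigenvector, weighted by
    anisotropy — the map the fiber ROIs are drawn on.
    """
    v1 = tv.eigvecs[..., :, 0]
    out = tv.fa[..., None] * np.abs(v1)
    out = np.where(np.isfinite(out), out, 0.0)
    return np.clip(out, 0.0, 1.0)
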