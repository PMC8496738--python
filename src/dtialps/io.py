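"""Readers and writers: NIfTI volumes, FSL bval/bvec, cohort CSV, YAML, JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import EXCLUSION_FLAGS, VOLUME_COLUMNS
from .gradients import GradientTable, read_bvals_bvecs, write_bvals_bvecs

__all__ = [
    "Geometry",
    "read_dwi",
    "write_dwi",
    "read_labels",
    "write_labels",
    "read_cohort",
    "write_cohort",
    "write_results",
    "load_yaml_spec",
    "save_yaml_spec",
]

_ENUMS = {
    "sex": {"woman", "man"},
    "grade": {"II", "III", "IV"},
    "idh1": {"mutant", "wild-type"},
    "side": {"left", "right"},
}

#: column dictionary for the cohort CSV (documented contract)
COHORT_COLUMNS = {
    "id": "patient identifier (string)",
    "age": "age in years (float, >= 0)",
    "sex": "woman | man",
    "grade": "tumor grade: II | III | IV",
    "idh1": "IDH1 status: mutant | wild-type",
    "side": "tumor-bearing hemisphere: left | right",
    **{c: "compartment volume in cm^3 (float, >= 0)" for c in VOLUME_COLUMNS},
    "alps": "ALPS index (unitless, > 0)",
    **{f: "exclusion flag (bool)" for f in EXCLUSION_FLAGS},
}


@dataclass(frozen=True)
class Geometry:
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    slice_gap: float = 0.0


def _ras_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_dwi(
    nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path
) -> tuple[np.ndarray, GradientTable, Geometry]:
    """Load a 4-D DWI NIfTI plus its FSL-dialect gradient files.

    The gradient-table length must match the 4th dimension; directions are
    interpreted in the image coordinate frame of the NIfTI affine.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4-D DWI, got {data.ndim}-D")
    gtab = read_bvals_bvecs(bval_path, bvec_path)
    if len(gtab) != data.shape[3]:
        raise ValueError(
            f"{bval_path}: {len(gtab)} gradient entries but DWI has "
            f"{data.shape[3]} volumes"
        )
    zooms = img.header.get_zooms()[:3]
    geom = Geometry(voxel_size=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))
    return data, gtab, geom


def write_dwi(
    out_dir: str | Path,
    dwi: np.ndarray,
    gtab: GradientTable,
    voxel_size: tuple[float, float, float],
    stem: str = "dwi",
) -> dict[str, Path]:
    """Write dwi.nii.gz + dwi.bval + dwi.bvec (RAS affine from voxel size)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _ras_affine(voxel_size)
    paths = {
        "nifti": out_dir / f"{stem}.nii.gz",
        "bval": out_dir / f"{stem}.bval",
        "bvec": out_dir / f"{stem}.bvec",
    }
    # float64 on disk so simulated signals round-trip bit-identically
    nib.save(nib.Nifti1Image(np.asarray(dwi, dtype=np.float64), aff), str(paths["nifti"]))
    write_bvals_bvecs(gtab, paths["bval"], paths["bvec"])
    return paths


def read_labels(path: str | Path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    labels = np.rint(data).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    return labels, Geometry(tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_labels(path: str | Path, labels: np.ndarray, voxel_size: tuple[float, float, float]) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _ras_affine(voxel_size)),
        str(path),
    )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV against the documented column dictionary.

    Enumerated columns are checked value-by-value; an unknown value raises
    with the offending row number (1-based data rows, header excluded).
    """
    df = pd.read_csv(path)
    required = ["id", "age", "grade", "idh1", "alps"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, allowed in _ENUMS.items():
        if col not in df.columns:
            continue
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise ValueError(
                f"{path}: unknown {col} value {df[col][bad].iloc[0]!r} at data row {row}"
            )
    for flag in EXCLUSION_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
        else:
            df[flag] = False
    return df


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def write_results(path: str | Path, results: dict, seed: int | None = None, config: dict | None = None) -> None:
    """JSON report with provenance (package version, seed, config echo)."""
    payload = {
        "software": {"name": "dtialps", "version": __version__},
        "seed": seed,
        "config": config or {},
        "results": results,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_yaml_spec(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: YAML spec must be a mapping")
    return out


def save_yaml_spec(path: str | Path, spec: dict) -> None:
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))
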