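"""Synthetic glioma cohort generator.

Draws per-patient covariates (age, sex, hemisphere, IDH1 status, compartment
volumes) cell-by-cell over the (grade, IDH1) design, then generates the ALPS
outcome from a linear model in standardized IDH1 status and peritumoral
edema volume:

    alps = intercept + scale * (b_idh1 * z(idh1) + b_edema * z(edema)) + eps

with z() the within-sample z-score and eps ~ Normal(0, residual_sd).  All
other covariates carry no direct effect — any marginal association they show
runs through their correlation with grade, exactly the structure a stepwise
selection should see through.

Default moments reproduce a 201-patient glioma cohort: 86/52/63 patients in
grades II/III/IV, grade-level ages 41.4/45.2/57.5 y, IDH1-mutant fractions
falling steeply with grade, and volume distributions per grade (truncated at
zero by redraw, since volumes cannot be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "make_cohort", "VOLUME_COLUMNS", "EXCLUSION_FLAGS"]

GRADES = ("II", "III", "IV")
VOLUME_COLUMNS = (
    "edema_cm3",
    "whole_tumor_cm3",
    "enhancing_cm3",
    "non_enhancing_cm3",
    "necrotic_cm3",
    "hemorrhagic_cm3",
)
EXCLUSION_FLAGS = ("under_18", "motion_artifact", "infratentorial_only", "idh1_missing")

# default per-grade (mean, sd) moments
_DEF_AGE = {"II": (41.4, 13.3), "III": (45.2, 13.6), "IV": (57.5, 15.1)}
_DEF_VOLUMES = {
    "edema_cm3": {"II": (13.81, 18.36), "III": (17.04, 21.11), "IV": (50.33, 35.70)},
    "whole_tumor_cm3": {"II": (52.82, 45.56), "III": (58.69, 40.92), "IV": (50.04, 27.35)},
    "enhancing_cm3": {"II": (1.59, 6.21), "III": (12.27, 19.26), "IV": (31.22, 15.46)},
    "non_enhancing_cm3": {"II": (47.02, 42.57), "III": (33.11, 30.57), "IV": (3.69, 18.75)},
    "necrotic_cm3": {"II": (1.94, 7.30), "III": (9.34, 22.39), "IV": (8.10, 13.05)},
    "hemorrhagic_cm3": {"II": (1.18, 10.95), "III": (3.05, 11.43), "IV": (8.06, 12.55)},
}
_DEF_CELLS = {
    ("II", "mutant"): 66,
    ("II", "wild-type"): 20,
    ("III", "mutant"): 34,
    ("III", "wild-type"): 18,
    ("IV", "mutant"): 7,
    ("IV", "wild-type"): 56,
}
_DEF_MAN_FRAC = {"II": 45 / 86, "III": 29 / 52, "IV": 42 / 63}
_DEF_RIGHT_FRAC = {"II": 37 / 86, "III": 16 / 52, "IV": 31 / 63}

#: Grade-level summary of the published glioma cohort the generator's
#: defaults emulate: group sizes, patient counts by category, and per-grade
#: mean (SD) of age, compartment volumes and the ALPS index, plus the
#: pooled ("All") column as printed.  The pooled mean of a quantity must
#: equal the size-weighted mean of its per-grade means; the reference table
#: satisfies that identity for every row except the enhancing-tumor volume,
#: whose printed pooled value (16.34) disagrees with the weighted mean of
#: its per-grade entries (13.64) — a suspected transcription error kept
#: here exactly as printed.
REFERENCE_GRADE_SUMMARY = {
    "n": {"II": 86, "III": 52, "IV": 63, "All": 201},
    "n_man": {"II": 45, "III": 29, "IV": 42, "All": 116},
    "n_right": {"II": 37, "III": 16, "IV": 31, "All": 84},
    "n_idh1_mutant": {"II": 66, "III": 34, "IV": 7, "All": 107},
    "age_mean": {"II": 41.4, "III": 45.2, "IV": 57.5, "All": 47.4},
    "edema_cm3_mean": {"II": 13.81, "III": 17.04, "IV": 50.33, "All": 26.09},
    "whole_tumor_cm3_mean": {"II": 52.82, "III": 58.69, "IV": 50.04, "All": 53.47},
    "enhancing_cm3_mean": {"II": 1.59, "III": 12.27, "IV": 31.22, "All": 16.34},
    "non_enhancing_cm3_mean": {"II": 47.02, "III": 33.11, "IV": 3.69, "All": 29.84},
    "necrotic_cm3_mean": {"II": 1.94, "III": 9.34, "IV": 8.10, "All": 5.78},
    "hemorrhagic_cm3_mean": {"II": 1.18, "III": 3.05, "IV": 8.06, "All": 3.82},
    "alps_mean": {"II": 1.454, "III": 1.421, "IV": 1.220, "All": 1.372},
    "alps_sd": {"II": 0.186, "III": 0.214, "IV": 0.112, "All": 0.202},
}

#: screening-flow exclusion counts of the emulated cohort: 239 screened,
#: 38 excluded (disjoint reasons), 201 analyzed
REFERENCE_SCREENING = {
    "screened": 239,
    "under_18": 2,
    "motion_artifact": 3,
    "infratentorial_only": 4,
    "idh1_missing": 29,
    "analyzed": 201,
}


@dataclass
class AlpsModel:
    """Linear outcome model for the ALPS index.

    ``beta_idh1`` / ``beta_edema`` are standardized coefficients (applied to
    z-scored covariates, in units of ``scale`` = the target outcome SD);
    ``residual_sd`` is in ALPS units.  The default residual SD of 0.168
    (0.83 outcome-SDs) makes the generated pooled ALPS SD land near 0.202
    given the covariate correlation the grade structure induces.
    """

    intercept: float = 1.372
    beta_idh1: float = 0.308
    beta_edema: float = -0.353
    scale: float = 0.202
    residual_sd: float = 0.168


@dataclass
class CohortSpec:
    """Design of the synthetic cohort (see module docstring for defaults)."""

    cells: dict[tuple[str, str], int] = field(default_factory=lambda: dict(_DEF_CELLS))
    age: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEF_AGE))
    volumes: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEF_VOLUMES.items()}
    )
    man_fraction: dict[str, float] = field(default_factory=lambda: dict(_DEF_MAN_FRAC))
    right_fraction: dict[str, float] = field(default_factory=lambda: dict(_DEF_RIGHT_FRAC))
    alps_model: AlpsModel = field(default_factory=AlpsModel)
    min_age: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        for (grade, idh1), n in self.cells.items():
            if grade not in GRADES or idh1 not in ("mutant", "wild-type"):
                raise ValueError(f"unknown cohort cell {(grade, idh1)!r}")
            if n <= 0:
                raise ValueError(f"cell {(grade, idh1)!r} count must be positive")
        for grade, (mu, sd) in self.age.items():
            if sd <= 0:
                raise ValueError(f"age SD for grade {grade} must be positive")
        for col, per_grade in self.volumes.items():
            if col not in VOLUME_COLUMNS:
                raise ValueError(f"unknown volume column {col!r}")
            for grade, (mu, sd) in per_grade.items():
                if sd <= 0:
                    raise ValueError(f"{col} SD for grade {grade} must be positive")
        if self.alps_model.residual_sd < 0 or self.alps_model.scale <= 0:
            raise ValueError("alps_model scale must be > 0 and residual_sd >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.cells.values())


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, n: int, lower: float
) -> tuple[np.ndarray, int]:
    """Redraw-below-``lower`` normal sampling; returns draws + redraw count."""
    out = rng.normal(mu, sd, n)
    redraws = 0
    bad = out < lower
    while bad.any():
        redraws += int(bad.sum())
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = out < lower
    return out, redraws


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def make_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate the per-patient cohort table.

    Returns a DataFrame with one row per patient and columns id, age, sex,
    grade, idh1, side, the six volume columns (cm^3), alps, and the four
    exclusion-flag columns (all False — flags are set by callers emulating a
    screening flow).  ``df.attrs`` records the seed and the fraction of
    volume draws redrawn at the zero truncation.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows: list[dict] = []
    n_redraw = 0
    n_draw = 0
    for (grade, idh1), n in sorted(spec.cells.items()):
        age_mu, age_sd = spec.age[grade]
        ages, r = _truncated_normal(rng, age_mu, age_sd, n, spec.min_age)
        sex = np.where(rng.random(n) < spec.man_fraction[grade], "man", "woman")
        side = np.where(rng.random(n) < spec.right_fraction[grade], "right", "left")
        vols = {}
        for col in VOLUME_COLUMNS:
            mu, sd = spec.volumes[col][grade]
            v, rr = _truncated_normal(rng, mu, sd, n, 0.0)
            n_redraw += rr
            n_draw += n
            vols[col] = v
        for i in range(n):
            rows.append(
                {
                    "age": ages[i],
                    "sex": sex[i],
                    "grade": grade,
                    "idh1": idh1,
                    "side": side[i],
                    **{col: vols[col][i] for col in VOLUME_COLUMNS},
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"P{i:04d}" for i in range(1, len(df) + 1)])

    m = spec.alps_model
    z_idh = _zscore((df["idh1"] == "mutant").to_numpy(float))
    z_edema = _zscore(df["edema_cm3"].to_numpy(float))
    eps = rng.normal(0.0, m.residual_sd, len(df)) if m.residual_sd > 0 else 0.0
    df["alps"] = m.intercept + m.scale * (m.beta_idh1 * z_idh + m.beta_edema * z_edema) + eps

    for flag in EXCLUSION_FLAGS:
        df[flag] = False
    df.attrs["seed"] = int(spec.seed if seed is None else seed)
    df.attrs["volume_redraw_fraction"] = n_redraw / max(n_draw, 1)
    return df
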