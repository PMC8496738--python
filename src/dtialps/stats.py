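"""Cohort-level statistics for the ALPS analysis.

Covers the full inferential layer of a typical glymphatic-imaging cohort
study: screening exclusions, normality testing, inter-observer ICC,
age-adjusted ANCOVA group comparisons with Bonferroni-corrected pairwise
contrasts, univariable regressions with standardized coefficients, stepwise
multivariable selection, variance inflation factors and grouped summaries.

Coding conventions (chosen so reported coefficient signs read naturally):
sex woman=0 / man=1; IDH1 wild-type=0 / mutant=1 (positive beta = mutation
associated with higher ALPS); grade ordinal II=2, III=3, IV=4.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .cohort import EXCLUSION_FLAGS, VOLUME_COLUMNS

__all__ = [
    "apply_exclusions",
    "ks_normality",
    "icc_absolute_agreement",
    "ICCResult",
    "ancova_adjusted_compare",
    "AncovaResult",
    "univariable_regressions",
    "stepwise_multivariable",
    "RegressionResult",
    "vif",
    "cohort_summary",
    "pooled_mean",
    "encode_predictors",
    "DEFAULT_CANDIDATES",
]

logger = logging.getLogger(__name__)

#: full candidate set for the multivariable model
DEFAULT_CANDIDATES = ("age", "sex", "grade", "idh1") + VOLUME_COLUMNS

_CODINGS = {
    "sex": {"woman": 0.0, "man": 1.0},
    "idh1": {"wild-type": 0.0, "mutant": 1.0},
    "grade": {"II": 2.0, "III": 3.0, "IV": 4.0},
}


# ---------------------------------------------------------------------------
# screening / exclusions

def apply_exclusions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop patients carrying any exclusion flag; log counts per reason.

    Flags: under_18, motion_artifact, infratentorial_only, idh1_missing.
    Counts (including the total excluded/retained) are logged and stored in
    ``result.attrs['exclusion_counts']``.
    """
    missing = [f for f in EXCLUSION_FLAGS if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks exclusion flag column(s) {missing}")
    flagged = cohort[list(EXCLUSION_FLAGS)].astype(bool)
    counts = {f: int(flagged[f].sum()) for f in EXCLUSION_FLAGS}
    keep = ~flagged.any(axis=1)
    out = cohort[keep].copy()
    counts["excluded_total"] = int((~keep).sum())
    counts["retained"] = int(keep.sum())
    for reason, n in counts.items():
        logger.info("exclusions: %s = %d", reason, n)
    if out.empty:
        warnings.warn("all patients excluded; cohort is empty", stacklevel=2)
    out.attrs = dict(cohort.attrs)
    out.attrs["exclusion_counts"] = counts
    return out


# ---------------------------------------------------------------------------
# normality

def ks_normality(values: np.ndarray | pd.Series) -> float:
    """Kolmogorov-Smirnov normality p-value with estimated mean/SD.

    Because mean and SD are estimated from the sample, the naive KS p-value
    is anti-conservative; the Lilliefors-corrected null distribution is used
    instead.  Requires n >= 5 and non-constant input.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need at least 5 values for the normality test, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


# ---------------------------------------------------------------------------
# inter-observer agreement

@dataclass(frozen=True)
class ICCResult:
    """Single-measure ICC under a two-way random, absolute-agreement model."""

    icc: float
    ci95: tuple[float, float]
    model: str = "ICC(2,1) two-way random, absolute agreement, single rater"


def icc_absolute_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) from two-way ANOVA mean squares, with an F-based CI.

    ``ratings`` is subjects x raters with no missing cells (>= 5 subjects).
    The estimate is (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n); the
    confidence interval follows the standard F-approximation for the
    absolute-agreement single-measure case.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("ratings must be a 2-D subjects x raters array (>= 2 raters)")
    if not np.isfinite(X).all():
        raise ValueError("ratings contain missing/non-finite cells")
    n, k = X.shape
    if n < 5:
        raise ValueError(f"need >= 5 subjects, got {n}")

    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # subjects
    msc = ss_cols / (k - 1)          # raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # Satterthwaite df for the rater+error combination, then F-based bounds
    if mse == 0 and msc == 0:
        ci = (1.0, 1.0)
    else:
        r = icc
        a = k * r / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            ci = (1.0, 1.0)
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            ci = (float(lower), float(upper))
    return ICCResult(icc=float(icc), ci95=ci)


# ---------------------------------------------------------------------------
# ANCOVA

@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]
    difference: float  # adjusted mean difference (first - second)
    p_raw: float
    p_bonferroni: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class AncovaResult:
    """Age-adjusted group comparison of an outcome."""

    adjusted_means: dict[str, float]
    overall_p: float
    contrasts: list[PairwiseContrast]
    group: str
    covariate: str


def ancova_adjusted_compare(
    cohort: pd.DataFrame,
    outcome: str = "alps",
    group: str = "grade",
    covariate: str = "age",
) -> AncovaResult:
    """ANCOVA: outcome ~ group (dummy-coded) + covariate, least squares.

    Adjusted group means are the model predictions at the grand-mean
    covariate.  All pairwise contrasts are tested with a Bonferroni
    multiplier equal to the number of pairs; each CI uses the t quantile at
    alpha divided by that multiplier, matching the corrected p-values.  When
    the covariate is constant it is dropped and the model reduces to a
    one-way ANOVA (adjusted means = raw group means).
    """
    df = cohort[[outcome, group, covariate]].dropna()
    levels = sorted(df[group].unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"need >= 2 groups in {group!r}")
    sizes = df[group].value_counts()
    if (sizes < 3).any():
        raise ValueError(f"every group needs >= 3 members, got {sizes.to_dict()}")

    y = df[outcome].to_numpy(float)
    n = len(y)
    cov = df[covariate].to_numpy(float)
    use_cov = np.ptp(cov) > 0
    # design: intercept + (g-1) dummies + covariate
    dummies = [(df[group] == lv).to_numpy(float) for lv in levels[1:]]
    cols = [np.ones(n), *dummies] + ([cov] if use_cov else [])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular ANCOVA design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    # overall group F-test vs covariate-only model
    cols0 = [np.ones(n)] + ([cov] if use_cov else [])
    X0 = np.column_stack(cols0)
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(resid @ resid)
    q = len(levels) - 1
    fstat = ((rss0 - rss1) / q) / (rss1 / dof)
    overall_p = float(sps.f.sf(fstat, q, dof))

    mean_cov = cov.mean()
    adj = {}
    rows = {}
    for i, lv in enumerate(levels):
        row = np.zeros(X.shape[1])
        row[0] = 1.0
        if i > 0:
            row[i] = 1.0
        if use_cov:
            row[-1] = mean_cov
        rows[lv] = row
        adj[lv] = float(row @ beta)

    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    tq = sps.t.ppf(1 - 0.05 / (2 * m), dof)
    contrasts = []
    for a, b in pairs:
        c = rows[a] - rows[b]
        diff = float(c @ beta)
        se = float(np.sqrt(s2 * c @ xtx_inv @ c))
        t = diff / se
        p_raw = float(2 * sps.t.sf(abs(t), dof))
        contrasts.append(
            PairwiseContrast(
                pair=(str(a), str(b)),
                difference=diff,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * m),
                ci95=(diff - tq * se, diff + tq * se),
            )
        )
    return AncovaResult(
        adjusted_means={str(k): v for k, v in adj.items()},
        overall_p=overall_p,
        contrasts=contrasts,
        group=group,
        covariate=covariate,
    )


# ---------------------------------------------------------------------------
# regression machinery

def encode_predictors(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric coding of predictors (see module docstring for conventions)."""
    out = {}
    for col in columns:
        if col in _CODINGS and not pd.api.types.is_numeric_dtype(cohort[col]):
            mapping = _CODINGS[col]
            vals = cohort[col]
            bad = ~vals.isin(mapping)
            if bad.any():
                raise ValueError(
                    f"unknown {col} value(s) {sorted(vals[bad].unique())}"
                )
            out[col] = vals.map(mapping).astype(float)
        else:
            out[col] = cohort[col].astype(float)
    return pd.DataFrame(out, index=cohort.index)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients, two-sided p-values and R^2 for y ~ X (X incl. intercept)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    rss = resid @ resid
    s2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(s2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, pvals, float(r2)


@dataclass(frozen=True)
class RegressionResult:
    """Standardized-coefficient regression summary."""

    predictors: list[str]
    beta: dict[str, float]  # standardized coefficients
    p: dict[str, float]
    r2: float
    n: int
    vif: dict[str, float] = field(default_factory=dict)


def univariable_regressions(
    cohort: pd.DataFrame,
    outcome: str = "alps",
    predictors: tuple[str, ...] = DEFAULT_CANDIDATES,
) -> dict[str, RegressionResult]:
    """Simple least squares of the z-scored outcome on each z-scored predictor.

    The standardized coefficient of a simple regression equals the Pearson
    correlation.  Zero-variance predictors are skipped with a warning.
    """
    enc = encode_predictors(cohort, list(predictors))
    y = _zscore(cohort[outcome].to_numpy(float))
    n = len(y)
    out: dict[str, RegressionResult] = {}
    for name in predictors:
        x = enc[name].to_numpy(float)
        if x.std(ddof=1) == 0:
            warnings.warn(f"predictor {name!r} has zero variance; skipped", stacklevel=2)
            continue
        X = np.column_stack([np.ones(n), _zscore(x)])
        beta, pvals, r2 = _ols_pvalues(X, y)
        out[name] = RegressionResult(
            predictors=[name],
            beta={name: float(beta[1])},
            p={name: float(pvals[1])},
            r2=r2,
            n=n,
        )
    return out


def stepwise_multivariable(
    cohort: pd.DataFrame,
    outcome: str = "alps",
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> RegressionResult:
    """Stepwise (forward entry / backward removal) multivariable selection.

    At each step the not-yet-included candidate with the smallest partial
    p-value enters if p <= ``p_enter``; any included predictor whose partial
    p rises above ``p_remove`` is then removed (largest first).  Iterates to
    stability.  All variables are z-scored, so coefficients are standardized.
    An empty selected set is a valid outcome.
    """
    enc = encode_predictors(cohort, list(candidates))
    usable = [c for c in candidates if enc[c].std(ddof=1) > 0]
    dropped = set(candidates) - set(usable)
    if dropped:
        warnings.warn(f"zero-variance candidate(s) skipped: {sorted(dropped)}", stacklevel=2)
    y = _zscore(cohort[outcome].to_numpy(float))
    n = len(y)
    Z = {c: _zscore(enc[c].to_numpy(float)) for c in usable}

    def fit(names: list[str]) -> tuple[np.ndarray, np.ndarray, float]:
        X = np.column_stack([np.ones(n)] + [Z[c] for c in names])
        return _ols_pvalues(X, y)

    selected: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward
        remaining = [c for c in usable if c not in selected]
        if remaining:
            trial_p = {}
            for c in remaining:
                _, pv, _ = fit(selected + [c])
                trial_p[c] = pv[-1]
            best = min(trial_p, key=lambda c: (trial_p[c], usable.index(c)))
            if trial_p[best] <= p_enter:
                selected.append(best)
                changed = True
        # backward
        while len(selected) > 0:
            _, pv, _ = fit(selected)
            worst_i = int(np.argmax(pv[1:]))
            if pv[1 + worst_i] > p_remove:
                selected.pop(worst_i)
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        return RegressionResult(predictors=[], beta={}, p={}, r2=0.0, n=n)
    beta, pvals, r2 = fit(selected)
    enc_sel = pd.DataFrame({c: Z[c] for c in selected})
    vifs = vif(enc_sel, tuple(selected)) if len(selected) >= 2 else {selected[0]: 1.0}
    return RegressionResult(
        predictors=list(selected),
        beta={c: float(b) for c, b in zip(selected, beta[1:])},
        p={c: float(p) for c, p in zip(selected, pvals[1:])},
        r2=r2,
        n=n,
        vif=vifs,
    )


def vif(data: pd.DataFrame, predictors: tuple[str, ...]) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j), R^2_j from
    regressing predictor j on the remaining predictors (with intercept).

    Perfect collinearity reports ``inf`` with a warning.
    """
    if len(predictors) < 2:
        raise ValueError("need >= 2 predictors for VIF")
    enc = encode_predictors(data, list(predictors))
    out = {}
    n = len(enc)
    for j in predictors:
        others = [c for c in predictors if c != j]
        X = np.column_stack([np.ones(n)] + [enc[c].to_numpy(float) for c in others])
        yj = enc[j].to_numpy(float)
        _, _, r2 = _ols_pvalues(X, yj)
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {j!r} is perfectly collinear with the others", stacklevel=2)
            out[j] = float("inf")
        else:
            out[j] = float(1.0 / (1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# summaries

def pooled_mean(group_means: np.ndarray, sizes: np.ndarray) -> float:
    """Size-weighted mean of group means — equals the pooled mean exactly."""
    group_means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if group_means.shape != sizes.shape:
        raise ValueError("group_means and sizes must align")
    if sizes.sum() <= 0:
        raise ValueError("total size must be positive")
    return float((group_means * sizes).sum() / sizes.sum())


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-grade and pooled mean +/- SD for age, volumes and ALPS, plus
    sex / side / IDH1 counts, in one tidy table (rows = statistics)."""
    if cohort.empty:
        raise ValueError("empty cohort")
    grades = [g for g in ("II", "III", "IV") if g in set(cohort["grade"])]
    groups = {g: cohort[cohort["grade"] == g] for g in grades}
    groups["All"] = cohort

    numeric = ["age", *VOLUME_COLUMNS, "alps"]
    rows = {}
    rows["n"] = {g: len(d) for g, d in groups.items()}
    for col in numeric:
        rows[f"{col}_mean"] = {g: d[col].mean() for g, d in groups.items()}
        rows[f"{col}_sd"] = {g: d[col].std(ddof=1) for g, d in groups.items()}
    for col, val in (("sex", "man"), ("side", "right"), ("idh1", "mutant")):
        rows[f"n_{val}"] = {g: int((d[col] == val).sum()) for g, d in groups.items()}
        rows[f"pct_{val}"] = {
            g: 100.0 * (d[col] == val).mean() for g, d in groups.items()
        }
    return pd.DataFrame(rows).T
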