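"""Confound correction and total-volume group statistics.

ROI densities are residualized against nuisance covariates (age, gender and
intracranial volume by default; total GM volume is accepted as an
alternative) by per-ROI ordinary least squares, and the total neocortical
GM volume is compared across groups with an ANCOVA plus planned
patient-vs-healthy contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GROUPS, canonical_group

DEFAULT_COVARIATES = ("age", "gender", "icv")


@dataclass
class CorrectedGM:
    """Residual ROI densities after covariate regression.

    ``data`` is subjects x ROIs (index = subject_id); ``groups`` is the
    aligned group label per subject; ``covariates`` records the covariates
    actually used (constant ones may have been dropped).
    """

    data: pd.DataFrame
    groups: pd.Series
    covariates: list[str] = field(default_factory=list)

    @property
    def roi_columns(self) -> list[str]:
        return list(self.data.columns)

    def group_matrix(self, group: str) -> np.ndarray:
        """Residual matrix restricted to one group (subjects x ROIs)."""
        g = canonical_group(group)
        return self.data.loc[(self.groups == g).to_numpy()].to_numpy(dtype=float)


@dataclass
class AncovaResult:
    """Group-factor F test plus planned patient-vs-healthy contrasts."""

    F: float
    df: tuple[int, int]
    p: float
    contrasts: dict[str, dict[str, float]]


def _design_matrix(
    cohort: pd.DataFrame, covariates: list[str] | tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design; gender dummy-coded (F=0 reference).

    Constant covariates are dropped with a warning; an exactly collinear
    covariate pair raises with both names.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort table")
        if cov == "gender":
            x = (cohort["gender"].astype(str).str.strip().str.upper() == "M").to_numpy(
                dtype=float
            )
        else:
            x = cohort[cov].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"covariate {cov!r} contains missing values")
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {cov!r} is constant and was dropped", UserWarning)
            continue
        cols.append(x)
        names.append(cov)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = np.corrcoef(cols[i], cols[j])[0, 1]
            if abs(r) > 1 - 1e-12:
                raise ValueError(
                    f"covariates {names[i]!r} and {names[j]!r} are collinear"
                )
    X = np.column_stack([np.ones(len(cohort))] + cols) if cols else np.ones((len(cohort), 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient covariate design: {names}")
    return X, names


def residualize_gm(
    cohort: pd.DataFrame, covariates: list[str] | tuple[str, ...] = DEFAULT_COVARIATES
) -> CorrectedGM:
    """Residualize every ROI density column against the covariates.

    Per ROI, ordinary least squares of density on the covariates (plus
    intercept) across all subjects; the residuals are returned. Column
    means are ~0 and residuals are orthogonal to every numeric covariate
    used, by the OLS normal equations.
    """
    roi_cols = [c for c in cohort.columns if c.startswith("roi_")]
    if not roi_cols:
        raise ValueError("cohort table has no roi_* density columns")
    if len(cohort) < len(covariates) + 2:
        raise ValueError(
            f"need at least {len(covariates) + 2} subjects to residualize "
            f"on {len(covariates)} covariates, got {len(cohort)}"
        )
    X, used = _design_matrix(cohort, covariates)
    Y = cohort[roi_cols].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    data = pd.DataFrame(resid, columns=roi_cols, index=cohort["subject_id"].to_numpy())
    groups = pd.Series(
        [canonical_group(g) for g in cohort["group"]], index=data.index, name="group"
    )
    return CorrectedGM(data=data, groups=groups, covariates=used)


def total_gm_ancova(
    cohort: pd.DataFrame,
    covariates: list[str] | tuple[str, ...] = DEFAULT_COVARIATES,
    holm_contrasts: bool = False,
) -> AncovaResult:
    """ANCOVA of total GM volume on group, controlling for the covariates.

    The group factor is tested with an extra-sum-of-squares F test (full
    model with group dummies vs covariates-only reduced model). Planned
    pairwise contrasts compare each patient group against healthy and are
    reported unadjusted unless ``holm_contrasts`` is set.
    """
    groups = pd.Series([canonical_group(g) for g in cohort["group"]])
    levels = [g for g in GROUPS if g in set(groups)]
    if len(levels) < 2:
        raise ValueError("ANCOVA needs at least two groups")
    counts = groups.value_counts()
    small = [g for g in levels if counts[g] < 3]
    if small:
        raise ValueError(f"groups with n < 3: {small}")
    y = cohort["total_gm_volume"].to_numpy(dtype=float)
    X_cov, _ = _design_matrix(cohort, covariates)
    ref = "healthy" if "healthy" in levels else levels[0]
    dummy_levels = [g for g in levels if g != ref]
    dummies = np.column_stack(
        [(groups == g).to_numpy(dtype=float) for g in dummy_levels]
    )
    X_full = np.column_stack([X_cov, dummies])
    n = len(y)

    def rss(X: np.ndarray) -> float:
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        return float(r @ r)

    rss_red = rss(X_cov)
    rss_full = rss(X_full)
    df1 = len(dummy_levels)
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough subjects for the full ANCOVA model")
    F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))

    # planned contrasts: dummy coefficients vs healthy reference
    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    beta = XtX_inv @ X_full.T @ y
    sigma2 = rss_full / df2
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    contrasts: dict[str, dict[str, float]] = {}
    raw_p = []
    for k, g in enumerate(dummy_levels):
        idx = X_cov.shape[1] + k
        t = beta[idx] / se[idx]
        pc = float(2 * stats.t.sf(abs(t), df2))
        contrasts[g] = {"estimate": float(beta[idx]), "t": float(t), "p": pc}
        raw_p.append(pc)
    if holm_contrasts and raw_p:
        from .regional import holm_adjust

        adj = holm_adjust(np.array(raw_p))
        for g, pa in zip(dummy_levels, adj):
            contrasts[g]["p_holm"] = float(pa)
    return AncovaResult(F=float(F), df=(df1, df2), p=p, contrasts=contrasts)


def age_slopes(cohort: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-group OLS of total GM volume on age: slope (cm^3/yr), Pearson R, p."""
    out: dict[str, dict[str, float]] = {}
    groups = pd.Series([canonical_group(g) for g in cohort["group"]])
    for g in GROUPS:
        mask = (groups == g).to_numpy()
        if not mask.any():
            continue
        age = cohort.loc[mask, "age"].to_numpy(dtype=float)
        vol = cohort.loc[mask, "total_gm_volume"].to_numpy(dtype=float)
        if len(age) < 3:
            raise ValueError(f"group {g!r} needs n >= 3 for an age slope, got {len(age)}")
        if np.ptp(age) == 0:
            raise ValueError(f"group {g!r} has zero age variance")
        fit = stats.linregress(age, vol)
        out[g] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "R": float(fit.rvalue),
            "p": float(fit.pvalue),
            "n": int(len(age)),
        }
    return out
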