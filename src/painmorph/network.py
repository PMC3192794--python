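"""Structural covariance networks and their distance dependence.

Structural covariance treats the across-subject correlation of corrected GM
density between two ROIs as an anatomical association. Its dependence on
the Euclidean distance between ROI centroids is summarized by a linear
regression over within-hemisphere pairs, 25-mm distance bins, and
seed-based maps of significantly strong connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .confound import CorrectedGM
from .regional import holm_adjust
from .simulate import ROIAtlas, canonical_group


@dataclass
class StructuralCovariance:
    """ROI x ROI Pearson correlation matrix of corrected densities for one group."""

    group: str
    matrix: pd.DataFrame
    n_subjects: int

    @property
    def roi_columns(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class DistanceFit:
    """Linear fit of pairwise correlation on inter-ROI distance.

    ``R`` is the magnitude of the fit correlation; the raw slope sign is
    reported separately (the regression slope is in correlation units per
    mm). The pair scatter is retained so slopes can be compared across
    groups with an interaction test.
    """

    group: str
    hemisphere: str | None
    slope: float
    intercept: float
    R: float
    slope_sign: int
    p: float
    n_pairs: int
    distances: np.ndarray = field(repr=False)
    correlations: np.ndarray = field(repr=False)
    roi_columns: list[str] = field(default_factory=list, repr=False)


def structural_covariance(corrected: CorrectedGM, group: str) -> StructuralCovariance:
    """Pairwise Pearson correlation of corrected ROI densities across one group.

    Entry (i, j) correlates ROI i's and ROI j's corrected densities over
    the group's subjects. A zero-variance ROI yields undefined entries,
    reported as NaN with a warning.
    """
    g = canonical_group(group)
    block = corrected.group_matrix(g)
    if block.shape[0] < 3:
        raise ValueError(f"group {g!r} needs n >= 3 subjects, got {block.shape[0]}")
    sd = block.std(axis=0)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.corrcoef(block, rowvar=False)
    if degenerate.any():
        bad = [corrected.roi_columns[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance ROI columns in group {g!r}: {bad}; correlations set to NaN",
            UserWarning,
        )
        mat[degenerate, :] = np.nan
        mat[:, degenerate] = np.nan
    np.fill_diagonal(mat, 1.0)
    matrix = pd.DataFrame(mat, index=corrected.roi_columns, columns=corrected.roi_columns)
    return StructuralCovariance(group=g, matrix=matrix, n_subjects=block.shape[0])


def pairwise_distances(atlas: ROIAtlas) -> pd.DataFrame:
    """Euclidean distances (mm) between all ROI centroid pairs."""
    coords = atlas.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    cols = atlas.roi_columns
    return pd.DataFrame(d, index=cols, columns=cols)


def _pair_scatter(
    cov: StructuralCovariance,
    dist: pd.DataFrame,
    mask: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Upper-triangle (distance, correlation) pairs, optionally ROI-masked."""
    cols = cov.roi_columns
    if list(dist.columns) != cols:
        raise ValueError("covariance and distance matrices index different ROIs")
    cmat = cov.matrix.to_numpy()
    dmat = dist.to_numpy()
    if mask is not None:
        idx = np.flatnonzero(mask)
        cmat = cmat[np.ix_(idx, idx)]
        dmat = dmat[np.ix_(idx, idx)]
        cols = [cols[i] for i in idx]
    iu = np.triu_indices(len(cols), k=1)
    r = cmat[iu]
    d = dmat[iu]
    keep = ~np.isnan(r)
    return d[keep], r[keep], cols


def correlation_distance_regression(
    cov: StructuralCovariance,
    dist: pd.DataFrame,
    atlas: ROIAtlas | None = None,
    hemisphere: str | None = "L",
    use_abs: bool = False,
) -> DistanceFit:
    """OLS of pairwise correlation on inter-ROI distance.

    By default only within-hemisphere pairs of the left hemisphere enter
    (pass ``hemisphere=None`` for the whole brain; then ``atlas`` is not
    needed). ``use_abs`` regresses absolute correlations instead of signed
    ones.
    """
    mask = None
    if hemisphere is not None:
        if atlas is None:
            raise ValueError("atlas is required for a within-hemisphere fit")
        mask = atlas.hemisphere_mask(hemisphere)
    d, r, cols = _pair_scatter(cov, dist, mask)
    if use_abs:
        r = np.abs(r)
    if len(d) < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.ptp(d) == 0:
        raise ValueError("degenerate regression: all pair distances are equal")
    fit = stats.linregress(d, r)
    return DistanceFit(
        group=cov.group,
        hemisphere=hemisphere,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        R=float(abs(fit.rvalue)),
        slope_sign=int(np.sign(fit.slope)),
        p=float(fit.pvalue),
        n_pairs=len(d),
        distances=d,
        correlations=r,
        roi_columns=cols,
    )


def compare_slopes(fit_a: DistanceFit, fit_b: DistanceFit) -> dict[str, float]:
    """Test the slope difference of two distance fits.

    Pools both pair scatters into one regression with a group indicator and
    a group x distance interaction term; the interaction t statistic tests
    the slope difference. Both fits must come from the same ROI set.
    """
    if fit_a.roi_columns != fit_b.roi_columns:
        raise ValueError("fits are based on different ROI sets")
    d = np.concatenate([fit_a.distances, fit_b.distances])
    r = np.concatenate([fit_a.correlations, fit_b.correlations])
    g = np.concatenate(
        [np.zeros(len(fit_a.distances)), np.ones(len(fit_b.distances))]
    )
    X = np.column_stack([np.ones_like(d), d, g, g * d])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    resid = r - X @ beta
    df = len(r) - X.shape[1]
    if df <= 0:
        raise ValueError("not enough pairs for the interaction test")
    sigma2 = float(resid @ resid) / df
    cov_beta = np.linalg.pinv(X.T @ X) * sigma2
    est = float(beta[3])
    se = float(np.sqrt(cov_beta[3, 3]))
    t = est / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), df))
    return {"interaction": est, "se": se, "t": float(t), "p": p, "df": int(df)}


def bin_correlations(
    cov: StructuralCovariance,
    dist: pd.DataFrame,
    bin_width_mm: float = 25.0,
    n_bins: int | None = 6,
    atlas: ROIAtlas | None = None,
    hemisphere: str | None = None,
    other: StructuralCovariance | None = None,
) -> pd.DataFrame:
    """Per-bin mean/SD of pairwise correlations over 25-mm distance ranges.

    Bins are half-open, lower-inclusive: ``[k*w, (k+1)*w)``, so a pair at
    exactly 25 mm lands in the second bin. With ``n_bins=None`` enough bins
    are used to cover the observed distance range. If ``other`` is given (e.g. a
    patient group against healthy), a per-bin Welch two-sample test of the
    correlation means is added; empty bins carry n = 0 and no test.
    """
    mask = atlas.hemisphere_mask(hemisphere) if hemisphere is not None else None
    d, r, _ = _pair_scatter(cov, dist, mask)
    if n_bins is None:  # auto-extend to cover the observed range
        n_bins = int(np.floor(d.max() / bin_width_mm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_mm
    if d.max() >= edges[-1]:
        raise ValueError(
            f"{n_bins} bins of {bin_width_mm} mm do not cover the observed "
            f"distance range (max {d.max():.1f} mm)"
        )
    rows = []
    if other is not None:
        d2, r2, _ = _pair_scatter(other, dist, mask)
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        sel = (d >= lo) & (d < hi)
        vals = r[sel]
        row: dict[str, float] = {
            "bin": k,
            "lo_mm": lo,
            "hi_mm": hi,
            "n": int(sel.sum()),
            "mean": float(vals.mean()) if sel.any() else np.nan,
            "sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
        }
        if other is not None:
            sel2 = (d2 >= lo) & (d2 < hi)
            vals2 = r2[sel2]
            row["n_other"] = int(sel2.sum())
            row["mean_other"] = float(vals2.mean()) if sel2.any() else np.nan
            if sel.sum() > 1 and sel2.sum() > 1:
                t, p = stats.ttest_ind(vals, vals2, equal_var=False)
                row["t"] = float(t)
                row["p"] = float(p)
            else:
                row["t"] = np.nan
                row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def strong_connections(
    cov: StructuralCovariance,
    seed_roi: str,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ROIs strongly connected to a seed ROI (r > threshold, Holm p < alpha).

    Correlation-test p-values use the group's subject count; the Holm
    correction runs over all seed pairs with defined correlations. Pairs
    with missing correlations are excluded and reported via a warning.
    """
    if seed_roi not in cov.roi_columns:
        raise ValueError(f"seed ROI {seed_roi!r} not in the covariance matrix")
    r_all = cov.matrix[seed_roi].drop(index=seed_roi)
    missing = r_all.index[r_all.isna()].tolist()
    if missing:
        warnings.warn(
            f"seed {seed_roi!r} has undefined correlations with {missing}; excluded",
            UserWarning,
        )
        r_all = r_all.dropna()
    n = cov.n_subjects
    r = r_all.to_numpy(dtype=float).clip(-1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p_raw = 2 * stats.t.sf(np.abs(t), n - 2)
    p_holm = holm_adjust(p_raw)
    table = pd.DataFrame(
        {"r": r, "p_raw": p_raw, "p_holm": p_holm}, index=r_all.index
    )
    out = table[(table["r"] > r_threshold) & (table["p_holm"] < alpha)].copy()
    out.sort_values("r", ascending=False, inplace=True)
    out.index.name = "roi"
    return out
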