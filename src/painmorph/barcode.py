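"""Ternary GM-density barcodes, threshold optimization and classification.

A subject's corrected ROI densities are z-scored against the subject's own
across-ROI mean and SD, then ternarized at a symmetric threshold ±θ into
{-1, 0, +1}: ROIs with clearly high, average, or clearly low GM density
relative to the subject's own profile. Group barcodes are built the same
way from per-group mean profiles. θ is chosen by scanning a grid and
balancing two curves: the sum of pairwise Pearson correlations between the
group barcodes (to be minimized — maximally distinct groups) and the joint
entropy of the group symbols across ROIs (kept near its maximum — maximal
retained information). Subjects are classified to the group whose barcode
correlates highest with their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confound import CorrectedGM
from .simulate import GROUPS, canonical_group

DEFAULT_THETA_GRID = np.round(np.arange(0.0, 2.51, 0.01), 10)
#: Threshold used when none is supplied; a typical optimum of the joint
#: entropy / group-difference scan on whole-brain profiles.
DEFAULT_THETA = 0.56


class UnclassifiableError(ValueError):
    """Raised when a barcode carries no usable signal (all zeros / constant)."""


def zprofile(values: np.ndarray) -> np.ndarray:
    """z-score a profile against its own across-ROI mean and SD (ddof=1).

    The result has mean 0 and SD 1; adding a constant to all ROIs or
    rescaling the whole profile by a positive factor leaves it unchanged.
    A constant profile has no defined z-score and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zprofile needs a 1-D profile with >= 2 ROIs")
    if np.ptp(x) == 0:
        raise ValueError("constant profile: z-score undefined")
    return (x - x.mean()) / x.std(ddof=1)


def ternarize(z: np.ndarray, theta: float) -> np.ndarray:
    """Ternarize a z-profile at the symmetric thresholds ±θ.

    +1 where z > θ, -1 where z < -θ, else 0; values exactly at |z| = θ map
    to 0 (in particular θ = 0 sends exact zeros to 0, everything else to
    its sign).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    z = np.asarray(z, dtype=float)
    out = np.zeros(z.shape, dtype=int)
    out[z > theta] = 1
    out[z < -theta] = -1
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _roi_indices(corrected: CorrectedGM, roi_subset: list[str] | None) -> np.ndarray:
    cols = corrected.roi_columns
    if roi_subset is None:
        return np.arange(len(cols))
    missing = [r for r in roi_subset if r not in cols]
    if missing:
        raise ValueError(f"roi_subset names not in corrected data: {missing}")
    return np.array([cols.index(r) for r in roi_subset])


def _profile_barcode(
    profile: np.ndarray,
    theta: float,
    idx: np.ndarray,
    renormalize: bool,
) -> np.ndarray:
    """Barcode of one profile, optionally restricted to an ROI subset.

    By default the z-score is taken over the whole profile and then
    subset (the subset inherits the whole-brain normalization);
    ``renormalize`` recomputes the z-score over the subset alone.
    """
    if renormalize:
        return ternarize(zprofile(profile[idx]), theta)
    return ternarize(zprofile(profile), theta)[idx]


def group_barcode(
    corrected: CorrectedGM,
    group: str,
    theta: float = DEFAULT_THETA,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
) -> np.ndarray:
    """Barcode of a group's mean corrected-density profile."""
    g = canonical_group(group)
    block = corrected.group_matrix(g)
    if block.shape[0] < 1:
        raise ValueError(f"group {g!r} has no subjects")
    idx = _roi_indices(corrected, roi_subset)
    return _profile_barcode(block.mean(axis=0), theta, idx, renormalize)


def subject_barcodes(
    corrected: CorrectedGM,
    theta: float = DEFAULT_THETA,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Barcodes for every subject (rows = subjects, ternary columns)."""
    idx = _roi_indices(corrected, roi_subset)
    cols = [corrected.roi_columns[i] for i in idx]
    rows = [
        _profile_barcode(row, theta, idx, renormalize)
        for row in corrected.data.to_numpy(dtype=float)
    ]
    return pd.DataFrame(rows, index=corrected.data.index, columns=cols)


@dataclass
class ThresholdScan:
    """Full θ-scan curves plus the selected optimum ``theta_star``."""

    theta: np.ndarray
    sum_r: np.ndarray
    joint_entropy: np.ndarray
    theta_star: float
    excluded: list[float] = field(default_factory=list)


def joint_entropy_bits(barcodes: np.ndarray) -> float:
    """Joint Shannon entropy (bits) of the per-ROI group-symbol tuples.

    ``barcodes`` is groups x ROIs; each ROI contributes one tuple of group
    symbols, and the entropy is taken over the empirical tuple frequencies
    (up to 3^G cells).
    """
    cells, counts = np.unique(barcodes.T, axis=0, return_counts=True)
    freq = counts / counts.sum()
    return float(-(freq * np.log2(freq)).sum())


def optimize_threshold(
    corrected: CorrectedGM,
    theta_grid: np.ndarray | None = None,
    groups: list[str] | None = None,
    entropy_tolerance: float = 0.05,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
) -> ThresholdScan:
    """Scan θ and pick the group-separating, information-preserving optimum.

    For each θ the group barcodes are rebuilt; ``sumR(θ)`` is the sum of
    pairwise Pearson correlations between them and ``jointH(θ)`` the joint
    entropy of the group symbols across ROIs. θ* minimizes sumR among the
    θ whose joint entropy is within ``entropy_tolerance`` of the maximum
    (ties: higher entropy, then smaller θ). θ values where some barcode
    has zero variance (correlation undefined) are excluded with a warning.
    """
    if theta_grid is None:
        theta_grid = DEFAULT_THETA_GRID
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta grid is empty")
    if groups is None:
        groups = [g for g in GROUPS if g in set(corrected.groups)]
    if len(groups) < 2:
        raise ValueError("need at least two groups to optimize the threshold")
    idx = _roi_indices(corrected, roi_subset)
    profiles = [corrected.group_matrix(g).mean(axis=0) for g in groups]
    zs = (
        [zprofile(p[idx]) for p in profiles]
        if renormalize
        else [zprofile(p)[idx] for p in profiles]
    )
    sum_r = np.full(theta_grid.size, np.nan)
    joint_h = np.full(theta_grid.size, np.nan)
    excluded: list[float] = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for k, theta in enumerate(theta_grid):
        codes = np.array([ternarize(z, theta) for z in zs])
        joint_h[k] = joint_entropy_bits(codes)
        identical = all(
            np.array_equal(codes[i], codes[j])
            for i in range(len(codes))
            for j in range(i + 1, len(codes))
        )
        if identical and codes.std(axis=1).min() > 0:
            # degenerate-but-defined case: every pair correlates at exactly 1
            sum_r[k] = float(n_pairs)
            continue
        rs = [
            _pearson(codes[i], codes[j])
            for i in range(len(codes))
            for j in range(i + 1, len(codes))
        ]
        if np.isnan(rs).any():
            excluded.append(float(theta))
            continue
        sum_r[k] = float(np.sum(rs))
    valid = ~np.isnan(sum_r)
    if not valid.any():
        raise ValueError("no valid threshold: every θ yields a degenerate barcode")
    if excluded:
        warnings.warn(
            f"{len(excluded)} θ value(s) excluded (zero-variance barcode)", UserWarning
        )
    h_max = np.nanmax(joint_h[valid])
    candidates = valid & (joint_h >= (1 - entropy_tolerance) * h_max)
    if not candidates.any():
        candidates = valid
    cand_idx = np.flatnonzero(candidates)
    # min sumR, then max entropy, then smallest θ
    order = np.lexsort((theta_grid[cand_idx], -joint_h[cand_idx], sum_r[cand_idx]))
    theta_star = float(theta_grid[cand_idx[order[0]]])
    return ThresholdScan(
        theta=theta_grid,
        sum_r=sum_r,
        joint_entropy=joint_h,
        theta_star=theta_star,
        excluded=excluded,
    )


@dataclass
class Classification:
    label: str
    correlations: dict[str, float]
    tie: bool = False


def classify(
    subject_barcode: np.ndarray, group_barcodes: dict[str, np.ndarray]
) -> Classification:
    """Assign a subject to the group with the highest barcode correlation.

    Ties are broken by the fixed group order (healthy, CBP, CRPS, OA) and
    flagged. A subject barcode with no variance (e.g. all zeros) cannot be
    correlated and raises :class:`UnclassifiableError`.
    """
    sb = np.asarray(subject_barcode)
    if sb.std() == 0:
        raise UnclassifiableError("subject barcode has no variance (all symbols equal)")
    order = [g for g in GROUPS if g in group_barcodes] + [
        g for g in group_barcodes if g not in GROUPS
    ]
    corrs: dict[str, float] = {}
    for g in order:
        gb = np.asarray(group_barcodes[g])
        if gb.shape != sb.shape:
            raise ValueError(f"group barcode {g!r} length mismatch")
        if gb.std() == 0:
            raise ValueError(f"group barcode {g!r} has no variance")
        corrs[g] = _pearson(sb, gb)
    best = max(corrs.values())
    winners = [g for g in order if corrs[g] == best]
    return Classification(label=winners[0], correlations=corrs, tie=len(winners) > 1)


def classify_cohort(
    corrected: CorrectedGM,
    theta: float = DEFAULT_THETA,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
    group_barcodes: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Classify every subject against group barcodes (built from the full cohort
    unless supplied). Returns true/predicted labels and the per-group correlations."""
    groups = [g for g in GROUPS if g in set(corrected.groups)]
    if group_barcodes is None:
        group_barcodes = {
            g: group_barcode(corrected, g, theta, roi_subset, renormalize) for g in groups
        }
    codes = subject_barcodes(corrected, theta, roi_subset, renormalize)
    rows = []
    for sid, row in zip(codes.index, codes.to_numpy()):
        res = classify(row, group_barcodes)
        rec = {"subject_id": sid, "true": corrected.groups.loc[sid], "pred": res.label,
               "tie": res.tie}
        rec.update({f"r_{g}": res.correlations[g] for g in group_barcodes})
        rows.append(rec)
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class ClassificationReport:
    """Confusion matrix with per-class sensitivity/specificity in percent."""

    confusion: pd.DataFrame  # true x predicted counts
    sensitivity: dict[str, float]
    specificity: dict[str, float]


def confusion_metrics(
    true_labels, predicted_labels, classes: list[str] | None = None
) -> ClassificationReport:
    """Per-class sensitivity and specificity (%) from label pairs.

    sensitivity_c = TP_c / (count of class c in truth); specificity_c =
    TN_c / (count of non-c in truth). A class absent from the truth has
    undefined sensitivity, reported as NaN.
    """
    t = [canonical_group(x) for x in true_labels]
    p = [canonical_group(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    if classes is None:
        present = set(t) | set(p)
        classes = [g for g in GROUPS if g in present]
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for ti, pi in zip(t, p):
        conf.loc[ti, pi] += 1
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    n = len(t)
    for c in classes:
        n_c = sum(1 for x in t if x == c)
        tp = conf.loc[c, c]
        tn = sum(
            1 for ti, pi in zip(t, p) if ti != c and pi != c
        )
        sens[c] = 100.0 * tp / n_c if n_c > 0 else np.nan
        spec[c] = 100.0 * tn / (n - n_c) if n - n_c > 0 else np.nan
    return ClassificationReport(confusion=conf, sensitivity=sens, specificity=spec)


def subsample_validation(
    corrected: CorrectedGM,
    n_per_group: int = 5,
    iterations: int = 10,
    theta: float = DEFAULT_THETA,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
    reoptimize: bool = False,
    seed: int = 0,
) -> dict:
    """Held-out classification with group barcodes built from random subsets.

    Per iteration, ``n_per_group`` subjects per group are drawn at random;
    their mean profiles define the group barcodes (θ fixed, or re-derived
    from the training means when ``reoptimize`` is set); all remaining
    subjects are classified and scored. Training subjects are never
    scored. Returns mean ± SD sensitivity/specificity per class over
    iterations.
    """
    rng = np.random.default_rng(seed)
    labels = corrected.groups
    groups = [g for g in GROUPS if g in set(labels)]
    for g in groups:
        if (labels == g).sum() <= n_per_group:
            raise ValueError(
                f"group {g!r} has {(labels == g).sum()} subjects; "
                f"need more than n_per_group={n_per_group}"
            )
    idx = _roi_indices(corrected, roi_subset)
    full = corrected.data.to_numpy(dtype=float)
    sens_runs: list[dict[str, float]] = []
    spec_runs: list[dict[str, float]] = []
    for _ in range(iterations):
        train_rows: dict[str, np.ndarray] = {}
        train_mask = np.zeros(len(labels), dtype=bool)
        for g in groups:
            members = np.flatnonzero((labels == g).to_numpy())
            chosen = rng.choice(members, size=n_per_group, replace=False)
            train_rows[g] = chosen
            train_mask[chosen] = True
        theta_it = theta
        if reoptimize:
            scan_corr = CorrectedGM(
                data=corrected.data.iloc[train_mask],
                groups=labels.iloc[train_mask],
                covariates=corrected.covariates,
            )
            theta_it = optimize_threshold(
                scan_corr, roi_subset=roi_subset, renormalize=renormalize
            ).theta_star
        anchors = {
            g: _profile_barcode(full[train_rows[g]].mean(axis=0), theta_it, idx, renormalize)
            for g in groups
        }
        held = np.flatnonzero(~train_mask)
        truths, preds = [], []
        for i in held:
            code = _profile_barcode(full[i], theta_it, idx, renormalize)
            try:
                res = classify(code, anchors)
            except UnclassifiableError:
                continue
            truths.append(labels.iloc[i])
            preds.append(res.label)
        report = confusion_metrics(truths, preds, classes=groups)
        sens_runs.append(report.sensitivity)
        spec_runs.append(report.specificity)
    out = {"n_per_group": n_per_group, "iterations": iterations, "per_class": {}}
    for g in groups:
        s = np.array([r[g] for r in sens_runs], dtype=float)
        q = np.array([r[g] for r in spec_runs], dtype=float)
        out["per_class"][g] = {
            "sensitivity_mean": float(np.nanmean(s)),
            "sensitivity_sd": float(np.nanstd(s, ddof=1)) if len(s) > 1 else 0.0,
            "specificity_mean": float(np.nanmean(q)),
            "specificity_sd": float(np.nanstd(q, ddof=1)) if len(q) > 1 else 0.0,
        }
    out["mean_sensitivity"] = float(
        np.nanmean([out["per_class"][g]["sensitivity_mean"] for g in groups])
    )
    out["mean_specificity"] = float(
        np.nanmean([out["per_class"][g]["specificity_mean"] for g in groups])
    )
    return out
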