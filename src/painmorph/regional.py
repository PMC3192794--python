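"""ROI-wise group statistics and the chronicity median split.

One-way ANOVA per ROI on corrected densities with Holm step-down
family-wise correction, selection of the most discriminative ROIs (by an F
threshold or a top-k rule), a median split of patients by pain duration,
and ROI-vs-duration correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .confound import CorrectedGM
from .simulate import canonical_group


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def roi_group_anova(corrected: CorrectedGM, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per ROI on corrected densities across groups.

    Returns a table indexed by ROI column with ``F, df1, df2, p_raw,
    p_holm, significant`` (Holm-adjusted p < alpha). An ROI with zero
    within-group variance gets F = +inf, p = 0, with a warning.
    """
    labels = corrected.groups.to_numpy()
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    masks = [labels == g for g in levels]
    ns = np.array([m.sum() for m in masks])
    if (ns < 2).any():
        raise ValueError(f"every group needs n >= 2, got sizes {dict(zip(levels, ns))}")
    Y = corrected.data.to_numpy(dtype=float)
    n, _ = Y.shape
    k = len(levels)
    grand = Y.mean(axis=0)
    ss_between = np.zeros(Y.shape[1])
    ss_within = np.zeros(Y.shape[1])
    for m, n_g in zip(masks, ns):
        block = Y[m]
        mu = block.mean(axis=0)
        ss_between += n_g * (mu - grand) ** 2
        ss_within += ((block - mu) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    degenerate = ss_within <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} ROI(s) have zero within-group variance; "
            "F reported as +inf",
            UserWarning,
        )
        F[degenerate] = np.inf
    p_raw = stats.f.sf(F, df1, df2)
    p_raw[degenerate] = 0.0
    p_holm = holm_adjust(p_raw)
    table = pd.DataFrame(
        {
            "F": F,
            "df1": df1,
            "df2": df2,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "significant": p_holm < alpha,
        },
        index=corrected.roi_columns,
    )
    table.index.name = "roi"
    return table


def select_discriminative_rois(
    table: pd.DataFrame,
    f_threshold: float | None = None,
    top_k: int | None = None,
) -> list[str]:
    """ROIs passing the selection rule, in descending-F order.

    Exactly one of ``f_threshold`` (keep ROIs with F above it) or ``top_k``
    (keep the k largest F) must be given. Ties are broken by ROI order in
    the table (i.e. ascending roi id). An empty selection is allowed but
    flagged with a warning.
    """
    if table.empty:
        raise ValueError("empty ANOVA table")
    if (f_threshold is None) == (top_k is None):
        raise ValueError("give exactly one of f_threshold or top_k")
    order = np.lexsort((np.arange(len(table)), -table["F"].to_numpy()))
    ranked = table.index.to_numpy()[order]
    if f_threshold is not None:
        selected = [r for r in ranked if table.loc[r, "F"] > f_threshold]
    else:
        if top_k < 0:
            raise ValueError("top_k must be >= 0")
        selected = list(ranked[:top_k])
    if not selected:
        warnings.warn("ROI selection is empty", UserWarning)
    return selected


@dataclass
class ChronicitySplit:
    """Median split of patients by pain duration (ties go to 'short')."""

    median_duration: float
    labels: pd.Series  # index = subject_id, values in {"short", "long"}


def chronicity_median_split(patients: pd.DataFrame) -> ChronicitySplit:
    """Split patients at the sample median of pain duration.

    Subjects exactly at the median are assigned to the short-duration
    grouping, which keeps the partition reproducible. Healthy rows are
    rejected.
    """
    groups = [canonical_group(g) for g in patients["group"]]
    if "healthy" in groups:
        raise ValueError("median split expects patient rows only")
    dur = patients["pain_duration"].to_numpy(dtype=float)
    if np.isnan(dur).any():
        raise ValueError("all patients need a pain_duration")
    med = float(np.median(dur))
    labels = pd.Series(
        np.where(dur <= med, "short", "long"),
        index=patients["subject_id"].to_numpy(),
        name="chronicity",
    )
    return ChronicitySplit(median_duration=med, labels=labels)


def duration_correlation(
    values: np.ndarray,
    durations: np.ndarray,
    log_scale: bool = True,
) -> dict[str, float]:
    """Pearson correlation of a corrected ROI column against pain duration.

    Durations enter on a log10 scale when ``log_scale`` is set (they must
    then be strictly positive). A constant value column has no defined
    correlation and raises.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(durations, dtype=float)
    if x.size != t.size:
        raise ValueError("values and durations differ in length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation")
    if log_scale:
        if (t <= 0).any():
            raise ValueError("durations must be > 0 on a log scale")
        t = np.log10(t)
    if np.ptp(x) == 0 or np.ptp(t) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, t)
    return {"R": float(r), "p": float(p), "n": int(x.size)}


def long_short_roi_contrast(
    corrected: CorrectedGM, split: ChronicitySplit, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch two-sample t per ROI, long- vs short-duration patients, Holm-corrected."""
    labels = split.labels.reindex(corrected.data.index)
    long_mask = (labels == "long").to_numpy()
    short_mask = (labels == "short").to_numpy()
    if long_mask.sum() < 2 or short_mask.sum() < 2:
        raise ValueError("both duration groupings need n >= 2")
    Y = corrected.data.to_numpy(dtype=float)
    t, p = stats.ttest_ind(Y[long_mask], Y[short_mask], equal_var=False)
    p_holm = holm_adjust(p)
    out = pd.DataFrame(
        {"t": t, "p_raw": p, "p_holm": p_holm, "significant": p_holm < alpha},
        index=corrected.roi_columns,
    )
    out.index.name = "roi"
    return out
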