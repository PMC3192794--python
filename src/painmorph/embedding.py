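"""Ternary embedding of barcode similarity and the chronicity model.

Each subject's barcode is correlated against the four group barcodes; the
correlations are mapped to similarity distances d = (r + 1) / 2 in [0, 1]
and the subject is placed in a 2-D "ternary" space as the d-weighted mean
of four anchors: the three patient-group poles of an equilateral triangle
and the healthy center. The Euclidean distance Δd of a patient from the
healthy reference location indexes whole-brain gray-matter reorganization
and is modelled against pain duration t as a saturating exponential

    Δd(t) = Δd0 + Δd1 * (1 - exp(-t / τ)),

with amplitude Δd1 (asymptotic deviation beyond the Δd0 floor) and time
constant τ in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .barcode import (
    DEFAULT_THETA,
    classify,
    group_barcode,
    subject_barcodes,
)
from .confound import CorrectedGM
from .simulate import GROUPS


@dataclass(frozen=True)
class EmbeddingAnchors:
    """Anchor coordinates: three patient poles plus the healthy center.

    The canonical layout puts the poles on the unit circle at 90°, 210°
    and 330° (an equilateral triangle) and the healthy center at its
    centroid, the origin. Any similarity transform of this frame yields an
    equivalent analysis.
    """

    coords: dict[str, tuple[float, float]]

    @classmethod
    def default(cls) -> "EmbeddingAnchors":
        poles = {}
        for g, deg in zip(("CBP", "CRPS", "OA"), (90.0, 210.0, 330.0)):
            rad = math.radians(deg)
            poles[g] = (math.cos(rad), math.sin(rad))
        poles["healthy"] = (0.0, 0.0)
        return cls(coords=poles)

    def as_array(self, order: tuple[str, ...] = GROUPS) -> np.ndarray:
        return np.array([self.coords[g] for g in order], dtype=float)


def corr_to_dist(r):
    """Map a correlation in [-1, 1] to a similarity distance d = (r + 1) / 2."""
    r = np.asarray(r, dtype=float)
    if np.any((r < -1 - 1e-12) | (r > 1 + 1e-12)):
        raise ValueError("correlations must lie in [-1, 1]")
    d = (np.clip(r, -1.0, 1.0) + 1.0) / 2.0
    return float(d) if d.ndim == 0 else d


def embed(
    d: dict[str, float] | np.ndarray,
    anchors: EmbeddingAnchors | None = None,
) -> tuple[float, float]:
    """Place a subject at the d-weighted mean of the anchor coordinates.

    ``d`` maps each anchor group to its similarity distance (or is an
    array in the canonical group order healthy, CBP, CRPS, OA). Weights
    are d_g / Σd, so a common rescaling of all d leaves the position
    unchanged; Σd must be positive.
    """
    if anchors is None:
        anchors = EmbeddingAnchors.default()
    if isinstance(d, dict):
        order = [g for g in GROUPS if g in d]
        weights = np.array([d[g] for g in order], dtype=float)
        coords = np.array([anchors.coords[g] for g in order], dtype=float)
    else:
        weights = np.asarray(d, dtype=float)
        coords = anchors.as_array()
        if len(weights) != len(coords):
            raise ValueError("d-vector length does not match the anchor count")
    if np.any(weights < 0):
        raise ValueError("similarity distances must be >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all similarity distances are zero: position undefined")
    xy = (weights / total) @ coords
    return float(xy[0]), float(xy[1])


def embed_cohort(
    corrected: CorrectedGM,
    theta: float = DEFAULT_THETA,
    roi_subset: list[str] | None = None,
    renormalize: bool = False,
    anchors: EmbeddingAnchors | None = None,
) -> pd.DataFrame:
    """Embed every subject from their barcode correlations to the 4 group barcodes.

    Returns one row per subject: group label, the four similarity
    distances ``d_<group>``, and the (x, y) coordinates. Subjects whose
    barcode has no variance cannot be embedded and are dropped with their
    ids listed in ``result.attrs["unembeddable"]``.
    """
    if anchors is None:
        anchors = EmbeddingAnchors.default()
    groups = [g for g in GROUPS if g in set(corrected.groups)]
    anchors_codes = {
        g: group_barcode(corrected, g, theta, roi_subset, renormalize) for g in groups
    }
    codes = subject_barcodes(corrected, theta, roi_subset, renormalize)
    rows = []
    skipped: list[str] = []
    for sid, row in zip(codes.index, codes.to_numpy()):
        try:
            res = classify(row, anchors_codes)
        except ValueError:
            skipped.append(sid)
            continue
        d = {g: corr_to_dist(res.correlations[g]) for g in groups}
        x, y = embed(d, anchors)
        rec = {"subject_id": sid, "group": corrected.groups.loc[sid], "x": x, "y": y}
        rec.update({f"d_{g}": d[g] for g in groups})
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("subject_id")
    out.attrs["unembeddable"] = skipped
    return out


def delta_d(
    embedded: pd.DataFrame,
    healthy_reference: np.ndarray | None = None,
    reference: str = "mean",
) -> pd.Series:
    """Δd: Euclidean distance of each point from the healthy reference.

    The reference defaults to the mean location of the embedded healthy
    subjects (``reference="median"`` uses the bagplot depth median
    instead); an explicit 2-vector overrides both.
    """
    if healthy_reference is None:
        healthy = embedded[embedded["group"] == "healthy"]
        if healthy.empty:
            raise ValueError("no healthy subjects to define the reference location")
        pts = healthy[["x", "y"]].to_numpy(dtype=float)
        if reference == "mean":
            healthy_reference = pts.mean(axis=0)
        elif reference == "median":
            from .bagplot import bagplot_summary

            healthy_reference = bagplot_summary(pts).median
        else:
            raise ValueError("reference must be 'mean' or 'median'")
    ref = np.asarray(healthy_reference, dtype=float)
    dx = embedded["x"].to_numpy(dtype=float) - ref[0]
    dy = embedded["y"].to_numpy(dtype=float) - ref[1]
    return pd.Series(np.hypot(dx, dy), index=embedded.index, name="delta_d")


def logduration_correlation(
    delta_d_values: np.ndarray, durations: np.ndarray
) -> dict[str, float]:
    """Pearson correlation of Δd against log10 pain duration."""
    dd = np.asarray(delta_d_values, dtype=float)
    t = np.asarray(durations, dtype=float)
    if dd.size != t.size:
        raise ValueError("delta_d and durations differ in length")
    if dd.size < 3:
        raise ValueError("need n >= 3")
    if (t <= 0).any():
        raise ValueError("durations must be > 0 for a log scale")
    if np.ptp(dd) == 0:
        raise ValueError("constant delta_d: correlation undefined")
    r, p = stats.pearsonr(dd, np.log10(t))
    return {"R": float(r), "p": float(p), "n": int(dd.size)}


@dataclass
class ExpFit:
    """Saturating-exponential fit Δd(t) = Δd0 + Δd1 (1 - exp(-t/τ))."""

    delta_d0: float
    delta_d1: float
    tau: float
    se: dict[str, float]
    R: float
    n: int
    rss: float
    linear_rss: float
    f_vs_linear: float
    p_vs_linear: float
    fitted: np.ndarray = field(repr=False, default=None)


def _exp_model(t: np.ndarray, d0: float, d1: float, tau: float) -> np.ndarray:
    return d0 + d1 * (1.0 - np.exp(-t / tau))


def fit_exponential_growth(
    delta_d_values: np.ndarray, durations: np.ndarray
) -> ExpFit:
    """Nonlinear least squares for the exponential chronicity model.

    τ is constrained positive. Initialization scans a coarse log-spaced τ
    grid, solving the then-linear (Δd0, Δd1) subproblem exactly at each τ,
    and refines from the best grid point. Standard errors come from the
    fit's curvature (Gauss-Newton covariance); the fit R is the Pearson
    correlation between observed and fitted Δd. The residual sum of
    squares of a straight-line fit and an F-style exponential-vs-linear
    comparison are also reported — for durations far below τ the model is
    indistinguishable from the line Δd0 + Δd1 t / τ.
    """
    y = np.asarray(delta_d_values, dtype=float)
    t = np.asarray(durations, dtype=float)
    if y.size != t.size:
        raise ValueError("delta_d and durations differ in length")
    n = y.size
    if n < 4:
        raise ValueError("need n >= 4 to fit three parameters")
    if (t <= 0).any():
        raise ValueError("durations must be > 0")

    taus = np.geomspace(0.02, 5.0 * t.max(), 120)
    best = None
    for tau in taus:
        A = np.column_stack([np.ones(n), 1.0 - np.exp(-t / tau)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((y - A @ coef) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], tau)
    _, d0_0, d1_0, tau_0 = best

    popt = pcov = None
    for p0 in ([d0_0, d1_0, tau_0], [y.min(), np.ptp(y), float(np.median(t))]):
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model,
                t,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            break
        except RuntimeError:
            continue
    if popt is None:
        raise RuntimeError(
            "exponential fit did not converge "
            f"(n={n}, grid best tau={tau_0:.3g}, rss={best[0]:.3g})"
        )
    d0, d1, tau = (float(v) for v in popt)
    fitted = _exp_model(t, d0, d1, tau)
    rss = float(((y - fitted) ** 2).sum())
    se_vals = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    se = {"delta_d0": float(se_vals[0]), "delta_d1": float(se_vals[1]), "tau": float(se_vals[2])}
    if np.ptp(fitted) > 0 and np.ptp(y) > 0:
        R = float(np.corrcoef(y, fitted)[0, 1])
    else:
        R = float("nan")
    lin = np.polyfit(t, y, 1)
    linear_rss = float(((y - np.polyval(lin, t)) ** 2).sum())
    df2 = n - 3
    if rss <= 0:
        f_stat, p_lin = float("inf"), 0.0
    else:
        f_stat = max((linear_rss - rss) / 1.0 / (rss / df2), 0.0)
        p_lin = float(stats.f.sf(f_stat, 1, df2))
    return ExpFit(
        delta_d0=d0,
        delta_d1=d1,
        tau=tau,
        se=se,
        R=R,
        n=n,
        rss=rss,
        linear_rss=linear_rss,
        f_vs_linear=float(f_stat),
        p_vs_linear=p_lin,
        fitted=fitted,
    )


def compare_taus(fit_a: ExpFit, fit_b: ExpFit) -> dict[str, float]:
    """Two-sample t-style comparison of fitted time constants.

    t = (τ_A - τ_B) / sqrt(SE_A² + SE_B²), with Welch-Satterthwaite
    degrees of freedom based on each fit's residual df (n - 3).
    """
    se_a, se_b = fit_a.se["tau"], fit_b.se["tau"]
    if not (np.isfinite(se_a) and np.isfinite(se_b)):
        raise ValueError("both fits need finite tau standard errors")
    diff = fit_a.tau - fit_b.tau
    denom = math.sqrt(se_a**2 + se_b**2)
    if denom == 0:
        return {"t": 0.0 if diff == 0 else math.inf, "p": 1.0 if diff == 0 else 0.0,
                "df": float(fit_a.n + fit_b.n - 6)}
    t_stat = diff / denom
    df_a, df_b = fit_a.n - 3, fit_b.n - 3
    va, vb = se_a**2, se_b**2
    df = (va + vb) ** 2 / (va**2 / df_a + vb**2 / df_b) if (va + vb) > 0 else df_a + df_b
    p = float(2 * stats.t.sf(abs(t_stat), df))
    return {"t": float(t_stat), "p": p, "df": float(df)}
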