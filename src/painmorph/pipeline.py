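"""End-to-end pipeline: simulate/load -> correct -> stats -> network ->
barcode -> embed -> chronicity, with a machine-readable JSON report.

Every run records its configuration, a hash of it, and the seeds used, so
two runs from the same config are byte-identical apart from nothing (no
timestamps are written). Stage failures halt the run naming the stage;
outputs written before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode import classify_cohort, confusion_metrics, optimize_threshold, subsample_validation
from .confound import age_slopes, residualize_gm, total_gm_ancova
from .embedding import (
    compare_taus,
    delta_d,
    embed_cohort,
    fit_exponential_growth,
    logduration_correlation,
)
from .io import read_atlas, read_cohort, write_atlas, write_cohort
from .network import (
    bin_correlations,
    compare_slopes,
    correlation_distance_regression,
    pairwise_distances,
    strong_connections,
    structural_covariance,
)
from .regional import chronicity_median_split, roi_group_anova, select_discriminative_rois
from .simulate import GROUPS, PATIENT_GROUPS, build_default_atlas, default_config, simulate_cohort

logger = logging.getLogger(__name__)

_pkg_version = "0.1.0"


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    With ``cohort_path`` unset, a synthetic cohort is generated from
    ``seed``; otherwise the cohort (and atlas) are read from disk.
    """

    output_dir: str = "painmorph_run"
    cohort_path: str | None = None
    atlas_path: str | None = None
    covariates: tuple[str, ...] = ("age", "gender", "icv")
    n_per_hemisphere: int = 41
    theta: float | None = None  # None -> optimized on the cohort
    entropy_tolerance: float = 0.05
    f_threshold: float = 2.7
    bin_width_mm: float = 25.0
    n_bins: int | None = None
    r_threshold: float = 0.6
    alpha: float = 0.05
    subsample_sizes: tuple[int, ...] = (5, 10)
    subsample_iterations: int = 10
    seed: int = 0
    oa_size: int | None = None

    def validate(self) -> None:
        if not self.covariates:
            raise ValueError("config must name at least one covariate")
        if self.cohort_path is not None and not os.path.exists(self.cohort_path):
            raise ValueError(f"cohort_path does not exist: {self.cohort_path}")
        if self.atlas_path is not None and not os.path.exists(self.atlas_path):
            raise ValueError(f"atlas_path does not exist: {self.atlas_path}")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must be in (0, 1)")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # hash the scientific settings only: where the outputs land must not
        # change what they contain
        payload = {k: v for k, v in self.as_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _round12(obj):
    """Round floats to 12 significant digits for cross-run comparability."""
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if not math.isfinite(x):
            return repr(x)
        return float(f"{x:.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write the report bundle.

    Returns the report dict (also written as ``report.json``). Tabular
    intermediates (cohort, atlas, corrected matrix, ANOVA table) are
    written alongside, and a manifest ties every file to the config hash.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {
        "version": _pkg_version,
        "config": config.as_dict(),
        "config_hash": chash,
        "stages": {},
    }
    files: list[str] = []

    def stage(name):
        def runner(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as exc:  # halt with stage name; keep partial outputs
                _write_report(report, out, chash, files)
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return runner

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.atlas_path:
            atlas = read_atlas(config.atlas_path)
        else:
            atlas = build_default_atlas(config.n_per_hemisphere, seed=config.seed)
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path, n_rois=atlas.n_rois)
        else:
            sim = default_config(atlas, seed=config.seed)
            if config.oa_size is not None:
                sim.group_sizes["OA"] = config.oa_size
            cohort = simulate_cohort(atlas, sim)
        write_atlas(atlas, out / "atlas.tsv")
        write_cohort(cohort, out / "cohort.csv")
        files.extend(["atlas.tsv", "cohort.csv"])
        counts = cohort["group"].value_counts().to_dict()
        report["stages"]["simulate"] = {
            "n_subjects": int(len(cohort)),
            "n_rois": int(atlas.n_rois),
            "group_sizes": {g: int(counts.get(g, 0)) for g in GROUPS},
            "n_clipped": int(cohort.attrs.get("n_clipped", 0)),
            "seed": config.seed,
        }
        state["atlas"], state["cohort"] = atlas, cohort

    @stage("correct")
    def _correct():
        cohort = state["cohort"]
        corrected = residualize_gm(cohort, config.covariates)
        ancova = total_gm_ancova(cohort, config.covariates)
        slopes = age_slopes(cohort)
        corrected.data.to_csv(out / "corrected_gm.tsv", sep="\t", float_format="%.12g")
        files.append("corrected_gm.tsv")
        report["stages"]["correct"] = {
            "covariates_used": corrected.covariates,
            "ancova": {
                "F": ancova.F,
                "df": list(ancova.df),
                "p": ancova.p,
                "contrasts": ancova.contrasts,
            },
            "age_slopes": slopes,
        }
        state["corrected"] = corrected

    @stage("stats")
    def _stats():
        corrected = state["corrected"]
        cohort = state["cohort"]
        anova = roi_group_anova(corrected, alpha=config.alpha)
        selected = select_discriminative_rois(anova, f_threshold=config.f_threshold)
        anova.to_csv(out / "roi_anova.tsv", sep="\t", float_format="%.12g")
        files.append("roi_anova.tsv")
        patients = cohort[cohort["group"] != "healthy"]
        split = chronicity_median_split(patients)
        report["stages"]["stats"] = {
            "n_significant": int(anova["significant"].sum()),
            "selected_rois": selected,
            "n_selected": len(selected),
            "median_duration": split.median_duration,
            "n_short": int((split.labels == "short").sum()),
            "n_long": int((split.labels == "long").sum()),
        }
        state["selected"], state["split"] = selected, split

    @stage("network")
    def _network():
        corrected, atlas = state["corrected"], state["atlas"]
        dist = pairwise_distances(atlas)
        covs = {g: structural_covariance(corrected, g) for g in GROUPS
                if g in set(corrected.groups)}
        fits = {
            g: correlation_distance_regression(covs[g], dist, atlas, hemisphere="L")
            for g in covs
        }
        net: dict = {
            "distance_fits": {
                g: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "R": f.R,
                    "slope_sign": f.slope_sign,
                    "p": f.p,
                    "n_pairs": f.n_pairs,
                }
                for g, f in fits.items()
            }
        }
        if "healthy" in fits:
            net["slope_comparisons"] = {
                g: compare_slopes(fits[g], fits["healthy"])
                for g in PATIENT_GROUPS
                if g in fits
            }
            net["binned_vs_healthy"] = {}
            for g in PATIENT_GROUPS:
                if g not in covs:
                    continue
                bins = bin_correlations(
                    covs[g], dist, config.bin_width_mm, config.n_bins,
                    other=covs["healthy"],
                )
                net["binned_vs_healthy"][g] = bins.to_dict(orient="records")
        seed_roi = corrected.roi_columns[0]
        net["strong_connections"] = {
            g: strong_connections(covs[g], seed_roi, config.r_threshold, config.alpha)
            .reset_index()
            .to_dict(orient="records")
            for g in covs
        }
        net["seed_roi"] = seed_roi
        report["stages"]["network"] = net
        state["covs"], state["dist"] = covs, dist

    @stage("barcode")
    def _barcode():
        corrected = state["corrected"]
        if config.theta is None:
            scan = optimize_threshold(corrected, entropy_tolerance=config.entropy_tolerance)
            theta = scan.theta_star
            scan_info = {
                "theta_star": scan.theta_star,
                "n_excluded": len(scan.excluded),
                "max_joint_entropy": float(np.nanmax(scan.joint_entropy)),
            }
        else:
            theta = config.theta
            scan_info = {"theta_star": theta, "fixed": True}
        result = classify_cohort(corrected, theta=theta)
        rep = confusion_metrics(result["true"], result["pred"])
        val = {}
        for n_sub in config.subsample_sizes:
            val[str(n_sub)] = subsample_validation(
                corrected,
                n_per_group=n_sub,
                iterations=config.subsample_iterations,
                theta=theta,
                seed=config.seed + n_sub,
            )
        report["stages"]["barcode"] = {
            "threshold": scan_info,
            "theta": theta,
            "confusion": rep.confusion.to_dict(),
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "n_ties": int(result["tie"].sum()),
            "subsample_validation": val,
        }
        state["theta"] = theta

    @stage("embed")
    def _embed():
        corrected = state["corrected"]
        embedded = embed_cohort(corrected, theta=state["theta"])
        dd = delta_d(embedded)
        embedded = embedded.assign(delta_d=dd)
        embedded.to_csv(out / "embedded.csv", float_format="%.12g")
        files.append("embedded.csv")
        report["stages"]["embed"] = {
            "n_embedded": int(len(embedded)),
            "n_unembeddable": len(embedded.attrs.get("unembeddable", [])),
            "healthy_mean": [
                float(embedded.loc[embedded["group"] == "healthy", "x"].mean()),
                float(embedded.loc[embedded["group"] == "healthy", "y"].mean()),
            ],
        }
        state["embedded"] = embedded

    @stage("chronicity")
    def _chronicity():
        embedded, cohort = state["embedded"], state["cohort"]
        dur = cohort.set_index("subject_id")["pain_duration"]
        chron: dict = {}
        fits = {}
        for g in PATIENT_GROUPS:
            sub = embedded[embedded["group"] == g]
            if len(sub) < 4:
                continue
            t = dur.loc[sub.index].to_numpy(dtype=float)
            dd = sub["delta_d"].to_numpy(dtype=float)
            corr = logduration_correlation(dd, t)
            fit = fit_exponential_growth(dd, t)
            fits[g] = fit
            chron[g] = {
                "log_duration_R": corr["R"],
                "log_duration_p": corr["p"],
                "delta_d0": fit.delta_d0,
                "delta_d1": fit.delta_d1,
                "tau": fit.tau,
                "tau_se": fit.se["tau"],
                "fit_R": fit.R,
                "f_vs_linear": fit.f_vs_linear,
                "p_vs_linear": fit.p_vs_linear,
                "n": fit.n,
            }
        if "CBP" in fits and "CRPS" in fits:
            chron["tau_comparison_CBP_vs_CRPS"] = compare_taus(fits["CBP"], fits["CRPS"])
        report["stages"]["chronicity"] = chron

    _write_report(report, out, chash, files)
    return report


def _write_report(report: dict, out: Path, chash: str, files: list[str]) -> None:
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_round12(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {"config_hash": chash, "files": sorted(set(files + ["report.json"]))}
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
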