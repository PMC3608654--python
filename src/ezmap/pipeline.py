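"""End-to-end workflows: score one subject, or run the full validation.

These functions tie the stages together the way the command-line
interface exposes them: covariate adjustment (when covariates are
supplied), scoring by the chosen method, dual thresholding, and output of
label maps, cluster tables, metrics, and a provenance record sufficient
to reproduce the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil

import numpy as np
import pandas as pd

from . import __version__
from .adjust import adjust_cohort, adjust_map, fit_covariate_model
from .bootstrap import (bootstrap_sd_map, classify_dispersion, ez_map,
                        uncoverage_rate, CLASS_LABELS)
from .clusters import (detect_abnormalities, estimate_smoothness, fwer_pseudo_t,
                       save_abnormality_result)
from .evaluate import DEFAULT_GRID, METHODS, save_roc_result, threshold_grid_search
from .exceptions import ValidationError
from .grids import CohortStack, load_covariates, load_volume, stack_cohort
from .scoring import reference_stats, save_score_map, t_map, z_map
from .simulate import SyntheticSpec, generate_cohorts

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Parameters of a single-subject run (mirrors the CLI flags)."""

    subject: str
    reference: list
    out_dir: str
    mask: str | None = None
    covariates: str | None = None
    subject_covariates: dict | None = None
    method: str = "EZ"
    alpha1: float = 0.05
    alpha2: float = 0.05
    corrected: bool = True
    connectivity: int = 26
    B: int = 1000
    seed: int | None = None
    covariate_alpha: float = 0.05
    covariate_cluster_gate: int = 100
    fwer_alpha_per_tail: float = 0.05
    fwer_sd_smoothing_fwhm: float = 8.0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method}")
        for name, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2)):
            if not (0.0 < a < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {a}")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError(f"connectivity must be 6/18/26, got {self.connectivity}")
        if len(self.reference) < 2:
            raise ValidationError("need at least 2 reference volumes")


def run_single_subject(config: RunConfig):
    """Score one subject and write label maps, cluster table and metrics.

    On error, partial outputs in the run directory are removed before the
    exception propagates (prefixed with the failing stage's name).
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    created = os.path.join(config.out_dir, "run")
    try:
        return _run_single_subject(config, created)
    except Exception:
        if os.path.isdir(created):
            shutil.rmtree(created, ignore_errors=True)
        raise


def _run_single_subject(config: RunConfig, out: str):
    os.makedirs(out, exist_ok=True)
    mask = load_volume(config.mask).mask if config.mask else None
    cov = load_covariates(config.covariates) if config.covariates else None
    reference = stack_cohort(config.reference, cov, mask, role_label="reference")
    subject = load_volume(config.subject)
    reference.grid.require_compatible(subject, what="test subject")
    subject = subject.with_data(subject.data)  # copy
    subject.mask = reference.mask.copy()

    if cov is not None and config.subject_covariates is not None:
        model = fit_covariate_model(reference, config.covariate_alpha,
                                    config.covariate_cluster_gate, config.connectivity)
        reference = adjust_cohort(reference, model)
        subject = adjust_map(subject, config.subject_covariates, model)

    if config.method == "FWER":
        result = fwer_pseudo_t(subject, reference, config.fwer_sd_smoothing_fwhm,
                               config.fwer_alpha_per_tail, config.connectivity)
    else:
        stats = reference_stats(reference)
        if config.method == "Z":
            score = z_map(subject, stats)
        elif config.method == "T":
            score = t_map(subject, stats)
        else:
            boot = bootstrap_sd_map(reference, n=len(reference) - 1,
                                    B=config.B, seed=config.seed)
            score = ez_map(z_map(subject, stats), boot)
        save_score_map(score, os.path.join(out, f"score_{config.method.lower()}.nii.gz"))
        smooth = estimate_smoothness(reference, stats)
        result = detect_abnormalities(score, smooth, config.alpha1, config.alpha2,
                                      config.corrected, config.connectivity)
    save_abnormality_result(result, reference.grid, out)
    provenance = {"software": "ezmap", "version": __version__,
                  "config": {k: v for k, v in dataclasses.asdict(config).items()}}
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    logger.info("single-subject run complete: %s", result.metrics)
    return result


def run_validation(spec: SyntheticSpec, out_dir: str, B: int = 1000,
                   seed: int | None = None, grid=DEFAULT_GRID,
                   methods=METHODS, n_sweep=(10, 20, 40),
                   lambdas=(0.1, 0.05, 0.01), make_plots: bool = True) -> dict:
    """Generate cohorts and run the full validation battery.

    Writes per-method ROC tables over the threshold grid, a coverage-rate
    report (empirical uncoverage of held-out controls, Z vs EZ), a
    dispersion-class summary, and bootstrap-SD histograms across the
    reference-size sweep.  Returns a summary dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = spec.seed if seed is None else seed
    reference, controls, patients, truths = generate_cohorts(spec)
    summary: dict = {"spec": dataclasses.asdict(spec)}

    # --- ROC grid per method
    roc_summaries = {}
    for method in methods:
        roc = threshold_grid_search(patients, controls, reference, method,
                                    grid=grid, B=B, seed=seed)
        save_roc_result(roc, out_dir)
        best = roc.rows[roc.optimal_index]
        roc_summaries[method] = best
    summary["roc_best"] = roc_summaries

    # --- coverage report (Z vs EZ uncoverage on held-out controls)
    stats = reference_stats(reference)
    boot = bootstrap_sd_map(reference, n=len(reference) - 1, B=B, seed=seed)
    rows = []
    for vol in controls.volumes:
        zm = z_map(vol, stats)
        em = ez_map(zm, boot)
        for lam in lambdas:
            rows.append({"lambda": lam, "z": uncoverage_rate(zm, lam),
                         "ez": uncoverage_rate(em, lam)})
    cov_df = pd.DataFrame(rows)
    cov_df.to_csv(os.path.join(out_dir, "uncoverage.tsv"), sep="\t", index=False)
    summary["uncoverage_median"] = {
        str(lam): {"z": float(g["z"].median()), "ez": float(g["ez"].median())}
        for lam, g in cov_df.groupby("lambda")}

    # --- dispersion classes (delta shrinks for small cohorts so the band exists)
    disp = classify_dispersion(boot, delta=min(10, boot.n - 4))
    labels, counts = np.unique(disp.classes[reference.mask], return_counts=True)
    frac = {CLASS_LABELS[int(l)]: float(c) / int(reference.mask.sum())
            for l, c in zip(labels, counts)}
    summary["dispersion_fractions"] = frac
    summary["dispersion_band"] = {"psi_L": disp.psi_L, "psi_U": disp.psi_U}

    # --- bootstrap SD vs reference size (combined control pool)
    pool = CohortStack(reference.volumes + controls.volumes, None, "reference")
    sweep = {}
    for i, n in enumerate(n_sweep):
        if len(pool) < n + 1:
            continue
        b = bootstrap_sd_map(pool, n=n, B=B, seed=None if seed is None else seed + i)
        vals = b.sd_star[pool.mask]
        vals = vals[np.isfinite(vals)]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        sweep[str(n)] = {"median": float(med), "iqr": float(q3 - q1)}
        pd.DataFrame({"sd_star": vals}).to_csv(
            os.path.join(out_dir, f"sd_star_n{n}.csv"), index=False)
        if make_plots:
            _plot_hist(vals, n, os.path.join(out_dir, f"sd_star_n{n}.png"))
    summary["sd_star_sweep"] = sweep

    with open(os.path.join(out_dir, "validation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _plot_hist(vals: np.ndarray, n: int, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(vals, bins=80, color="steelblue")
    ax.set_xlabel("bootstrap SD of Z-scores (sd*)")
    ax.set_ylabel("voxels")
    ax.set_title(f"reference size n = {n}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
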