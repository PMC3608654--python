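"""Discrimination of patients from test controls on abnormal-voxel counts.

The end-to-end validation question is whether a scoring method, with a
given pair of thresholds (alpha1, alpha2), separates patients from
held-out normal controls in terms of the global number of abnormal voxels
it reports per subject.  This module provides the ROC/AUC machinery
(AUC = Mann-Whitney U / (n_p * n_c), one-tailed Wilcoxon-Mann-Whitney
significance), the optimal operating point (closest to the top-left
corner), group-difference tests on the three global count metrics, and
the grid search over threshold settings.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bootstrap import bootstrap_sd_map, ez_map
from .clusters import detect_abnormalities, estimate_smoothness, fwer_pseudo_t
from .exceptions import ContractError, ValidationError
from .grids import CohortStack
from .scoring import reference_stats, t_map, z_map

#: the threshold grid explored in validation: voxel level alpha1 crossed
#: with cluster level alpha2, uncorrected and corrected.
DEFAULT_GRID: tuple = tuple(
    (a1, a2, corr)
    for a1 in (0.05, 0.01)
    for a2, corr in ((0.05, False), (0.01, False), (0.05, True), (0.01, True))
)

METHODS = ("EZ", "Z", "T", "FWER")


def roc_auc_wmw(patient_counts: Sequence[float], control_counts: Sequence[float],
                alternative: str = "greater") -> tuple[float, float]:
    """AUC with midrank ties plus a one-tailed Wilcoxon-Mann-Whitney p.

    AUC is the probability that a random patient count exceeds a random
    control count, ties counting one half: ``U / (n_p * n_c)``.  The
    p-value (default alternative: patients > controls) uses exact
    enumeration for small tie-free samples and the tie-corrected normal
    approximation otherwise.
    """
    p = np.asarray(patient_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if p.size == 0 or c.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([p, c])).size < p.size + c.size
    method = "exact" if (p.size * c.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(p, c, alternative=alternative, method=method)
    auc = float(res.statistic) / (p.size * c.size)
    return auc, float(res.pvalue)


def roc_curve_counts(patient_counts, control_counts) -> list[tuple[float, float, float]]:
    """ROC points (fpr, tpr, cutoff) over all observed count cutoffs.

    A subject is called a patient when its count >= cutoff (step
    function over the observed counts; no binning).
    """
    p = np.asarray(patient_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    y = np.concatenate([np.ones_like(p), np.zeros_like(c)])
    fpr, tpr, thr = _sk_roc_curve(y, np.concatenate([p, c]))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def optimal_cutoff(curve: Sequence[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Operating point closest to (FPR 0, TPR 1); ties -> higher sensitivity.

    Returns (cutoff, sensitivity, specificity).
    """
    if len(curve) == 0:
        raise ValidationError("empty ROC curve")
    best = None
    for fpr, tpr, thr in curve:
        if not np.isfinite(thr):
            continue
        d = float(np.hypot(fpr, 1.0 - tpr))
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and tpr > best[1][1]):
            best = (d, (thr, tpr, 1.0 - fpr))
    if best is None:  # only the degenerate +inf point present
        fpr, tpr, thr = curve[0]
        return thr, tpr, 1.0 - fpr
    return best[1]


def group_difference_tests(patient_counts, control_counts,
                           paired_counts_a=None, paired_counts_b=None) -> dict:
    """Two-sample Welch t, WMW, and optional paired-t p-values (two-sided)."""
    p = np.asarray(patient_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    out = {
        "t_welch_p": float(sps.ttest_ind(p, c, equal_var=False).pvalue),
        "wmw_p": float(sps.mannwhitneyu(p, c, alternative="two-sided").pvalue),
    }
    if paired_counts_a is not None or paired_counts_b is not None:
        a = np.asarray(paired_counts_a, dtype=float)
        b = np.asarray(paired_counts_b, dtype=float)
        if a.shape != b.shape:
            raise ValidationError("paired count lists must have equal length")
        diff = a - b
        if diff.size < 2 or diff.std(ddof=1) == 0.0:
            # zero-variance differences: identical lists are maximally
            # non-significant, a constant nonzero shift maximally significant
            out["paired_t_p"] = 1.0 if np.allclose(diff, 0.0) else 0.0
            out["paired_t_degenerate"] = True
        else:
            out["paired_t_p"] = float(sps.ttest_rel(a, b).pvalue)
            out["paired_t_degenerate"] = False
    return out


@dataclasses.dataclass
class ROCResult:
    """One row per grid setting: AUC, WMW p, curve, and operating point."""

    rows: list            # dicts: alpha1, alpha2, corrected, auc, p, cutoff, sensitivity, specificity
    curves: list          # per-row ROC point lists
    optimal_index: int
    method: str

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["optimal"] = False
        df.loc[self.optimal_index, "optimal"] = True
        df.insert(0, "method", self.method)
        return df


def _check_disjoint(reference: CohortStack, controls: CohortStack) -> None:
    if reference.covariates is None or controls.covariates is None:
        return
    if "subject_id" not in reference.covariates or "subject_id" not in controls.covariates:
        return
    overlap = set(reference.covariates["subject_id"]) & set(controls.covariates["subject_id"])
    if overlap:
        raise ContractError(
            f"test controls overlap the reference group: {sorted(overlap)[:5]}"
        )


def subject_counts(subjects: CohortStack, reference: CohortStack, method: str,
                   grid: Sequence[tuple[float, float, bool]] = DEFAULT_GRID,
                   B: int = 1000, seed: int | None = None,
                   connectivity: int = 26,
                   fwer_alpha_per_tail: float = 0.05,
                   fwer_sd_smoothing_fwhm: float = 8.0) -> np.ndarray:
    """Per-subject n_all abnormal counts, shape (n_settings, n_subjects)."""
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method}")
    stats = reference_stats(reference)
    counts = np.zeros((len(grid), len(subjects)), dtype=int)
    if method == "FWER":
        for j, vol in enumerate(subjects.volumes):
            res = fwer_pseudo_t(vol, reference, fwer_sd_smoothing_fwhm,
                                fwer_alpha_per_tail, connectivity)
            counts[:, j] = res.metrics["n_all"]
        return counts
    smooth = estimate_smoothness(reference, stats)
    boot = None
    if method == "EZ":
        boot = bootstrap_sd_map(reference, n=len(reference) - 1, B=B, seed=seed)
    for j, vol in enumerate(subjects.volumes):
        if method == "Z":
            score = z_map(vol, stats)
        elif method == "T":
            score = t_map(vol, stats)
        else:
            score = ez_map(z_map(vol, stats), boot)
        for i, (a1, a2, corr) in enumerate(grid):
            res = detect_abnormalities(score, smooth, a1, a2, corr, connectivity)
            counts[i, j] = res.metrics["n_all"]
    return counts


def threshold_grid_search(patients: CohortStack, controls: CohortStack,
                          reference: CohortStack, method: str = "EZ",
                          grid: Sequence[tuple[float, float, bool]] = DEFAULT_GRID,
                          B: int = 1000, seed: int | None = None,
                          connectivity: int = 26) -> ROCResult:
    """ROC/AUC over the threshold grid for one method.

    The reference group must be disjoint from the test controls — the test
    controls exist precisely to play "pseudo-patients" never seen by the
    normative model.
    """
    _check_disjoint(reference, controls)
    pat = subject_counts(patients, reference, method, grid, B, seed, connectivity)
    con = subject_counts(controls, reference, method, grid, B, seed, connectivity)
    rows, curves = [], []
    for i, (a1, a2, corr) in enumerate(grid):
        auc, p = roc_auc_wmw(pat[i], con[i])
        curve = roc_curve_counts(pat[i], con[i])
        cutoff, sens, spec = optimal_cutoff(curve)
        rows.append({"alpha1": a1, "alpha2": a2, "corrected": corr,
                     "auc": auc, "wmw_p": p, "cutoff": cutoff,
                     "sensitivity": sens, "specificity": spec})
        curves.append(curve)
    optimal = int(np.argmax([r["auc"] for r in rows]))
    return ROCResult(rows, curves, optimal, method)


def save_roc_result(result: ROCResult, out_dir: str | os.PathLike,
                    prefix: str | None = None) -> None:
    """TSV table + JSON + per-setting CSV curves."""
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or f"roc_{result.method.lower()}"
    df = result.to_dataframe()
    df.to_csv(os.path.join(out_dir, f"{prefix}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, f"{prefix}.json"), "w") as fh:
        json.dump({"method": result.method, "rows": result.rows,
                   "optimal_index": result.optimal_index}, fh, indent=2)
    for i, curve in enumerate(result.curves):
        pd.DataFrame(curve, columns=["fpr", "tpr", "cutoff"]).to_csv(
            os.path.join(out_dir, f"{prefix}_curve{i}.csv"), index=False)
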