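"""Two-level abnormality thresholding and cluster-extent inference.

A subject's score map is declared abnormal in two stages: a voxel-level
two-sided threshold ``alpha1`` on the score's null distribution, followed
by a cluster-extent threshold ``alpha2`` on the surviving contiguous
clusters.  Cluster p-values come from Gaussian-random-field (GRF) theory
in the classic cluster-size exceedance form: for a stationary unit-
variance Gaussian field with smoothness FWHM thresholded at u,

* the expected number of clusters per sign is the resel count times the
  3-D Euler-characteristic density
  ``rho_3(u) = (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2)``,
* the expected suprathreshold volume is ``S * (1 - Phi(u))`` voxels,
* a single cluster's size satisfies ``P(n >= k) = exp(-beta k^{2/3})``
  with ``beta = (Gamma(5/2) / E[n])^{2/3}``, and
* the familywise (corrected) p-value of a size-k cluster is
  ``1 - exp(-E[m] P(n >= k))``.

Each sign (abnormally high / abnormally low) is treated as its own
family.  Smoothness is estimated from the variance of spatial derivatives
of the standardized reference residuals.

The module also provides the FWER pseudo-t comparator: a pseudo-t map
with spatially smoothed SD, thresholded at the per-tail maximum-statistic
quantile calibrated by leave-one-out over the reference cohort, with no
extent threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os

import numpy as np
from scipy import ndimage, stats as sps
from sklearn.base import BaseEstimator

from .exceptions import (ContractError, GridCompatibilityError,
                         InsufficientCohortError, ValidationError)
from .grids import CohortStack, VolumeGrid, save_mask
from .scoring import ReferenceStats, ScoreMap, reference_stats

logger = logging.getLogger(__name__)

_4LN2 = 4.0 * math.log(2.0)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D labeling structure for 6-, 18- or 26-connectivity."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValidationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def drop_small_clusters(volume: np.ndarray, gate: int, connectivity: int = 26) -> np.ndarray:
    """Keep only connected components with strictly more than ``gate`` voxels."""
    volume = np.asarray(volume).astype(bool)
    labels, n = ndimage.label(volume, structure=connectivity_structure(connectivity))
    if n == 0:
        return volume
    sizes = np.bincount(labels.ravel())
    keep = sizes > gate
    keep[0] = False
    return keep[labels]


# ---------------------------------------------------------------------------
# Smoothness

@dataclasses.dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (voxels) and resel count of the score field."""

    fwhm: tuple[float, float, float]
    resel_count: float
    source: str = "residuals"  # "residuals" | "known"
    n_mask_voxels: int = 0

    def __post_init__(self) -> None:
        if any(not np.isfinite(f) or f <= 0 for f in self.fwhm):
            raise ValidationError(f"FWHM components must be positive, got {self.fwhm}")
        if self.resel_count <= 0:
            raise ValidationError("resel count must be positive")


def smoothness_from_fwhm(fwhm, n_mask_voxels: int) -> SmoothnessEstimate:
    """Build a smoothness estimate from a known FWHM (voxels)."""
    if np.isscalar(fwhm):
        fwhm = (float(fwhm),) * 3
    fwhm = tuple(float(f) for f in fwhm)
    resels = n_mask_voxels / float(np.prod(fwhm))
    return SmoothnessEstimate(fwhm, resels, "known", n_mask_voxels)


def estimate_smoothness(reference: CohortStack,
                        stats: ReferenceStats | None = None) -> SmoothnessEstimate:
    """Estimate field smoothness from standardized reference residuals.

    For each axis the variance of lag-1 finite differences of the
    standardized residuals, relative to the residual variance, estimates
    ``lambda_a = 2 (1 - rho_a(1))``, the discrete analogue of the spatial
    derivative variance; ``FWHM_a = sqrt(4 ln 2 / lambda_a)``.  White
    noise gives ``lambda = 2`` and hence FWHM ``sqrt(2 ln 2) ~ 1.18``
    voxels, the resolution floor of an unsmoothed lattice field.
    """
    if stats is None:
        stats = reference_stats(reference)
    ok = stats.scorable
    X = np.stack([v.data for v in reference.volumes])        # (n, x, y, z)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (X - stats.mean_map) / stats.sd_map
    R[:, ~ok] = np.nan
    denom = np.nanmean(R[:, ok] ** 2)
    fwhm = []
    for axis in range(3):
        d = np.diff(R, axis=axis + 1)
        d = d[np.isfinite(d)]
        if d.size < 10:
            logger.warning("axis %d too thin for smoothness estimation; using floor", axis)
            fwhm.append(math.sqrt(2.0 * math.log(2.0)))
            continue
        lam = float(np.mean(d**2) / denom)
        lam = min(max(lam, 1e-6), 2.0)  # negative lag-1 correlation -> resolution floor
        fwhm.append(math.sqrt(_4LN2 / lam))
    n_mask = int(ok.sum())
    resels = n_mask / float(np.prod(fwhm))
    return SmoothnessEstimate(tuple(fwhm), resels, "residuals", n_mask)


# ---------------------------------------------------------------------------
# Voxel-level threshold

def score_threshold(score: ScoreMap, alpha1: float) -> float:
    """Two-sided critical value of the score's null distribution."""
    if not (0.0 < alpha1 < 1.0):
        raise ValidationError(f"alpha1 must be in (0, 1), got {alpha1}")
    kind = score.null_model.get("kind")
    if kind == "gaussian":
        return float(sps.norm.ppf(1.0 - alpha1 / 2.0))
    if kind == "t":
        return float(sps.t.ppf(1.0 - alpha1 / 2.0, score.null_model["df"]))
    raise ContractError(f"no critical value for null model {score.null_model}")


def voxel_threshold(score: ScoreMap, alpha1: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed suprathreshold masks (high, low) at two-sided level alpha1."""
    c = score_threshold(score, alpha1)
    ok = score.scorable
    high = ok & (score.values > c)
    low = ok & (score.values < -c)
    return high, low


# ---------------------------------------------------------------------------
# GRF cluster inference

def _grf_expected(u: float, resels: float, n_mask_voxels: int) -> tuple[float, float]:
    """(E[number of clusters], E[cluster size in voxels]) at threshold u."""
    rho3 = (_4LN2 ** 1.5) / (2.0 * math.pi) ** 2 * (u * u - 1.0) * math.exp(-u * u / 2.0)
    em = max(resels * rho3, 1e-300)
    en_total = n_mask_voxels * sps.norm.sf(u)
    en = max(en_total / em, 1e-300)
    return em, en


def grf_cluster_p(k: int, u: float, smooth: SmoothnessEstimate) -> tuple[float, float]:
    """(uncorrected, corrected) GRF p-value of one size-k cluster."""
    if smooth.resel_count <= 0:
        raise ContractError("zero resels")
    em, en = _grf_expected(u, smooth.resel_count, smooth.n_mask_voxels)
    beta = (math.gamma(2.5) / en) ** (2.0 / 3.0)
    p_unc = math.exp(-beta * float(k) ** (2.0 / 3.0))
    p_corr = 1.0 - math.exp(-em * p_unc)
    return p_unc, p_corr


@dataclasses.dataclass
class Cluster:
    indices: tuple  # tuple of coordinate arrays (np.nonzero style)
    size: int
    sign: str       # "high" | "low"
    p_uncorrected: float
    p_corrected: float
    peak_score: float = math.nan
    centroid: tuple[float, float, float] | None = None


@dataclasses.dataclass
class ClusterSet:
    clusters: list
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.clusters)


@dataclasses.dataclass
class AbnormalityResult:
    """Signed abnormal-voxel labeling with surviving clusters and counts."""

    abnormal_high: np.ndarray
    abnormal_low: np.ndarray
    surviving_clusters: ClusterSet
    thresholds: dict

    @property
    def metrics(self) -> dict:
        n_high = int(self.abnormal_high.sum())
        n_low = int(self.abnormal_low.sum())
        return {"n_all": n_high + n_low, "n_low": n_low, "n_high": n_high}


def count_abnormal(result: AbnormalityResult) -> tuple[int, int, int]:
    """Global metrics (n_all, n_low, n_high); n_all = n_low + n_high."""
    m = result.metrics
    return m["n_all"], m["n_low"], m["n_high"]


def cluster_inference(supra: tuple[np.ndarray, np.ndarray],
                      smooth: SmoothnessEstimate,
                      alpha1: float, alpha2: float,
                      corrected: bool = True,
                      connectivity: int = 26,
                      score: ScoreMap | None = None,
                      threshold_u: float | None = None) -> ClusterSet:
    """GRF cluster-extent test on the signed suprathreshold masks.

    ``threshold_u`` is the Gaussian-scale voxel threshold that produced
    ``supra``; by default it is the two-sided Gaussian quantile at
    ``alpha1`` (scores with t nulls are mapped through their own quantile
    by :func:`detect_abnormalities`).  Clusters whose (corrected or
    uncorrected, per the flag) p-value is <= alpha2 are retained.
    """
    if not (0.0 < alpha2 < 1.0):
        raise ValidationError(f"alpha2 must be in (0, 1), got {alpha2}")
    u = threshold_u if threshold_u is not None else float(sps.norm.ppf(1.0 - alpha1 / 2.0))
    structure = connectivity_structure(connectivity)
    clusters: list[Cluster] = []
    for sign, vol in zip(("high", "low"), supra):
        labels, n = ndimage.label(np.asarray(vol, dtype=bool), structure=structure)
        for lab in range(1, n + 1):
            idx = np.nonzero(labels == lab)
            k = idx[0].size
            p_unc, p_corr = grf_cluster_p(k, u, smooth)
            if (p_corr if corrected else p_unc) <= alpha2:
                peak = math.nan
                centroid = tuple(float(c.mean()) for c in idx)
                if score is not None:
                    vals = score.values[idx]
                    peak = float(vals[np.nanargmax(np.abs(vals))])
                clusters.append(Cluster(idx, int(k), sign, p_unc, p_corr, peak, centroid))
    return ClusterSet(clusters, connectivity)


def detect_abnormalities(score: ScoreMap, smooth: SmoothnessEstimate,
                         alpha1: float = 0.05, alpha2: float = 0.05,
                         corrected: bool = True,
                         connectivity: int = 26) -> AbnormalityResult:
    """Full two-level decision for one score map.

    For t-null maps the GRF formulas receive the Gaussian threshold of
    equal tail probability (the t map's own quantile defines the supra
    sets; GRF theory is stated for Gaussian fields).
    """
    supra = voxel_threshold(score, alpha1)
    u_gauss = float(sps.norm.ppf(1.0 - alpha1 / 2.0))
    clusters = cluster_inference(supra, smooth, alpha1, alpha2, corrected,
                                 connectivity, score=score, threshold_u=u_gauss)
    high = np.zeros(score.mask.shape, dtype=bool)
    low = np.zeros(score.mask.shape, dtype=bool)
    for cl in clusters.clusters:
        (high if cl.sign == "high" else low)[cl.indices] = True
    thresholds = {"alpha1": alpha1, "alpha2": alpha2, "corrected": corrected,
                  "connectivity": connectivity, "statistic": score.statistic_kind}
    return AbnormalityResult(high, low, clusters, thresholds)


# ---------------------------------------------------------------------------
# FWER pseudo-t comparator

class PseudoTFWERScorer(BaseEstimator):
    """Pseudo-t with smoothed SD and max-statistic FWER thresholds.

    The pseudo-t replaces the noisy voxelwise SD with a spatially smoothed
    SD (Gaussian kernel, ``sd_smoothing_fwhm`` mm).  Per-tail thresholds
    are the ``1 - alpha_per_tail`` quantiles of the max (and min) pseudo-t
    over leave-one-out reference subjects — an empirical familywise
    calibration.  No cluster-extent threshold is applied.
    """

    def __init__(self, mask: np.ndarray = None,
                 voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 sd_smoothing_fwhm: float = 8.0,
                 alpha_per_tail: float = 0.05):
        self.mask = mask
        self.voxel_size = voxel_size
        self.sd_smoothing_fwhm = sd_smoothing_fwhm
        self.alpha_per_tail = alpha_per_tail

    def _smooth_sd(self, sd_flat: np.ndarray) -> np.ndarray:
        mask = self.mask
        sigma = [self.sd_smoothing_fwhm / vs / math.sqrt(_4LN2 * 2.0)
                 for vs in self.voxel_size]
        vol = np.zeros(mask.shape)
        vol[mask] = sd_flat
        num = ndimage.gaussian_filter(vol, sigma)
        den = ndimage.gaussian_filter(mask.astype(float), sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = num / den
        return sm[mask]

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        if n < 3:
            raise InsufficientCohortError(f"pseudo-t needs n >= 3 reference subjects, got {n}")
        if self.mask is None:
            raise ValidationError("PseudoTFWERScorer needs the 3-D analysis mask")
        self.n_ = n
        self.mean_ = X.mean(axis=0)
        self.smoothed_sd_ = self._smooth_sd(X.std(axis=0, ddof=1))
        max_high, max_low = [], []
        for j in range(n):
            rest = np.delete(X, j, axis=0)
            mean_j = rest.mean(axis=0)
            sd_j = self._smooth_sd(rest.std(axis=0, ddof=1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_j = (X[j] - mean_j) / sd_j
            t_j = t_j[np.isfinite(t_j)]
            max_high.append(t_j.max())
            max_low.append(-t_j.min())
        self.threshold_high_ = float(np.quantile(max_high, 1.0 - self.alpha_per_tail))
        self.threshold_low_ = float(np.quantile(max_low, 1.0 - self.alpha_per_tail))
        return self

    def decision_function(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (x - self.mean_) / self.smoothed_sd_


def fwer_pseudo_t(subject: VolumeGrid, reference: CohortStack,
                  sd_smoothing_fwhm: float = 8.0,
                  alpha_per_tail: float = 0.05,
                  connectivity: int = 26) -> AbnormalityResult:
    """FWER-controlled pseudo-t abnormality map (no extent threshold)."""
    grid = reference.grid
    grid.require_compatible(subject, what="test subject")
    est = PseudoTFWERScorer(mask=grid.mask, voxel_size=grid.voxel_size,
                            sd_smoothing_fwhm=sd_smoothing_fwhm,
                            alpha_per_tail=alpha_per_tail)
    est.fit(reference.as_matrix())
    t = est.decision_function(subject.masked_values())
    high = np.zeros(grid.shape, dtype=bool)
    low = np.zeros(grid.shape, dtype=bool)
    finite = np.isfinite(t)
    high[grid.mask] = finite & (t > est.threshold_high_)
    low[grid.mask] = finite & (t < -est.threshold_low_)
    clusters: list[Cluster] = []
    structure = connectivity_structure(connectivity)
    for sign, vol in (("high", high), ("low", low)):
        labels, nlab = ndimage.label(vol, structure=structure)
        for lab in range(1, nlab + 1):
            idx = np.nonzero(labels == lab)
            clusters.append(Cluster(idx, int(idx[0].size), sign, math.nan, math.nan,
                                    centroid=tuple(float(c.mean()) for c in idx)))
    thresholds = {"alpha_per_tail": alpha_per_tail,
                  "sd_smoothing_fwhm": sd_smoothing_fwhm,
                  "statistic": "PSEUDO_T",
                  "threshold_high": est.threshold_high_,
                  "threshold_low": est.threshold_low_}
    return AbnormalityResult(high, low, ClusterSet(clusters, connectivity), thresholds)


# ---------------------------------------------------------------------------
# Output

def save_abnormality_result(result: AbnormalityResult, like: VolumeGrid,
                            out_dir: str | os.PathLike, prefix: str = "abnormal") -> None:
    """Write the label maps, a TSV cluster table, and a metrics JSON."""
    os.makedirs(out_dir, exist_ok=True)
    save_mask(result.abnormal_high, like, os.path.join(out_dir, f"{prefix}_high.nii.gz"))
    save_mask(result.abnormal_low, like, os.path.join(out_dir, f"{prefix}_low.nii.gz"))
    rows = ["label\tsize\tpeak_score\tp_uncorrected\tp_corrected\tsign\tcentroid_ijk"]
    for i, cl in enumerate(result.surviving_clusters.clusters, start=1):
        cen = "NA" if cl.centroid is None else ",".join(f"{c:.1f}" for c in cl.centroid)
        rows.append(f"{i}\t{cl.size}\t{cl.peak_score:.4g}\t{cl.p_uncorrected:.4g}"
                    f"\t{cl.p_corrected:.4g}\t{cl.sign}\t{cen}")
    with open(os.path.join(out_dir, f"{prefix}_clusters.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
    payload = {"metrics": result.metrics, "thresholds": result.thresholds}
    with open(os.path.join(out_dir, f"{prefix}_metrics.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
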