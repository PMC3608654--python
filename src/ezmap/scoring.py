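"""Per-voxel reference statistics and classical single-subject scores.

Given a small normative cohort, a new subject's map is scored voxel by
voxel against the cohort mean and SD.  Two classical statistics are
provided:

* the standard Z-score, ``Z_i = (x_i - mean_i) / sd_i``, referred to a
  standard Gaussian null, and
* the "one vs. many" (Crawford–Howell) t-score,
  ``t_i = Z_i / sqrt(1 + 1/n)``, referred to a t distribution with
  ``n - 1`` degrees of freedom — the exact null when the cohort values
  are iid Gaussian.

The scorers are sklearn-style estimators operating on the flattened
in-mask matrix (``n_subjects x n_voxels``); the module-level functions
wrap them for :class:`~ezmap.grids.CohortStack` / ``VolumeGrid`` inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import ContractError, GridCompatibilityError, InsufficientCohortError
from .grids import CohortStack, VolumeGrid, save_volume

logger = logging.getLogger(__name__)

DEFAULT_SD_FLOOR = 1e-6


@dataclasses.dataclass
class ReferenceStats:
    """Voxelwise normative summary of the reference cohort.

    ``sd_map`` uses the n-1 denominator.  Voxels whose SD falls below
    ``sd_floor`` are flagged and excluded from all scoring (a score there
    would be dominated by division noise).
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    n: int
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    flagged: np.ndarray  # boolean, same shape; True where SD < sd_floor
    sd_floor: float = DEFAULT_SD_FLOOR

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def scorable(self) -> np.ndarray:
        """Mask of voxels that are in the analysis mask and not flagged."""
        return self.mask & ~self.flagged


@dataclasses.dataclass
class ScoreMap:
    """A per-voxel statistic volume with its null-distribution metadata.

    ``values`` is NaN outside the scorable mask.  ``null_model`` is one of
    ``{"kind": "gaussian"}``, ``{"kind": "t", "df": int}``,
    ``{"kind": "empirical"}``.
    """

    values: np.ndarray
    statistic_kind: str  # "Z" | "T" | "EZ" | "PSEUDO_T"
    null_model: dict
    n_reference: int
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    @property
    def scorable(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)

    def masked_values(self) -> np.ndarray:
        vals = self.values[self.mask]
        return vals[np.isfinite(vals)]

    def as_volume(self) -> VolumeGrid:
        return VolumeGrid(self.values, self.voxel_size, self.mask.copy(), self.affine)


class ZScorer(TransformerMixin, BaseEstimator):
    """Standard Z-scoring against a reference cohort.

    Fit on the reference matrix ``X`` of shape (n_subjects, n_voxels);
    ``transform`` maps new subject rows to Z-scores.  Voxels with reference
    SD below ``sd_floor`` are flagged and transformed to NaN.

    Attributes (after fit): ``mean_``, ``sd_`` (ddof=1), ``n_``, ``df_``,
    ``flagged_`` (boolean per voxel).
    """

    statistic_kind = "Z"

    def __init__(self, sd_floor: float = DEFAULT_SD_FLOOR):
        self.sd_floor = sd_floor

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if X.shape[0] < 3:
            raise InsufficientCohortError(
                f"reference cohort needs n >= 3 subjects, got {X.shape[0]}"
            )
        self.n_ = X.shape[0]
        self.df_ = self.n_ - 1
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.flagged_ = self.sd_ < self.sd_floor
        n_flagged = int(self.flagged_.sum())
        if n_flagged:
            logger.info("%d voxels flagged for SD < %g", n_flagged, self.sd_floor)
        return self

    def _zscores(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=np.float64, ensure_2d=False)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.mean_.shape[0]:
            raise GridCompatibilityError(
                f"subject has {X.shape[1]} voxels, reference has {self.mean_.shape[0]}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (X - self.mean_) / self.sd_
        z[:, self.flagged_] = np.nan
        return z[0] if one_d else z

    def transform(self, X) -> np.ndarray:
        return self._zscores(X)

    def null_model(self) -> dict:
        return {"kind": "gaussian"}


class OneVsManyTScorer(ZScorer):
    """Crawford–Howell "one vs. many" t-scoring: ``t = Z / sqrt(1 + 1/n)``,
    null t(n-1).  Exact for iid Gaussian reference values."""

    statistic_kind = "T"

    def transform(self, X) -> np.ndarray:
        return self._zscores(X) / np.sqrt(1.0 + 1.0 / self.n_)

    def null_model(self) -> dict:
        check_is_fitted(self, "df_")
        return {"kind": "t", "df": int(self.df_)}


def theoretical_t_sd(df: int) -> float:
    """SD of the t distribution, sqrt(df / (df - 2)); requires df > 2."""
    if df <= 2:
        raise ContractError(f"t distribution with df={df} has no finite SD")
    return float(np.sqrt(df / (df - 2.0)))


# ---------------------------------------------------------------------------
# Volume-level wrappers

def reference_stats(reference: CohortStack, sd_floor: float = DEFAULT_SD_FLOOR) -> ReferenceStats:
    """Voxelwise mean and SD (n-1 denominator) of the reference cohort."""
    scorer = ZScorer(sd_floor=sd_floor).fit(reference.as_matrix())
    grid = reference.grid
    mean_map = grid.with_masked_values(scorer.mean_).data
    sd_map = grid.with_masked_values(scorer.sd_, fill=0.0).data
    flagged = np.zeros(grid.shape, dtype=bool)
    flagged[grid.mask] = scorer.flagged_
    return ReferenceStats(mean_map, sd_map, scorer.n_, grid.mask.copy(),
                          grid.voxel_size, flagged, sd_floor)


def _score_subject(subject: VolumeGrid, stats: ReferenceStats, kind: str) -> ScoreMap:
    if subject.shape != stats.mask.shape:
        raise GridCompatibilityError(
            f"subject shape {subject.shape} != reference shape {stats.mask.shape}"
        )
    values = np.full(stats.mask.shape, np.nan)
    ok = stats.scorable
    n_excluded = int(stats.mask.sum() - ok.sum())
    if n_excluded:
        logger.info("%d flagged voxels excluded from %s-scoring", n_excluded, kind)
    values[ok] = (subject.data[ok] - stats.mean_map[ok]) / stats.sd_map[ok]
    if kind == "T":
        values /= np.sqrt(1.0 + 1.0 / stats.n)
        null = {"kind": "t", "df": stats.df}
    else:
        null = {"kind": "gaussian"}
    return ScoreMap(values, kind, null, stats.n, stats.mask.copy(),
                    stats.voxel_size, subject.affine)


def z_map(subject: VolumeGrid, stats: ReferenceStats) -> ScoreMap:
    """Standard Z-score map of one subject against the reference stats."""
    return _score_subject(subject, stats, "Z")


def t_map(subject: VolumeGrid, stats: ReferenceStats) -> ScoreMap:
    """One-vs-many t-score map: ``Z / sqrt(1 + 1/n)`` with a t(n-1) null."""
    return _score_subject(subject, stats, "T")


def save_score_map(score: ScoreMap, path: str | os.PathLike) -> None:
    """Write a score map as NIfTI plus a JSON sidecar with its metadata."""
    save_volume(score.as_volume(), path)
    sidecar = {
        "statistic_kind": score.statistic_kind,
        "null_model": score.null_model,
        "n_reference": int(score.n_reference),
    }
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
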