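"""Bootstrap variance of Z-scores and the Enhanced Z-score (EZ).

A Z-score computed against a *small* reference cohort inherits extra
variance from the sampling of that cohort: with n reference subjects the
held-out-control Z-score is distributed as ``sqrt(1 + 1/n) * t(n-1)``
under Gaussianity, with SD > 1.  Thresholding such Z-scores against a
standard Gaussian therefore over-calls abnormality.

The bootstrap procedure estimates this sample-to-sample SD per voxel,
nonparametrically: each replicate resamples n+1 subjects from the
available controls, treats the first n as a reference group, scores the
(n+1)-th against them, and the SD over replicates of those Z-scores is
``sd*``.  The Enhanced Z-score divides the observed Z by ``sd*``::

    EZ_i = Z_i / sd*_i

and is referred to a standard Gaussian, giving a more conservative and
better-calibrated test than the raw Z.

The estimator also supports the diagnostics built on ``sd*``: dispersion
classification against the theoretical t SD band, and empirical
uncoverage rates.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats as sps
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError, GridCompatibilityError, InsufficientCohortError, ValidationError
from .grids import CohortStack, VolumeGrid
from .scoring import ScoreMap, ZScorer, theoretical_t_sd

logger = logging.getLogger(__name__)

DEFAULT_B = 1000


@dataclasses.dataclass
class BootstrapSDMap:
    """Bootstrap SD of Z-scores (``sd_star``) and replicate-mean diagnostic."""

    sd_star: np.ndarray
    mean_z: np.ndarray
    B: int
    n: int
    seed: int | None
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    scheme: str = "resample"
    n_dropped: int = 0  # replicate-voxel values dropped for zero reference SD


@dataclasses.dataclass
class DispersionClassMap:
    """Voxel classification of bootstrap t-score SD against the
    theoretical band [psi_L, psi_U]."""

    classes: np.ndarray  # int8 volume with values from CLASS_*
    psi_L: float
    psi_U: float
    mask: np.ndarray


CLASS_UNSCORED = 0
CLASS_UNDER = 1
CLASS_CLOSE = 2
CLASS_OVER = 3
CLASS_LABELS = {CLASS_UNSCORED: "UNSCORED", CLASS_UNDER: "UNDER",
                CLASS_CLOSE: "CLOSE", CLASS_OVER: "OVER"}


def _bootstrap_sd(X: np.ndarray, n: int, B: int, rng: np.random.Generator,
                  scheme: str = "resample"):
    """Core replicate loop on the (N_subjects, V) matrix.

    Returns (sd_star, mean_z, n_dropped) over B replicate Z-scores per
    voxel; replicates with zero reference SD at a voxel are dropped at
    that voxel only.
    """
    N, V = X.shape
    if N < n + 1:
        raise InsufficientCohortError(f"bootstrap needs N >= n+1 = {n + 1} controls, got {N}")
    if B < 2:
        raise ValidationError(f"need B >= 2 bootstrap replicates, got {B}")
    if scheme not in ("resample", "holdout"):
        raise ValidationError(f"unknown bootstrap scheme {scheme!r}")

    # streaming moments over replicates, NaN-aware via masks
    sum_z = np.zeros(V)
    sum_z2 = np.zeros(V)
    count = np.zeros(V)
    chunk = max(1, min(B, int(2e8 / (8 * n * V))))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        if scheme == "resample":
            idx = rng.integers(0, N, size=(b, n + 1))
            ref_idx, test_idx = idx[:, :n], idx[:, n]
        else:  # holdout: the test subject is excluded from the reference draw
            test_idx = rng.integers(0, N, size=b)
            ref_idx = rng.integers(0, N - 1, size=(b, n))
            ref_idx += (ref_idx >= test_idx[:, None])
        ref = X[ref_idx]                       # (b, n, V)
        mean = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (X[test_idx] - mean) / sd
        ok = sd > 0
        zz = np.where(ok, z, 0.0)
        sum_z += zz.sum(axis=0)
        sum_z2 += (zz * zz).sum(axis=0)
        count += ok.sum(axis=0)
        done += b
    n_dropped = int(B * V - count.sum())
    if n_dropped:
        logger.info("dropped %d replicate values with degenerate reference SD", n_dropped)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_z = sum_z / count
        var = (sum_z2 - count * mean_z**2) / (count - 1)
    sd_star = np.sqrt(np.maximum(var, 0.0))
    sd_star[count < 2] = np.nan
    mean_z[count < 1] = np.nan
    return sd_star, mean_z, n_dropped


class EZScorer(ZScorer):
    """Enhanced Z-scoring: Z divided by the bootstrap SD of Z-scores.

    Parameters
    ----------
    B : int
        Number of bootstrap replicates (default 1000; enough that the
        Monte-Carlo error of ``sd*`` is small against the dispersion band).
    n_reference : int or None
        Reference-group size per replicate; default ``N - 1`` where N is
        the number of fitted control subjects.
    scheme : {"resample", "holdout"}
        "resample" draws all n+1 slots with replacement from the N controls
        (standard nonparametric bootstrap); "holdout" excludes the test
        slot's subject from the reference draw.
    seed : int or None
        Seed for the replicate RNG; same seed + inputs reproduces ``sd*``
        bit-exactly.

    Attributes (after fit): those of :class:`ZScorer` plus ``sd_star_``
    and ``mean_z_`` per voxel.
    """

    statistic_kind = "EZ"

    def __init__(self, B: int = DEFAULT_B, n_reference: int | None = None,
                 scheme: str = "resample", seed: int | None = None,
                 sd_floor: float = 1e-6):
        super().__init__(sd_floor=sd_floor)
        self.B = B
        self.n_reference = n_reference
        self.scheme = scheme
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n = self.n_reference if self.n_reference is not None else X.shape[0] - 1
        # reference stats come from the first n subjects; any extra controls
        # exist to feed the bootstrap's held-out slot
        super().fit(X[:n])
        rng = np.random.default_rng(self.seed)
        self.sd_star_, self.mean_z_, self.n_dropped_ = _bootstrap_sd(
            X, n, self.B, rng, self.scheme)
        self.flagged_ |= ~np.isfinite(self.sd_star_) | (self.sd_star_ <= 0)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "sd_star_")
        z = self._zscores(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            return z / self.sd_star_

    def null_model(self) -> dict:
        return {"kind": "gaussian"}


# ---------------------------------------------------------------------------
# Volume-level wrappers

def bootstrap_sd_map(controls: CohortStack, n: int, B: int = DEFAULT_B,
                     seed: int | None = None, scheme: str = "resample") -> BootstrapSDMap:
    """Voxelwise bootstrap SD of Z-scores from the control cohort.

    Each of the B replicates resamples n+1 of the N controls (with
    replacement), forms reference mean/SD from the first n, and scores the
    (n+1)-th; ``sd_star`` is the SD (n-1 denominator) of the replicate
    Z-scores per voxel.
    """
    X = controls.as_matrix()
    rng = np.random.default_rng(seed)
    sd_flat, mz_flat, dropped = _bootstrap_sd(X, n, B, rng, scheme)
    grid = controls.grid
    sd_star = grid.with_masked_values(sd_flat).data
    mean_z = grid.with_masked_values(mz_flat).data
    return BootstrapSDMap(sd_star, mean_z, B, n, seed, grid.mask.copy(),
                          grid.voxel_size, scheme, dropped)


def ez_map(z: ScoreMap, boot: BootstrapSDMap) -> ScoreMap:
    """Enhanced Z-score map: ``EZ_i = Z_i / sd*_i`` (standard-Gaussian null)."""
    if z.statistic_kind != "Z":
        raise ContractError(f"ez_map expects a Z map, got {z.statistic_kind}")
    if z.values.shape != boot.sd_star.shape or not np.array_equal(z.mask, boot.mask):
        raise GridCompatibilityError("Z map and bootstrap SD map are on different grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = z.values / boot.sd_star
    values[~np.isfinite(boot.sd_star) | (boot.sd_star <= 0)] = np.nan
    return ScoreMap(values, "EZ", {"kind": "gaussian"}, z.n_reference,
                    z.mask.copy(), z.voxel_size, z.affine)


def tail_probability(score: ScoreMap) -> VolumeGrid:
    """Two-sided Gaussian tail probability ``TP_i = 2 (1 - Phi(|v_i|))``.

    Only defined for standard-Gaussian-null maps (Z, EZ); the sign of the
    score itself carries the abnormally-high vs abnormally-low label.
    """
    if score.null_model.get("kind") != "gaussian":
        raise ContractError(
            f"tail_probability needs a Gaussian null, got {score.null_model}"
        )
    tp = np.full(score.values.shape, np.nan)
    ok = np.isfinite(score.values)
    tp[ok] = 2.0 * sps.norm.sf(np.abs(score.values[ok]))
    return VolumeGrid(tp, score.voxel_size, score.mask.copy(), score.affine)


def classify_dispersion(boot: BootstrapSDMap, df: int | None = None,
                        delta: int = 10) -> DispersionClassMap:
    """Classify voxels by bootstrap t-score SD against the theoretical band.

    The implied t-score SD is ``sd* / sqrt(1 + 1/n)``; the CLOSE band is
    ``[psi_L, psi_U]`` where ``psi_L`` is the SD of t(df + delta) and
    ``psi_U`` the SD of t(df - delta) (SD of t shrinks as df grows).
    """
    if df is None:
        df = boot.n - 1
    if df - delta <= 2:
        raise ContractError(
            f"t SD undefined for df - delta = {df - delta} <= 2"
        )
    psi_L = theoretical_t_sd(df + delta)
    psi_U = theoretical_t_sd(df - delta)
    sd_t = boot.sd_star / np.sqrt(1.0 + 1.0 / boot.n)
    classes = np.zeros(boot.sd_star.shape, dtype=np.int8)
    ok = boot.mask & np.isfinite(sd_t)
    classes[ok & (sd_t < psi_L)] = CLASS_UNDER
    classes[ok & (sd_t > psi_U)] = CLASS_OVER
    classes[ok & (sd_t >= psi_L) & (sd_t <= psi_U)] = CLASS_CLOSE
    return DispersionClassMap(classes, psi_L, psi_U, boot.mask.copy())


def uncoverage_rate(score: ScoreMap, lam: float) -> float:
    """Fraction of in-mask voxels outside ``+/- z_{1 - lam/2}``.

    The empirical analogue of the nominal uncoverage rate ``lam`` for a
    control subject: for a well-calibrated score the two agree.
    """
    if not (0.0 < lam < 1.0):
        raise ValidationError(f"lam must be in (0, 1), got {lam}")
    vals = score.masked_values()
    if vals.size == 0:
        raise ValidationError("score map has no finite in-mask values")
    c = sps.norm.ppf(1.0 - lam / 2.0)
    return float(np.mean(np.abs(vals) > c))
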