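"""Voxelwise demographic covariate adjustment.

FA varies systematically with age, sex and education.  Before scoring a
subject against the reference cohort, those effects are estimated by a
voxelwise ordinary-least-squares regression (value ~ intercept + age +
sex + education) on the reference group, and removed — but only at voxels
where the overall regression F test is significant AND the significant
voxels form a large enough contiguous cluster.  Applying the regression
everywhere would merely inject estimation noise into the smooth residual
field and reduce detection sensitivity; the cluster gate keeps the
adjustment to regions with coherent demographic effects.

Sex is coded F=0 / M=1; age and education are in years.  Covariates are
centered at the reference-cohort means, so an adjusted map is directly
comparable to the reference mean map.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import CollinearityError, InsufficientCohortError, ValidationError
from .grids import CohortStack, VolumeGrid, encode_covariates, save_volume
from .clusters import drop_small_clusters

COEF_NAMES = ("intercept", "age", "sex", "education")


@dataclasses.dataclass
class CovariateModel:
    """Fitted voxelwise regression of map values on demographics."""

    beta_maps: dict          # name -> 3-D coefficient array
    beta_se_maps: dict       # name -> 3-D standard-error array
    f_stat_map: np.ndarray
    significant_mask: np.ndarray
    df: tuple[int, int]      # (numerator, denominator)
    centering: dict          # covariate name -> reference mean
    alpha: float
    cluster_gate: int
    mask: np.ndarray
    voxel_size: tuple[float, float, float]

    @property
    def f_critical(self) -> float:
        return float(sps.f.ppf(1.0 - self.alpha, *self.df))


class CovariateAdjuster(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer removing demographic effects.

    Fit on the reference matrix ``X`` (n_subjects x n_voxels) with
    covariates ``C`` (n_subjects x 3: age, sex01, education); transform
    subtracts the fitted covariate effects at significant voxels only.

    Parameters
    ----------
    alpha : float
        Voxel-level significance of the overall regression F test
        (numerator df 3, denominator df n-4).
    cluster_gate : int
        Connected components of suprathreshold voxels must contain
        strictly more than this many voxels to survive.
    connectivity : {6, 18, 26}
        3-D neighbourhood used for the component labeling.
    mask : 3-D boolean array or None
        Analysis mask; required for the cluster gate (the voxel axis of X
        is the flattened in-mask order).  With ``mask=None`` the gate is
        applied along the flat axis (1-D components), which is only
        sensible in tests.
    """

    def __init__(self, alpha: float = 0.05, cluster_gate: int = 100,
                 connectivity: int = 26, mask: np.ndarray | None = None):
        self.alpha = alpha
        self.cluster_gate = cluster_gate
        self.connectivity = connectivity
        self.mask = mask

    def fit(self, X, C):
        X = np.asarray(X, dtype=np.float64)
        C = np.asarray(C, dtype=np.float64)
        n, V = X.shape
        if C.shape != (n, 3):
            raise ValidationError(f"covariates must be (n, 3), got {C.shape}")
        if n < 6:
            raise InsufficientCohortError(
                f"covariate regression needs n >= 6 (df_denominator >= 2), got {n}"
            )
        if np.any(C.std(axis=0) == 0):
            raise CollinearityError("constant covariate column")
        D = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise CollinearityError("collinear covariate design")
        self.centering_ = C.mean(axis=0)
        dfn, dfd = 3, n - 4
        # OLS for every voxel at once
        DtD_inv = np.linalg.inv(D.T @ D)
        beta = DtD_inv @ (D.T @ X)               # (4, V)
        resid = X - D @ beta
        rss = (resid**2).sum(axis=0)
        tss = ((X - X.mean(axis=0))**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((tss - rss) / dfn) / (rss / dfd)
            sigma2 = rss / dfd
        self.beta_ = beta
        self.beta_se_ = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
        self.f_stat_ = f
        self.df_ = (dfn, dfd)
        self.f_critical_ = float(sps.f.ppf(1.0 - self.alpha, dfn, dfd))
        sig = np.isfinite(f) & (f > self.f_critical_)
        # noiseless fits (rss ~ 0 with real effect) count as significant
        sig |= (rss <= 1e-20 * np.maximum(tss, 1.0)) & (tss > 0)
        self.significant_ = self._gate(sig)
        return self

    def _gate(self, sig_flat: np.ndarray) -> np.ndarray:
        if self.mask is None:
            # 1-D run-length components along the flat axis
            vol = sig_flat[None, None, :]
            kept = drop_small_clusters(vol, self.cluster_gate, self.connectivity)
            return kept[0, 0]
        vol = np.zeros(self.mask.shape, dtype=bool)
        vol[self.mask] = sig_flat
        kept = drop_small_clusters(vol, self.cluster_gate, self.connectivity)
        return kept[self.mask]

    def transform(self, X, C):
        check_is_fitted(self, "beta_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        C = np.atleast_2d(np.asarray(C, dtype=np.float64))
        if not np.all(np.isfinite(C)):
            raise ValidationError("missing covariate value")
        effect = (C - self.centering_) @ self.beta_[1:]   # (n, V)
        out = X.copy()
        out[:, self.significant_] -= effect[:, self.significant_]
        return out


# ---------------------------------------------------------------------------
# Volume-level wrappers

def fit_covariate_model(reference: CohortStack, alpha: float = 0.05,
                        cluster_gate: int = 100, connectivity: int = 26) -> CovariateModel:
    """Fit the voxelwise demographic regression on the reference cohort."""
    grid = reference.grid
    est = CovariateAdjuster(alpha=alpha, cluster_gate=cluster_gate,
                            connectivity=connectivity, mask=grid.mask)
    est.fit(reference.as_matrix(), reference.covariate_matrix())
    beta_maps, se_maps = {}, {}
    for k, name in enumerate(COEF_NAMES):
        beta_maps[name] = grid.with_masked_values(est.beta_[k]).data
        se_maps[name] = grid.with_masked_values(est.beta_se_[k]).data
    f_map = grid.with_masked_values(est.f_stat_).data
    sig = np.zeros(grid.shape, dtype=bool)
    sig[grid.mask] = est.significant_
    centering = dict(zip(("age", "sex", "education"), est.centering_))
    return CovariateModel(beta_maps, se_maps, f_map, sig, est.df_, centering,
                          alpha, cluster_gate, grid.mask.copy(), grid.voxel_size)


def adjust_map(subject: VolumeGrid, subject_covariates, model: CovariateModel) -> VolumeGrid:
    """Remove fitted covariate effects from one subject's map.

    ``subject_covariates`` is a mapping or pandas row with age, sex,
    education.  At voxels in the model's significant mask the returned
    value is ``value - sum_k beta_k (c_k - centering_k)``; elsewhere the
    map is unchanged.  Applying the same model twice is a no-op the second
    time only if the covariates equal the centering values; the operation
    is idempotent in the sense that re-adjusting an adjusted map with
    zero-deviation covariates changes nothing.
    """
    if subject.shape != model.mask.shape:
        raise ValidationError("subject not on the model grid")
    row = _covariate_row(subject_covariates)
    data = subject.data.copy()
    sig = model.significant_mask
    effect = np.zeros(subject.shape)
    for name in ("age", "sex", "education"):
        effect += model.beta_maps[name] * (row[name] - model.centering[name])
    data[sig] -= effect[sig]
    return subject.with_data(data)


def adjust_cohort(cohort: CohortStack, model: CovariateModel) -> CohortStack:
    """Adjust every subject in a cohort using its covariate table."""
    if cohort.covariates is None:
        raise ValidationError("cohort has no covariate table to adjust with")
    C = cohort.covariate_matrix()
    vols = [adjust_map(v, {"age": c[0], "sex": c[1], "education": c[2]}, model)
            for v, c in zip(cohort.volumes, C)]
    return CohortStack(vols, cohort.covariates, cohort.role_label)


def _covariate_row(row) -> dict:
    try:
        vals = {k: row[k] for k in ("age", "sex", "education")}
    except (KeyError, IndexError, TypeError) as exc:
        raise ValidationError(f"covariate row incomplete: {exc}") from exc
    out = {}
    for k, v in vals.items():
        if k == "sex" and isinstance(v, str):
            v = {"F": 0.0, "M": 1.0}.get(v.upper())
            if v is None:
                raise ValidationError("sex must be F/M or 0/1")
        v = float(v)
        if not np.isfinite(v):
            raise ValidationError(f"missing covariate {k}")
        out[k] = v
    return out


def save_covariate_model(model: CovariateModel, out_dir: str | os.PathLike) -> None:
    """Persist as one NIfTI per coefficient plus a JSON sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    like = VolumeGrid(model.f_stat_map, model.voxel_size, model.mask)
    for name, arr in model.beta_maps.items():
        save_volume(like.with_data(np.nan_to_num(arr)), os.path.join(out_dir, f"beta_{name}.nii.gz"))
    save_volume(like.with_data(np.nan_to_num(model.f_stat_map)),
                os.path.join(out_dir, "f_stat.nii.gz"))
    save_volume(like.with_data(model.significant_mask.astype(float)),
                os.path.join(out_dir, "significant_mask.nii.gz"))
    sidecar = {"df": list(model.df), "centering": model.centering,
               "alpha": model.alpha, "cluster_gate": model.cluster_gate}
    with open(os.path.join(out_dir, "covariate_model.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
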