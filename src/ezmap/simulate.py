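"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real FA maps are spatially smooth scalar fields on a masked lattice with
across-subject variation at each voxel, demographic trends, and — in
patients — focal signed lesions.  The generator emulates exactly that:

* each subject's map is a baseline level plus a stationary smooth
  Gaussian field (white noise convolved with a Gaussian kernel on a
  torus, variance-renormalized) scaled by the between-subject SD;
* the per-voxel SD is either a single sigma, or drawn from a two-
  component Gaussian scale mixture
  ``pi_1 N(mu, sigma_1^2) + (1 - pi_1) N(mu, sigma_2^2)`` — the
  variance-heterogeneity model under which the one-vs-many t loses its
  nominal coverage.  The mixture can be assigned per voxel (fixed across
  subjects: subpopulations of voxels) or per subject (subpopulations of
  people, e.g. variance increasing above some age);
* optional linear covariate effects (age, sex, education) are added;
* patients receive spherical lesions of signed effect expressed in units
  of the local between-subject SD, and the ground-truth lesion masks are
  returned alongside the cohorts.

The default lattice is 32x32x32 voxels of 1 mm with an ellipsoidal
analysis mask, small enough that every pipeline stage runs in seconds;
cohort sizes default to the 21 reference / 21 test-control / 34 patient
design used throughout the validation experiments.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .exceptions import ContractError, ValidationError
from .grids import CohortStack, VolumeGrid, cohort_from_arrays

_FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclasses.dataclass
class Lesion:
    """Spherical focal lesion: signed effect in units of the local SD."""

    center: tuple[int, int, int] | None = None  # None -> mask centroid
    radius: float = 3.6                         # voxels (~200-voxel ball)
    effect: float = -3.0                        # signed, in sigma units


@dataclasses.dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic experiment."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    smoothing_fwhm: float = 3.0          # mm; spatial correlation of the maps
    baseline_mean: float = 0.45          # FA-like level
    between_subject_sd: float = 0.05     # sigma, FA units
    mixture: tuple[float, float, float] | None = None  # (pi1, sigma1, sigma2)
    mixture_mode: str = "voxel"          # "voxel" | "subject"
    covariate_effects: tuple[float, float, float] | None = None  # per year / M / year
    n_reference: int = 21
    n_test_controls: int = 21
    n_patients: int = 34
    lesions: Sequence[Lesion] = dataclasses.field(default_factory=lambda: [Lesion()])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixture is not None:
            pi1, s1, s2 = self.mixture
            # pi1 = 1 is allowed as the degenerate single-Gaussian boundary
            if not (0.0 < pi1 <= 1.0) or s1 <= 0 or s2 <= 0:
                raise ValidationError(f"invalid mixture parameters {self.mixture}")
        if self.mixture_mode not in ("voxel", "subject"):
            raise ValidationError(f"mixture_mode must be voxel|subject, got {self.mixture_mode}")
        if min(self.n_reference, self.n_test_controls, self.n_patients) < 1:
            raise ValidationError("all cohort sizes must be >= 1")
        self.lesions = [l if isinstance(l, Lesion) else Lesion(**l) for l in self.lesions]

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(text)
        for key in ("shape", "voxel_size"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("mixture") is not None:
            d["mixture"] = tuple(d["mixture"])
        if d.get("covariate_effects") is not None:
            d["covariate_effects"] = tuple(d["covariate_effects"])
        return cls(**d)


def ellipsoid_mask(shape: tuple[int, int, int], relative_radius: float = 0.42) -> np.ndarray:
    """Ellipsoidal analysis mask centered in the lattice."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - (s - 1) / 2.0) / (relative_radius * s)) ** 2
             for g, s in zip(grids, shape))
    return r2 <= 1.0


def _kernel_norm(shape, sigma_vox) -> float:
    """L2 norm of the periodic Gaussian kernel: the SD of filtered unit noise."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma_vox, mode="wrap")
    return float(np.sqrt((k**2).sum()))


def smooth_unit_field(rng: np.random.Generator, shape, fwhm_vox) -> np.ndarray:
    """Stationary unit-variance Gaussian field with Gaussian autocorrelation.

    White noise is convolved with a Gaussian kernel on the torus (so the
    field is exactly stationary) and renormalized analytically by the
    kernel's L2 norm.
    """
    if np.isscalar(fwhm_vox):
        fwhm_vox = (float(fwhm_vox),) * 3
    sigma_vox = [max(f, 1e-6) * _FWHM_TO_SIGMA for f in fwhm_vox]
    noise = rng.standard_normal(shape)
    if max(sigma_vox) < 1e-3:
        return noise
    field = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
    return field / _kernel_norm(shape, sigma_vox)


def generate_mixture_voxels(spec: SyntheticSpec, n_subjects: int, n_voxels: int,
                            rng: np.random.Generator | None = None,
                            mode: str | None = None) -> np.ndarray:
    """Draw an (n_subjects, n_voxels) matrix from the two-Gaussian scale mixture.

    mode "voxel": each voxel is assigned SD sigma_1 with probability pi_1,
    else sigma_2, fixed across subjects.  mode "subject": every
    subject-voxel value is drawn independently from the mixture, i.e. the
    across-subject distribution at each voxel is itself the mixture — the
    regime in which the t(n-1) reference distribution breaks down.
    """
    if spec.mixture is None:
        raise ContractError("spec.mixture is not set")
    pi1, s1, s2 = spec.mixture
    mode = mode or spec.mixture_mode
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if mode == "voxel":
        sd = np.where(rng.random(n_voxels) < pi1, s1, s2)
        return spec.baseline_mean + rng.standard_normal((n_subjects, n_voxels)) * sd
    if mode == "subject":
        sd = np.where(rng.random((n_subjects, n_voxels)) < pi1, s1, s2)
        return spec.baseline_mean + rng.standard_normal((n_subjects, n_voxels)) * sd
    raise ValidationError(f"mode must be voxel|subject, got {mode}")


def _sample_covariates(rng: np.random.Generator, n: int, prefix: str) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i:03d}" for i in range(n)],
        "age": np.round(rng.uniform(20, 60, size=n), 1),
        "sex": rng.choice(["F", "M"], size=n),
        "education": np.round(rng.uniform(8, 22, size=n), 1),
    })


def _lesion_mask(spec: SyntheticSpec, mask: np.ndarray) -> np.ndarray:
    truth = np.zeros(spec.shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    for les in spec.lesions:
        center = les.center
        if center is None:
            coords = np.nonzero(mask)
            center = tuple(float(c.mean()) for c in coords)
        ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= les.radius**2
        if not (ball <= mask).all():
            raise ValidationError(f"lesion at {center} extends outside the analysis mask")
        truth |= ball
    return truth


def generate_cohorts(spec: SyntheticSpec):
    """Generate (reference, test_controls, patients, truth_masks).

    All subjects share one lattice, mask, and per-voxel SD structure; the
    same seed reproduces the cohorts bit-exactly.  ``truth_masks`` is a
    list (one boolean volume per patient) marking the inserted lesions.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_struct, rng_ref, rng_ctl, rng_pat = [np.random.default_rng(s) for s in ss.spawn(4)]
    mask = ellipsoid_mask(spec.shape)
    fwhm_vox = tuple(spec.smoothing_fwhm / vs for vs in spec.voxel_size)

    if spec.mixture is not None and spec.mixture_mode == "voxel":
        pi1, s1, s2 = spec.mixture
        sd_map = np.where(rng_struct.random(spec.shape) < pi1, s1, s2)
    else:
        sd_map = np.full(spec.shape, spec.between_subject_sd)

    def subject_sd(rng) -> np.ndarray:
        if spec.mixture is not None and spec.mixture_mode == "subject":
            pi1, s1, s2 = spec.mixture
            return np.where(rng.random(spec.shape) < pi1, s1, s2)
        return sd_map

    def build_group(rng, n, prefix, lesioned=False):
        cov = _sample_covariates(rng, n, prefix)
        effects = np.zeros((n, 1, 1, 1))
        if spec.covariate_effects is not None:
            ba, bs, be = spec.covariate_effects
            sex01 = (cov["sex"] == "M").to_numpy(float)
            eff = (ba * (cov["age"].to_numpy() - 40.0)
                   + bs * sex01
                   + be * (cov["education"].to_numpy() - 15.0))
            effects = eff.reshape(n, 1, 1, 1)
        lesion_offset = _lesion_offsets(spec, mask, sd_map) if lesioned else None
        lesion_truth = _lesion_mask(spec, mask) if lesioned else None
        arrays, truths = [], []
        for i in range(n):
            field = smooth_unit_field(rng, spec.shape, fwhm_vox)
            data = spec.baseline_mean + subject_sd(rng) * field + effects[i]
            if lesioned:
                data = data + lesion_offset
            arrays.append(data)
            truths.append(lesion_truth)
        return arrays, cov, truths

    ref_arrays, ref_cov, _ = build_group(rng_ref, spec.n_reference, "ref")
    ctl_arrays, ctl_cov, _ = build_group(rng_ctl, spec.n_test_controls, "ctl")
    pat_arrays, pat_cov, pat_truths = build_group(rng_pat, spec.n_patients, "pat",
                                                  lesioned=True)
    reference = cohort_from_arrays(ref_arrays, mask, spec.voxel_size, ref_cov, "reference")
    controls = cohort_from_arrays(ctl_arrays, mask, spec.voxel_size, ctl_cov, "test_control")
    patients = cohort_from_arrays(pat_arrays, mask, spec.voxel_size, pat_cov, "patient")
    return reference, controls, patients, pat_truths


def _lesion_offsets(spec: SyntheticSpec, mask: np.ndarray, sd_map: np.ndarray) -> np.ndarray:
    """Additive lesion field: effect (in sigma units) times the local SD."""
    offset = np.zeros(spec.shape)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    for les in spec.lesions:
        center = les.center
        if center is None:
            coords = np.nonzero(mask)
            center = tuple(float(c.mean()) for c in coords)
        ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= les.radius**2
        if not (ball <= mask).all():
            raise ValidationError(f"lesion at {center} extends outside the analysis mask")
        offset += np.where(ball, les.effect * sd_map, 0.0)
    return offset
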