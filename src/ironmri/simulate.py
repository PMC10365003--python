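"""Synthetic decay curves, multi-echo phantoms and patient cohorts.

Every downstream stage (fitting, mapping, grading, cohort statistics) is
exercised against data from this module, so each generator exposes the
ground truth it was built from and is bit-for-bit reproducible for a fixed
seed.

Three generators:

* :func:`simulate_decay` — a single-ROI mono-exponential decay
  ``y(TE) = K exp(-TE/T2*) + floor`` under Rician magnitude noise,
* :func:`simulate_phantom` — a 2-D multi-echo stack with organ-like regions
  of prescribed ``(K, T2*)`` over a pure-noise background,
* :func:`simulate_cohort` — a patient table whose organ T2* values and
  serum ferritin follow prescribed marginals and prescribed pairwise
  Spearman correlations via a Gaussian copula.

The Rician model is the standard one for magnitude MRI: the noiseless value
is perturbed by two independent zero-mean Gaussian channels of SD ``sigma``
and the magnitude is taken, so a zero-signal background pixel is Rayleigh
with mean ``sigma * sqrt(pi/2)`` — the late-echo noise floor that inflates
naive T2* fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EchoSeries, EchoTrain, ImageStack, default_echo_train
from .exceptions import InvalidInputError, InvalidSpecError

__all__ = [
    "DecayParams",
    "PhantomSpec",
    "SimCohortSpec",
    "simulate_decay",
    "simulate_phantom",
    "simulate_cohort",
    "disk_mask",
    "rect_mask",
    "default_cohort_spec",
    "lognormal_from_moments",
    "spearman_to_pearson",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class DecayParams:
    """Ground-truth parameters of one decaying region.

    Parameters
    ----------
    K : float
        Signal amplitude at TE = 0 (arbitrary units), > 0.
    T2star : float
        Effective transverse relaxation time (ms), > 0.
    noise_floor : float
        Additive plateau (a.u.) added to the noiseless decay; models the
        rectified-background contribution picked up by an ROI that brushes
        air or very dark tissue.
    sigma : float
        Per-channel Gaussian noise SD (a.u.) of the Rician model.
    seed : int
        RNG seed; fixing it fixes every output bit-for-bit.
    """

    K: float
    T2star: float
    noise_floor: float = 0.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise InvalidInputError(f"K must be > 0, got {self.K}")
        if self.T2star <= 0:
            raise InvalidInputError(f"T2star must be > 0, got {self.T2star}")
        if self.noise_floor < 0:
            raise InvalidInputError("noise_floor must be >= 0")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")

    def clean_signal(self, tes: np.ndarray) -> np.ndarray:
        """Noiseless magnitude: K * exp(-TE/T2*) + noise_floor."""
        return self.K * np.exp(-np.asarray(tes, float) / self.T2star) + self.noise_floor


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (clean + N(0, sigma)) + i N(0, sigma)."""
    if sigma == 0:
        return np.asarray(clean, float).copy()
    real = clean + rng.normal(0.0, sigma, size=np.shape(clean))
    imag = rng.normal(0.0, sigma, size=np.shape(clean))
    return np.hypot(real, imag)


def simulate_decay(echo_train: EchoTrain, params: DecayParams,
                   rng: np.random.Generator | None = None) -> EchoSeries:
    """Simulate one ROI-mean decay series.

    Parameters
    ----------
    echo_train : EchoTrain
        Echo schedule (ms).
    params : DecayParams
        Ground truth; ``params.seed`` seeds the noise unless an explicit
        ``rng`` is given (used by the phantom generator to share a stream).

    Returns
    -------
    EchoSeries
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    clean = params.clean_signal(echo_train.tes)
    return EchoSeries(echo_train, _rician(clean, params.sigma, rng))


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Boolean disk; ``center`` is (row, col) in pixels."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def rect_mask(shape: tuple[int, int], rows: tuple[int, int],
              cols: tuple[int, int]) -> np.ndarray:
    """Boolean rectangle covering rows[0]:rows[1], cols[0]:cols[1]."""
    m = np.zeros(shape, dtype=bool)
    m[rows[0]:rows[1], cols[0]:cols[1]] = True
    return m


@dataclass(frozen=True)
class PhantomSpec:
    """A 2-D multi-echo phantom: disjoint labelled regions over noise.

    ``regions`` maps label -> (boolean mask, DecayParams).  Pixels outside
    every region are pure-noise background (decay amplitude 0, Rayleigh
    magnitude of SD ``background_sigma``).  A single ``seed`` governs all
    noise in the phantom; the per-region ``DecayParams.seed`` values are
    ignored here so that region order cannot silently change the stream.
    """

    image_shape: tuple[int, int]
    regions: dict[str, tuple[np.ndarray, DecayParams]]
    echo_train: EchoTrain
    background_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise InvalidSpecError(f"bad image_shape {self.image_shape}")
        if self.background_sigma < 0:
            raise InvalidSpecError("background_sigma must be >= 0")
        occupancy = np.zeros(self.image_shape, dtype=int)
        for label, (mask, params) in self.regions.items():
            mask = np.asarray(mask)
            if mask.shape != tuple(self.image_shape) or mask.dtype != bool:
                raise InvalidSpecError(
                    f"region {label!r}: mask must be a boolean array of shape "
                    f"{self.image_shape}"
                )
            if not mask.any():
                raise InvalidSpecError(f"region {label!r} is empty")
            occupancy += mask
        if np.any(occupancy > 1):
            raise InvalidSpecError("regions overlap")

    def region_mask(self, label: str) -> np.ndarray:
        return np.asarray(self.regions[label][0])

    def background_mask(self) -> np.ndarray:
        bg = np.ones(self.image_shape, dtype=bool)
        for mask, _ in self.regions.values():
            bg &= ~np.asarray(mask)
        return bg


def simulate_phantom(spec: PhantomSpec) -> ImageStack:
    """Render the phantom: one image per echo, independent noise per pixel.

    Each region pixel follows its region's clean decay under the region's
    Rician ``sigma``; background pixels are pure noise magnitude with
    ``spec.background_sigma``.
    """
    ny, nx = spec.image_shape
    tes = spec.echo_train.tes
    rng = np.random.default_rng(spec.seed)

    clean = np.zeros((ny, nx, tes.size))
    sigma = np.full((ny, nx), spec.background_sigma)
    for mask, params in spec.regions.values():
        mask = np.asarray(mask)
        clean[mask] = params.clean_signal(tes)
        sigma[mask] = params.sigma

    sig3 = sigma[..., None]
    if np.all(sigma == 0):
        data = clean
    else:
        real = clean + rng.normal(0.0, 1.0, clean.shape) * sig3
        imag = rng.normal(0.0, 1.0, clean.shape) * sig3
        data = np.where(sig3 > 0, np.hypot(real, imag), clean)
    return ImageStack(data, spec.echo_train)


# ---------------------------------------------------------------------------
# Cohort simulation (Gaussian copula)
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "ferritin_ng_dl",
    "t2s_heart_ms", "t2s_liver_ms", "t2s_pancreas_ms",
]

#: cohort variable order used by the copula correlation matrix
COPULA_VARS = ["t2s_heart_ms", "t2s_liver_ms", "t2s_pancreas_ms", "ferritin_ng_dl"]


def spearman_to_pearson(rho_s):
    """Latent-Gaussian Pearson correlation reproducing a target Spearman.

    For a bivariate Gaussian, rho_s = (6/pi) asin(rho_p / 2); inverting gives
    rho_p = 2 sin(pi rho_s / 6), which is exact for continuous marginals
    pushed through a Gaussian copula.
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, float) / 6.0)


def lognormal_from_moments(mean: float, sd: float):
    """Frozen scipy log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise InvalidInputError("log-normal moments need mean > 0, sd >= 0")
    s2 = np.log1p((sd / mean) ** 2)
    return stats.lognorm(s=np.sqrt(s2), scale=mean * np.exp(-s2 / 2.0))


@dataclass(frozen=True)
class SimCohortSpec:
    """Specification of a synthetic patient cohort.

    Parameters
    ----------
    n : int
        Number of patients, >= 3.
    marginals : dict
        Maps each of ``COPULA_VARS`` to a frozen scipy distribution (must
        expose ``.ppf``); organ T2* on the ms scale, ferritin in ng/dl.
    rank_corr : pandas.DataFrame
        Target pairwise Spearman correlation matrix, indexed by
        ``COPULA_VARS`` (symmetric, unit diagonal, entries in [-1, 1]).
    seed : int
    age_range : tuple
        Inclusive integer range patient ages are drawn uniformly from.
    """

    n: int
    marginals: dict
    rank_corr: pd.DataFrame
    seed: int = 0
    age_range: tuple[int, int] = (9, 37)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidSpecError(f"cohort needs n >= 3, got {self.n}")
        missing = [v for v in COPULA_VARS if v not in self.marginals]
        if missing:
            raise InvalidSpecError(f"missing marginals for {missing}")
        R = self.rank_corr.loc[COPULA_VARS, COPULA_VARS].to_numpy(float)
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise InvalidSpecError("rank_corr must be symmetric with unit diagonal")
        if np.any(np.abs(R) > 1):
            raise InvalidSpecError("rank correlations must lie in [-1, 1]")

    def latent_correlation(self) -> np.ndarray:
        """Pearson correlation of the latent Gaussian; raises if not PSD."""
        R = self.rank_corr.loc[COPULA_VARS, COPULA_VARS].to_numpy(float)
        C = spearman_to_pearson(R)
        np.fill_diagonal(C, 1.0)
        eigmin = np.linalg.eigvalsh(C).min()
        if eigmin < -1e-10:
            raise InvalidSpecError(
                f"converted copula correlation is not positive semidefinite "
                f"(min eigenvalue {eigmin:.3g})"
            )
        return C


# Table-1-style cohort: organ T2* and ferritin are right-skewed, so the
# default marginals are log-normals matched to the published mean/SD pairs;
# the default rank correlations are the published organ/ferritin Spearman r.
_DEFAULT_MOMENTS = {
    "t2s_heart_ms": (32.04, 14.94),
    "t2s_liver_ms": (3.84, 3.49),
    "t2s_pancreas_ms": (18.28, 13.98),
    "ferritin_ng_dl": (4640.75, 4821.93),
}

_DEFAULT_RANK_CORR = pd.DataFrame(
    [
        # heart   liver  pancreas ferritin
        [1.000, 0.223, 0.504, -0.344],
        [0.223, 1.000, 0.270, -0.734],
        [0.504, 0.270, 1.000, -0.401],
        [-0.344, -0.734, -0.401, 1.000],
    ],
    index=COPULA_VARS, columns=COPULA_VARS,
)


def default_cohort_spec(n: int = 39, seed: int = 0, *,
                        rank_corr: pd.DataFrame | None = None) -> SimCohortSpec:
    """Cohort spec mirroring the study population (n = 39 by default)."""
    marginals = {k: lognormal_from_moments(*mv) for k, mv in _DEFAULT_MOMENTS.items()}
    return SimCohortSpec(
        n=n,
        marginals=marginals,
        rank_corr=_DEFAULT_RANK_CORR if rank_corr is None else rank_corr,
        seed=seed,
    )


def simulate_cohort(spec: SimCohortSpec) -> pd.DataFrame:
    """Draw a patient cohort through a Gaussian copula.

    Latent multivariate-normal draws with correlation
    ``2 sin(pi * rho_spearman / 6)`` are pushed through the normal CDF and
    each marginal's quantile function, so the sample rank correlations
    target ``spec.rank_corr`` while each variable keeps its prescribed
    marginal distribution.

    Returns
    -------
    pandas.DataFrame
        Columns ``patient_id, age, sex, ferritin_ng_dl, t2s_heart_ms,
        t2s_liver_ms, t2s_pancreas_ms``.
    """
    C = spec.latent_correlation()
    rng = np.random.default_rng(spec.seed)
    # eigendecomposition square root: tolerant of exactly-singular targets
    # (e.g. a perfect rank correlation of 1)
    w, V = np.linalg.eigh(C)
    z = rng.standard_normal((spec.n, len(COPULA_VARS)))
    latent = z @ (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    u = stats.norm.cdf(latent)

    out = {"patient_id": [f"P{i + 1:03d}" for i in range(spec.n)]}
    out["age"] = rng.integers(spec.age_range[0], spec.age_range[1] + 1, spec.n)
    out["sex"] = rng.choice(["M", "F"], spec.n)
    for j, var in enumerate(COPULA_VARS):
        out[var] = spec.marginals[var].ppf(u[:, j])
    return pd.DataFrame(out)[COHORT_COLUMNS]
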