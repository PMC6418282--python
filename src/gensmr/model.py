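"""Model core: parameter containers, detection functions, and log-likelihoods.

The generalized spatial mark-resight (genSMR) model observes one latent
activity-center process three ways:

- a *marking* process — binomial live-trap captures with a hazard
  half-normal detection function,
- a *resighting* process — Poisson camera-trap counts with a half-normal
  encounter rate, identity known only for marked individuals,
- a *telemetry* process — GPS locations of marked individuals, bivariate
  normal around the activity center with per-axis scale ``sigma_d``.

A one-time activity-center relocation between the marking and resighting
periods ("transiency") is modeled as a bivariate normal kernel with scale
``sigma_t``, truncated to the rectangular state space.  Sex enters as a
Bernoulli(``p_sex``) partial-identity covariate, and data augmentation adds
an inclusion probability ``psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, ndtr

from .geometry import StateSpace

__all__ = [
    "Parameters",
    "ModelSpec",
    "LatentState",
    "halfnormal_rate",
    "hazard_to_prob",
    "marking_loglik",
    "resighting_loglik",
    "telemetry_loglik",
    "transience_logdensity",
    "sex_logprior",
    "inclusion_logprior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_sex_pair(value) -> np.ndarray:
    """Normalize a scalar-or-pair parameter to a (2,) array [male, female]."""
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 1:
        return np.repeat(arr, 2)
    if arr.size == 2:
        return arr
    raise ValueError("sex-structured parameters must be a scalar or a pair")


@dataclass
class Parameters:
    """Model parameters.

    ``lam0_r`` and ``sigma_d`` may each be a scalar (pooled across sexes) or a
    ``(male, female)`` pair for the sex-specific detection variant.  Units:
    ``lam0_m`` is a per trap-day capture hazard, ``lam0_r`` a per-occasion
    expected count at distance zero, ``sigma_d``/``sigma_t`` are km.
    """

    lam0_m: float = 0.0
    lam0_r: float | tuple[float, float] = 0.0
    sigma_d: float | tuple[float, float] = 1.0
    sigma_t: float = 0.0
    psi: float = 0.5
    p_sex: float = 0.5

    def __post_init__(self) -> None:
        self.lam0_m = float(self.lam0_m)
        self._lam0_r = _as_sex_pair(self.lam0_r)
        self._sigma_d = _as_sex_pair(self.sigma_d)
        self.sigma_t = float(self.sigma_t)
        if self.lam0_m < 0 or np.any(self._lam0_r < 0):
            raise ValueError("baseline detection rates must be >= 0")
        if np.any(self._sigma_d <= 0):
            raise ValueError("sigma_d must be > 0")
        if self.sigma_t < 0:
            raise ValueError("sigma_t must be >= 0")
        if not (0.0 < self.psi < 1.0):
            raise ValueError("psi must be in (0, 1)")
        if not (0.0 <= self.p_sex <= 1.0):
            raise ValueError("p_sex must be in [0, 1]")

    @property
    def lam0_r_pair(self) -> np.ndarray:
        return self._lam0_r

    @property
    def sigma_d_pair(self) -> np.ndarray:
        return self._sigma_d

    @property
    def sex_specific(self) -> bool:
        return (self._lam0_r[0] != self._lam0_r[1]) or (
            self._sigma_d[0] != self._sigma_d[1]
        )


@dataclass
class ModelSpec:
    """Flags selecting a model variant.

    ``generalized`` toggles genSMR (marking process modeled) versus conSMR
    (marking ignored, camera-only state space).  The remaining flags switch
    telemetry integration, one-time activity-center transiency, the sex
    partial-identity constraint on latent allocation, and sex-specific
    detection parameters.  ``A`` is the data-augmentation size.
    """

    generalized: bool = True
    use_telemetry: bool = True
    use_transience: bool = False
    use_sex_constraint: bool = True
    sex_specific_detection: bool = False
    A: int = 350

    def __post_init__(self) -> None:
        if self.A < 1:
            raise ValueError("augmentation size A must be >= 1")


@dataclass
class LatentState:
    """Augmented latent state: inclusion, centers, sexes, and the allocation
    of identity-free unmarked detection records to individuals."""

    z: np.ndarray  # (A,) 0/1 inclusion
    s_M: np.ndarray  # (A, 2)
    s_R: np.ndarray  # (A, 2)
    sex: np.ndarray  # (A,) 0 = male, 1 = female
    alloc: np.ndarray  # (n_records,) individual index per unmarked record


def halfnormal_rate(d, lam0, sigma_d):
    """Half-normal encounter rate ``lam0 * exp(-d^2 / (2 sigma_d^2))``.

    Monotone nonincreasing in distance ``d`` (km, >= 0).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    lam0 = np.asarray(lam0, dtype=float)
    sigma_d = np.asarray(sigma_d, dtype=float)
    if np.any(lam0 < 0):
        raise ValueError("lam0 must be >= 0")
    if np.any(sigma_d <= 0):
        raise ValueError("sigma_d must be > 0")
    return lam0 * np.exp(-(d**2) / (2.0 * sigma_d**2))


def hazard_to_prob(rate):
    """Complementary log-log link: per-occasion probability ``1 - exp(-rate)``."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    return -np.expm1(-rate)


def _pairwise_sq_dist(s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of s (n,2) and x (J,2)."""
    diff = s[:, None, :] - x[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _binom_logpmf(y, n, p, hazard):
    """Binomial log-pmf where p = 1 - exp(-hazard); log(1-p) = -hazard.

    Written in hazard form so that p -> 0 and p -> 1 stay finite where the
    data allow.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(p), 0.0)
    out = (
        gammaln(n + 1.0)
        - gammaln(y + 1.0)
        - gammaln(n - y + 1.0)
        + term
        - (n - y) * hazard
    )
    return np.where((y > 0) & (p <= 0.0), -np.inf, out)


def marking_loglik(
    y_m: np.ndarray,
    s_m: np.ndarray,
    params: Parameters,
    E_m: np.ndarray,
    live_coords: np.ndarray,
    z: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> float:
    """Binomial marking log-likelihood summed over included individuals.

    ``y_m[i, j] ~ Binomial(E_m[i, j], 1 - exp(-lam0_m * hn(d_ij)))`` with
    distances taken from the marking-period activity centers ``s_m``.
    Individuals with ``z = 0`` contribute nothing (their all-zero histories
    are accounted for in the inclusion update, not here).
    """
    y_m = np.atleast_2d(np.asarray(y_m, dtype=float))
    E_m = np.atleast_2d(np.asarray(E_m, dtype=float))
    if np.any(y_m > E_m):
        raise ValueError("marking counts exceed exposure")
    if np.any(y_m < 0):
        raise ValueError("marking counts must be nonnegative")
    s_m = np.atleast_2d(s_m)
    d2 = _pairwise_sq_dist(s_m, np.atleast_2d(live_coords))
    sig = params.sigma_d_pair
    if sex is not None and params.sex_specific:
        sig_i = sig[np.asarray(sex, dtype=int)][:, None]
    else:
        sig_i = sig[0]
    hazard = params.lam0_m * np.exp(-d2 / (2.0 * sig_i**2))
    p = -np.expm1(-hazard)
    ll = _binom_logpmf(y_m, E_m, p, hazard)
    if z is not None:
        ll = ll[np.asarray(z, dtype=bool)]
    return float(ll.sum())


def resighting_loglik(
    counts: np.ndarray,
    s_r: np.ndarray,
    sex: np.ndarray | None,
    params: Parameters,
    E_r: np.ndarray,
    camera_coords: np.ndarray,
    z: np.ndarray | None = None,
) -> float:
    """Poisson resighting log-likelihood of occasion-summed counts.

    ``counts[i, j] ~ Poisson(E_r[i, j] * lam0_r * hn(d_ij))`` with distances
    from the resighting-period centers ``s_r``; ``lam0_r`` and ``sigma_d``
    may be sex-specific.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("resighting counts must be nonnegative")
    E_r = np.atleast_2d(np.asarray(E_r, dtype=float))
    d2 = _pairwise_sq_dist(np.atleast_2d(s_r), np.atleast_2d(camera_coords))
    lam0 = params.lam0_r_pair
    sig = params.sigma_d_pair
    if sex is not None:
        sex = np.asarray(sex, dtype=int)
        lam0_i = lam0[sex][:, None]
        sig_i = sig[sex][:, None]
    else:
        lam0_i, sig_i = lam0[0], sig[0]
    mu = E_r * lam0_i * np.exp(-d2 / (2.0 * sig_i**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(mu), 0.0)
    ll = np.where((counts > 0) & (mu <= 0.0), -np.inf, term - mu - gammaln(counts + 1.0))
    if z is not None:
        ll = ll[np.asarray(z, dtype=bool)]
    return float(ll.sum())


def telemetry_loglik(
    telemetry: Sequence[np.ndarray],
    s: np.ndarray,
    sigma_d: float | np.ndarray,
) -> float:
    """Independent bivariate-normal telemetry log-density.

    ``telemetry[i]`` is an ``(L_i, 2)`` array of locations for individual
    ``i`` (already thinned to at most one per occasion upstream), centered on
    that individual's activity center with per-axis sd ``sigma_d`` (scalar or
    per-individual).  Locations are not truncated to the state space.
    """
    s = np.atleast_2d(s)
    if len(telemetry) > s.shape[0]:
        raise ValueError("telemetry provided for an individual without an activity center")
    sigma = np.broadcast_to(np.asarray(sigma_d, dtype=float), (s.shape[0],))
    total = 0.0
    for i, locs in enumerate(telemetry):
        locs = np.atleast_2d(np.asarray(locs, dtype=float))
        if locs.size == 0:
            continue
        resid = locs - s[i]
        ss = float(np.einsum("ij,ij->", resid, resid))
        n = locs.shape[0]
        total += -n * (_LOG_2PI + 2.0 * np.log(sigma[i])) - ss / (2.0 * sigma[i] ** 2)
    return float(total)


def _rect_truncation_mass(mu: np.ndarray, sigma: float, ss: StateSpace) -> np.ndarray:
    """Mass of a diagonal bivariate normal centered at ``mu`` inside the
    state-space rectangle: the product of two 1-D normal-CDF differences."""
    mu = np.atleast_2d(mu)
    px = ndtr((ss.xmax - mu[:, 0]) / sigma) - ndtr((ss.xmin - mu[:, 0]) / sigma)
    py = ndtr((ss.ymax - mu[:, 1]) / sigma) - ndtr((ss.ymin - mu[:, 1]) / sigma)
    return px * py


def transience_logdensity(
    s_r: np.ndarray,
    s_m: np.ndarray,
    sigma_t: float,
    state_space: StateSpace,
    total: bool = True,
):
    """Log-density of the truncated activity-center relocation kernel.

    ``s_r ~ BVN(s_m, sigma_t^2 I)`` truncated to the state-space rectangle;
    the normalizing constant is exact (product of two 1-D CDF differences,
    valid because the covariance is diagonal and the region rectangular).
    Points outside the rectangle have density -inf.
    """
    if sigma_t <= 0:
        raise ValueError("sigma_t must be > 0 for the transience density")
    s_r = np.atleast_2d(np.asarray(s_r, dtype=float))
    s_m = np.atleast_2d(np.asarray(s_m, dtype=float))
    resid = s_r - s_m
    log_kernel = -(_LOG_2PI + 2.0 * np.log(sigma_t)) - np.einsum(
        "ij,ij->i", resid, resid
    ) / (2.0 * sigma_t**2)
    mass = _rect_truncation_mass(s_m, sigma_t, state_space)
    ld = np.where(state_space.contains(s_r), log_kernel - np.log(mass), -np.inf)
    return float(ld.sum()) if total else ld


def sex_logprior(sex: np.ndarray, p_sex: float) -> float:
    """Sum of independent Bernoulli(``p_sex``) log-pmfs (1 = female)."""
    sex = np.asarray(sex)
    n_f = int(np.sum(sex == 1))
    n_m = int(sex.size - n_f)
    if p_sex == 0.0:
        return 0.0 if n_f == 0 else -np.inf
    if p_sex == 1.0:
        return 0.0 if n_m == 0 else -np.inf
    return n_f * float(np.log(p_sex)) + n_m * float(np.log1p(-p_sex))


def inclusion_logprior(z: np.ndarray, psi: float) -> float:
    """Sum of independent Bernoulli(``psi``) log-pmfs over augmented rows."""
    z = np.asarray(z).astype(bool)
    n1 = int(z.sum())
    return n1 * float(np.log(psi)) + (z.size - n1) * float(np.log1p(-psi))
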