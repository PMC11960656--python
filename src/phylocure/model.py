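"""Joint log-density of the phylogenetic survival-cure model.

The model treats each species as a "cured" non-tool-user with probability
p_i, or a susceptible tool user (probability 1 - p_i) whose first detection
in an observation channel arrives after an Exponential(lambda) amount of
research effort. A species observed after effort N contributes the detection
density (1 - p_i) * lambda * exp(-lambda N); an unobserved species after
effort N contributes the censored mixture p_i + (1 - p_i) * exp(-lambda N).
Two channels (literature and video) share p_i but have channel-specific
rates lambda = exp(-gamma).

The cure probability is a logistic regression with two feeding-strategy
intercepts, a slope on encephalization quotient, and a species-level effect
k with a multivariate-normal prior whose covariance is an Ornstein-Uhlenbeck
Gaussian-process kernel on patristic distances:

    logit(p_i) = alpha_F[i] + beta * EQ_i + k_i,   k ~ MVN(0, K),
    K_ij = eta_sq * exp(-rho_sq * D_ij).

Priors: Normal(0, 1) on gamma_lit, gamma_vid, alpha_1, alpha_2, beta;
Exponential(rate 0.5) on eta_sq and rho_sq.

Note p_i is the probability of NOT using tools; user-facing reports are on
the tool-use scale 1 - p_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import expit

from .data import Dataset
from .phylo import DistanceMatrix

__all__ = [
    "ModelParameters",
    "ModelData",
    "KernelMatrix",
    "rate_from_gamma",
    "channel_loglik",
    "cure_logit",
    "phylo_kernel",
    "joint_logdensity",
]

PRIOR_EXP_RATE = 0.5  # Exponential prior rate on eta_sq and rho_sq
DEFAULT_JITTER_FRAC = 1e-9  # relative diagonal jitter, escalates x10 to 1e-6


@dataclass
class ModelParameters:
    """One point in the model's parameter space."""

    gamma_lit: float
    gamma_vid: float
    alpha: np.ndarray  # length 2: (generalist, specialist) intercepts
    beta: float
    k: np.ndarray  # per-species phylogenetic effects
    eta_sq: float
    rho_sq: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.alpha.shape != (2,):
            raise ValueError("alpha must have exactly two feeding levels")
        if not (self.eta_sq > 0 and self.rho_sq > 0):
            raise ValueError("eta_sq and rho_sq must be positive")


@dataclass
class ModelData:
    """Dataset columns as aligned arrays, in the canonical species order."""

    species_ids: list[str]
    feeding_index: np.ndarray  # 0 = generalist, 1 = specialist
    eq: np.ndarray
    lit_detected: np.ndarray  # bool
    lit_effort: np.ndarray
    vid_detected: np.ndarray
    vid_effort: np.ndarray

    @classmethod
    def from_dataset(
        cls, dataset: Dataset, standardize_eq: bool = False
    ) -> "ModelData":
        recs = dataset.subset_in_tree().records
        eq = np.array([r.eq for r in recs])
        if standardize_eq:
            eq = (eq - eq.mean()) / eq.std(ddof=0)
        return cls(
            species_ids=[r.species_id for r in recs],
            feeding_index=np.array([r.feeding_index for r in recs]),
            eq=eq,
            lit_detected=np.array([r.literature.detected for r in recs]),
            lit_effort=np.array([r.literature.effort for r in recs]),
            vid_detected=np.array([r.video.detected for r in recs]),
            vid_effort=np.array([r.video.effort for r in recs]),
        )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def any_evidence(self) -> np.ndarray:
        return self.lit_detected | self.vid_detected


@dataclass(frozen=True)
class KernelMatrix:
    K: np.ndarray
    jitter: float
    cho: tuple  # scipy cho_factor output

    @property
    def L(self) -> np.ndarray:
        """Lower-triangular Cholesky factor of K (including jitter)."""
        c, lower = self.cho
        return np.tril(c) if lower else np.triu(c).T


def rate_from_gamma(gamma: float):
    """Detection rate lambda = 1 / exp(gamma); exp(gamma) is the expected
    research effort until discovery for a susceptible species."""
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise ValueError("gamma must be finite")
    out = np.exp(-gamma)
    return float(out) if out.ndim == 0 else out


def channel_loglik(detected, effort, p, lam) -> float | np.ndarray:
    """Log-density of one channel's detection record under the cure mixture.

    detected : contributes log(1-p) + log(lam) - lam*effort
    censored : contributes log(p + (1-p) * exp(-lam*effort))

    Vectorized over species; scalar inputs give a scalar. Returns -inf only
    when the mixture mass is exactly zero (p == 1 with a detection).
    """
    detected = np.asarray(detected, dtype=bool)
    effort = np.asarray(effort, dtype=float)
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rate lam must be positive")
    for arr in (effort, p, lam):
        if np.any(np.isnan(arr)):
            raise ValueError("NaN input to channel_loglik")
    if np.any(effort < 0):
        raise ValueError("effort must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    scalar = detected.ndim == 0 and effort.ndim == 0 and p.ndim == 0
    detected, effort, p, lam = np.broadcast_arrays(detected, effort, p, lam)
    out = np.empty(detected.shape, dtype=float)
    d = detected
    with np.errstate(divide="ignore"):
        out[d] = np.log1p(-p[d]) + np.log(lam[d]) - lam[d] * effort[d]
        # censored mixture via log-sum-exp: log(p + (1-p) e^{-lam N})
        c = ~d
        out[c] = np.logaddexp(
            np.log(p[c]), np.log1p(-p[c]) - lam[c] * effort[c]
        )
    return float(out) if scalar else out


def cure_logit(
    feeding_index, eq, k, params: ModelParameters
) -> float | np.ndarray:
    """Cure (non-tool-use) probability from the logistic submodel."""
    lin = params.alpha[np.asarray(feeding_index)] + params.beta * np.asarray(
        eq
    ) + np.asarray(k)
    out = expit(lin)
    return float(out) if np.ndim(out) == 0 else out


def phylo_kernel(
    D: DistanceMatrix | np.ndarray,
    eta_sq: float,
    rho_sq: float,
    jitter_frac: float = DEFAULT_JITTER_FRAC,
) -> KernelMatrix:
    """OU Gaussian-process kernel K_ij = eta_sq * exp(-rho_sq * D_ij).

    A relative diagonal jitter (default 1e-9 * eta_sq) is added for Cholesky
    robustness, escalating tenfold up to 1e-6 * eta_sq before raising with
    the offending minimum eigenvalue.
    """
    if not (eta_sq > 0 and rho_sq > 0):
        raise ValueError("eta_sq and rho_sq must be positive")
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    K = eta_sq * np.exp(-rho_sq * Dm)
    frac = jitter_frac
    while True:
        jitter = frac * eta_sq
        try:
            cho = cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
            return KernelMatrix(K=K, jitter=jitter, cho=cho)
        except np.linalg.LinAlgError:
            frac *= 10.0
            if frac > 1.001e-6:
                min_eig = float(np.linalg.eigvalsh(K).min())
                raise np.linalg.LinAlgError(
                    f"kernel not positive definite (min eigenvalue {min_eig:g})"
                )


def _mvn_logpdf_zero_mean(x: np.ndarray, km: KernelMatrix) -> float:
    n = x.shape[0]
    alpha = cho_solve(km.cho, x)
    logdet = 2.0 * np.sum(np.log(np.diag(km.cho[0])))
    return -0.5 * (x @ alpha + logdet + n * np.log(2.0 * np.pi))


def _std_normal_logpdf(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * x**2 - 0.5 * np.log(2.0 * np.pi)))


def _exp_prior_logpdf(x: float, rate: float = PRIOR_EXP_RATE) -> float:
    if x <= 0:
        return -np.inf
    return np.log(rate) - rate * x


def joint_logdensity(
    params: ModelParameters,
    data: ModelData,
    D: DistanceMatrix,
    jitter_frac: float = DEFAULT_JITTER_FRAC,
) -> float:
    """Unnormalized log-posterior: two-channel likelihood + priors."""
    if list(D.labels) != list(data.species_ids):
        raise ValueError("distance matrix and data are not aligned")
    if params.k.shape[0] != data.n_species:
        raise ValueError("k length does not match dataset size")
    p = cure_logit(data.feeding_index, data.eq, params.k, params)
    ll = float(
        np.sum(
            channel_loglik(
                data.lit_detected,
                data.lit_effort,
                p,
                rate_from_gamma(params.gamma_lit),
            )
        )
        + np.sum(
            channel_loglik(
                data.vid_detected,
                data.vid_effort,
                p,
                rate_from_gamma(params.gamma_vid),
            )
        )
    )
    km = phylo_kernel(D, params.eta_sq, params.rho_sq, jitter_frac)
    lp = _mvn_logpdf_zero_mean(params.k, km)
    lp += _std_normal_logpdf(
        [params.gamma_lit, params.gamma_vid, *params.alpha, params.beta]
    )
    lp += _exp_prior_logpdf(params.eta_sq)
    lp += _exp_prior_logpdf(params.rho_sq)
    return ll + lp
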