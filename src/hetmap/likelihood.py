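"""Mixture likelihood over the six QTL genotypes, with EM building blocks.

Each sampled individual contributes a 2T-dimensional phenotype vector
Y_i = (x1(1..T), x2(1..T)).  Conditional on its (unobserved) QTL genotype
j, Y_i is multivariate normal with an ODE-determined mean trajectory and a
shared SAD(1) covariance; the mixture weights are the probabilities of
each QTL genotype conditional on the observed marker genotype m_i, derived
from the marker-QTL haplotype frequencies.  All density work is done in
log space with log-sum-exp, and the covariance is factorized once and
shared across individuals.

Two log-likelihoods appear:

* the *conditional* mixture log-likelihood
  sum_i log sum_j pi_{j|m_i} f_j(Y_i)  -- the model's objective for
  likelihood-ratio tests;
* the *joint* log-likelihood sum_i log sum_j P(j, m_i) f_j(Y_i), which
  additionally models the marker genotype.  The closed-form haplotype
  M-step (expected haplotype counting with phase split by the current
  phase weights) is the exact M-step of an EM on the joint model with
  (genotype, phase) latent, so the joint log-likelihood is guaranteed
  non-decreasing across EM sweeps; it is the ascent objective tracked by
  the estimation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from . import covariance as cov
from . import dynamics as dyn
from . import genetics as gen
from .errors import InvalidParameterError, NumericalDegeneracyError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Dataset:
    """n individuals with marker codes and stacked phenotype vectors.

    marker : int array (n,), codes 2=MM, 1=Mm, 0=mm.
    Y : float array (n, 2T), variable-major rows.
    grid : the observation design.
    truth_qtl : optional int array (n,) of true QTL genotype codes
        (simulated data only).
    """

    marker: np.ndarray
    Y: np.ndarray
    grid: dyn.TimeGrid
    truth_qtl: np.ndarray | None = None
    sample_ids: list | None = None

    def __post_init__(self):
        self.marker = np.asarray(self.marker, dtype=np.int64)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[0] != self.marker.shape[0]:
            raise InvalidParameterError("marker/Y dimension mismatch")
        if self.Y.shape[1] != 2 * self.grid.T:
            raise InvalidParameterError(
                f"Y has {self.Y.shape[1]} columns, expected {2 * self.grid.T}"
            )
        if not np.all(np.isfinite(self.Y)):
            raise InvalidParameterError("Y contains non-finite values")
        if not np.all(np.isin(self.marker, [0, 1, 2])):
            raise InvalidParameterError("marker codes must be in {0, 1, 2}")

    @property
    def n(self) -> int:
        return int(self.Y.shape[0])


@dataclass
class ModelSpec:
    """Full parameterization of the mixture model.

    theta : (6, p) array of ODE parameters, row j per QTL genotype
        (p = 3 linear, 5 nonlinear).
    """

    model: str
    theta: np.ndarray
    sad: cov.SADParams
    hf: gen.HaplotypeFreqs
    init: dyn.State = field(default_factory=lambda: dyn.State(1.0, 1.0))
    grid: dyn.TimeGrid = field(default_factory=dyn.TimeGrid)
    w_convention: str = "proportion"

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        p = len(dyn.PARAM_NAMES[self.model])
        if self.theta.shape != (6, p):
            raise InvalidParameterError(
                f"theta must have shape (6, {p}) for the {self.model} model"
            )

    def genotype_means(self) -> np.ndarray:
        """(6, 2T) matrix of genotype mean vectors, row j."""
        return np.stack(
            [
                dyn.mean_vector(
                    self.model,
                    dyn.params_from_array(self.model, self.theta[j]),
                    self.init,
                    self.grid,
                    self.w_convention,
                )
                for j in range(6)
            ]
        )


def log_density_matrix(
    Y: np.ndarray, means: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """(n, 6) matrix of log N(Y_i; mu_j, Sigma), one Cholesky shared."""
    n, d = Y.shape
    L = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    const = -0.5 * (d * _LOG_2PI + logdet)
    out = np.empty((n, means.shape[0]))
    for j in range(means.shape[0]):
        Z = solve_triangular(L, (Y - means[j]).T, lower=True)
        out[:, j] = const - 0.5 * np.einsum("ij,ij->j", Z, Z)
    return out


def _log_prior_rows(table: np.ndarray, marker: np.ndarray) -> np.ndarray:
    """Per-individual log prior rows from a (3, 6) probability table."""
    with np.errstate(divide="ignore"):
        logt = np.log(table)
    return logt[marker]


def mixture_loglik(data: Dataset, spec: ModelSpec) -> float:
    """Conditional mixture log-likelihood sum_i log sum_j pi_{j|m_i} f_j."""
    means = spec.genotype_means()
    sigma = cov.sad1_covariance(spec.sad, data.grid.T)
    logf = log_density_matrix(data.Y, means, sigma)
    logpi = _log_prior_rows(gen.conditional_qtl_probabilities(spec.hf), data.marker)
    return float(logsumexp(logpi + logf, axis=1).sum())


def joint_loglik(data: Dataset, spec: ModelSpec) -> float:
    """Joint (marker, phenotype) log-likelihood -- the EM ascent objective."""
    means = spec.genotype_means()
    sigma = cov.sad1_covariance(spec.sad, data.grid.T)
    logf = log_density_matrix(data.Y, means, sigma)
    logpj = _log_prior_rows(gen.joint_genotype_table(spec.hf), data.marker)
    return float(logsumexp(logpj + logf, axis=1).sum())


def posterior_from_logs(logpi: np.ndarray, logf: np.ndarray) -> np.ndarray:
    """Row-normalized posteriors from log priors + log densities."""
    logw = logpi + logf
    norm = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(norm)):
        i = int(np.where(~np.isfinite(norm))[0][0])
        raise NumericalDegeneracyError(
            f"all mixture components underflowed for individual {i}"
        )
    post = np.exp(logw - norm[:, None])
    post[logpi == -np.inf] = 0.0
    return post


def e_step(data: Dataset, spec: ModelSpec) -> np.ndarray:
    """Posterior QTL-genotype probabilities, (n, 6), rows summing to one.

    Entries with zero prior are exactly zero.
    """
    means = spec.genotype_means()
    sigma = cov.sad1_covariance(spec.sad, data.grid.T)
    logf = log_density_matrix(data.Y, means, sigma)
    logpi = _log_prior_rows(gen.conditional_qtl_probabilities(spec.hf), data.marker)
    return posterior_from_logs(logpi, logf)


def m_step_haplotypes(
    post: np.ndarray,
    marker: np.ndarray,
    hf_current: gen.HaplotypeFreqs,
    n: int | None = None,
) -> gen.HaplotypeFreqs:
    """Closed-form haplotype-frequency update by expected haplotype counting.

    S[j, m] collects posterior mass per (QTL genotype, marker genotype)
    cell; unambiguous cells contribute their haplotypes directly while the
    three Mm double-heterozygote cells are split between the two phases by
    the weights theta computed from ``hf_current`` (the E-step over phase).
    Each individual contributes exactly two haplotypes, so the output lies
    on the 6-simplex by construction.
    """
    post = np.asarray(post, dtype=float)
    marker = np.asarray(marker, dtype=np.int64)
    if n is None:
        n = post.shape[0]
    S = np.zeros((6, 3))
    for m in range(3):
        sel = marker == m
        if np.any(sel):
            S[:, m] = post[sel].sum(axis=0)
    return m_step_haplotypes_from_counts(S, hf_current, n)


def m_step_haplotypes_from_counts(
    S: np.ndarray, hf_current: gen.HaplotypeFreqs, n: int
) -> gen.HaplotypeFreqs:
    """Haplotype M-step from the (6, 3) posterior-mass table S[j, m]
    (sufficient statistic of :func:`m_step_haplotypes`)."""
    th = gen.phase_weights(hf_current)
    t1, t2, t3 = th.theta1, th.theta2, th.theta3
    f = np.empty(6)
    # MQ
    f[0] = 2 * S[5, 2] + S[4, 2] + S[3, 2] + S[5, 1] + t1 * S[4, 1] + t2 * S[3, 1]
    # Mq
    f[1] = (
        2 * S[2, 2] + S[4, 2] + S[1, 2] + S[2, 1]
        + (1 - t1) * S[4, 1] + t3 * S[1, 1]
    )
    # Mq+
    f[2] = (
        2 * S[0, 2] + S[3, 2] + S[1, 2] + S[0, 1]
        + (1 - t2) * S[3, 1] + (1 - t3) * S[1, 1]
    )
    # mQ
    f[3] = (
        2 * S[5, 0] + S[5, 1] + S[4, 0] + S[3, 0]
        + (1 - t1) * S[4, 1] + (1 - t2) * S[3, 1]
    )
    # mq
    f[4] = (
        2 * S[2, 0] + S[2, 1] + S[4, 0] + S[1, 0]
        + t1 * S[4, 1] + (1 - t3) * S[1, 1]
    )
    # mq+
    f[5] = (
        2 * S[0, 0] + S[0, 1] + S[3, 0] + S[1, 0]
        + t2 * S[3, 1] + t3 * S[1, 1]
    )
    f /= 2.0 * n
    f = np.clip(f, 0.0, 1.0)
    return gen.HaplotypeFreqs.from_array(f)


def q_function(data: Dataset, post: np.ndarray, spec: ModelSpec) -> float:
    """EM complete-data objective sum_ij Pi_ij [log pi_{j|m_i} + log f_j],
    with the convention 0 * (-inf) = 0 at zero-posterior entries."""
    means = spec.genotype_means()
    sigma = cov.sad1_covariance(spec.sad, data.grid.T)
    logf = log_density_matrix(data.Y, means, sigma)
    logpi = _log_prior_rows(gen.conditional_qtl_probabilities(spec.hf), data.marker)
    terms = logpi + logf
    post = np.asarray(post, dtype=float)
    masked = np.where(post > 0, terms, 0.0)
    return float((post * masked).sum())
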