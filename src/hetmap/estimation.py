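"""Hybrid maximum-likelihood estimator.

The fitting strategy interleaves three ingredients, one EM sweep each:

1. an E-step computing posterior QTL-genotype probabilities (log space);
2. the closed-form haplotype-frequency M-step (expected haplotype
   counting, phase split recomputed from the current frequencies each
   sweep -- an ECM-style update that is a fixed point at the truth);
3. blockwise Nelder-Mead ascent of the complete-data objective: each
   genotype's ODE parameters are refit to its posterior-weighted mean
   trajectory in the Mahalanobis metric of the current covariance
   (Runge-Kutta evaluated means), then the seven SAD(1) covariance
   parameters are refit against the pooled posterior-weighted scatter.

Each Nelder-Mead block is warm-started at the current value, so a sweep
can never decrease the complete-data objective; the whole procedure is a
generalized EM and the joint (marker, phenotype) log-likelihood ascends
monotonically (up to optimizer tolerance).  Multi-start with deterministic
per-genotype offsets plus seeded jitter guards against mixture label
swaps; start 0 places all genotypes exactly at the null fit so the full
model provably starts at (and ascends from) the null log-likelihood.

Rates and innovation SDs are optimized on the log scale and the innovation
correlation through atanh, so all invariants hold by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import covariance as cov
from . import dynamics as dyn
from . import genetics as gen
from . import likelihood as lik
from .errors import (
    DegenerateMarkerError,
    HetmapError,
    InvalidParameterError,
    NonConvergenceError,
    UndefinedPhaseError,
)

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12
_RATE_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# fast scalar evaluation of RK4 mean trajectories (2x2 matrices as tuples)

def _mat_mul(A, B):
    a, b, c, d = A
    e, f, g, h = B
    return (a * e + b * g, a * f + b * h, c * e + d * g, c * f + d * h)


def _mat_pow(M, n):
    R = (1.0, 0.0, 0.0, 1.0)
    while n:
        if n & 1:
            R = _mat_mul(R, M)
        M = _mat_mul(M, M)
        n >>= 1
    return R


def _linear_mean_fast(r, k1, k2, init, grid: dyn.TimeGrid) -> np.ndarray:
    """Variable-major linear-model RK4 trajectory, scalar arithmetic."""
    h = grid.h
    hA = (h * (r - k1), h * k2, h * k1, h * (r - k2))
    M = (1.0 + hA[0], hA[1], hA[2], 1.0 + hA[3])
    P = hA
    for k in (2.0, 3.0, 4.0):
        P = _mat_mul(P, hA)
        P = (P[0] / k, P[1] / k, P[2] / k, P[3] / k)
        M = (M[0] + P[0], M[1] + P[1], M[2] + P[2], M[3] + P[3])
    y1, y2 = init.x1, init.x2
    T = grid.T
    out = np.empty(2 * T)
    cache: dict = {}
    for k, g in enumerate(grid.steps_per_gap()):
        Mg = cache.get(g)
        if Mg is None:
            Mg = _mat_pow(M, g)
            cache[g] = Mg
        y1, y2 = Mg[0] * y1 + Mg[1] * y2, Mg[2] * y1 + Mg[3] * y2
        out[k] = y1
        out[T + k] = y2
    return out


def _mean_for(model, row, init, grid, w_convention) -> np.ndarray:
    if model == dyn.LINEAR:
        return _linear_mean_fast(row[0], row[1], row[2], init, grid)
    return dyn.mean_vector(
        model, dyn.params_from_array(model, row), init, grid, w_convention
    )


# ---------------------------------------------------------------------------
# parameter packing (unconstrained optimizer space)

def _pack_theta(row) -> np.ndarray:
    u = np.array(row, dtype=float)
    u[1:] = np.log(np.maximum(u[1:], _RATE_FLOOR))
    return u


def _unpack_theta(u) -> np.ndarray:
    row = np.array(u, dtype=float)
    row[1:] = np.exp(np.clip(row[1:], -60.0, 30.0))
    return row


def _pack_psi(psi: cov.SADParams) -> np.ndarray:
    return np.array(
        [
            psi.a1,
            psi.a2,
            psi.c1,
            psi.c2,
            math.log(psi.nu1),
            math.log(psi.nu2),
            math.atanh(np.clip(psi.rho, -0.999999, 0.999999)),
        ]
    )


def _unpack_psi(v) -> cov.SADParams:
    v = np.asarray(v, dtype=float)
    return cov.SADParams(
        a1=float(v[0]),
        a2=float(v[1]),
        c1=float(v[2]),
        c2=float(v[3]),
        nu1=float(np.exp(np.clip(v[4], -30.0, 10.0))),
        nu2=float(np.exp(np.clip(v[5], -30.0, 10.0))),
        rho=float(np.tanh(v[6])),
    )


def _nm(fun, x0, maxiter):
    return minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "maxfev": 2 * maxiter,
            "xatol": 1e-6,
            "fatol": 1e-8,
        },
    )


# ---------------------------------------------------------------------------
# configuration / results

@dataclass
class FitConfig:
    """Optimizer settings shared by all fitters."""

    max_em_iter: int = 500
    em_tol: float = 1e-6          # relative joint-loglik change
    n_starts: int = 5
    inner_maxiter: int = 80       # Nelder-Mead budget per block per sweep
    null_maxiter: int = 400       # budget for the initial null curve fit
    null_rounds: int = 60         # block-alternation rounds in fit_null
    seed: int = 0
    jitter: float = 0.03          # SD of the multiplicative start jitter
    relabel: bool = True          # enable in-EM label-swap checks
    relabel_every: int = 10       # EM-sweep period of label-swap checks
    canonical_gauge: bool = True  # report fits in the canonical allele gauge
    swap_polish: bool = True      # post-fit pairwise label-swap restarts
    swap_polish_k: int = 3        # candidate transpositions tried per round
    swap_polish_iters: int = 30   # EM budget of each polish restart

    def __post_init__(self):
        if self.max_em_iter < 1 or self.n_starts < 1:
            raise InvalidParameterError("counts must be positive")
        if self.em_tol <= 0:
            raise InvalidParameterError("em_tol must be positive")


@dataclass
class ConstraintSpec:
    """Equality pattern over genotype ODE parameters.

    ``groups[param]`` is a partition of the genotype indices {0..5}; all
    genotypes in a group share that parameter's value.  The free (full)
    model has every genotype in its own group for every parameter.
    """

    model: str
    groups: dict

    @classmethod
    def free(cls, model: str) -> "ConstraintSpec":
        names = dyn.PARAM_NAMES[model]
        return cls(model, {p: tuple((j,) for j in range(6)) for p in names})

    @classmethod
    def all_shared(cls, model: str) -> "ConstraintSpec":
        names = dyn.PARAM_NAMES[model]
        return cls(model, {p: (tuple(range(6)),) for p in names})

    @classmethod
    def share(cls, model: str, shared_params) -> "ConstraintSpec":
        """Share the named parameters across all genotypes, leave the rest
        free per genotype."""
        names = dyn.PARAM_NAMES[model]
        groups = {}
        for p in names:
            if p in shared_params:
                groups[p] = (tuple(range(6)),)
            else:
                groups[p] = tuple((j,) for j in range(6))
        return cls(model, groups)

    def __post_init__(self):
        names = dyn.PARAM_NAMES[self.model]
        if set(self.groups) != set(names):
            raise InvalidParameterError(
                "constraint must cover every ODE parameter exactly once"
            )
        for p, gs in self.groups.items():
            seen = sorted(j for g in gs for j in g)
            if seen != list(range(6)):
                raise InvalidParameterError(
                    f"groups for {p!r} are not a partition of genotypes 0..5"
                )


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``loglik`` is the conditional mixture log-likelihood (plain normal
    log-likelihood for the null fit); ``joint_loglik`` additionally models
    the marker and is the EM ascent objective whose per-sweep values are
    in ``trace``.
    """

    kind: str
    model: str
    theta: np.ndarray
    psi: cov.SADParams
    hf: gen.HaplotypeFreqs | None
    genetics: gen.GeneticParams | None
    loglik: float
    joint_loglik: float | None
    trace: list
    n_iter: int
    converged: bool
    seed: int
    start_logliks: list
    init: dyn.State = field(default_factory=lambda: dyn.State(1.0, 1.0))
    grid: dyn.TimeGrid = field(default_factory=dyn.TimeGrid)
    w_convention: str = "proportion"

    def spec(self) -> lik.ModelSpec:
        if self.hf is None:
            raise HetmapError("null fits carry no mixture specification")
        return lik.ModelSpec(
            model=self.model,
            theta=self.theta,
            sad=self.psi,
            hf=self.hf,
            init=self.init,
            grid=self.grid,
            w_convention=self.w_convention,
        )


# ---------------------------------------------------------------------------
# null (single-curve) fit

def _psi_init_from_residuals(R: np.ndarray, T: int) -> cov.SADParams:
    """Moment-based SAD(1) start: pooled lag-1 regression of residuals."""
    n = R.shape[0]
    E = np.stack([R[:, :T], R[:, T:]], axis=2)  # (n, T, 2)
    if T >= 2:
        X = E[:, :-1, :].reshape(-1, 2)
        Z = E[:, 1:, :].reshape(-1, 2)
        try:
            phiT, *_ = np.linalg.lstsq(X, Z, rcond=None)
            eps = np.vstack([E[:, 0, :], Z - X @ phiT])
            phi = phiT.T
        except np.linalg.LinAlgError:
            phi = np.zeros((2, 2))
            eps = E.reshape(-1, 2)
    else:
        phi = np.zeros((2, 2))
        eps = E.reshape(-1, 2)
    nu = np.maximum(eps.std(axis=0), 1e-8)
    c = np.corrcoef(eps[:, 0], eps[:, 1])[0, 1]
    if not np.isfinite(c):
        c = 0.0
    return cov.SADParams(
        a1=float(phi[0, 0]),
        a2=float(phi[1, 1]),
        c1=float(phi[0, 1]),
        c2=float(phi[1, 0]),
        nu1=float(nu[0]),
        nu2=float(nu[1]),
        rho=float(np.clip(c, -0.95, 0.95)),
    )


def _theta_starts(model: str, data: lik.Dataset, init: dyn.State) -> list:
    T = data.grid.T
    tot0 = init.x1 + init.x2
    totT = float(np.mean(data.Y[:, T - 1] + data.Y[:, -1]))
    tT = data.grid.times[-1]
    r0 = math.log(max(totT / max(tot0, 1e-12), 1e-6)) / tT
    base = [(r0, 0.01, 0.01), (r0, 0.03, 0.003), (r0, 0.005, 0.02)]
    if model == dyn.LINEAR:
        return [np.array(b) for b in base]
    out = []
    for b in base:
        for k34 in ((0.5, 0.6), (0.6, 0.5)):
            out.append(np.array(b + k34))
    return out


def fit_null(
    data: lik.Dataset,
    model: str,
    cfg: FitConfig | None = None,
    init: dyn.State | None = None,
    w_convention: str = "proportion",
) -> FitResult:
    """Single-curve fit: one ODE parameter set and one SAD(1) set
    maximizing the plain multivariate-normal likelihood (no mixture, no
    genetic parameters)."""
    cfg = cfg or FitConfig()
    init = init or dyn.State(1.0, 1.0)
    if data.n < 30:
        warnings.warn("fewer than 30 individuals; estimates may be unstable")
    grid, n, d = data.grid, data.n, data.Y.shape[1]
    ybar = data.Y.mean(axis=0)
    R0 = data.Y - ybar
    S0 = R0.T @ R0

    def sse(u):
        try:
            mu = _mean_for(model, _unpack_theta(u), init, grid, w_convention)
        except HetmapError:
            return _PENALTY
        r = ybar - mu
        return float(r @ r)

    best = None
    for th0 in _theta_starts(model, data, init):
        res = _nm(sse, _pack_theta(th0), cfg.null_maxiter)
        if best is None or res.fun < best.fun:
            best = res
    theta = _unpack_theta(best.x)
    mu = _mean_for(model, theta, init, grid, w_convention)
    psi = _psi_init_from_residuals(data.Y - mu, grid.T)

    def loglik_parts(theta_row, psi_cur):
        mu = _mean_for(model, theta_row, init, grid, w_convention)
        sig = cov.sad1_covariance(psi_cur, grid.T)
        c, low = cho_factor(sig, lower=True)
        dm = ybar - mu
        Smu = S0 + n * np.outer(dm, dm)
        tr = float(np.trace(cho_solve((c, low), Smu)))
        logdet = cov.sad1_logdet(psi_cur, grid.T)
        return -0.5 * (n * d * _LOG_2PI + n * logdet + tr)

    ll = loglik_parts(theta, psi)
    converged = False
    it = 0
    for it in range(1, cfg.null_rounds + 1):
        sig = cov.sad1_covariance(psi, grid.T)
        sinv = cho_solve(cho_factor(sig, lower=True), np.eye(d))

        def quad(u):
            try:
                mu = _mean_for(model, _unpack_theta(u), init, grid, w_convention)
            except HetmapError:
                return _PENALTY
            r = ybar - mu
            return float(n * (r @ (sinv @ r)))

        theta = _unpack_theta(_nm(quad, _pack_theta(theta), cfg.inner_maxiter).x)
        mu = _mean_for(model, theta, init, grid, w_convention)
        dm = ybar - mu
        Smu = S0 + n * np.outer(dm, dm)

        def psi_obj(v):
            try:
                p = _unpack_psi(v)
                sig = cov.sad1_covariance(p, grid.T)
                c, low = cho_factor(sig, lower=True)
            except (HetmapError, np.linalg.LinAlgError):
                return _PENALTY
            tr = float(np.trace(cho_solve((c, low), Smu)))
            return n * cov.sad1_logdet(p, grid.T) + tr

        psi = _unpack_psi(_nm(psi_obj, _pack_psi(psi), cfg.inner_maxiter).x)
        ll_new = loglik_parts(theta, psi)
        if it >= 3 and abs(ll_new - ll) < 1e-8 * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return FitResult(
        kind="null",
        model=model,
        theta=theta,
        psi=psi,
        hf=None,
        genetics=None,
        loglik=ll,
        joint_loglik=None,
        trace=[],
        n_iter=it,
        converged=converged,
        seed=cfg.seed,
        start_logliks=[ll],
        init=init,
        grid=grid,
        w_convention=w_convention,
    )


# ---------------------------------------------------------------------------
# full / constrained mixture fit

def _initial_haplotypes(marker: np.ndarray) -> gen.HaplotypeFreqs:
    n = marker.shape[0]
    p_hat = float(np.clip((2 * (marker == 2).sum() + (marker == 1).sum()) / (2 * n),
                          0.1, 0.9))
    for d in (0.01, 0.005, 0.0):
        try:
            return gen.haplotype_frequencies(
                gen.GeneticParams(p_hat, 1 / 3, 1 / 3, d, d)
            )
        except HetmapError:
            continue
    raise NonConvergenceError("could not build a valid haplotype start")


def _floor_haplotypes(hf: gen.HaplotypeFreqs) -> gen.HaplotypeFreqs:
    f = hf.as_array()
    if f.min() >= 1e-12:
        return hf
    eps = 1e-9
    f = (1.0 - 6 * eps) * f + eps
    return gen.HaplotypeFreqs.from_array(f / f.sum())


def _posterior_marker_counts(post: np.ndarray, marker: np.ndarray) -> np.ndarray:
    S = np.zeros((6, 3))
    for m in range(3):
        sel = marker == m
        if np.any(sel):
            S[:, m] = post[sel].sum(axis=0)
    return S


def _hf_from_counts(S: np.ndarray, hf0: gen.HaplotypeFreqs, n: int,
                    iters: int = 25) -> gen.HaplotypeFreqs:
    hf = hf0
    for _ in range(iters):
        try:
            hf = lik.m_step_haplotypes_from_counts(S, hf, n)
        except UndefinedPhaseError:
            hf = _floor_haplotypes(hf)
            hf = lik.m_step_haplotypes_from_counts(S, hf, n)
        hf = _floor_haplotypes(hf)
    return hf


def _hf_em_fast(S, f, n, iters):
    """Gene-counting EM on the (6, 3) posterior-mass table, raw floats
    (no dataclass validation; used only inside the relabel search)."""
    f0, f1, f2, f3, f4, f5 = f
    inv2n = 1.0 / (2.0 * n)
    for _ in range(iters):
        d1 = f0 * f4 + f1 * f3
        d2 = f0 * f5 + f2 * f3
        d3 = f1 * f5 + f2 * f4
        t1 = f0 * f4 / d1 if d1 > 0 else 0.5
        t2 = f0 * f5 / d2 if d2 > 0 else 0.5
        t3 = f1 * f5 / d3 if d3 > 0 else 0.5
        f0 = inv2n * (2 * S[5, 2] + S[4, 2] + S[3, 2] + S[5, 1]
                      + t1 * S[4, 1] + t2 * S[3, 1])
        f1 = inv2n * (2 * S[2, 2] + S[4, 2] + S[1, 2] + S[2, 1]
                      + (1 - t1) * S[4, 1] + t3 * S[1, 1])
        f2 = inv2n * (2 * S[0, 2] + S[3, 2] + S[1, 2] + S[0, 1]
                      + (1 - t2) * S[3, 1] + (1 - t3) * S[1, 1])
        f3 = inv2n * (2 * S[5, 0] + S[5, 1] + S[4, 0] + S[3, 0]
                      + (1 - t1) * S[4, 1] + (1 - t2) * S[3, 1])
        f4 = inv2n * (2 * S[2, 0] + S[2, 1] + S[4, 0] + S[1, 0]
                      + t1 * S[4, 1] + (1 - t3) * S[1, 1])
        f5 = inv2n * (2 * S[0, 0] + S[0, 1] + S[3, 0] + S[1, 0]
                      + t2 * S[3, 1] + t3 * S[1, 1])
    return np.array([f0, f1, f2, f3, f4, f5])


def _joint_table_fast(f):
    f0, f1, f2, f3, f4, f5 = f
    return np.array([
        [f5 * f5, 2 * f4 * f5, f4 * f4, 2 * f3 * f5, 2 * f3 * f4, f3 * f3],
        [2 * f2 * f5, 2 * f1 * f5 + 2 * f2 * f4, 2 * f1 * f4,
         2 * f0 * f5 + 2 * f2 * f3, 2 * f0 * f4 + 2 * f1 * f3, 2 * f0 * f3],
        [f2 * f2, 2 * f1 * f2, f1 * f1, 2 * f0 * f2, 2 * f0 * f1, f0 * f0],
    ])


_ALL_PERMS = None


def _best_relabel(S: np.ndarray, hf0: gen.HaplotypeFreqs, n: int):
    """Search all 720 genotype-label permutations for the one whose
    marker composition best matches the haplotype model.

    Mixture components are anchored to genotype labels only through the
    marker-dependent priors, so EM can converge to a mode with permuted
    labels.  Given the posterior-by-marker mass table S (which is
    invariant to how individuals were assigned to components), each
    candidate relabeling sigma gets its own converged haplotype estimate
    and the multinomial score sum_{c,m} S[c,m] log P(sigma(c), m); the
    best permutation and its haplotype frequencies are returned.
    """
    global _ALL_PERMS
    if _ALL_PERMS is None:
        from itertools import permutations

        _ALL_PERMS = [np.array(p) for p in permutations(range(6))]
    f_start = hf0.as_array()
    best_perm, best_f, best_score = None, None, -np.inf
    for perm in _ALL_PERMS:
        Sp = np.empty_like(S)
        Sp[perm] = S
        f = _hf_em_fast(Sp, f_start, n, iters=20)
        joint = _joint_table_fast(f)  # [m, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            logj = np.log(joint.T)  # [j, m]
        score = float(np.where(Sp > 0, Sp * logj, 0.0).sum())
        if score > best_score:
            best_perm, best_f, best_score = tuple(int(x) for x in perm), f, score
    best_hf = _floor_haplotypes(
        gen.HaplotypeFreqs.from_array(np.clip(best_f, 0, 1))
    )
    return best_perm, best_hf


def _canonical_allele_gauge(theta: np.ndarray, hf: gen.HaplotypeFreqs):
    """Fix the allele-labelling gauge of a fitted model.

    The mixture likelihood is exactly invariant under relabelling the three
    QTL alleles (the haplotype frequencies absorb any permutation), so a
    fit identifies the model only up to that gauge.  The package reports
    the representative in which the estimated allele frequencies are
    ordered q >= Q >= q+ (allele q the most frequent, the methylated
    epiallele q+ the rarest).
    """
    f = hf.as_array()
    freqs = np.array([f[0] + f[3], f[1] + f[4], f[2] + f[5]])  # Q, q, q+
    order = np.argsort(-freqs, kind="stable")
    sigma = np.empty(3, dtype=np.int64)
    sigma[order[0]] = 1  # most frequent allele -> q
    sigma[order[1]] = 0  # second -> Q
    sigma[order[2]] = 2  # rarest -> q+
    if np.array_equal(sigma, [0, 1, 2]):
        return theta, hf
    new_theta = np.empty_like(theta)
    for j in range(6):
        a, b = gen.J_TO_ALLELE_PAIR[j]
        new_theta[gen.qtl_pair_to_index(int(sigma[a]), int(sigma[b]))] = theta[j]
    new_f = np.empty(6)
    for m in range(2):
        for a in range(3):
            new_f[3 * m + sigma[a]] = f[3 * m + a]
    return new_theta, gen.HaplotypeFreqs.from_array(new_f)


def _update_theta_blocks(
    theta, model, constraint, W, ybar_w, sinv, init, grid, w_convention, maxiter
):
    """Blockwise Nelder-Mead over the genotype ODE parameters.

    Per-genotype private parameters first, then (if any) the shared
    groups jointly.  ``ybar_w[j]`` is genotype j's posterior-weighted mean
    phenotype and ``W[j]`` its posterior mass.
    """
    names = dyn.PARAM_NAMES[model]
    theta = theta.copy()
    private = {j: [] for j in range(6)}
    shared = []
    for pi, pname in enumerate(names):
        for g in constraint.groups[pname]:
            if len(g) == 1:
                private[g[0]].append(pi)
            else:
                shared.append((pi, g))

    def quad_j(j, row):
        try:
            mu = _mean_for(model, row, init, grid, w_convention)
        except HetmapError:
            return _PENALTY
        r = ybar_w[j] - mu
        return float(W[j] * (r @ (sinv @ r)))

    for j in range(6):
        idx = private[j]
        if not idx or W[j] < 1e-9:
            continue
        base = _pack_theta(theta[j])

        def obj(u, j=j, idx=idx, base=base):
            v = base.copy()
            v[idx] = u
            return quad_j(j, _unpack_theta(v))

        res = _nm(obj, base[idx], maxiter)
        new = base.copy()
        new[idx] = res.x
        theta[j] = _unpack_theta(new)

    if shared:
        affected = sorted({j for _, g in shared for j in g})
        packed0 = np.array(
            [_pack_theta(theta[g[0]])[pi] for pi, g in shared]
        )

        def obj_shared(u):
            th = theta.copy()
            for (pi, g), val in zip(shared, u):
                packed_rows = {j: _pack_theta(th[j]) for j in g}
                for j in g:
                    v = packed_rows[j]
                    v[pi] = val
                    th[j] = _unpack_theta(v)
            return sum(quad_j(j, th[j]) for j in affected if W[j] > 1e-9)

        res = _nm(obj_shared, packed0, maxiter)
        for (pi, g), val in zip(shared, res.x):
            for j in g:
                v = _pack_theta(theta[j])
                v[pi] = val
                theta[j] = _unpack_theta(v)
    return theta


def _cluster_start(data, model, null, cfg, init, grid, w_convention):
    """Data-driven start: cluster the phenotype vectors in a metric that
    approximates within-genotype noise, seed six centers by the
    farthest-point rule so rare genotype classes are not swallowed by
    large ones, fit one ODE curve per cluster, and choose the
    cluster-to-genotype labelling by the marker-composition score.
    Deterministic.

    The per-column scale is the median absolute difference of *sorted*
    column values: with a handful of well-separated location components,
    most sorted neighbours belong to the same component, so this estimates
    the within-class noise scale without knowing the classes (a pooled SD
    would be dominated by between-class spread and compress exactly the
    discriminating directions).
    """
    if data.n < 12:
        return None
    scales = np.empty(data.Y.shape[1])
    for c in range(data.Y.shape[1]):
        d = np.abs(np.diff(np.sort(data.Y[:, c])))
        s = np.median(d[d > 0]) if np.any(d > 0) else 0.0
        scales[c] = s if s > 0 else max(data.Y[:, c].std(), 1e-12)
    Z = data.Y / scales
    # farthest-point seeding, then a few Lloyd iterations
    d0 = np.linalg.norm(Z - Z.mean(axis=0), axis=1)
    centers = [int(np.argmax(d0))]
    mind = np.linalg.norm(Z - Z[centers[0]], axis=1)
    for _ in range(5):
        nxt = int(np.argmax(mind))
        centers.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(Z - Z[nxt], axis=1))
    cent = Z[centers].copy()
    labels = np.zeros(data.n, dtype=np.int64)
    for _ in range(10):
        dist = ((Z[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(6):
            if (labels == c).any():
                cent[c] = Z[labels == c].mean(axis=0)
    theta = np.tile(null.theta, (6, 1))
    for c in range(6):
        members = labels == c
        if not members.any():
            continue
        ybar_c = data.Y[members].mean(axis=0)

        def sse(u, ybar_c=ybar_c):
            try:
                mu = _mean_for(model, _unpack_theta(u), init, grid, w_convention)
            except HetmapError:
                return _PENALTY
            r = ybar_c - mu
            return float(r @ r)

        theta[c] = _unpack_theta(_nm(sse, _pack_theta(null.theta), 250).x)
    hard = np.zeros((data.n, 6))
    hard[np.arange(data.n), labels] = 1.0
    S = _posterior_marker_counts(hard, data.marker)
    hf0 = _initial_haplotypes(data.marker)
    perm, hf_start = _best_relabel(S, hf0, data.n)
    inv = np.argsort(np.array(perm))
    # SAD start from the within-cluster residuals (the null-fit residuals
    # are inflated by between-genotype spread)
    mu_arr = np.stack(
        [_mean_for(model, theta[c], init, grid, w_convention) for c in range(6)]
    )
    psi_start = _psi_init_from_residuals(data.Y - mu_arr[labels], grid.T)
    return theta[inv], hf_start, psi_start


def _em_single_start(
    data, model, theta0, psi0, hf0, cfg, constraint, init, grid, w_convention
):
    n, d, T = data.n, data.Y.shape[1], data.grid.T
    theta, psi, hf = theta0.copy(), psi0, hf0
    trace = []
    converged = False
    relabels = 0
    it = 0
    for it in range(1, cfg.max_em_iter + 1):
        means = np.stack(
            [_mean_for(model, theta[j], init, grid, w_convention) for j in range(6)]
        )
        sig = cov.sad1_covariance(psi, T)
        logf = lik.log_density_matrix(data.Y, means, sig)
        joint = gen.joint_genotype_table(hf)
        with np.errstate(divide="ignore"):
            logpj = np.log(joint)[data.marker]
        ll = float(logsumexp(logpj + logf, axis=1).sum())
        trace.append(ll)
        flat = it >= 2 and abs(ll - trace[-2]) < cfg.em_tol * (1.0 + abs(ll))
        post = lik.posterior_from_logs(logpj, logf)
        # Label-swap repair: periodically (and whenever EM has flattened)
        # search genotype relabelings for one that explains the marker
        # data better; adopt only if the joint loglik improves, so the
        # ascent guarantee is preserved.
        if cfg.relabel and relabels < 6 and (flat or it % cfg.relabel_every == 0):
            S = _posterior_marker_counts(post, data.marker)
            perm, hf_cand = _best_relabel(S, hf0, n)
            if perm != tuple(range(6)):
                perm_arr = np.array(perm)
                inv = np.argsort(perm_arr)
                with np.errstate(divide="ignore"):
                    logpj_cand = np.log(gen.joint_genotype_table(hf_cand))[
                        data.marker
                    ]
                ll_cand = float(
                    logsumexp(logpj_cand + logf[:, inv], axis=1).sum()
                )
                if ll_cand > ll + 1e-9:
                    theta = theta[inv]
                    hf = hf_cand
                    relabels += 1
                    trace.append(ll_cand)
                    post = lik.posterior_from_logs(logpj_cand, logf[:, inv])
                    flat = False
        if flat:
            converged = True
            break

        # --- haplotype M-step (exact EM step for the joint model)
        try:
            hf = lik.m_step_haplotypes(post, data.marker, hf, n)
        except UndefinedPhaseError:
            hf = _floor_haplotypes(hf)
            hf = lik.m_step_haplotypes(post, data.marker, hf, n)
        hf = _floor_haplotypes(hf)

        # --- genotype ODE parameters against posterior-weighted means
        W = post.sum(axis=0)
        ybar_w = np.where(
            W[:, None] > 1e-9, (post.T @ data.Y) / np.maximum(W, 1e-12)[:, None], 0.0
        )
        sinv = cho_solve(cho_factor(sig, lower=True), np.eye(d))
        theta = _update_theta_blocks(
            theta, model, constraint, W, ybar_w, sinv, init, grid,
            w_convention, cfg.inner_maxiter,
        )

        # --- SAD(1) parameters against the pooled posterior scatter
        means = np.stack(
            [_mean_for(model, theta[j], init, grid, w_convention) for j in range(6)]
        )
        S = np.zeros((d, d))
        for j in range(6):
            if W[j] < 1e-12:
                continue
            R = data.Y - means[j]
            S += R.T @ (post[:, j][:, None] * R)

        def psi_obj(v):
            try:
                p = _unpack_psi(v)
                sg = cov.sad1_covariance(p, T)
                c, low = cho_factor(sg, lower=True)
            except (HetmapError, np.linalg.LinAlgError):
                return _PENALTY
            tr = float(np.trace(cho_solve((c, low), S)))
            return n * cov.sad1_logdet(p, T) + tr

        psi = _unpack_psi(_nm(psi_obj, _pack_psi(psi), cfg.inner_maxiter).x)
    if cfg.canonical_gauge:
        theta, hf = _canonical_allele_gauge(theta, hf)
    return theta, psi, hf, trace, it, converged


def fit_full(
    data: lik.Dataset,
    model: str,
    cfg: FitConfig | None = None,
    constraint: ConstraintSpec | None = None,
    null: FitResult | None = None,
    init: dyn.State | None = None,
    w_convention: str = "proportion",
    warm: tuple | None = None,
) -> FitResult:
    """Mixture fit of the full (or constrained) six-genotype model.

    Generalized EM with the closed-form haplotype M-step; best of
    ``cfg.n_starts`` starts by final joint log-likelihood; deterministic
    given ``cfg.seed``.

    The start schedule is: an optional caller-supplied warm start
    ``warm = (theta, psi, hf)``; the exact-null start (all genotypes at
    the null fit, so the full model provably ascends from the null
    log-likelihood); the data-driven cluster start; then deterministic
    per-genotype offsets with seeded jitter.  ``cfg.n_starts`` counts how
    many of these run.
    """
    cfg = cfg or FitConfig()
    init = init or dyn.State(1.0, 1.0)
    constraint = constraint or ConstraintSpec.free(model)
    if constraint.model != model:
        raise InvalidParameterError("constraint model mismatch")
    if null is None:
        null = fit_null(data, model, cfg, init=init, w_convention=w_convention)
    hf0 = _initial_haplotypes(data.marker)
    offsets = np.array([1.0 + 0.05 * (j - 2.5) / 2.5 for j in range(6)])

    kinds = (["warm"] if warm is not None else []) + ["null", "cluster"]
    best = None
    start_lls = []
    for s in range(cfg.n_starts):
        kind = kinds[s] if s < len(kinds) else "jitter"
        hf_s = hf0
        psi_s = null.psi
        if kind == "warm":
            theta0 = np.asarray(warm[0], dtype=float).copy()
            psi_s = warm[1]
            hf_s = warm[2]
        elif kind == "null":
            theta0 = np.tile(null.theta, (6, 1))
        elif kind == "cluster":
            cluster = _cluster_start(
                data, model, null, cfg, init, data.grid, w_convention
            )
            if cluster is None:
                theta0 = null.theta[None, :] * offsets[:, None]
            else:
                theta0, hf_s, psi_s = cluster
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), s]))
            jit = np.exp(cfg.jitter * rng.standard_normal((6, null.theta.size)))
            theta0 = null.theta[None, :] * offsets[:, None] * jit
        try:
            out = _em_single_start(
                data, model, theta0, psi_s, hf_s, cfg, constraint,
                init, data.grid, w_convention,
            )
        except HetmapError:
            start_lls.append(float("-inf"))
            continue
        theta, psi, hf, trace, n_iter, conv = out
        start_lls.append(trace[-1])
        if best is None or trace[-1] > best[3][-1]:
            best = (theta, psi, hf, trace, n_iter, conv)
    if best is None:
        raise NonConvergenceError("no EM start produced a finite likelihood")
    theta, psi, hf, trace, n_iter, conv = best
    if cfg.swap_polish:
        theta, psi, hf, trace, n_iter, conv = _swap_polish(
            data, model, best, cfg, constraint, init, w_convention
        )
    spec = lik.ModelSpec(
        model=model, theta=theta, sad=psi, hf=hf, init=init,
        grid=data.grid, w_convention=w_convention,
    )
    cond_ll = lik.mixture_loglik(data, spec)
    return FitResult(
        kind="constrained" if _is_constrained(constraint) else "full",
        model=model,
        theta=theta,
        psi=psi,
        hf=hf,
        genetics=gen.genetic_params_from_haplotypes(hf),
        loglik=cond_ll,
        joint_loglik=trace[-1],
        trace=trace,
        n_iter=n_iter,
        converged=conv,
        seed=cfg.seed,
        start_logliks=start_lls,
        init=init,
        grid=data.grid,
        w_convention=w_convention,
    )


def _swap_polish(data, model, best, cfg, constraint, init, w_convention):
    """Try short EM restarts from pairwise genotype-label transpositions.

    Near-tied labelings of heterozygote classes are separate EM modes that
    differ only after all parameters re-adapt, so a one-shot relabel check
    cannot reach them.  The most promising transpositions (ranked by the
    marker-composition score) are restarted for a limited number of
    sweeps; an improvement in the joint log-likelihood is adopted and the
    search repeats from the improved fit.
    """
    import dataclasses
    from itertools import combinations

    theta, psi, hf, trace, n_iter, conv = best
    grid = data.grid
    n = data.n
    hf0 = _initial_haplotypes(data.marker)
    polish_cfg = dataclasses.replace(
        cfg, max_em_iter=cfg.swap_polish_iters, swap_polish=False
    )
    for _ in range(2):
        ll_best = trace[-1]
        means = np.stack(
            [_mean_for(model, theta[j], init, grid, w_convention) for j in range(6)]
        )
        sig = cov.sad1_covariance(psi, grid.T)
        logf = lik.log_density_matrix(data.Y, means, sig)
        with np.errstate(divide="ignore"):
            logpj = np.log(gen.joint_genotype_table(hf))[data.marker]
        post = lik.posterior_from_logs(logpj, logf)
        S = _posterior_marker_counts(post, data.marker)
        cands = []
        for a, b in combinations(range(6), 2):
            perm = list(range(6))
            perm[a], perm[b] = b, a
            Sp = np.empty_like(S)
            for c in range(6):
                Sp[perm[c]] = S[c]
            hf_c = _hf_from_counts(Sp, hf0, n)
            joint = gen.joint_genotype_table(hf_c)
            with np.errstate(divide="ignore"):
                logj = np.log(joint.T)
            score = float(np.where(Sp > 0, Sp * logj, 0.0).sum())
            cands.append((score, tuple(perm), hf_c))
        cands.sort(key=lambda c: -c[0])
        adopted = None
        for score, perm, hf_c in cands[: cfg.swap_polish_k]:
            inv = np.argsort(np.array(perm))
            try:
                out = _em_single_start(
                    data, model, theta[inv], psi, hf_c, polish_cfg,
                    constraint, init, grid, w_convention,
                )
            except HetmapError:
                continue
            if out[3][-1] > ll_best + 1e-6 * (1.0 + abs(ll_best)):
                ll_best = out[3][-1]
                adopted = out
        if adopted is None:
            break
        theta, psi, hf, trace, n_iter, conv = adopted
    return theta, psi, hf, trace, n_iter, conv


def _is_constrained(constraint: ConstraintSpec) -> bool:
    return any(
        len(g) > 1 for gs in constraint.groups.values() for g in gs
    )


def fit_constrained(
    data: lik.Dataset,
    model: str,
    constraint: ConstraintSpec,
    cfg: FitConfig | None = None,
    **kwargs,
) -> FitResult:
    """Mixture fit with the simplex search restricted by an equality
    pattern over genotype ODE parameters (see :class:`ConstraintSpec`)."""
    return fit_full(data, model, cfg, constraint=constraint, **kwargs)


# ---------------------------------------------------------------------------
# heritability

def compute_heritability(spec: lik.ModelSpec, t_ref: float | None = None):
    """Variance-decomposition heritability at a reference time.

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) per variable, where
    sigma_g^2 is the genotype-frequency-weighted variance of the six mean
    curves at t_ref and sigma_e^2 the SAD(1) marginal residual variance
    there.  Returns (h2_x1, h2_x2, average); t_ref defaults to the last
    observation time.
    """
    grid = spec.grid
    if t_ref is None:
        t_ref = grid.times[-1]
    if t_ref not in grid.times:
        raise InvalidParameterError(f"t_ref={t_ref} not on the grid")
    k = grid.times.index(t_ref)
    w = gen.joint_genotype_table(spec.hf).sum(axis=0)
    means = spec.genotype_means()
    V = cov.marginal_variances(spec.sad, grid.T)[k]
    out = []
    for var, col in ((0, k), (1, grid.T + k)):
        mu = means[:, col]
        mbar = float(w @ mu)
        sg = float(w @ (mu - mbar) ** 2)
        se = float(V[var, var])
        out.append(sg / (sg + se) if sg + se > 0 else 0.0)
    return out[0], out[1], 0.5 * (out[0] + out[1])
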