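"""Likelihood-ratio testing and genetic-effect trajectories.

QTL existence is tested by comparing the full six-genotype mixture against
the single-curve null with the statistic LR = -2 (logL0 - logL1); because
the mixture null distribution is nonstandard, critical values come from an
empirical permutation scheme in which each individual's marker code is
shuffled against the (intact) phenotype vectors, preserving the
longitudinal covariance under the null.

Every full-model fit inside the permutation loop -- including the one on
the observed labels -- starts from the same marker-independent null fit
and uses identical optimizer settings, so the observed statistic is
exchangeable with the permuted ones under the null and the p-value
p = (1 + #{LR_perm >= LR_obs}) / (n_perm + 1) is exactly calibrated for
any permutation count.

Additive and dominance effect curves use the classical biallelic contrasts
applied pairwise to the three alleles (Q/q, Q/q+, q/q+): for homozygote
curves mu_AA, mu_BB and heterozygote mu_AB,
a(t) = (mu_AA - mu_BB)/2 and d(t) = mu_AB - (mu_AA + mu_BB)/2, per
variable.  The three-allele decomposition is not uniquely defined; this
pairwise reading is one defensible choice and outputs are labelled by
allele pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import estimation as est
from . import likelihood as lik
from .errors import HetmapError, InvalidParameterError

#: (allele pair label, (j_AA, j_AB, j_BB)) for the pairwise contrasts.
ALLELE_PAIRS = (
    ("Q/q", (5, 4, 2)),
    ("Q/q+", (5, 3, 0)),
    ("q/q+", (2, 1, 0)),
)


@dataclass
class LRTestResult:
    """Likelihood-ratio test outcome (threshold fields filled only when a
    permutation run was performed)."""

    lr: float
    loglik_null: float
    loglik_full: float
    threshold: float | None = None
    n_perm: int = 0
    alpha: float | None = None
    p_value: float | None = None
    perm_lrs: list = field(default_factory=list)
    n_failures: int = 0
    seed: int | None = None

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.lr > self.threshold


def _lr_from_fits(null: est.FitResult, full: est.FitResult) -> float:
    lr = -2.0 * (null.loglik - full.loglik)
    # clamp tiny negative values caused by finite optimizer tolerance
    if -1e-6 * (1.0 + abs(null.loglik)) < lr < 0.0:
        lr = 0.0
    return lr


def lr_existence(
    data: lik.Dataset,
    model: str,
    cfg: est.FitConfig | None = None,
    null: est.FitResult | None = None,
    full: est.FitResult | None = None,
    **fit_kwargs,
) -> LRTestResult:
    """LR statistic for QTL existence (no permutation threshold)."""
    cfg = cfg or est.FitConfig()
    if null is None:
        null = est.fit_null(data, model, cfg, **fit_kwargs)
    if full is None:
        full = est.fit_full(data, model, cfg, null=null, **fit_kwargs)
    return LRTestResult(
        lr=_lr_from_fits(null, full),
        loglik_null=null.loglik,
        loglik_full=full.loglik,
    )


def permutation_threshold(
    data: lik.Dataset,
    model: str,
    n_perm: int = 100,
    alpha: float = 0.05,
    cfg: est.FitConfig | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> LRTestResult:
    """Empirical LR threshold and p-value by marker-label permutation.

    Marker codes are permuted against intact phenotype rows ``n_perm``
    times; the threshold is the empirical (1 - alpha) quantile of the
    permuted statistics.  Permutation fits that fail are excluded and
    counted.
    """
    if n_perm < 20:
        raise InvalidParameterError("n_perm must be >= 20")
    if alpha * (n_perm + 1) < 1:
        raise InvalidParameterError("alpha too small for this n_perm")
    cfg = cfg or est.FitConfig()
    null = est.fit_null(data, model, cfg, **fit_kwargs)
    full = est.fit_full(data, model, cfg, null=null, **fit_kwargs)
    lr_obs = _lr_from_fits(null, full)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779]))
    lrs = []
    failures = 0
    for _ in range(n_perm):
        perm = rng.permutation(data.n)
        pdata = lik.Dataset(
            marker=data.marker[perm], Y=data.Y, grid=data.grid
        )
        try:
            pfull = est.fit_full(pdata, model, cfg, null=null, **fit_kwargs)
            lrs.append(_lr_from_fits(null, pfull))
        except HetmapError:
            failures += 1
    lrs_arr = np.array(lrs)
    threshold = float(np.quantile(lrs_arr, 1.0 - alpha)) if len(lrs) else np.inf
    p = (1.0 + float((lrs_arr >= lr_obs).sum())) / (len(lrs) + 1.0)
    return LRTestResult(
        lr=lr_obs,
        loglik_null=null.loglik,
        loglik_full=full.loglik,
        threshold=threshold,
        n_perm=n_perm,
        alpha=alpha,
        p_value=p,
        perm_lrs=[float(v) for v in lrs],
        n_failures=failures,
        seed=seed,
    )


@dataclass
class EffectTrajectories:
    """Additive and dominance curves per allele pair and variable.

    ``additive[(pair, var)]`` and ``dominance[(pair, var)]`` are arrays over
    the observation grid, with pair in {"Q/q", "Q/q+", "q/q+"} and var in
    {"x1", "x2"}.
    """

    times: tuple
    additive: dict
    dominance: dict


def effect_trajectories(spec: lik.ModelSpec) -> EffectTrajectories:
    """Pairwise additive/dominance genetic-effect curves from the fitted
    genotype mean trajectories."""
    means = spec.genotype_means()
    T = spec.grid.T
    add, dom = {}, {}
    for pair, (jaa, jab, jbb) in ALLELE_PAIRS:
        for var, sl in (("x1", slice(0, T)), ("x2", slice(T, 2 * T))):
            mu_aa, mu_ab, mu_bb = means[jaa, sl], means[jab, sl], means[jbb, sl]
            add[(pair, var)] = 0.5 * (mu_aa - mu_bb)
            dom[(pair, var)] = mu_ab - 0.5 * (mu_aa + mu_bb)
    return EffectTrajectories(times=spec.grid.times, additive=add, dominance=dom)
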