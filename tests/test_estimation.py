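"""Fitters: null-model recovery, nesting, constraints, heritability, and
the allele-labelling gauge."""

import dataclasses

import numpy as np
import pytest

import hetmap as hm
from hetmap import covariance as cov
from hetmap import dynamics as dyn
from hetmap import estimation as est
from hetmap import genetics as gen
from hetmap import likelihood as lik
from hetmap.errors import InvalidParameterError


class TestFitNull:
    def test_recovers_single_genotype_parameters(self):
        # pooled data from one genotype only
        theta_qq = np.array([0.12, 0.003, 0.006])
        sad = cov.SADParams(0.76, 1.23, 1.22, 0.62, 0.01, 0.01, 0.4824)
        grid = dyn.TimeGrid()
        rng = np.random.default_rng(8)
        n = 120
        mu = dyn.mean_vector(
            "linear", dyn.ODEParamsLinear(*theta_qq), dyn.State(1, 1), grid
        )
        Y = mu + cov.simulate_residual_matrix(sad, 9, n, rng)
        data = lik.Dataset(marker=rng.integers(0, 3, n), Y=Y, grid=grid)
        fit = est.fit_null(data, "linear", hm.FitConfig(n_starts=1))
        assert fit.theta[0] == pytest.approx(0.12, abs=0.005)
        assert fit.theta[1] == pytest.approx(0.003, abs=0.005)
        assert fit.theta[2] == pytest.approx(0.006, abs=0.005)
        assert fit.psi.nu1 == pytest.approx(0.01, rel=0.5)

    def test_nested_below_full(self, small_fit):
        sc, data, null, full = small_fit
        assert null.loglik <= full.loglik + 1e-6


class TestFitFull:
    def test_deterministic_given_seed(self, small_dataset, cheap_cfg):
        sc, data = small_dataset
        a = est.fit_full(data, "linear", cheap_cfg)
        b = est.fit_full(data, "linear", cheap_cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.loglik == b.loglik

    def test_monotone_trace(self, small_fit):
        sc, data, null, full = small_fit
        d = np.diff(full.trace)
        assert d.min() > -1e-6 * (1.0 + abs(full.trace[-1]))

    def test_refit_is_fixed_point(self, small_fit, cheap_cfg):
        sc, data, null, full = small_fit
        cfg = dataclasses.replace(cheap_cfg, relabel=False)
        refit = est.fit_full(
            data, "linear", cfg, null=null,
            warm=(full.theta, full.psi, full.hf),
        )
        rel = abs(refit.joint_loglik - full.joint_loglik) / (
            1.0 + abs(full.joint_loglik)
        )
        assert rel < 1e-3

    def test_genetics_backsolved_on_simplex(self, small_fit):
        sc, data, null, full = small_fit
        g = full.genetics
        assert 0 <= g.p_M <= 1
        assert 0 <= g.q_Q and 0 <= g.q_q and g.q_Q + g.q_q <= 1 + 1e-9


class TestConstraints:
    def test_free_constraint_matches_fit_full(self, small_dataset, cheap_cfg):
        sc, data = small_dataset
        a = est.fit_full(data, "linear", cheap_cfg)
        b = est.fit_constrained(
            data, "linear", est.ConstraintSpec.free("linear"), cheap_cfg
        )
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_all_shared_nested_below_full(self, small_dataset, cheap_cfg):
        sc, data = small_dataset
        full = est.fit_full(data, "linear", cheap_cfg)
        shared = est.fit_constrained(
            data, "linear", est.ConstraintSpec.all_shared("linear"), cheap_cfg
        )
        assert shared.loglik <= full.loglik + 1e-6

    def test_all_shared_collapses_to_single_curve(self, small_dataset, cheap_cfg):
        sc, data = small_dataset
        shared = est.fit_constrained(
            data, "linear", est.ConstraintSpec.all_shared("linear"), cheap_cfg
        )
        assert np.ptp(shared.theta, axis=0).max() < 1e-12

    def test_invalid_partition_rejected(self):
        with pytest.raises(InvalidParameterError):
            est.ConstraintSpec(
                "linear",
                {"r": ((0, 1), (1, 2, 3, 4, 5)), "k1": (tuple(range(6)),),
                 "k2": (tuple(range(6)),)},
            )

    def test_missing_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            est.ConstraintSpec("linear", {"r": (tuple(range(6)),)})


class TestHeritability:
    def test_equal_means_gives_zero(self, hf_example):
        sc = hm.build_scenario("linear_n200_h005")
        theta = np.tile(sc.theta[5], (6, 1))
        spec = lik.ModelSpec(
            model="linear", theta=theta, sad=sc.sad, hf=hf_example
        )
        assert est.compute_heritability(spec)[2] == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_noise_gives_one(self, hf_example):
        sc = hm.build_scenario("linear_n200_h005")
        tiny = cov.SADParams(0.76, 1.23, 1.22, 0.62, 1e-9, 1e-9, 0.4824)
        spec = lik.ModelSpec(
            model="linear", theta=sc.theta, sad=tiny, hf=hf_example
        )
        assert est.compute_heritability(spec)[2] == pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo_decomposition(self):
        sc = hm.build_scenario("linear_n200_h005", n=10_000)
        spec = sc.spec()
        data = hm.simulate_dataset(sc, seed=4)
        t_idx = 8
        h2_x1 = est.compute_heritability(spec, t_ref=9.0)[0]
        # empirical decomposition at t=9 for x1
        x = data.Y[:, t_idx]
        groups = [x[data.truth_qtl == j] for j in range(6)]
        w = np.array([len(g) for g in groups]) / len(x)
        means = np.array([g.mean() for g in groups])
        sg = float(w @ (means - w @ means) ** 2)
        h2_emp = sg / (sg + np.average(
            [g.var() for g in groups if len(g) > 1],
            weights=[len(g) for g in groups if len(g) > 1],
        ))
        assert h2_x1 == pytest.approx(h2_emp, abs=0.05)

    def test_off_grid_reference_rejected(self, linear_scenario):
        with pytest.raises(InvalidParameterError):
            est.compute_heritability(linear_scenario.spec(), t_ref=3.14)


class TestAlleleGauge:
    @pytest.mark.parametrize("sigma", [(1, 0, 2), (2, 1, 0), (1, 2, 0)])
    def test_gauge_restores_canonical_order(self, sigma, hf_example,
                                            linear_scenario):
        """Applying any allele permutation and re-canonicalizing recovers
        the original representation."""
        theta = linear_scenario.theta
        f = hf_example.as_array()
        sig = np.array(sigma)
        theta_p = np.empty_like(theta)
        for j in range(6):
            a, b = gen.J_TO_ALLELE_PAIR[j]
            theta_p[gen.qtl_pair_to_index(int(sig[a]), int(sig[b]))] = theta[j]
        f_p = np.empty(6)
        for m in range(2):
            for a in range(3):
                f_p[3 * m + sig[a]] = f[3 * m + a]
        hf_p = gen.HaplotypeFreqs.from_array(f_p)
        theta_c, hf_c = est._canonical_allele_gauge(theta_p, hf_p)
        np.testing.assert_allclose(theta_c, theta, atol=1e-12)
        np.testing.assert_allclose(hf_c.as_array(), f, atol=1e-12)

    def test_permuted_spec_has_identical_likelihood(self, hf_example,
                                                    linear_scenario):
        """The mixture likelihood is invariant under allele relabelling."""
        sc = hm.build_scenario("linear_n200_h005", n=50)
        data = hm.simulate_dataset(sc, seed=13)
        sig = np.array([2, 0, 1])
        theta = sc.theta
        f = hf_example.as_array()
        theta_p = np.empty_like(theta)
        for j in range(6):
            a, b = gen.J_TO_ALLELE_PAIR[j]
            theta_p[gen.qtl_pair_to_index(int(sig[a]), int(sig[b]))] = theta[j]
        f_p = np.empty(6)
        for m in range(2):
            for a in range(3):
                f_p[3 * m + sig[a]] = f[3 * m + a]
        spec_a = lik.ModelSpec(model="linear", theta=theta, sad=sc.sad,
                               hf=hf_example)
        spec_b = lik.ModelSpec(model="linear", theta=theta_p, sad=sc.sad,
                               hf=gen.HaplotypeFreqs.from_array(f_p))
        assert lik.mixture_loglik(data, spec_a) == pytest.approx(
            lik.mixture_loglik(data, spec_b), rel=1e-12
        )
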