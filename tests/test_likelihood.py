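"""Mixture likelihood, E-step posteriors, and the closed-form haplotype
M-step against an expected-haplotype-counting oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import hetmap as hm
from hetmap import covariance as cov
from hetmap import dynamics as dyn
from hetmap import genetics as gen
from hetmap import likelihood as lik

PSI = cov.SADParams(0.76, 1.23, 1.22, 0.62, 0.01, 0.01, 0.4824)


def make_spec(hf, theta=None, grid=None):
    sc = hm.build_scenario("linear_n200_h005")
    return lik.ModelSpec(
        model="linear",
        theta=sc.theta if theta is None else theta,
        sad=PSI,
        hf=hf,
        grid=grid or dyn.TimeGrid(),
    )


@pytest.fixture(scope="module")
def sim_data():
    sc = hm.build_scenario("linear_n200_h005", n=80)
    return sc, hm.simulate_dataset(sc, seed=5)


class TestMixtureLoglik:
    def test_degenerate_prior_equals_plain_mvn(self, sim_data):
        sc, data = sim_data
        # only allele Q present: every individual is QQ regardless of marker
        hf = gen.HaplotypeFreqs(0.6, 0, 0, 0.4, 0, 0)
        spec = make_spec(hf)
        ll = lik.mixture_loglik(data, spec)
        C = cov.sad1_covariance(PSI, 9)
        mu = spec.genotype_means()[5]
        direct = multivariate_normal(mean=mu, cov=C).logpdf(data.Y).sum()
        assert ll == pytest.approx(direct, abs=1e-6)

    def test_duplication_doubles(self, sim_data, hf_example):
        sc, data = sim_data
        spec = make_spec(hf_example)
        doubled = lik.Dataset(
            marker=np.concatenate([data.marker, data.marker]),
            Y=np.vstack([data.Y, data.Y]),
            grid=data.grid,
        )
        assert lik.mixture_loglik(doubled, spec) == pytest.approx(
            2 * lik.mixture_loglik(data, spec), rel=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_truth_beats_perturbed(self, seed, hf_example):
        sc = hm.build_scenario("linear_n200_h005", n=60)
        data = hm.simulate_dataset(sc, seed=seed)
        spec = make_spec(hf_example)
        theta_bad = sc.theta.copy()
        theta_bad[:, 0] *= 1.5
        spec_bad = make_spec(hf_example, theta=theta_bad)
        assert lik.mixture_loglik(data, spec) > lik.mixture_loglik(
            data, spec_bad
        )


class TestEStep:
    def test_equal_means_returns_priors(self, sim_data):
        sc, data = sim_data
        # with identical genotype curves the densities cancel and the
        # posterior equals the marker-conditional prior
        hf = hm.haplotype_frequencies(
            hm.GeneticParams(0.5, 1 / 3, 1 / 3, 0, 0)
        )
        theta = np.tile(sc.theta[5], (6, 1))
        post = lik.e_step(data, make_spec(hf, theta=theta))
        cond = gen.conditional_qtl_probabilities(hf)
        np.testing.assert_allclose(post, cond[data.marker], atol=1e-9)

    def test_zero_prior_gives_zero_posterior(self, sim_data):
        sc, data = sim_data
        hf = gen.HaplotypeFreqs(0.35, 0.25, 0.0, 0.2, 0.2, 0.0)  # no q+
        post = lik.e_step(data, make_spec(hf))
        assert np.all(post[:, [0, 1, 3]] == 0.0)  # q+-bearing genotypes

    def test_rows_sum_to_one(self, sim_data, hf_example):
        sc, data = sim_data
        post = lik.e_step(data, make_spec(hf_example))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_modal_posterior_recovers_truth(self):
        sc = hm.build_scenario("linear_n200_h02")
        data = hm.simulate_dataset(sc, seed=9)
        post = lik.e_step(data, sc.spec())
        assert (post.argmax(axis=1) == data.truth_qtl).mean() > 0.9


def oracle_m_step(post, marker, hf):
    """Expected-haplotype counting over the 18 (marker, QTL) cells with
    the double-heterozygote phase split by the theta weights."""
    th = gen.phase_weights(hf)
    n = post.shape[0]
    S = np.zeros((6, 3))
    for i in range(n):
        S[:, marker[i]] += post[i]
    counts = np.zeros(6)  # MQ, Mq, Mq+, mQ, mq, mq+
    # haplotype content per (j, m) cell: list of (hap index, weight)
    content = {
        (5, 2): [(0, 2)], (4, 2): [(0, 1), (1, 1)], (3, 2): [(0, 1), (2, 1)],
        (2, 2): [(1, 2)], (1, 2): [(1, 1), (2, 1)], (0, 2): [(2, 2)],
        (5, 0): [(3, 2)], (4, 0): [(3, 1), (4, 1)], (3, 0): [(3, 1), (5, 1)],
        (2, 0): [(4, 2)], (1, 0): [(4, 1), (5, 1)], (0, 0): [(5, 2)],
        (5, 1): [(0, 1), (3, 1)], (2, 1): [(1, 1), (4, 1)],
        (0, 1): [(2, 1), (5, 1)],
        (4, 1): [(0, th.theta1), (4, th.theta1),
                 (1, 1 - th.theta1), (3, 1 - th.theta1)],
        (3, 1): [(0, th.theta2), (5, th.theta2),
                 (2, 1 - th.theta2), (3, 1 - th.theta2)],
        (1, 1): [(1, th.theta3), (5, th.theta3),
                 (2, 1 - th.theta3), (4, 1 - th.theta3)],
    }
    for (j, m), items in content.items():
        for hap, w in items:
            counts[hap] += w * S[j, m]
    return counts / (2 * n)


class TestMStepHaplotypes:
    def test_all_mm_qq_gives_pure_mq(self, hf_example):
        n = 40
        post = np.zeros((n, 6))
        post[:, 5] = 1.0
        marker = np.full(n, 2)
        hf = lik.m_step_haplotypes(post, marker, hf_example)
        assert hf.f_MQ == pytest.approx(1.0, abs=1e-12)

    def test_simplex_preserved(self, hf_example):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 50
            post = rng.dirichlet(np.ones(6), size=n)
            marker = rng.integers(0, 3, size=n)
            hf = lik.m_step_haplotypes(post, marker, hf_example)
            assert abs(hf.as_array().sum() - 1.0) < 1e-12

    def test_matches_counting_oracle(self, hf_example):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 30
            post = rng.dirichlet(np.ones(6), size=n)
            marker = rng.integers(0, 3, size=n)
            hf = lik.m_step_haplotypes(post, marker, hf_example)
            ref = oracle_m_step(post, marker, hf_example)
            np.testing.assert_allclose(hf.as_array(), ref, atol=1e-12)


class TestQFunction:
    def test_one_hot_equals_complete_data(self, sim_data, hf_example):
        sc, data = sim_data
        spec = make_spec(hf_example)
        means = spec.genotype_means()
        C = cov.sad1_covariance(PSI, 9)
        cond = gen.conditional_qtl_probabilities(hf_example)
        post = np.zeros((data.n, 6))
        j_fixed = 4
        post[:, j_fixed] = 1.0
        q = lik.q_function(data, post, spec)
        mvn = multivariate_normal(mean=means[j_fixed], cov=C)
        expected = sum(
            np.log(cond[m, j_fixed]) + mvn.logpdf(y)
            for m, y in zip(data.marker, data.Y)
        )
        assert q == pytest.approx(expected, rel=1e-9)

    def test_jensen_gap_is_posterior_entropy(self, sim_data, hf_example):
        sc, data = sim_data
        spec = make_spec(hf_example)
        post = lik.e_step(data, spec)
        q = lik.q_function(data, post, spec)
        ll = lik.mixture_loglik(data, spec)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(post > 0, post * np.log(post), 0.0))
        assert ll == pytest.approx(q + ent, abs=1e-6)
        assert q <= ll + 1e-9
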