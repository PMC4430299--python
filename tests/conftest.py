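import pytest

import hetmap as hm


@pytest.fixture(scope="session")
def gp_example():
    """The genetic-parameter set used throughout the simulation design."""
    return hm.GeneticParams(p_M=0.6, q_Q=0.4, q_q=0.5, d1=0.01, d2=0.02)


@pytest.fixture(scope="session")
def hf_example(gp_example):
    return hm.haplotype_frequencies(gp_example)


@pytest.fixture(scope="session")
def linear_scenario():
    return hm.build_scenario("linear_n200_h005")


@pytest.fixture(scope="session")
def cheap_cfg():
    """Fast optimizer settings for tests that exercise mechanics rather
    than estimator quality."""
    return hm.FitConfig(
        n_starts=1, em_tol=1e-4, max_em_iter=30, inner_maxiter=40,
        swap_polish=False,
    )


@pytest.fixture(scope="session")
def small_dataset(linear_scenario):
    """A small simulated dataset (n=60) shared across fitting tests."""
    sc = hm.build_scenario("linear_n200_h005", n=60)
    return sc, hm.simulate_dataset(sc, seed=42)


@pytest.fixture(scope="session")
def small_fit(small_dataset, cheap_cfg):
    sc, data = small_dataset
    null = hm.fit_null(data, "linear", cheap_cfg)
    full = hm.fit_full(data, "linear", cheap_cfg, null=null)
    return sc, data, null, full


def random_valid_genetic_params(rng):
    """Rejection-sample a GeneticParams whose haplotype frequencies are
    valid (used by brute-force comparison tests)."""
    while True:
        p = rng.uniform(0.1, 0.9)
        qQ = rng.uniform(0.05, 0.6)
        qq = rng.uniform(0.05, 0.9 - qQ)
        d1 = rng.uniform(-0.05, 0.05)
        d2 = rng.uniform(-0.05, 0.05)
        try:
            gp = hm.GeneticParams(p, qQ, qq, d1, d2)
            hm.haplotype_frequencies(gp)
            return gp
        except hm.errors.HetmapError:
            continue
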