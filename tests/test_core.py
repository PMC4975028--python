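"""Elementary FGM operations: fitness map, founder placement, mutation law."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fgmcohorts import (
    ModelParams,
    Mutation,
    apply_mutation,
    exact_mean_fitness_factor,
    expected_mean_effect,
    fitness,
    initial_phenotype,
    log_fitness,
    sample_mutation,
    selection_coefficient,
)

finite_vectors = arrays(
    float,
    st.integers(1, 6),
    elements=st.floats(-5, 5, allow_nan=False, allow_infinity=False),
)


@pytest.mark.parametrize(
    "z, expected",
    [
        (np.zeros(4), 1.0),
        (np.array([math.sqrt(math.log(2))]), 0.5),
        (np.array([0.5, 0.5]), math.exp(-0.5)),
    ],
)
def test_fitness_examples(z, expected):
    assert fitness(z) == pytest.approx(expected, abs=1e-12)


def test_fitness_rejects_non_finite():
    with pytest.raises(ValueError):
        fitness(np.array([1.0, np.nan]))
    with pytest.raises(ValueError):
        log_fitness(np.array([np.inf]))


@given(finite_vectors)
def test_fitness_isotropy_and_log_consistency(z):
    """Gaussian fitness is invariant to trait permutation and sign flips,
    and exp(log_fitness) reproduces fitness to machine precision."""
    w = fitness(z)
    assert fitness(z[::-1].copy()) == pytest.approx(w, rel=1e-12)
    assert fitness(-z) == pytest.approx(w, rel=1e-12)
    assert abs(math.exp(log_fitness(z)) - w) <= 1e-12
    assert 0.0 < w <= 1.0
    if np.any(np.abs(z) > 1e-3):
        assert w < 1.0


@pytest.mark.parametrize("placement", ["axis", "random_direction"])
@pytest.mark.parametrize("w0", [1.0, 0.5, 0.037])
def test_initial_phenotype_hits_w0_exactly(placement, w0, rng):
    p = ModelParams(n=5, m=2, sigma2=0.001, U=0.0, N=10, w0=w0,
                    generations=1, placement=placement)
    z = initial_phenotype(p, rng)
    assert z.shape == (5,)
    assert fitness(z) == pytest.approx(w0, abs=1e-12)
    if placement == "axis":
        assert np.all(z[1:] == 0.0)
    if w0 == 1.0:
        assert np.all(z == 0.0)


def test_random_direction_norm_is_seed_independent():
    p = ModelParams(n=8, m=1, sigma2=0.0, U=0.0, N=10, w0=0.5,
                    generations=1, placement="random_direction")
    for seed in range(25):
        z = initial_phenotype(p, np.random.default_rng(seed))
        assert fitness(z) == pytest.approx(0.5, abs=1e-12)


def test_sample_mutation_full_pleiotropy_and_zero_variance(rng):
    p = ModelParams(n=4, m=4, sigma2=0.0, U=0.0, N=10, generations=1)
    mut = sample_mutation(p, rng, mutation_id=0, generation=3)
    assert sorted(mut.trait_indices) == [0, 1, 2, 3]
    assert mut.deltas == (0.0, 0.0, 0.0, 0.0)
    assert mut.origin_generation == 3


def test_sample_mutation_marginals(rng):
    """Per-trait deltas are Normal(0, sigma2) and each trait is hit with
    frequency m/n, to within 3 standard errors at 1e5 draws."""
    n, m, sigma2, draws = 10, 3, 0.004, 100_000
    p = ModelParams(n=n, m=m, sigma2=sigma2, U=0.0, N=10, generations=1)
    deltas = np.empty(draws * m)
    hits = np.zeros(n)
    for i in range(draws):
        mut = sample_mutation(p, rng, i, 0)
        deltas[i * m:(i + 1) * m] = mut.deltas
        hits[list(mut.trait_indices)] += 1
        assert len(set(mut.trait_indices)) == m
    se_mean = math.sqrt(sigma2 / deltas.size)
    assert abs(deltas.mean()) < 3 * se_mean
    # variance of the sample variance of a normal: 2 sigma^4 / k
    se_var = math.sqrt(2 * sigma2**2 / deltas.size)
    assert abs(deltas.var() - sigma2) < 3 * se_var
    freq = hits / draws
    se_freq = math.sqrt((m / n) * (1 - m / n) / draws)
    assert np.all(np.abs(freq - m / n) < 4 * se_freq)


def test_apply_mutation_is_additive_and_pure():
    z = np.array([0.1, -0.2, 0.3])
    mut = Mutation(0, 0, (0, 2), (0.05, -0.1))
    out = apply_mutation(z, mut)
    assert np.allclose(out, [0.15, -0.2, 0.2])
    assert np.allclose(z, [0.1, -0.2, 0.3])  # input untouched
    undo = Mutation(1, 0, (0, 2), (-0.05, 0.1))
    assert np.allclose(apply_mutation(out, undo), z, atol=1e-15)


def test_apply_mutation_out_of_range():
    with pytest.raises(IndexError):
        apply_mutation(np.zeros(2), Mutation(0, 0, (5,), (0.1,)))


def test_mutation_validation():
    with pytest.raises(ValueError):
        Mutation(0, 0, (1, 1), (0.1, 0.2))
    with pytest.raises(ValueError):
        Mutation(0, 0, (1,), (0.1, 0.2))


@pytest.mark.parametrize(
    "wp, wo, s",
    [(0.5, 0.5, 0.0), (0.5, 0.55, 0.1), (1.0, 0.99, -0.01)],
)
def test_selection_coefficient(wp, wo, s):
    assert selection_coefficient(wp, wo) == pytest.approx(s)


def test_selection_coefficient_domain():
    with pytest.raises(ValueError):
        selection_coefficient(0.0, 0.5)


def test_mean_effect_first_order_vs_exact():
    assert expected_mean_effect(3, 0.004) == pytest.approx(-0.012)
    assert expected_mean_effect(5, 0.0) == 0.0
    exact = exact_mean_fitness_factor(3, 0.004) - 1.0
    assert exact == pytest.approx(-0.011881, abs=5e-6)
    assert abs(exact - (-0.012)) / 0.012 < 0.01


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(n=3, m=4, sigma2=0.01, U=0.001, N=100, generations=10)
    with pytest.raises(ValueError):
        ModelParams(n=3, m=1, sigma2=-0.01, U=0.001, N=100, generations=10)
    with pytest.raises(ValueError):
        ModelParams(n=3, m=1, sigma2=0.01, U=0.001, N=100, w0=0.0, generations=10)
    with pytest.raises(ValueError):
        ModelParams(n=3, m=1, sigma2=0.01, U=0.001, N=100, generations=10,
                    placement="corner")


def test_from_mean_effect_conversion():
    p = ModelParams.from_mean_effect(E_S=-0.012, m=3, n=10, U=0.001, N=100,
                                     generations=10)
    assert p.sigma2 == pytest.approx(0.004)
    assert p.mean_effect == pytest.approx(-0.012)
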