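"""The constrained MLE: likelihood, both search modes, boundary refinement,
spurious calls and the supporting comparison estimators."""

import numpy as np
import pytest

from methpat import (
    ErrorModel,
    PatternCounts,
    PatternDistribution,
    binomial_closed_form,
    boundary_refine,
    call_spurious,
    encode_pattern,
    estimate_fast,
    estimate_slow,
    full_transition_matrix,
    inversion_estimate,
    log_likelihood,
    marginal_methylation,
    naive_estimate,
)
from conftest import random_counts


def test_log_likelihood_identity_error_model():
    """With M = I the likelihood at theta = y/N is the multinomial entropy sum."""
    counts = PatternCounts(2, {"00": 10, "01": 5, "10": 3, "11": 2})
    model = ErrorModel(2, 0.0, 0.0)
    theta = naive_estimate(counts)
    y = np.array([10, 5, 3, 2], dtype=float)
    expected = float(y @ np.log(y / 20))
    assert log_likelihood(theta, counts, model) == pytest.approx(expected, abs=1e-12)


def test_log_likelihood_minus_inf_on_unreachable_pattern():
    counts = PatternCounts(2, {"00": 10, "11": 5})
    model = ErrorModel(2, 0.0, 0.0)
    theta = PatternDistribution.from_dict(2, {"00": 1.0})
    assert log_likelihood(theta, counts, model) == -np.inf


def test_log_likelihood_dense_oracle():
    counts = PatternCounts(2, {"00": 10, "01": 5, "10": 3, "11": 2})
    model = ErrorModel(2, 0.05, 0.02)
    theta = PatternDistribution(2, np.arange(1, 5), np.full(4, 0.25))
    phi = theta.to_dense() @ full_transition_matrix(model)
    expected = float(counts.dense_counts() @ np.log(phi))
    assert log_likelihood(theta, counts, model) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("mode", ["slow", "fast"])
def test_error_free_mle_is_read_proportions(rng, mode):
    """With eps = eta = 0 the MLE reduces to the plain multinomial MLE y/N."""
    for n in (2, 4):
        counts = random_counts(rng, n, n_patterns=2**n // 2)
        model = ErrorModel(n, 0.0, 0.0)
        fit = estimate_slow(counts, model) if mode == "slow" else estimate_fast(counts, model)
        for pat, y in counts.counts.items():
            assert fit.theta_hat.prob(encode_pattern(pat)) == pytest.approx(
                y / counts.n_read, abs=1e-12
            )
        assert call_spurious(fit) == frozenset()


def test_mle_beats_dirichlet_random_search(rng):
    """The optimiser's log-likelihood dominates a 1e5-point random search
    of the simplex (n=2)."""
    counts = random_counts(rng, 2, n_patterns=4, n_read=200)
    model = ErrorModel(2, 0.04, 0.01)
    fit = estimate_slow(counts, model)
    M = full_transition_matrix(model)
    y = counts.dense_counts()
    draws = rng.dirichlet(np.ones(4), size=100_000)
    search_ll = (y @ np.log(draws @ M).T).max()
    assert fit.log_likelihood >= search_ll - 1e-6


def test_mle_unique_across_restarts(rng, table1):
    """Random interior restarts converge to the same point (unique MLE)."""
    _, counts, model = table1
    support_size = counts.observed_indices().size
    baseline = estimate_fast(counts, model)
    for _ in range(10):
        start = rng.dirichlet(np.ones(support_size))
        fit = estimate_fast(counts, model, theta0=start)
        for k in counts.observed_indices():
            assert fit.theta_hat.prob(int(k)) == pytest.approx(
                baseline.theta_hat.prob(int(k)), abs=1e-5
            )


def test_mle_dominates_naive_projection(table1):
    _, counts, model = table1
    fit = estimate_fast(counts, model)
    assert fit.log_likelihood >= log_likelihood(naive_estimate(counts), counts, model)


def test_support_subset_when_no_read_error(rng):
    """With eta = 0 the reported support is contained in the observed one
    (slow mode over all patterns)."""
    for n in (3, 4):
        counts = random_counts(rng, n, n_patterns=2 ** (n - 1), n_read=400)
        model = ErrorModel(n, 0.03, 0.0)
        fit = estimate_slow(counts, model)
        observed = set(int(k) for k in counts.observed_indices())
        assert set(int(k) for k in fit.theta_hat.support) <= observed


def test_skew_towards_less_methylated_when_no_read_error(rng):
    """With eta = 0 non-conversion only adds methylation, so the corrected
    distribution has mean methylation <= that of the raw proportions."""
    from methpat import methylation_count
    from methpat.patterns import index_bits

    for n in (3, 5):
        counts = random_counts(rng, n, n_patterns=2 ** (n - 1), n_read=600)
        model = ErrorModel(n, 0.04, 0.0)
        fit = estimate_slow(counts, model)

        def mean_meth(dist):
            bits = index_bits(dist.support, n)
            return float(dist.probs @ bits.sum(axis=1))

        assert mean_meth(fit.theta_hat) <= mean_meth(naive_estimate(counts)) + 1e-9


def test_n1_matches_binomial_closed_form():
    """Single-site estimation equals inverting the 2x2 matrix and clipping."""
    model = ErrorModel(1, 0.02, 0.01)
    for y1 in (0, 3, 40, 97, 100):
        counts = PatternCounts(1, {"0": 100 - y1, "1": y1})
        fit = estimate_slow(counts, model)
        closed = binomial_closed_form(counts, model)
        assert fit.theta_hat.prob(2) == pytest.approx(closed.prob(2), abs=1e-5)


def test_boundary_refine_snaps_negligible_component(table1):
    """A 1e-12 component on a truly spurious pattern is snapped to exact 0."""
    _, counts, model = table1
    obs = counts.observed_indices()
    probs = counts.count_vector(obs) / counts.n_read
    k_spurious = encode_pattern("000010")  # one conversion error from 000000
    i = int(np.searchsorted(obs, k_spurious))
    probs[i] = 1e-12
    theta = PatternDistribution(6, obs, probs / probs.sum(), validate=False)
    refined, ll, snapped, _, _ = boundary_refine(theta, counts, model)
    assert k_spurious in snapped
    assert refined.prob(k_spurious) == 0.0


def test_boundary_refine_leaves_interior_point_alone():
    counts = PatternCounts(2, {"00": 40, "01": 30, "10": 20, "11": 10})
    model = ErrorModel(2, 0.01, 0.01)
    theta = PatternDistribution(2, np.arange(1, 5), np.array([0.4, 0.3, 0.2, 0.1]))
    refined, _, snapped, _, _ = boundary_refine(theta, counts, model)
    assert snapped == ()
    assert np.allclose(refined.probs, theta.probs)


def test_spurious_calls_are_exact_zeros(table1_fast, table1):
    _, counts, _ = table1
    observed = set(int(k) for k in counts.observed_indices())
    spurious = call_spurious(table1_fast)
    assert spurious <= observed
    for k in spurious:
        assert table1_fast.theta_hat.prob(k) == 0.0
    for k in table1_fast.theta_hat.support:
        assert int(k) not in spurious


def test_marginal_methylation():
    assert np.allclose(
        marginal_methylation(PatternDistribution.from_dict(3, {"111": 1.0})), [1, 1, 1]
    )
    uniform = PatternDistribution(3, np.arange(1, 9), np.full(8, 1 / 8))
    assert np.allclose(marginal_methylation(uniform), [0.5, 0.5, 0.5])
    mix = PatternDistribution.from_dict(2, {"10": 0.5, "01": 0.5})
    assert np.allclose(marginal_methylation(mix), [0.5, 0.5])


def test_inversion_estimate_leaves_simplex(table1):
    """Naive matrix inversion produces negative components on real data —
    the reason constrained optimisation is needed at all."""
    _, counts, model = table1
    inverted = inversion_estimate(counts, model)
    assert np.any(inverted < 0)
    assert inverted.sum() == pytest.approx(1.0, abs=1e-8)


def test_slow_mode_guard():
    counts = PatternCounts(9, {"0" * 9: 5, "1" * 9: 5})
    model = ErrorModel(9, 0.01, 0.01)
    with pytest.raises(ValueError, match="slow mode"):
        estimate_slow(counts, model)
    # the override works and still recovers a sane answer
    fit = estimate_slow(counts, model, force=True)
    assert fit.theta_hat.probs.sum() == pytest.approx(1.0)


def test_fast_mode_pattern_limit_warning(rng):
    counts = random_counts(rng, 9, n_patterns=250, n_read=5000)
    model = ErrorModel(9, 0.005, 0.005)
    with pytest.warns(UserWarning, match="soft limit"):
        estimate_fast(counts, model, max_iter=50)
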