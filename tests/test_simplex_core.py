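"""Weight-distribution geometry: construction, MWU, capped projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import mwu_oracle, projection_oracle

from reconboost import (
    GeneWeights,
    ReweightConfig,
    classify_genes,
    indicator_weights,
    mwu_step,
    project_capped,
    relative_entropy,
    uniform_weights,
)

# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [1, 4, 1000])
def test_uniform_weights_are_uniform(n):
    w = uniform_weights(n)
    np.testing.assert_allclose(w.weights, np.full(n, 1.0 / n))
    assert abs(w.weights.sum() - 1.0) <= 1e-9


def test_uniform_weights_rejects_nonpositive_count():
    with pytest.raises(ValueError):
        uniform_weights(0)


@pytest.mark.parametrize(
    "S, n, expected",
    [
        ([0, 1], 4, [0.5, 0.5, 0.0, 0.0]),
        ([2], 3, [0.0, 0.0, 1.0]),
        (list(range(5)), 5, [0.2] * 5),
    ],
)
def test_indicator_weights(S, n, expected):
    np.testing.assert_allclose(indicator_weights(S, n).weights, expected)


def test_indicator_weights_rejects_empty_set():
    with pytest.raises(ValueError):
        indicator_weights([], 4)
    with pytest.raises(ValueError):
        indicator_weights(np.zeros(4, dtype=bool), 4)


def test_gene_weights_validation():
    with pytest.raises(ValueError):
        GeneWeights(np.array([0.7, 0.7]))  # sum != 1
    with pytest.raises(ValueError):
        GeneWeights(np.array([1.2, -0.2]))  # negative entry
    with pytest.raises(ValueError):
        GeneWeights(np.array([0.5, 0.5]), cap=0.3)  # entries exceed cap
    with pytest.raises(ValueError):
        GeneWeights(np.full(4, 0.25), cap=0.2)  # cap*n < 1 infeasible


# ---------------------------------------------------------------------------
# relative entropy
# ---------------------------------------------------------------------------


def test_relative_entropy_identity_is_zero():
    p = GeneWeights(np.array([0.1, 0.2, 0.3, 0.4]))
    assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-12)


def test_relative_entropy_half_support_is_ln2():
    n = 8
    chi = indicator_weights(list(range(n // 2)), n)
    assert relative_entropy(chi, uniform_weights(n)) == pytest.approx(np.log(2))


def test_relative_entropy_hand_value():
    p = GeneWeights(np.array([0.8, 0.2]))
    q = GeneWeights(np.array([0.5, 0.5]))
    expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
    assert relative_entropy(p, q) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.19274, abs=5e-6)


def test_relative_entropy_support_violation_raises():
    p = GeneWeights(np.array([0.5, 0.5]))
    q = GeneWeights(np.array([1.0, 0.0]))
    with pytest.raises(ValueError):
        relative_entropy(p, q)
    # 0 log 0 convention: fine the other way around
    assert relative_entropy(q, p) == pytest.approx(np.log(2))


# ---------------------------------------------------------------------------
# multiplicative update
# ---------------------------------------------------------------------------


def test_mwu_step_eta_zero_is_identity():
    p = GeneWeights(np.array([0.1, 0.6, 0.3]))
    out = mwu_step(p, np.array([3.0, 1.0, 2.0]), eta=0.0)
    np.testing.assert_allclose(out.weights, p.weights, atol=1e-12)


def test_mwu_step_constant_gradient_is_identity():
    p = GeneWeights(np.array([0.1, 0.6, 0.3]))
    out = mwu_step(p, np.full(3, 7.5), eta=2.0)
    np.testing.assert_allclose(out.weights, p.weights, atol=1e-12)


def test_mwu_step_hand_value():
    # exp(-ln 4) = 1/4: second gene's weight shrinks to 0.125 pre-normalization
    p = GeneWeights(np.array([0.5, 0.5]))
    out = mwu_step(p, np.array([0.0, np.log(4.0)]), eta=1.0)
    np.testing.assert_allclose(out.weights, [0.8, 0.2], atol=1e-12)


def test_mwu_step_rejects_negative_eta():
    with pytest.raises(ValueError):
        mwu_step(uniform_weights(3), np.zeros(3), eta=-0.1)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    n=st.integers(2, 5),
    seed=st.integers(0, 10**6),
    eta=st.floats(0.1, 5.0),
)
def test_mwu_step_matches_numeric_minimizer(n, seed, eta):
    """Closed form equals the minimizer of the linearized-loss + KL objective."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n))
    m = rng.uniform(0, 3, n)
    ours = mwu_step(GeneWeights(p), m, eta).weights
    np.testing.assert_allclose(ours, mwu_oracle(p, m, eta), atol=1e-5)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(n=st.integers(1, 50), seed=st.integers(0, 10**6), eta=st.floats(0, 10))
def test_mwu_step_returns_simplex_vector(n, seed, eta):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n) * 0.3)
    m = rng.uniform(0, 5, n)
    out = mwu_step(GeneWeights(p), m, eta).weights
    assert np.all(out >= 0)
    assert abs(out.sum() - 1.0) <= 1e-9


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    n=st.integers(2, 30),
    s_size=st.integers(1, 29),
    seed=st.integers(0, 10**6),
    eta=st.floats(0, 5),
)
def test_mwu_marginal_on_low_error_set_never_decreases(n, s_size, seed, eta):
    """When every gene in S has error <= every gene outside, p_S cannot drop."""
    if s_size >= n:
        s_size = n - 1
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, s_size, replace=False)] = True
    m = np.empty(n)
    m[mask] = rng.uniform(0.0, 1.0, s_size)
    m[~mask] = rng.uniform(m[mask].max(), m[mask].max() + 2.0, n - s_size)
    before = GeneWeights(p)
    after = mwu_step(before, m, eta)
    assert after.marginal(mask) >= before.marginal(mask) - 1e-12


# ---------------------------------------------------------------------------
# capped projection
# ---------------------------------------------------------------------------


def test_project_capped_noop_within_cap():
    p = GeneWeights(np.array([0.3, 0.3, 0.4]))
    out = project_capped(p, cap=0.5)
    np.testing.assert_allclose(out.weights, p.weights, atol=1e-12)


def test_project_capped_single_pass():
    p = GeneWeights(np.array([0.9, 0.05, 0.05]))
    out = project_capped(p, cap=0.5)
    np.testing.assert_allclose(out.weights, [0.5, 0.25, 0.25], atol=1e-12)


def test_project_capped_needs_second_pass():
    # first pass caps 0.6 and rescales 0.35 -> 0.525 over the cap
    p = GeneWeights(np.array([0.6, 0.35, 0.05]))
    out = project_capped(p, cap=0.4)
    np.testing.assert_allclose(out.weights, [0.4, 0.4, 0.2], atol=1e-12)
    np.testing.assert_allclose(
        out.weights, projection_oracle(p.weights, 0.4), atol=1e-5
    )


def test_project_capped_rejects_infeasible_cap():
    with pytest.raises(ValueError):
        project_capped(uniform_weights(4), cap=0.2)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(n=st.integers(2, 5), seed=st.integers(0, 10**6))
def test_project_capped_matches_numeric_kl_projection(n, seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n) * 0.5)
    cap = rng.uniform(1.0 / n, 1.0)
    ours = project_capped(GeneWeights(p), cap).weights
    np.testing.assert_allclose(ours, projection_oracle(p, cap), atol=1e-5)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(n=st.integers(2, 40), seed=st.integers(0, 10**6))
def test_project_capped_invariants(n, seed):
    """Simplex closure, cap respected, idempotence, max entry non-increasing."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n) * 0.2)
    cap = rng.uniform(1.0 / n, 1.0)
    out = project_capped(GeneWeights(p), cap)
    assert np.all(out.weights >= 0)
    assert abs(out.weights.sum() - 1.0) <= 1e-9
    assert out.weights.max() <= cap + 1e-12
    assert out.weights.max() <= p.max() + 1e-12
    twice = project_capped(out, cap)
    np.testing.assert_allclose(twice.weights, out.weights, atol=1e-12)


def test_project_capped_preserves_proportions_below_cap():
    p = GeneWeights(np.array([0.5, 0.3, 0.15, 0.05]))
    out = project_capped(p, cap=0.4).weights
    # uncapped entries keep their relative proportions
    assert out[1] / out[2] == pytest.approx(0.3 / 0.15, rel=1e-9)
    assert out[2] / out[3] == pytest.approx(0.15 / 0.05, rel=1e-9)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_classify_genes_uniform_all_informative():
    mask = classify_genes(uniform_weights(10), delta=0.2)
    assert mask.all()


def test_classify_genes_threshold():
    p = GeneWeights(np.array([0.5, 0.3, 0.1, 0.05, 0.05]))
    mask = classify_genes(p, delta=0.2)  # threshold 0.8/5 = 0.16
    np.testing.assert_array_equal(mask, [True, True, False, False, False])


def test_classify_genes_indicator_recovers_exactly_the_set():
    chi = indicator_weights([1, 3], 5)
    mask = classify_genes(chi, delta=0.2)
    np.testing.assert_array_equal(mask, [False, True, False, True, False])


def test_classify_genes_strict_at_threshold():
    # entry exactly at (1-delta)/n is not informative
    n, delta = 4, 0.2
    thr = (1 - delta) / n
    p = GeneWeights(np.array([thr, thr, thr, 1 - 3 * thr]))
    mask = classify_genes(p, delta)
    np.testing.assert_array_equal(mask, [False, False, False, True])


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def test_reweight_config_cap_rule():
    cfg = ReweightConfig(epsilon=0.5, s_size=50)
    assert cfg.cap_for(100) == pytest.approx(1.0 / (0.5 * 50))
    # default |S| = n/2
    assert ReweightConfig(epsilon=0.5).cap_for(100) == pytest.approx(0.04)


def test_reweight_config_validation():
    with pytest.raises(ValueError):
        ReweightConfig(epsilon=1.5)
    with pytest.raises(ValueError):
        ReweightConfig(delta=1.0)
    with pytest.raises(ValueError):
        ReweightConfig(gradient_scale="bogus")
    with pytest.raises(ValueError):
        # cap*n < 1: 1/(1*200) * 100 = 0.5
        ReweightConfig(epsilon=1.0, s_size=200).cap_for(100)
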