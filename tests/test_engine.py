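import numpy as np
import pytest

from saflex.alphabet import StructuralLetter
from saflex.descriptors import FragmentSeries
from saflex.engine import (
    EncodingFailure,
    MultiChainFragmentSeries,
    emission_log_matrix,
    encode,
    entropy_neff,
    forward_backward,
    forward_backward_from_log_emissions,
    log_emission,
    log_emission_consensus,
    map_decode,
    map_joint_log_score,
    posterior,
)
from saflex.synthetic import (
    SyntheticSpec,
    brute_force_encode,
    mask_fragments,
    random_alphabet,
    sample_chain,
)

LOG_2PI = np.log(2 * np.pi)


def _std_letter(mu=None, sigma=None):
    return StructuralLetter(code="A1", legacy_code="A", sl_class="helix", frequency=1.0,
                            mu=np.zeros(4) if mu is None else mu,
                            sigma=np.eye(4) if sigma is None else sigma)


class TestLogEmission:
    def test_bivariate_standard_normal_at_mean(self):
        val = log_emission(_std_letter(), [0, 0, np.nan, np.nan], {1, 2})
        assert val == pytest.approx(-LOG_2PI, abs=1e-12)

    def test_full_standard_normal_at_mean(self):
        assert log_emission(_std_letter(), np.zeros(4), {1, 2, 3, 4}) == pytest.approx(
            -2 * LOG_2PI, abs=1e-12)

    def test_empty_availability_gives_density_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        letter = _std_letter(mu=rng.normal(size=4), sigma=A @ A.T + np.eye(4))
        assert log_emission(letter, np.full(4, np.nan), set()) == 0.0

    def test_matches_scipy_logpdf_on_restrictions(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(3)
        for _ in range(10):
            A = rng.normal(size=(4, 4))
            letter = _std_letter(mu=rng.normal(size=4), sigma=A @ A.T + 0.5 * np.eye(4))
            J = sorted(rng.choice([1, 2, 3, 4], size=rng.integers(1, 5), replace=False))
            x = np.full(4, np.nan)
            idx = [d - 1 for d in J]
            x[idx] = rng.normal(size=len(J))
            want = multivariate_normal(letter.mu[idx],
                                       letter.sigma[np.ix_(idx, idx)]).logpdf(x[idx])
            assert log_emission(letter, x, set(J)) == pytest.approx(want, rel=1e-12)

    def test_indefinite_restriction_names_letter(self):
        letter = _std_letter(sigma=np.diag([1.0, -1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="A1"):
            log_emission(letter, np.zeros(4), {1, 2})


from oracle_utils import gauss_legendre_marginal as _gauss_legendre_marginal


def test_restricted_gaussian_equals_numerical_marginalization():
    """J-restriction is exact marginalization of the 4-D Gaussian."""
    rng = np.random.default_rng(42)
    subsets = [{1}, {2}, {4}, {1, 2}, {1, 3}, {2, 4}, {3, 4}, {1, 2, 3},
               {1, 2, 4}, {2, 3, 4}]
    cases = 0
    while cases < 20:
        A = rng.normal(size=(4, 4))
        sigma = A @ A.T + 0.5 * np.eye(4)
        mu = rng.normal(scale=2.0, size=4)
        J = subsets[cases % len(subsets)]
        letter = _std_letter(mu=mu, sigma=sigma)
        x = np.full(4, np.nan)
        idx = [d - 1 for d in sorted(J)]
        x[idx] = mu[idx] + rng.normal(scale=1.0, size=len(idx))
        want = _gauss_legendre_marginal(mu, sigma, x, J)
        got = log_emission(letter, x, J)
        assert got == pytest.approx(want, abs=1e-6)
        cases += 1


class TestConsensusEmission:
    def test_single_chain_reduction(self):
        letter = _std_letter()
        x = np.array([0.3, -0.2, 0.1, 0.5])
        J = {1, 2, 3, 4}
        assert log_emission_consensus(letter, [(x, J)]) == log_emission(letter, x, J)

    def test_identical_observations_double(self):
        letter = _std_letter()
        x = np.array([0.3, -0.2, 0.1, 0.5])
        one = log_emission(letter, x, {1, 2, 3, 4})
        assert log_emission_consensus(letter, [(x, {1, 2, 3, 4})] * 2) == pytest.approx(2 * one)

    def test_all_missing_chain_drops_out(self):
        letter = _std_letter()
        x = np.array([0.3, -0.2, 0.1, 0.5])
        obs = [(x, {1, 2, 3, 4}), (np.full(4, np.nan), set())]
        assert log_emission_consensus(letter, obs) == log_emission(letter, x, {1, 2, 3, 4})


class TestForwardBackwardToy:
    """Two-letter toy with hand-enumerated paths:
    start 1/2, pi=[[.9,.1],[.2,.8]], e1=(1,1), e2=(2,1) ->
    path probabilities .9, .05, .2, .4 summing to 1.55."""

    @pytest.fixture()
    def table(self):
        log_e = np.log(np.array([[1.0, 1.0], [2.0, 1.0]]))
        return forward_backward_from_log_emissions(
            log_e, np.array([[0.9, 0.1], [0.2, 0.8]]))

    def test_evidence_and_forward(self, table):
        assert np.exp(table.log_evidence) == pytest.approx(1.55, rel=1e-12)
        np.testing.assert_allclose(np.exp(table.log_forward[1]), [1.1, 0.45], rtol=1e-12)

    def test_posterior_row(self, table):
        np.testing.assert_allclose(posterior(table)[1], [1.1 / 1.55, 0.45 / 1.55],
                                   rtol=1e-12)

    def test_map_path_and_score(self, table):
        assert list(map_decode(table)) == [0, 0]
        assert np.exp(map_joint_log_score(table)) == pytest.approx(0.9, rel=1e-12)

    def test_position_invariant_evidence(self, table):
        from scipy.special import logsumexp
        per_pos = logsumexp(table.log_forward + table.log_backward, axis=1)
        np.testing.assert_allclose(per_pos, table.log_evidence, atol=1e-8)


def test_single_all_missing_fragment_gives_uniform_posterior(toy_alphabet):
    series = FragmentSeries(values=np.full((1, 4), np.nan), available=[set()])
    table = forward_backward(series, toy_alphabet)
    assert np.exp(table.log_evidence) == pytest.approx(1.0, rel=1e-12)
    np.testing.assert_allclose(posterior(table)[0], [0.5, 0.5], rtol=1e-12)


class TestEntropyNeff:
    def test_dirac(self):
        ent, neff = entropy_neff([1.0, 0.0, 0.0])
        assert ent == 0.0 and neff == 1.0

    @pytest.mark.parametrize("m", [2, 5, 27])
    def test_uniform(self, m):
        ent, neff = entropy_neff(np.full(m, 1.0 / m))
        assert ent == pytest.approx(np.log(m), rel=1e-12)
        assert neff == pytest.approx(m, rel=1e-12)

    def test_half_half(self):
        ent, neff = entropy_neff([0.5, 0.5, 0.0, 0.0])
        assert ent == pytest.approx(np.log(2)) and neff == pytest.approx(2.0)


def _random_instance(rng):
    """Random small synthetic instance, possibly with missing descriptors."""
    m = int(rng.integers(2, 5))
    n = int(rng.integers(1, 7))
    k = int(rng.integers(1, 4))
    spec = SyntheticSpec(m=m, n=n, k=k, seed=int(rng.integers(2**31)),
                         mean_separation=float(rng.uniform(0.5, 4.0)))
    a = random_alphabet(spec)
    _, multi = sample_chain(a, n, k, seed=int(rng.integers(2**31)))
    if rng.random() < 0.6:  # degrade availability on some fragments/chains
        chains = []
        for s in multi.per_chain:
            drops = {}
            for i in range(n):
                if rng.random() < 0.35:
                    keep = [d for d in (1, 2, 3, 4) if rng.random() < 0.5]
                    drops[i] = frozenset(keep)
            chains.append(mask_fragments(s, drops))
        multi = MultiChainFragmentSeries(per_chain=chains)
    return multi if k > 1 else multi.per_chain[0], a


@pytest.mark.parametrize("batch_seed", [0, 1])
def test_engine_matches_enumeration_oracle(batch_seed):
    """Evidence, POST and MAP score agree with exhaustive path enumeration."""
    rng = np.random.default_rng(1234 + batch_seed)
    for _ in range(60):
        series, a = _random_instance(rng)
        ev, post, best, best_p = brute_force_encode(series, a)
        table = forward_backward(series, a)
        assert np.exp(table.log_evidence) == pytest.approx(ev, rel=1e-10)
        np.testing.assert_allclose(posterior(table), post, rtol=1e-9, atol=1e-12)
        assert np.exp(map_joint_log_score(table)) == pytest.approx(best_p, rel=1e-10)
        # the decoded path attains the enumerated maximum
        decoded = tuple(map_decode(table))
        log_e = emission_log_matrix(series, a)
        logp = -np.log(a.m) + log_e[0, decoded[0]] + sum(
            np.log(a.transition[decoded[i - 1], decoded[i]]) + log_e[i, decoded[i]]
            for i in range(1, len(decoded)))
        assert np.exp(logp) == pytest.approx(best_p, rel=1e-10)


def test_map_dominates_random_paths(synthetic_alphabet):
    rng = np.random.default_rng(5)
    _, multi = sample_chain(synthetic_alphabet, 12, 1, seed=6)
    series = multi.per_chain[0]
    table = forward_backward(series, synthetic_alphabet)
    log_e = emission_log_matrix(series, synthetic_alphabet)
    m, n = synthetic_alphabet.m, series.n
    best = map_joint_log_score(table)
    logpi = np.log(synthetic_alphabet.transition)
    for _ in range(1000):
        path = rng.integers(m, size=n)
        logp = -np.log(m) + log_e[0, path[0]] + sum(
            logpi[path[i - 1], path[i]] + log_e[i, path[i]] for i in range(1, n))
        assert logp <= best + 1e-9


def test_encode_consensus_k1_identical_to_single(synthetic_alphabet):
    _, multi = sample_chain(synthetic_alphabet, 8, 1, seed=2)
    single = encode(multi.per_chain[0], synthetic_alphabet)
    cons = encode(multi, synthetic_alphabet)
    assert single.map_sequence == cons.map_sequence
    np.testing.assert_array_equal(single.post, cons.post)
    assert single.log_evidence == cons.log_evidence


def test_encode_consensus_chain_order_invariant(synthetic_alphabet):
    _, multi = sample_chain(synthetic_alphabet, 8, 3, seed=3)
    fwd = encode(multi, synthetic_alphabet)
    rev = encode(MultiChainFragmentSeries(per_chain=multi.per_chain[::-1]),
                 synthetic_alphabet)
    assert fwd.map_sequence == rev.map_sequence
    np.testing.assert_allclose(fwd.post, rev.post, rtol=1e-12)


def test_consensus_reduces_uncertainty(synthetic_alphabet):
    """Replicates sharing one hidden path sharpen the posterior."""
    means = []
    for seed in range(5):
        _, multi = sample_chain(synthetic_alphabet, 30, 2, seed=seed)
        cons = encode(multi, synthetic_alphabet)
        singles = [encode(s, synthetic_alphabet) for s in multi.per_chain]
        means.append((cons.ent.mean(), [s.ent.mean() for s in singles]))
    for cons_mean, single_means in means:
        assert all(cons_mean <= sm + 1e-12 for sm in single_means)


def test_masking_never_decreases_entropy_context_free():
    """n=1, no context: with equal isotropic covariances and the observation
    at one letter's mean, every descriptor pulls toward that letter, so any
    restriction of J provably flattens the posterior (the log likelihood
    ratio is a sum of non-negative per-coordinate terms)."""
    from saflex.alphabet import StructuralAlphabet

    mu1 = np.array([5.4, 5.0, 5.4, 2.0])
    mu2 = np.array([6.5, 9.8, 6.5, 0.3])
    letters = [
        _std_letter(mu=mu1, sigma=np.eye(4)),
        StructuralLetter(code="B1", legacy_code="M", sl_class="strand",
                         frequency=0.5, mu=mu2, sigma=np.eye(4)),
    ]
    a = StructuralAlphabet(letters=letters, transition=np.full((2, 2), 0.5))
    series = FragmentSeries.from_values(mu1.reshape(1, 4))
    ents = {}
    for J in ({1, 2, 3, 4}, {1, 2, 3}, {1, 2}, {1}, set()):
        sub = mask_fragments(series, {0: frozenset(J)})
        ents[frozenset(J)] = encode(sub, a).ent[0]
    full_ent = ents[frozenset({1, 2, 3, 4})]
    for J, ent in ents.items():
        if J != frozenset({1, 2, 3, 4}):
            assert ent >= full_ent - 1e-12
    assert ents[frozenset()] == pytest.approx(np.log(2))


def test_all_minus_inf_emissions_raise_encoding_failure():
    log_e = np.array([[-np.inf, -np.inf]])
    with pytest.raises(EncodingFailure):
        forward_backward_from_log_emissions(log_e, np.full((2, 2), 0.5))


def test_post_rows_sum_to_one(alphabet27):
    _, multi = sample_chain(alphabet27, 40, 1, seed=9)
    res = encode(multi.per_chain[0], alphabet27)
    np.testing.assert_allclose(res.post.sum(axis=1), 1.0, atol=1e-9)
    assert res.ent.min() >= 0 and res.ent.max() <= np.log(27) + 1e-12
    assert res.neff.min() >= 1 - 1e-12 and res.neff.max() <= 27 + 1e-9
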