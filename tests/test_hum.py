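import itertools

import numpy as np
import pytest

from preconrisk import (
    DecisionConfig,
    classify_set,
    hum_bootstrap_ci,
    hum_ipw,
    hum_nonparametric,
    optimism_correct,
)


def _tilted_profiles(rng, n_per_class, strength=1.5, K=4):
    """Profiles mildly concentrated on their own class (informative but noisy)."""
    out = []
    for k in range(K):
        alpha = np.ones(K)
        alpha[k] += strength
        out.append(rng.dirichlet(alpha, size=n_per_class))
    return out


def test_classify_vertices_is_identity():
    assignment, correct = classify_set(np.eye(4))
    assert assignment == (1, 2, 3, 4)
    assert correct == 1


def test_classify_all_uniform_ties_score_zero():
    profiles = np.full((4, 4), 0.25)
    _, correct = classify_set(profiles)
    assert correct == 0


def test_classify_swapped_pair_scores_zero():
    profiles = np.eye(4)[[1, 0, 2, 3]]  # classes 1 and 2 swapped
    assignment, correct = classify_set(profiles)
    assert assignment == (2, 1, 3, 4)
    assert correct == 0


def test_perfectly_separated_profiles_give_hum_one():
    rng = np.random.default_rng(0)
    profs = [np.tile(np.eye(4)[k], (3, 1)) for k in range(4)]
    est = hum_nonparametric(profs, mode="exact")
    assert est.value == 1.0
    assert est.mode == "exact"


def test_exact_mode_matches_brute_force_tuple_loop():
    """Vectorized exact enumeration equals a literal loop over all tuples
    scored one at a time with the forced-choice classifier."""
    rng = np.random.default_rng(5)
    profs = _tilted_profiles(rng, 4)
    est = hum_nonparametric(profs, mode="exact")
    total = 0
    for tup in itertools.product(*[range(len(p)) for p in profs]):
        P = np.vstack([profs[k][tup[k]] for k in range(4)])
        total += classify_set(P)[1]
    assert est.value == pytest.approx(total / 4**4)


def test_mc_mode_unbiased_for_exact_over_seeds():
    rng = np.random.default_rng(6)
    profs = _tilted_profiles(rng, 5)
    exact = hum_nonparametric(profs, mode="exact").value
    values = [
        hum_nonparametric(profs, mode="monte_carlo", mc_draws=20_000, seed=s).value
        for s in range(8)
    ]
    se_mean = np.sqrt(exact * (1 - exact) / (20_000 * 8))
    assert np.mean(values) == pytest.approx(exact, abs=3 * se_mean)


def test_forced_choice_chance_rate_is_one_over_k_factorial():
    """With profiles carrying no class information the correct-classification
    rate of the decision rule is 1/4! (fresh profiles per tuple)."""
    rng = np.random.default_rng(42)
    N = 20_000
    hits = sum(classify_set(rng.dirichlet(np.ones(4), size=4))[1] for _ in range(N))
    rate = hits / N
    se = np.sqrt((1 / 24) * (1 - 1 / 24) / N)
    assert rate == pytest.approx(1 / 24, abs=3 * se)


def test_exact_mode_refused_above_tuple_ceiling():
    rng = np.random.default_rng(1)
    profs = _tilted_profiles(rng, 40)
    with pytest.raises(ValueError, match="ceiling"):
        hum_nonparametric(profs, mode="exact", max_exact_tuples=10_000)


def test_ipw_reduces_to_unweighted_with_unit_probabilities():
    rng = np.random.default_rng(2)
    profs = _tilted_profiles(rng, 6)
    pis = [np.ones(len(p)) for p in profs]
    unweighted = hum_nonparametric(profs, mode="exact").value
    weighted = hum_ipw(profs, pis, mode="exact").value
    assert weighted == pytest.approx(unweighted, abs=1e-12)


def test_ipw_invariant_to_constant_verification_probability():
    """Equal pi_R cancel in the ratio: the adjusted and unadjusted
    estimators coincide exactly."""
    rng = np.random.default_rng(3)
    profs = _tilted_profiles(rng, 6)
    unweighted = hum_nonparametric(profs, mode="exact").value
    for c in (0.9, 0.5, 0.2):
        pis = [np.full(len(p), c) for p in profs]
        assert hum_ipw(profs, pis, mode="exact").value == pytest.approx(unweighted, abs=1e-10)


def test_ipw_rejects_nonpositive_probabilities():
    rng = np.random.default_rng(4)
    profs = _tilted_profiles(rng, 3)
    pis = [np.full(len(p), 0.5) for p in profs]
    pis[0][0] = 0.0
    with pytest.raises(ValueError, match="probabilities"):
        hum_ipw(profs, pis)


def test_two_class_hum_equals_pair_counting_oracle():
    """For K=2 with equal weights, the HUM is the fraction of between-class
    pairs whose profiles order correctly with strict inequality."""
    rng = np.random.default_rng(7)
    p1 = rng.dirichlet([2, 1], size=30)  # class 1 leans toward coordinate 1
    p2 = rng.dirichlet([1, 2], size=25)
    est = hum_nonparametric([p1, p2], mode="exact")
    oracle = np.mean(p1[:, 0][:, None] > p2[:, 0][None, :])
    assert est.value == pytest.approx(oracle, abs=1e-12)


def test_hum_invariant_to_within_class_relabeling_and_joint_class_permutation():
    rng = np.random.default_rng(8)
    profs = _tilted_profiles(rng, 5)
    base = hum_nonparametric(profs, mode="exact").value
    shuffled = [p[rng.permutation(len(p))] for p in profs]
    assert hum_nonparametric(shuffled, mode="exact").value == pytest.approx(base)
    sigma = [2, 0, 3, 1]
    permuted = [profs[sigma[k]][:, sigma] for k in range(4)]
    assert hum_nonparametric(permuted, mode="exact").value == pytest.approx(base)


def test_weight_vector_changes_assignments():
    """An extreme weight on one class can flip the minimizing assignment."""
    profiles = np.array(
        [
            [0.4, 0.3, 0.15, 0.15],
            [0.45, 0.35, 0.1, 0.1],
            [0.05, 0.05, 0.8, 0.1],
            [0.05, 0.05, 0.1, 0.8],
        ]
    )
    _, equal = classify_set(profiles, DecisionConfig())
    _, tilted = classify_set(profiles, DecisionConfig(weights=np.array([10.0, 0.1, 1.0, 1.0])))
    assert equal == 0 and tilted == 1


def test_bootstrap_degenerate_pipeline_gives_zero_se_and_unit_ci():
    data = list(range(30))
    se, ci = hum_bootstrap_ci(data, lambda d: 1.0, B=60, seed=0)
    assert se == 0.0
    assert ci == (1.0, 1.0)


def test_bootstrap_se_stable_when_doubling_replicates():
    rng = np.random.default_rng(9)
    data = rng.binomial(1, 0.3, 400).astype(float)
    se1, ci1 = hum_bootstrap_ci(data, lambda d: float(np.mean(d)), B=150, seed=1)
    se2, ci2 = hum_bootstrap_ci(data, lambda d: float(np.mean(d)), B=300, seed=2)
    assert se2 == pytest.approx(se1, rel=0.4)
    for ci in (ci1, ci2):
        assert 0.0 <= ci[0] <= ci[1] <= 1.0


def test_optimism_zero_for_constant_pipeline():
    data = list(range(20))
    est = optimism_correct(data, lambda fit, score: 0.42, B=50, seed=0)
    assert est.optimism["mean_optimism"] == 0.0
    assert est.value == pytest.approx(0.42)


def test_optimism_vanishes_for_large_sample_fixed_model():
    """With a fixed model form and a large sample, apparent and out-of-bag
    performance agree and the mean optimism is ~0."""
    rng = np.random.default_rng(11)
    data = rng.normal(1.0, 1.0, 20_000)

    def fit_and_score(fit_data, score_data):
        thr = float(np.mean(np.asarray(fit_data)))  # "fit" = estimate a cutoff
        return float(np.mean(np.asarray(score_data) > thr))

    est = optimism_correct(data, fit_and_score, B=60, seed=3)
    assert abs(est.optimism["mean_optimism"]) < 0.005
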