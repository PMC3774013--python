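"""Bayesian posterior, Tariff fitting/scoring, assignment and CSMF tally."""

import math

import numpy as np
import pytest

from va2012.interpret import (
    Assignment,
    ConditionalProbabilityMatrix,
    CSMFVector,
    PROB_FLOOR,
    TariffMatrix,
    assign,
    bayes_posterior,
    csmf_from_assignments,
    fit_tariff,
    tariff_score,
)
from va2012.questionnaire import VARecord


def _record(responses, record_id="r1", age_group="adult"):
    return VARecord(record_id, age_group, "female", responses)


def _matrix(p, causes=None, indicators=None, prior=None):
    p = np.asarray(p, dtype=float)
    causes = causes or [f"c{j}" for j in range(p.shape[1])]
    indicators = indicators or [f"i{k}" for k in range(p.shape[0])]
    if prior is None:
        return ConditionalProbabilityMatrix.uniform_prior(causes, indicators, p)
    return ConditionalProbabilityMatrix(causes, indicators, p, np.asarray(prior))


# --- Bayes ---------------------------------------------------------------


def test_identical_columns_return_prior():
    matrix = _matrix([[0.4, 0.4], [0.7, 0.7]], prior=[0.3, 0.7])
    record = _record({"i0": "yes", "i1": "yes"})
    post, degenerate = bayes_posterior(record, matrix)
    assert not degenerate
    np.testing.assert_allclose(post, [0.3, 0.7])


def test_two_cause_hand_computation():
    matrix = _matrix([[0.8, 0.2]])
    post, _ = bayes_posterior(_record({"i0": "yes"}), matrix)
    np.testing.assert_allclose(post, [0.8, 0.2])  # 0.8/(0.8+0.2)


def _oracle_posterior(record, matrix, mode):
    """Independent brute-force product-and-normalize oracle (pure python)."""
    weights = []
    for j in range(len(matrix.causes)):
        w = float(matrix.prior[j])
        for k, iid in enumerate(matrix.indicators):
            resp = record.responses.get(iid)
            p = max(float(matrix.p[k, j]), PROB_FLOOR)
            if resp == "yes":
                w *= p
            elif resp == "no" and mode == "full_bernoulli":
                w *= max(1.0 - float(matrix.p[k, j]), PROB_FLOOR)
        weights.append(w)
    total = sum(weights)
    return [w / total for w in weights]


@pytest.mark.parametrize("mode", ["positive_only", "full_bernoulli"])
def test_three_cause_fixture_matches_oracle(mode):
    matrix = _matrix(
        [[0.9, 0.3, 0.05], [0.2, 0.8, 0.4]], prior=[0.5, 0.25, 0.25]
    )
    record = _record({"i0": "yes", "i1": "yes"})
    post, _ = bayes_posterior(record, matrix, mode)
    np.testing.assert_allclose(post, _oracle_posterior(record, matrix, mode))


def test_full_bernoulli_uses_no_answers():
    matrix = _matrix([[0.9, 0.1]])
    record = _record({"i0": "no"})
    positive, _ = bayes_posterior(record, matrix, "positive_only")
    np.testing.assert_allclose(positive, [0.5, 0.5])  # ignored
    full, _ = bayes_posterior(record, matrix, "full_bernoulli")
    np.testing.assert_allclose(full, [0.1 / 1.0, 0.9 / 1.0])


def test_dont_know_and_not_applicable_contribute_nothing():
    matrix = _matrix([[0.9, 0.1], [0.8, 0.2]])
    base = _record({"i0": "yes"})
    augmented = _record({"i0": "yes", "i1": "dont_know"})
    na = _record({"i0": "yes", "i1": "not_applicable"})
    for other in (augmented, na):
        np.testing.assert_allclose(
            bayes_posterior(base, matrix, "full_bernoulli")[0],
            bayes_posterior(other, matrix, "full_bernoulli")[0],
        )


def test_zero_probability_floored_not_veto():
    matrix = _matrix([[0.0, 0.5]])
    post, degenerate = bayes_posterior(_record({"i0": "yes"}), matrix)
    assert not degenerate
    assert post[0] > 0  # floored at PROB_FLOOR, not an absolute veto
    np.testing.assert_allclose(post, [PROB_FLOOR / (PROB_FLOOR + 0.5),
                                      0.5 / (PROB_FLOOR + 0.5)])


def test_unknown_indicator_rejected():
    matrix = _matrix([[0.5, 0.5]])
    with pytest.raises(KeyError):
        bayes_posterior(_record({"mystery": "yes"}), matrix)


def test_posterior_sums_to_one():
    rng = np.random.default_rng(7)
    matrix = _matrix(rng.uniform(0, 1, size=(12, 5)))
    record = _record({f"i{k}": "yes" for k in range(0, 12, 2)})
    post, _ = bayes_posterior(record, matrix)
    assert math.isclose(post.sum(), 1.0, abs_tol=1e-12)


def test_permutation_equivariance():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.05, 0.95, size=(6, 4))
    prior = np.array([0.1, 0.2, 0.3, 0.4])
    record = _record({"i0": "yes", "i3": "yes", "i4": "no"})
    base, _ = bayes_posterior(record, _matrix(p, prior=prior), "full_bernoulli")
    perm = [2, 0, 3, 1]
    permuted_matrix = ConditionalProbabilityMatrix(
        [f"c{j}" for j in perm],
        [f"i{k}" for k in range(6)],
        p[:, perm],
        prior[perm],
    )
    permuted, _ = bayes_posterior(record, permuted_matrix, "full_bernoulli")
    np.testing.assert_allclose(permuted, base[perm])


def test_uninformative_indicator_leaves_posterior_unchanged():
    p = np.array([[0.9, 0.2], [0.5, 0.5]])
    with_extra = _matrix(p)
    without = _matrix(p[:1])
    rec_with = _record({"i0": "yes", "i1": "yes"})
    rec_without = _record({"i0": "yes"})
    np.testing.assert_allclose(
        bayes_posterior(rec_with, with_extra)[0],
        bayes_posterior(rec_without, without)[0],
    )


def test_response_order_independence():
    matrix = _matrix(np.random.default_rng(0).uniform(0.1, 0.9, size=(5, 3)))
    forward = _record({f"i{k}": "yes" for k in range(5)})
    backward = _record({f"i{k}": "yes" for k in reversed(range(5))})
    np.testing.assert_allclose(
        bayes_posterior(forward, matrix)[0], bayes_posterior(backward, matrix)[0]
    )


# --- Tariff --------------------------------------------------------------


def _training_cohort(rates, n_per_cause, seed=0):
    """Deterministic cohort hitting exact endorsement counts per cause."""
    rates = np.asarray(rates, dtype=float)
    n_ind, n_causes = rates.shape
    records, truth = [], {}
    rid = 0
    for j in range(n_causes):
        endorsements = np.round(rates[:, j] * n_per_cause).astype(int)
        for r in range(n_per_cause):
            responses = {
                f"i{k}": ("yes" if r < endorsements[k] else "no")
                for k in range(n_ind)
            }
            rec = _record(responses, record_id=f"t{rid}")
            records.append(rec)
            truth[rec.record_id] = f"c{j}"
            rid += 1
    return records, truth


def test_equal_endorsement_row_gets_zero_tariffs():
    records, truth = _training_cohort([[0.5, 0.5, 0.5]], 10)
    tm = fit_tariff(records, truth, ["c0", "c1", "c2"], ["i0"])
    np.testing.assert_array_equal(tm.tariff, [[0.0, 0.0, 0.0]])


def test_tariff_sign_for_distinctive_indicator():
    records, truth = _training_cohort([[0.9, 0.1, 0.1, 0.1]], 10)
    tm = fit_tariff(records, truth, [f"c{j}" for j in range(4)], ["i0"])
    assert tm.tariff[0, 0] > 0
    assert all(tm.tariff[0, j] <= 0 for j in range(1, 4))


def test_tariff_matches_quantile_oracle():
    rates = np.array([[0.9, 0.4, 0.2, 0.0], [0.3, 0.3, 0.6, 0.8]])
    records, truth = _training_cohort(rates, 10)
    tm = fit_tariff(records, truth, [f"c{j}" for j in range(4)], ["i0", "i1"])
    for k in range(2):
        x = rates[k]
        iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
        expected = (x - np.median(x)) / iqr
        np.testing.assert_allclose(tm.tariff[k], expected, atol=1e-12)


def test_iqr_zero_falls_back_to_mad():
    # constant-but-nonidentical: IQR over {0,1,1,1} with linear interpolation
    # is 0.25... choose rates where IQR is exactly 0 but spread exists
    rates = np.array([[0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 1.0]])
    records, truth = _training_cohort(rates, 10)
    causes = [f"c{j}" for j in range(7)]
    x = rates[0]
    assert np.quantile(x, 0.75) - np.quantile(x, 0.25) == 0.0
    tm = fit_tariff(records, truth, causes, ["i0"])
    mad = 1.4826 * np.median(np.abs(x - np.median(x)))
    assert mad == 0.0
    np.testing.assert_array_equal(tm.tariff, np.zeros((1, 7)))


def test_missing_training_cause_listed():
    records, truth = _training_cohort([[0.5, 0.5]], 5)
    with pytest.raises(ValueError, match="c2"):
        fit_tariff(records, truth, ["c0", "c1", "c2"], ["i0"])


def test_tariff_invariant_under_doubled_training():
    rates = np.array([[0.8, 0.2, 0.4], [0.1, 0.6, 0.3]])
    records, truth = _training_cohort(rates, 10)
    doubled, doubled_truth = _training_cohort(rates, 20)
    causes = ["c0", "c1", "c2"]
    tm1 = fit_tariff(records, truth, causes, ["i0", "i1"])
    tm2 = fit_tariff(doubled, doubled_truth, causes, ["i0", "i1"])
    np.testing.assert_allclose(tm1.tariff, tm2.tariff)


def test_tariff_score_no_endorsement_is_zero():
    tm = TariffMatrix(["c0", "c1"], ["i0", "i1"], [[1.0, -1.0], [0.5, 0.5]])
    scores = tariff_score(_record({"i0": "no", "i1": "dont_know"}), tm)
    np.testing.assert_array_equal(scores, [0.0, 0.0])


def test_single_endorsement_equals_tariff_row():
    tm = TariffMatrix(["c0", "c1"], ["i0", "i1"], [[1.5, -0.5], [0.25, 0.75]])
    scores = tariff_score(_record({"i1": "yes"}), tm)
    np.testing.assert_array_equal(scores, [0.25, 0.75])


def test_multi_endorsement_matches_summation_oracle():
    rng = np.random.default_rng(11)
    tariff = rng.normal(size=(6, 4))
    tm = TariffMatrix([f"c{j}" for j in range(4)], [f"i{k}" for k in range(6)], tariff)
    responses = {f"i{k}": ("yes" if k % 2 == 0 else "no") for k in range(6)}
    scores = tariff_score(_record(responses), tm)
    expected = [
        sum(tariff[k, j] for k in range(6) if responses[f"i{k}"] == "yes")
        for j in range(4)
    ]
    np.testing.assert_allclose(scores, expected)


# --- assignment ----------------------------------------------------------


def test_assign_top_cause_no_threshold():
    matrix = _matrix([[0.7, 0.3]])
    a = assign(_record({"i0": "yes"}), "bayes", matrix, tau=0.0)
    assert a.top_cause == "c0"
    assert math.isclose(a.top_value, 0.7)
    assert not a.tied


def test_assign_threshold_yields_unknown():
    matrix = _matrix([[0.4, 0.35, 0.25]])
    a = assign(_record({"i0": "yes"}), "bayes", matrix, tau=0.5)
    assert a.top_cause == "VA-99"
    assert math.isclose(a.top_value, 0.4)


def test_assign_exact_tie_takes_first_and_records():
    matrix = _matrix([[0.5, 0.5]])
    a = assign(_record({"i0": "yes"}), "bayes", matrix)
    assert a.top_cause == "c0"
    assert a.tied


def test_assign_tariff_engine():
    tm = TariffMatrix(["c0", "c1"], ["i0"], [[-1.0, 2.0]])
    a = assign(_record({"i0": "yes"}), "tariff", tm)
    assert a.top_cause == "c1"
    assert a.top_value == 2.0


def test_assign_engine_matrix_mismatch():
    with pytest.raises(TypeError):
        assign(_record({}), "bayes", TariffMatrix(["c0"], ["i0"], [[0.0]]))
    with pytest.raises(ValueError):
        assign(_record({}), "forest", _matrix([[0.5, 0.5]]))
    with pytest.raises(ValueError):
        assign(_record({}), "bayes", _matrix([[0.5, 0.5]]), tau=1.5)


# --- CSMF tally ----------------------------------------------------------


def _fake_assignment(rid, causes, values, engine="bayes"):
    values = np.asarray(values, dtype=float)
    top = int(np.argmax(values))
    return Assignment(rid, list(causes), values, causes[top], float(values[top]), engine)


def test_point_mass_csmf():
    assignments = [
        _fake_assignment(f"r{i}", ["a", "b"], [0.9, 0.1]) for i in range(10)
    ]
    csmf = csmf_from_assignments(assignments, "top_cause")
    assert csmf.as_dict() == {"a": 1.0, "b": 0.0}


def test_posterior_average():
    assignments = [
        _fake_assignment("r0", ["a", "b"], [1.0, 0.0]),
        _fake_assignment("r1", ["a", "b"], [0.0, 1.0]),
    ]
    csmf = csmf_from_assignments(assignments, "posterior_average")
    np.testing.assert_allclose(csmf.fractions, [0.5, 0.5])


def test_mixed_fixture_matches_tally_oracle():
    rng = np.random.default_rng(5)
    causes = ["a", "b", "c"]
    assignments = []
    for i in range(50):
        v = rng.dirichlet(np.ones(3))
        assignments.append(_fake_assignment(f"r{i}", causes, v))
    csmf = csmf_from_assignments(assignments, "top_cause")
    counts = {c: 0 for c in causes}
    for a in assignments:
        counts[a.top_cause] += 1
    expected = [counts[c] / 50 for c in causes]
    np.testing.assert_allclose(csmf.fractions, expected)
    assert abs(csmf.fractions.sum() - 1.0) < 1e-9


def test_unknown_assignments_get_their_own_bin():
    a = _fake_assignment("r0", ["a", "b"], [0.4, 0.3])
    a.top_cause = "VA-99"
    csmf = csmf_from_assignments([a], "top_cause")
    assert csmf.as_dict()["VA-99"] == 1.0


def test_empty_assignments_rejected():
    with pytest.raises(ValueError):
        csmf_from_assignments([], "top_cause")


def test_csmf_vector_validation():
    with pytest.raises(ValueError):
        CSMFVector(["a", "b"], [0.6, 0.5])
    with pytest.raises(ValueError):
        CSMFVector(["a", "b"], [-0.1, 1.1])
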