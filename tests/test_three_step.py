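"""Bias-adjusted 3-step analyses: assignment, error matrix, step-3 models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lcsmix.three_step import (
    classification_errors,
    modal_assignment,
    proportional_assignment,
    step3_distal,
    step3_multinomial,
)


class TestModalAssignment:
    def test_one_hot(self):
        post = np.eye(3)[np.array([2, 0, 1])]
        np.testing.assert_array_equal(modal_assignment(post), [2, 0, 1])

    def test_tie_breaks_low(self):
        assert modal_assignment(np.array([[0.5, 0.5]]))[0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(4), size=200)
        expected = np.array([int(np.flatnonzero(r == r.max())[0]) for r in post])
        np.testing.assert_array_equal(modal_assignment(post), expected)

    def test_proportional_uses_probabilities(self):
        rng = np.random.default_rng(1)
        post = np.tile([0.7, 0.3], (50_000, 1))
        a = proportional_assignment(post, rng)
        assert a.mean() == pytest.approx(0.3, abs=0.01)


class TestClassificationErrors:
    def test_one_hot_gives_identity(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        ct = classification_errors(post, modal_assignment(post))
        np.testing.assert_allclose(ct.Q, np.eye(3))

    def test_uniform_four_subject_toy(self):
        # all rows (0.5, 0.5): every subject assigned to class 0 (tie rule),
        # so Q[k] = (1, 0) for both true classes
        post = np.full((4, 2), 0.5)
        a = modal_assignment(post)
        ct = classification_errors(post, a)
        np.testing.assert_allclose(ct.Q, [[1.0, 0.0], [1.0, 0.0]])
        assert ct.counts.tolist() == [4, 0]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        post = rng.dirichlet(np.ones(5), size=300)
        ct = classification_errors(post, modal_assignment(post))
        np.testing.assert_allclose(ct.Q.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_computed_two_class(self):
        post = np.array([[0.8, 0.2], [0.6, 0.4], [0.3, 0.7], [0.1, 0.9]])
        a = modal_assignment(post)  # [0, 0, 1, 1]
        ct = classification_errors(post, a)
        # Q[0] = ([0.8+0.6]/1.8, [0.3+0.1]/1.8)
        np.testing.assert_allclose(ct.Q[0], [1.4 / 1.8, 0.4 / 1.8])
        np.testing.assert_allclose(ct.Q[1], [0.6 / 2.2, 1.6 / 2.2])


def _logit_cohort(rng, n=2500, beta=(0.9, -0.6)):
    """3-class multinomial-logit cohort with two covariates (class 0 ref)."""
    z = pd.DataFrame({"x1": rng.binomial(1, 0.4, n), "x2": rng.normal(0, 1, n)})
    logits = np.zeros((n, 3))
    logits[:, 1] = -0.3 + beta[0] * z["x1"] + 0.2 * z["x2"]
    logits[:, 2] = 0.1 + beta[1] * z["x1"] - 0.4 * z["x2"]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    cls = (rng.random((n, 1)) > p.cumsum(axis=1)[:, :-1]).sum(axis=1)
    return z, cls


class TestStep3Multinomial:
    def test_identity_q_equals_standard_multinomial_fit(self):
        # with no classification error the corrected likelihood reduces to
        # ordinary multinomial logistic regression; statsmodels is the oracle
        rng = np.random.default_rng(3)
        z, cls = _logit_cohort(rng)
        res = step3_multinomial(cls, np.eye(3), z, reference=0)
        X = sm.add_constant(z.to_numpy(dtype=float))
        oracle = sm.MNLogit(cls, X).fit(disp=0, method="newton", tol=1e-12, maxiter=500)
        coefs = np.asarray(oracle.params)
        theirs_by_class = {str(k + 1): coefs[:, k] for k in range(2)}
        names = ["intercept", "x1", "x2"]
        for (_, row) in res.table.iterrows():
            j = names.index(row["predictor"])
            assert row["coef"] == pytest.approx(
                theirs_by_class[row["class"]][j], abs=1e-6
            )

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(4)
        z, cls = _logit_cohort(rng, n=6000)
        res = step3_multinomial(cls, np.eye(3), z, reference=0)
        t = res.table
        b11 = float(t[(t.predictor == "x1") & (t["class"] == "1")]["coef"].iloc[0])
        b21 = float(t[(t.predictor == "x1") & (t["class"] == "2")]["coef"].iloc[0])
        assert b11 == pytest.approx(0.9, abs=0.25)
        assert b21 == pytest.approx(-0.6, abs=0.25)

    def test_null_effect_ci_coverage(self):
        # a covariate with zero generating effect: the 95% Wald CI for its
        # OR should cover 1.0 at roughly the nominal rate
        rng = np.random.default_rng(5)
        covered = 0
        reps = 40
        for _ in range(reps):
            n = 800
            z = pd.DataFrame({"x_null": rng.binomial(1, 0.5, n)})
            cls = rng.integers(0, 2, n)  # membership independent of x_null
            res = step3_multinomial(cls, np.eye(2), z, reference=0)
            row = res.table[res.table.predictor == "x_null"].iloc[0]
            covered += int(row["ci_low"] <= 1.0 <= row["ci_high"])
        assert covered >= int(0.85 * reps)

    def test_missing_covariates_dropped_with_count(self):
        rng = np.random.default_rng(6)
        z, cls = _logit_cohort(rng, n=500)
        z.loc[:9, "x1"] = np.nan
        res = step3_multinomial(cls, np.eye(3), z, reference=0)
        assert res.n_dropped == 10 and res.n_used == 490

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            step3_multinomial(np.zeros(5, dtype=int), np.eye(2),
                              pd.DataFrame({"x": np.zeros(5)}), reference=7)


class TestStep3Distal:
    def test_identity_q_equals_assigned_class_means(self):
        rng = np.random.default_rng(7)
        cls = rng.integers(0, 3, 900)
        y = (rng.random(900) < np.array([0.2, 0.5, 0.8])[cls]).astype(float)
        res = step3_distal(cls, np.eye(3), y)
        for k in range(3):
            assert res.table["prob"].iloc[k] == pytest.approx(y[cls == k].mean(), abs=1e-9)
        np.testing.assert_allclose(
            res.table["pi"].to_numpy(), np.bincount(cls) / 900, atol=1e-9
        )

    def test_constant_outcome_degenerate(self):
        cls = np.array([0, 1, 0, 1])
        res = step3_distal(cls, np.eye(2), np.zeros(4))
        np.testing.assert_allclose(res.table["prob"], 0.0, atol=1e-12)
        assert any("constant" in f for f in res.flags)

    def test_missing_outcomes_excluded(self):
        cls = np.array([0, 1, 0, 1, 0])
        y = np.array([1.0, 0.0, np.nan, 1.0, np.nan])
        res = step3_distal(cls, np.eye(2), y)
        assert res.n_used == 3 and res.n_dropped == 2

    def test_error_correction_deattenuates(self):
        # with known misclassification, the corrected estimator moves the
        # naive assigned-class means back toward the true class probabilities
        rng = np.random.default_rng(8)
        n = 40_000
        true = rng.integers(0, 2, n)
        rho = np.array([0.2, 0.7])
        y = (rng.random(n) < rho[true]).astype(float)
        Q = np.array([[0.85, 0.15], [0.15, 0.85]])
        assigned = np.where(rng.random(n) < 0.85, true, 1 - true)
        res = step3_distal(assigned, Q, y)
        naive0 = y[assigned == 0].mean()
        est0 = res.table["prob"].iloc[0]
        assert abs(est0 - 0.2) < abs(naive0 - 0.2)
        assert est0 == pytest.approx(0.2, abs=0.03)


class TestRecoveryOnDefaultCohort:
    def test_distal_ordering_recovered(self, recovery_run):
        # generated ordering SD > MD > CH > {SR, CR} must survive the full
        # pipeline (fit, modal assignment, error correction)
        for outcome in ("treatment_seeking", "diagnosis_T9"):
            t = recovery_run.distal[outcome].table.set_index("class")["prob"]
            assert t["SD"] > t["MD"] > t["CH"] > max(t["SR"], t["CR"]) - 0.02

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(9)
        z, cls = _logit_cohort(rng, n=400)
        res1 = step3_multinomial(cls, np.eye(3), z, reference=0)
        perm = rng.permutation(400)
        res2 = step3_multinomial(cls[perm], np.eye(3), z.iloc[perm].reset_index(drop=True),
                                 reference=0)
        np.testing.assert_allclose(
            res1.table["coef"].to_numpy(), res2.table["coef"].to_numpy(), atol=1e-6
        )
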