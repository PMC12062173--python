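"""4PL probabilities, Fisher information, and Reckase summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcat4pl import (
    BankError,
    ItemBank,
    ItemParameters,
    item_information,
    mdiff,
    mdisc,
    prob_correct,
)
from mcat4pl import test_information as accumulated_information


class TestProbCorrect:
    @pytest.mark.parametrize(
        "item, theta, expected",
        [
            # zero slope: symmetric midpoint of the asymptote band
            (ItemParameters("a", [0.0, 0.0], 0.0), [3.0, -7.0], 0.5),
            # independently evaluated 0.2 + 0.75*logistic(0.5)
            (
                ItemParameters("b", [1.5, 0.0], -1.0, 0.2, 0.95),
                [1.0, 0.0],
                0.666844,
            ),
            (ItemParameters("c", [0.0], 0.0, 0.25, 0.75), [0.0], 0.5),
        ],
    )
    def test_point_values(self, item, theta, expected):
        assert prob_correct(item, np.array(theta)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_lower_asymptote_limit(self):
        item = ItemParameters("lo", [1.0], 0.0, 0.25, 1.0)
        assert prob_correct(item, np.array([-40.0])) == pytest.approx(0.25, abs=1e-9)
        assert prob_correct(item, np.array([40.0])) == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_rejected(self, item_2pl):
        with pytest.raises(BankError):
            prob_correct(item_2pl, np.array([0.0, 0.0]))

    def test_nonfinite_theta_rejected(self, item_2pl):
        with pytest.raises(BankError):
            prob_correct(item_2pl, np.array([np.nan]))

    @given(
        chi=st.floats(0.0, 0.4),
        gap=st.floats(0.05, 0.6),
        a=st.floats(0.1, 3.0),
        d=st.floats(-3.0, 3.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_bounds_and_monotonicity(self, chi, gap, a, d):
        """chi <= P <= gamma everywhere; nondecreasing for positive slope."""
        gamma = min(chi + gap + 0.05, 1.0)
        item = ItemParameters("h", [a], d, chi, gamma)
        grid = np.linspace(-6, 6, 41)
        probs = np.array([prob_correct(item, np.array([t])) for t in grid])
        assert np.all(probs >= chi - 1e-12) and np.all(probs <= gamma + 1e-12)
        assert np.all(np.diff(probs) >= -1e-12)


def _fd_information(item, theta, h=1e-4):
    """Expected negative Hessian of the Bernoulli log-likelihood by
    central finite differences — the independent information oracle."""
    D = len(theta)
    info = np.zeros((D, D))

    def loglik(t, y):
        p = prob_correct(item, t)
        return np.log(p) if y else np.log(1 - p)

    for i in range(D):
        for j in range(D):
            acc = 0.0
            p0 = prob_correct(item, theta)
            for y, w in ((1, p0), (0, 1 - p0)):
                tpp = theta.copy(); tpp[i] += h; tpp[j] += h
                tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
                tmp = theta.copy(); tmp[i] -= h; tmp[j] += h
                tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
                d2 = (
                    loglik(tpp, y) - loglik(tpm, y) - loglik(tmp, y) + loglik(tmm, y)
                ) / (4 * h * h)
                acc += w * d2
            info[i, j] = -acc
    return info


class TestItemInformation:
    def test_zero_slope_gives_zero_matrix(self):
        item = ItemParameters("z", [0.0, 0.0], 1.0)
        assert np.all(item_information(item, np.array([0.5, -0.5])) == 0.0)

    def test_2pl_closed_form(self, item_2pl):
        # a^2 P(1-P) at P=0.5
        assert item_information(item_2pl, np.array([0.0]))[0, 0] == pytest.approx(
            0.25
        )

    def test_4pl_value(self):
        item = ItemParameters("f", [1.0], 0.0, 0.2, 1.0)
        # (0.8*0.25)^2 / (0.6*0.4)
        assert item_information(item, np.array([0.0]))[0, 0] == pytest.approx(
            1.0 / 6.0, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finite_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chi = rng.uniform(0, 0.3)
        gamma = rng.uniform(0.8, 1.0)
        item = ItemParameters(
            "r", rng.uniform(0.3, 2.0, 2), rng.uniform(-1.5, 1.5), chi, gamma
        )
        theta = rng.uniform(-2, 2, 2)
        np.testing.assert_allclose(
            item_information(item, theta), _fd_information(item, theta), atol=1e-5
        )

    def test_psd_and_rank_one(self):
        item = ItemParameters("p", [1.2, 0.7], -0.4, 0.15, 0.92)
        info = item_information(item, np.array([0.3, -0.8]))
        np.testing.assert_allclose(info, info.T)
        eig = np.linalg.eigvalsh(info)
        assert eig.min() >= -1e-12
        assert np.sum(eig > 1e-12) == 1


class TestTestInformation:
    def test_empty_set_returns_prior(self, bank_2d):
        prior = np.diag([2.0, 3.0])
        np.testing.assert_array_equal(
            accumulated_information(bank_2d, set(), np.zeros(2), prior), prior
        )

    def test_orthogonal_items_with_identity_prior(self, bank_2d):
        total = accumulated_information(
            bank_2d, {"x1", "x2"}, np.zeros(2), np.eye(2)
        )
        np.testing.assert_allclose(total, np.diag([1.25, 1.25]))

    def test_adding_item_never_decreases_determinant(self, bank_2d):
        theta = np.array([0.4, -0.2])
        acc = np.eye(2)
        det = np.linalg.det(acc)
        for ids in ({"x1"}, {"x1", "x2"}, {"x1", "x2", "x3"}):
            new = accumulated_information(bank_2d, ids, theta, np.eye(2))
            assert np.linalg.det(new) >= det - 1e-12
            det = np.linalg.det(new)

    def test_unknown_item_rejected(self, bank_2d):
        with pytest.raises(BankError):
            accumulated_information(bank_2d, {"nope"}, np.zeros(2), np.eye(2))


class TestReckaseSummaries:
    def test_norm_and_ratio(self):
        item = ItemParameters("m", [3.0, 4.0], 5.0)
        assert mdisc(item) == pytest.approx(5.0)
        assert mdiff(item) == pytest.approx(-1.0)
        assert mdiff(item, flip_sign=True) == pytest.approx(1.0)

    def test_zero_intercept(self):
        assert mdiff(ItemParameters("m0", [1.0, 0.0], 0.0)) == 0.0

    def test_hard_item_at_band_top(self):
        assert mdiff(ItemParameters("hard", [1.0], -2.0)) == pytest.approx(2.0)

    def test_zero_mdisc_signalled(self):
        item = ItemParameters("deg", [0.0], 1.0)
        with pytest.raises(BankError):
            mdiff(item)


class TestBankInvariants:
    def test_duplicate_ids_rejected(self):
        items = [ItemParameters("a", [1.0], 0.0), ItemParameters("a", [1.0], 1.0)]
        with pytest.raises(BankError):
            ItemBank(items=items, n_dimensions=1)

    def test_asymptote_order_enforced(self):
        with pytest.raises(BankError):
            ItemParameters("bad", [1.0], 0.0, 0.8, 0.7)

    def test_trait_covariance_must_be_pd(self):
        items = [ItemParameters("a", [1.0, 0.0], 0.0)]
        with pytest.raises(BankError):
            ItemBank(
                items=items,
                n_dimensions=2,
                trait_covariance=np.array([[1.0, 1.2], [1.2, 1.0]]),
            )

    def test_2pl_reduction_matches_logistic(self, item_2pl):
        from scipy.special import expit

        for t in (-2.0, 0.0, 1.3):
            assert prob_correct(item_2pl, np.array([t])) == pytest.approx(
                expit(t)
            )
            assert item_information(item_2pl, np.array([t]))[0, 0] == pytest.approx(
                expit(t) * (1 - expit(t))
            )
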