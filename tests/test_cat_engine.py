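"""Starting items, selection rules, staged stop rule, session mechanics."""

import numpy as np
import pytest

from mcat4pl import (
    CatSession,
    ItemBank,
    ItemParameters,
    StopRuleConfig,
    administer,
    item_information,
    mdiff,
    next_item,
    run_session,
    select_starting_item,
    should_stop,
    simulate_responses,
)
from mcat4pl.ability import AbilityEstimate
from mcat4pl.cat_engine import STAGE1_SEM, STAGE2_SEM, SessionError
from tests.conftest import respond_from_vector


class TestStartingItems:
    def test_age_buckets(self, bank_1d):
        assert select_starting_item(bank_1d, "4;6") == "b2"
        assert select_starting_item(bank_1d, 5) == "b0"
        assert select_starting_item(bank_1d, "7;2") == "b3"
        assert select_starting_item(bank_1d, "3") == "b2"

    def test_missing_mapping_signalled(self, bank_2d):
        with pytest.raises(SessionError):
            select_starting_item(bank_2d, "5")

    def test_unparseable_age_signalled(self, bank_1d):
        with pytest.raises(SessionError):
            select_starting_item(bank_1d, "toddler")


class TestNextItem:
    def test_single_candidate_under_every_rule(self, bank_1d):
        session = CatSession(bank=bank_1d)
        for iid in ["b0", "b1", "b2", "b4"]:
            administer(session, iid, 1)
        for rule in ("D", "T", "A", "W", "E", "AP", "TP", "WP", "EP"):
            assert next_item(session, rule) == "b3"

    def test_higher_slope_wins_at_matched_location(self):
        # two 2PL candidates a=2 vs a=1 at d=0; a=2 maximizes information
        items = [
            ItemParameters("weak", [1.0], 0.0),
            ItemParameters("strong", [2.0], 0.0),
        ]
        bank = ItemBank(items=items, n_dimensions=1)
        session = CatSession(bank=bank)
        for rule in ("D", "T", "A", "E"):
            assert next_item(session, rule) == "strong"

    def test_1d_rules_reduce_to_max_information(self, bank_1d):
        session = CatSession(bank=bank_1d)
        administer(session, "b0", 1)
        theta = session.current_estimate.theta
        infos = {
            iid: item_information(bank_1d[iid], theta)[0, 0]
            for iid in session.remaining
        }
        best = max(sorted(infos), key=lambda k: infos[k])
        for rule in ("D", "T", "E"):
            assert next_item(session, rule) == best

    def test_posterior_rule_matches_sigma_average(self, bank_1d):
        """AP equals brute-force averaging of the A-criterion over the
        session's sigma-point grid (independent reimplementation)."""
        session = CatSession(bank=bank_1d)
        administer(session, "b0", 1)
        est = session.current_estimate
        prec = np.linalg.inv(bank_1d.trait_covariance)
        base_at = lambda th: prec + sum(
            item_information(bank_1d[i], th) for i in session.administered
        )
        post_sd = np.sqrt(np.linalg.inv(base_at(est.theta))[0, 0])
        pts = [est.theta[0], est.theta[0] + post_sd, est.theta[0] - post_sd]
        scores = {}
        for iid in session.remaining:
            vals = []
            for t in pts:
                M = base_at(np.array([t])) + item_information(
                    bank_1d[iid], np.array([t])
                )
                vals.append(-np.trace(np.linalg.inv(M)))
            scores[iid] = np.mean(vals)
        expected = max(sorted(scores), key=lambda k: scores[k])
        assert next_item(session, "AP") == expected

    def test_exhausted_bank_signalled(self, bank_2d):
        session = CatSession(bank=bank_2d)
        resp = simulate_responses(bank_2d, np.zeros(2), seed=0)
        run_session(session, respond_from_vector(bank_2d, resp), rule="D")
        with pytest.raises(SessionError):
            next_item(session, "D")

    def test_unknown_rule_rejected(self, bank_1d):
        with pytest.raises(ValueError):
            next_item(CatSession(bank=bank_1d), "Z")


def _session_with_sems(bank, sems_history, n_dims=6):
    """Forge a session whose estimate history has the given SEM rows."""
    session = CatSession.__new__(CatSession)
    session.bank = bank
    session.stop_config = StopRuleConfig()
    session.administered = [f"fake{i}" for i in range(len(sems_history))]
    session.responses = [1] * len(sems_history)
    session.estimate_history = [
        AbilityEstimate(theta=np.zeros(n_dims), sem=np.asarray(s, float))
        for s in sems_history
    ]
    session.stopped = False
    session.stop_reason = None
    return session


@pytest.fixture
def six_dim_bank():
    items = [
        ItemParameters(f"q{k}", np.eye(6)[k % 6] * 1.5, 0.0) for k in range(200)
    ]
    return ItemBank(items=items, n_dimensions=6)


class TestShouldStop:
    def test_stage1_stop(self, six_dim_bank):
        hist = [[0.9] * 6] * 29 + [[0.30] * 6]
        session = _session_with_sems(six_dim_bank, hist)
        assert should_stop(session) == (True, "stage1_sem")

    def test_one_dimension_blocks_stage1(self, six_dim_bank):
        hist = [[0.9] * 6] * 29 + [[0.30] * 5 + [0.40]]
        session = _session_with_sems(six_dim_bank, hist)
        assert should_stop(session) == (False, None)

    def test_stage2_threshold_applies_from_item_50(self, six_dim_bank):
        hist = [[0.9] * 6] * 54 + [[0.42] * 6]
        session = _session_with_sems(six_dim_bank, hist)
        assert should_stop(session) == (True, "stage2_sem")
        # the same SEM at item 30 does not stop (stage 1 still active)
        early = _session_with_sems(six_dim_bank, hist[:29] + [[0.42] * 6])
        assert should_stop(early) == (False, None)

    def test_stability_rule(self, six_dim_bank):
        # ranges of 0.008 per dimension: 6 * 0.008^2 = 0.000384 < 0.0005
        base = np.full(6, 0.80)
        hist = [[0.9] * 6] * 55
        for k in range(10):
            hist.append(base + 0.008 * (k % 2))
        session = _session_with_sems(six_dim_bank, hist)
        assert should_stop(session) == (True, "stability")

    def test_stability_needs_item_60(self, six_dim_bank):
        base = np.full(6, 0.80)
        hist = [[0.9] * 6] * 45 + [list(base + 0.008 * (k % 2)) for k in range(10)]
        session = _session_with_sems(six_dim_bank, hist)
        assert should_stop(session) == (False, None)

    def test_threshold_constants_are_reliability_conversions(self):
        assert STAGE1_SEM == pytest.approx(np.sqrt(1 - 0.85), abs=1e-15)
        assert STAGE2_SEM == pytest.approx(np.sqrt(1 - 0.80), abs=1e-15)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StopRuleConfig(stage1_threshold=0.5, stage2_threshold=0.4)
        with pytest.raises(ValueError):
            StopRuleConfig(stability_window=1)


class TestAdminister:
    def test_history_grows(self, bank_1d):
        session = CatSession(bank=bank_1d)
        administer(session, "b0", 1)
        assert len(session.administered) == 1
        assert len(session.estimate_history) == 1

    def test_duplicate_rejected(self, bank_1d):
        session = CatSession(bank=bank_1d)
        administer(session, "b0", 1)
        with pytest.raises(SessionError):
            administer(session, "b0", 0)

    def test_after_stop_rejected(self, bank_2d):
        session = CatSession(bank=bank_2d)
        resp = simulate_responses(bank_2d, np.zeros(2), seed=1)
        run_session(session, respond_from_vector(bank_2d, resp), rule="D")
        assert session.stopped
        with pytest.raises(SessionError):
            administer(session, session.administered[0], 1)

    def test_correct_answer_does_not_lower_on_dimension_map(self, bank_1d):
        session = CatSession(bank=bank_1d)
        administer(session, "b0", 1)
        before = session.current_estimate.theta[0]
        administer(session, "b1", 1)
        assert session.current_estimate.theta[0] >= before - 1e-9


class TestSessionBehavior:
    def test_termination_guarantee(self, small_bank):
        rng = np.random.default_rng(0)
        for i in range(3):
            theta = rng.multivariate_normal(
                np.zeros(small_bank.n_dimensions), small_bank.trait_covariance
            )
            resp = simulate_responses(small_bank, theta, seed=50 + i)
            session = CatSession(bank=small_bank, age_group="5")
            run_session(session, respond_from_vector(small_bank, resp), rule="AP")
            assert session.stopped and session.stop_reason is not None

    def test_reliability_floor_on_sem_stop(self):
        # dense high-information bank so SEM-threshold stops actually occur
        items = [
            ItemParameters(
                f"d{k}_{i}", np.eye(6)[k] * 3.0, -3.0 * b
            )
            for k in range(6)
            for i, b in enumerate(np.linspace(-1.5, 1.5, 12))
        ]
        bank = ItemBank(items=items, n_dimensions=6)
        rng = np.random.default_rng(1)
        checked = 0
        for i in range(4):
            theta = 0.5 * rng.standard_normal(6)
            resp = simulate_responses(bank, theta, seed=80 + i)
            session = CatSession(bank=bank, age_group="5")
            run_session(session, respond_from_vector(bank, resp), rule="AP")
            rel = session.estimate_history[-1].reliability[:6]
            if session.stop_reason == "stage1_sem":
                assert rel.min() > 1 - STAGE1_SEM**2  # >= 0.85
                checked += 1
            elif session.stop_reason == "stage2_sem":
                assert rel.min() > 1 - STAGE2_SEM**2  # >= 0.80
                checked += 1
        assert checked > 0

    def test_difficulty_adapts_to_responses(self):
        """Served difficulty rises after correct answers, drops after
        incorrect — emergent from information-based selection."""
        rng = np.random.default_rng(2)
        items = [
            ItemParameters(f"u{i}", [rng.uniform(1.2, 2.2)], -b)
            for i, b in enumerate(np.linspace(-2.2, 2.2, 30))
        ]
        bank = ItemBank(items=items, n_dimensions=1)
        after_correct, after_incorrect = [], []
        for i in range(8):
            theta = rng.standard_normal(1)
            resp = simulate_responses(bank, theta, seed=30 + i)
            session = CatSession(bank=bank, age_group="5")
            run_session(session, respond_from_vector(bank, resp), rule="T")
            diffs = [mdiff(bank[iid]) for iid in session.administered]
            for prev_resp, nxt in zip(session.responses, diffs[1:]):
                (after_correct if prev_resp else after_incorrect).append(nxt)
        assert np.mean(after_correct) > np.mean(after_incorrect)
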