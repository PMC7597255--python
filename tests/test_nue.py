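"""Greedy embedding search: criteria, thresholds, termination, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from nuecte import (
    ARConfig,
    NeighborConfig,
    NUEConfig,
    bootstrap_threshold,
    build_candidate_set,
    ksg_conditional_mutual_information,
    ksg_mutual_information,
    nn_predict,
    run_nue,
    select_candidate_cmi,
    select_candidate_la,
    select_candidate_msr,
    selection_for_gamma,
    simulate_ar,
    standardize,
)
from nuecte.embedding import CandidateVariable, lagged_design, present_column

NOJIT = NeighborConfig(T=10, jitter_seed=None)


def nojit_cfg(**kw):
    kw.setdefault("neighbor", NeighborConfig(T=kw.get("T", 10), jitter_seed=None))
    return NUEConfig(**kw)


@pytest.fixture(scope="module")
def ar_data():
    return standardize(simulate_ar(ARConfig(N=400, seed=42)))


class TestCandidateSet:
    @pytest.mark.parametrize(
        "L,m,d,count,lags",
        [
            (5, 1, 5, 25, {1, 2, 3, 4, 5}),
            (2, 2, 3, 6, {2, 4, 6}),
            (76, 1, 8, 608, set(range(1, 9))),
        ],
    )
    def test_pool_size_and_lags(self, L, m, d, count, lags):
        pool = build_candidate_set(L, m, d)
        assert len(pool) == count
        assert len(set(pool)) == count
        for p in range(L):
            assert {c.lag for c in pool if c.process == p} == lags
        # process-major, lag-minor ordering
        assert pool[0] == (0, m) and pool[d] == (1, m)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_candidate_set(1, 1, 5)
        with pytest.raises(ValueError):
            build_candidate_set(5, 0, 5)

    def test_lagged_design_alignment(self, rng):
        data = rng.standard_normal((50, 2))
        X = lagged_design(data, [CandidateVariable(1, 3)], max_lag=5)
        assert X.shape == (45, 1)
        assert np.array_equal(X[:, 0], data[2:47, 1])
        y = present_column(data, 0, 5)
        assert np.array_equal(y, data[5:, 0])


class TestStandardize:
    def test_population_variance_convention(self):
        out = standardize(np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]]))
        root32 = np.sqrt(3.0 / 2.0)
        assert np.allclose(out[:, 0], [-root32, 0.0, root32], atol=1e-12)
        assert abs(out.mean(axis=0)).max() < 1e-12
        assert abs(out.var(axis=0) - 1).max() < 1e-12

    def test_idempotent(self, rng):
        data = rng.standard_normal((200, 3)) * 4 + 2
        once = standardize(data)
        assert np.allclose(standardize(once), once, atol=1e-12)

    def test_constant_channel_named_in_error(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 2.0
        with pytest.raises(ValueError, match="1"):
            standardize(data)


class TestSelectionCriteria:
    def test_cmi_with_empty_selection_is_mi_argmax(self, ar_data):
        cfg = nojit_cfg(variant="bootstrap")
        winner, crit = select_candidate_cmi(ar_data, 1, [], None, cfg)
        pool = build_candidate_set(5, 1, 5)
        y = present_column(ar_data, 1, 5)
        vals = [
            ksg_mutual_information(
                lagged_design(ar_data, [c], 5), y, NOJIT
            ).value
            for c in pool
        ]
        assert winner == pool[int(np.argmax(vals))]
        assert crit == pytest.approx(max(vals), abs=1e-12)

    def test_singleton_pool_returned_regardless(self, ar_data):
        cfg = nojit_cfg(variant="bootstrap")
        only = [CandidateVariable(4, 5)]
        winner, _ = select_candidate_cmi(ar_data, 1, [], only, cfg)
        assert winner == only[0]

    def test_ar_driver_lag_wins_first_iteration(self):
        # the quadratic parent of node 2 is channel 1 at lag 2
        hits = 0
        for s in range(10):
            data = standardize(simulate_ar(ARConfig(N=1024, seed=300 + s)))
            winner, _ = select_candidate_cmi(
                data, 1, [], None, NUEConfig(variant="bootstrap", seed=s)
            )
            hits += winner == (0, 2)
        assert hits >= 9

    def test_la_reduces_to_mi_with_empty_selection(self, ar_data):
        cfg = nojit_cfg(variant="la")
        w_la, c_la = select_candidate_la(ar_data, 1, [], None, cfg)
        w_mi, c_mi = select_candidate_cmi(ar_data, 1, [], None, cfg)
        assert w_la == w_mi and c_la == pytest.approx(c_mi, abs=1e-12)

    def test_la_recomposition_from_ksg_terms(self, ar_data):
        cfg = nojit_cfg(variant="la")
        S = [CandidateVariable(1, 1), CandidateVariable(0, 2)]
        cand = [CandidateVariable(3, 1)]
        _, crit = select_candidate_la(ar_data, 1, S, cand, cfg)
        y = present_column(ar_data, 1, 5)
        w = lagged_design(ar_data, cand, 5)
        value = ksg_mutual_information(w, y, NOJIT).value
        red = syn = 0.0
        for sj in S:
            wj = lagged_design(ar_data, [sj], 5)
            red += ksg_mutual_information(w, wj, NOJIT).value
            syn += ksg_conditional_mutual_information(w, wj, y, NOJIT).value
        assert crit == pytest.approx(value + (2.0 / len(S)) * (syn - red), abs=1e-10)

    def test_la_penalizes_duplicate_of_selected(self, rng):
        # a candidate column identical to the selected one: criterion is
        # dominated by the -2 I(W;W) redundancy term and goes strongly negative
        base = rng.standard_normal((300, 3))
        base[:, 2] = base[:, 1] + 1e-6 * rng.standard_normal(300)
        data = standardize(base)
        cfg = nojit_cfg(variant="la")
        S = [CandidateVariable(1, 1)]
        _, crit = select_candidate_la(data, 0, S, [CandidateVariable(2, 1)], cfg)
        assert crit < -1.0

    def test_msr_lambda_zero_matches_cmi_winner(self, ar_data):
        for target in range(5):
            cfg = nojit_cfg(variant="msr", lambda_weight=0.0)
            S = [CandidateVariable(target, 1)]
            w_msr, _ = select_candidate_msr(ar_data, target, S, None, cfg)
            w_cmi, _ = select_candidate_cmi(ar_data, target, S, None, cfg)
            assert w_msr == w_cmi

    def test_msr_lambda_one_is_msr_argmin(self, ar_data):
        cfg = nojit_cfg(variant="msr", lambda_weight=1.0)
        winner, crit = select_candidate_msr(ar_data, 2, [], None, cfg)
        pool = build_candidate_set(5, 1, 5)
        y = present_column(ar_data, 2, 5)
        msrs = [
            nn_predict(lagged_design(ar_data, [c], 5), y, NOJIT).msr for c in pool
        ]
        assert winner == pool[int(np.argmin(msrs))]
        assert crit == pytest.approx(-min(msrs), rel=1e-9)


class TestBootstrapThreshold:
    def test_b1_equals_single_shuffled_estimate(self, ar_data):
        cfg = nojit_cfg(variant="bootstrap", bootstrap_size=1, seed=17)
        winner = CandidateVariable(0, 2)
        got = bootstrap_threshold(winner, ar_data, 1, [], cfg)
        # replay the single permutation pair from the same child stream
        n = ar_data.shape[0] - 5
        rng = np.random.default_rng([17, 2, 1, 1])
        w = lagged_design(ar_data, [winner], 5)[:, 0]
        y = present_column(ar_data, 1, 5)
        ws = w[rng.permutation(n)]
        ys = y[rng.permutation(n)]
        want = ksg_mutual_information(ws, ys, NOJIT).value
        assert got == want

    def test_deterministic_given_seed(self, ar_data):
        cfg = NUEConfig(variant="bootstrap", bootstrap_size=25, seed=5)
        a = bootstrap_threshold(CandidateVariable(0, 2), ar_data, 1, [], cfg)
        b = bootstrap_threshold(CandidateVariable(0, 2), ar_data, 1, [], cfg)
        assert a == b

    def test_null_calibration(self):
        # independent channels: the original MI beats the 95th shuffle
        # percentile in about 5% of replications
        exceed = 0
        outer = 100
        for s in range(outer):
            r = np.random.default_rng(10_000 + s)
            data = r.standard_normal((105, 2))
            cfg = NUEConfig(variant="bootstrap", T=5, bootstrap_size=60, seed=s,
                            neighbor=NeighborConfig(T=5))
            winner, crit = select_candidate_cmi(
                data, 1, [], [CandidateVariable(0, 1)], cfg
            )
            i95 = bootstrap_threshold(winner, data, 1, [], cfg)
            exceed += crit > i95
        assert 0 <= exceed <= 15  # ~5 expected of 100


class TestRunNUE:
    @pytest.mark.parametrize("variant", ["msr", "bootstrap", "la", "aic"])
    def test_structural_invariants(self, ar_data, variant):
        cfg = NUEConfig(variant=variant, lambda_weight=0.5, bootstrap_size=20, seed=3)
        sel = run_nue(ar_data, 2, cfg)
        pool = set(build_candidate_set(5, 1, 5))
        assert set(sel.selected) <= pool
        assert len(set(sel.selected)) == len(sel.selected)
        rejected = sum(not e.accepted for e in sel.trace)
        assert rejected in (0, 1)
        assert len(sel.trace) == len(sel.selected) + rejected
        assert [e.candidate for e in sel.trace if e.accepted] == sel.selected
        if variant in ("msr", "aic"):
            assert len(sel.selected) >= 1
        if rejected:
            assert sel.termination_reason in (
                "msr_no_improvement",
                "bootstrap_nonsignificant",
                "aic_no_improvement",
            )
        else:
            assert sel.termination_reason == "candidates_exhausted"

    def test_msr_trace_obeys_gamma_rule(self, ar_data):
        cfg = NUEConfig(variant="msr", lambda_weight=0.5, gamma=0.02, seed=1)
        sel = run_nue(ar_data, 3, cfg)
        prev = None
        for e in sel.trace:
            if e.iteration == 1:
                assert e.accepted
            else:
                assert e.threshold == prev
                assert e.accepted == ((prev - e.msr) > cfg.gamma)
            if e.accepted:
                prev = e.msr

    def test_gamma_infinite_selects_single_variable(self, ar_data):
        cfg = NUEConfig(variant="msr", lambda_weight=1.0, gamma=1e9, seed=0)
        for target in range(5):
            sel = run_nue(ar_data, target, cfg)
            assert len(sel.selected) == 1

    def test_iid_noise_forced_first_acceptance(self):
        r = np.random.default_rng(8)
        data = standardize(r.standard_normal((512, 5)))
        sel = run_nue(data, 0, NUEConfig(variant="msr", lambda_weight=1.0, gamma=0.0, seed=8))
        assert len(sel.selected) >= 1
        assert sel.termination_reason == "msr_no_improvement"

    def test_msr_lambda0_and_bootstrap_share_winners(self, ar_data):
        msr = run_nue(ar_data, 2, NUEConfig(variant="msr", lambda_weight=0.0, gamma=0.0, seed=4))
        boot = run_nue(ar_data, 2, NUEConfig(variant="bootstrap", bootstrap_size=20, seed=4))
        common = min(len(msr.trace), len(boot.trace))
        for k in range(common):
            if msr.trace[k].accepted and boot.trace[k].accepted:
                assert msr.trace[k].candidate == boot.trace[k].candidate
            else:
                break

    def test_identical_config_identical_selection(self, ar_data):
        cfg = NUEConfig(variant="msr", lambda_weight=0.5, gamma=0.01, seed=11)
        a = run_nue(ar_data, 1, cfg)
        b = run_nue(ar_data, 1, cfg)
        assert a.selected == b.selected
        assert [e.criterion for e in a.trace] == [e.criterion for e in b.trace]

    def test_record_too_short_rejected(self, rng):
        data = rng.standard_normal((15, 3))
        with pytest.raises(ValueError):
            run_nue(data, 0, NUEConfig(variant="msr"))

    @pytest.mark.parametrize("literal", [False, True])
    def test_aic_rule_direction_honored(self, ar_data, literal):
        cfg = NUEConfig(variant="aic", seed=2, aic_literal_direction=literal)
        sel = run_nue(ar_data, 1, cfg)
        assert len(sel.selected) >= 1
        prev = None
        for e in sel.trace:
            if e.iteration > 1:
                expected = (e.aic > prev) if literal else (e.aic < prev)
                assert e.accepted == expected
            if e.accepted:
                prev = e.aic


class TestGammaDerivation:
    @pytest.mark.parametrize("gamma", [0.01, 0.05, 0.15])
    def test_derived_selection_equals_direct_run(self, ar_data, gamma):
        base_cfg = NUEConfig(variant="msr", lambda_weight=0.5, gamma=0.0, seed=6)
        base = run_nue(ar_data, 3, base_cfg)
        derived, iters = selection_for_gamma(base, gamma)
        direct = run_nue(ar_data, 3, replace(base_cfg, gamma=gamma))
        assert derived == direct.selected
        assert iters == direct.n_iterations
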