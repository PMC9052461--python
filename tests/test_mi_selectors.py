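from __future__ import annotations

import numpy as np
import pytest

from omicsel import CriterionParams, DiscretizedMatrix, Method, greedy_select
from omicsel.infotheory import mutual_information, normalized_mi
from omicsel.mi_selectors import new_state, score_candidate, _pairwise_rows

from _oracles import oracle_mi, oracle_nmi, oracle_step_scores
from conftest import labels_from_codes, random_discrete_instance

ALL_METHODS = ["MIFS", "MIFS-U", "mRMR", "NMIFS", "INMIFS", "VWMRmR"]


def disc_of(states: np.ndarray) -> DiscretizedMatrix:
    d, n = states.shape
    return DiscretizedMatrix(tuple(f"f{i}" for i in range(d)),
                             tuple(f"s{j}" for j in range(n)), states)


def run_instance(method, states, y, params):
    data = disc_of(states)
    labels = labels_from_codes(y)
    return greedy_select(method, data, labels, params)


class TestFirstStepAndConventions:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_empty_set_score_is_pure_relevance(self, method):
        rng = np.random.default_rng(0)
        states, y = random_discrete_instance(rng, d=6, n=40)
        data = disc_of(states)
        labels = labels_from_codes(y)
        state = new_state(Method(method), data, labels)
        for i in range(6):
            got = score_candidate(Method(method), f"f{i}", state,
                                  CriterionParams())
            if method in ("INMIFS", "VWMRmR"):
                want = oracle_nmi(list(states[i]), list(y))
            else:
                want = oracle_mi(list(states[i]), list(y))
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_k1_selects_max_relevance_feature(self, method):
        rng = np.random.default_rng(1)
        states, y = random_discrete_instance(rng, d=8, n=50)
        res = run_instance(method, states, y, CriterionParams(k=1))
        scores = oracle_step_scores(method, [], states, y, 0.5, 1.0, 1)
        best = max(scores.values())
        picked = int(res.selected[0][1:])
        assert scores[picked] == pytest.approx(best, abs=1e-9)

    def test_mifs_beta_zero_ignores_redundancy(self):
        rng = np.random.default_rng(2)
        states, y = random_discrete_instance(rng, d=8, n=40)
        res = run_instance("MIFS", states, y, CriterionParams(beta=0.0, k=5))
        rel = np.array([oracle_mi(list(states[i]), list(y)) for i in range(8)])
        # pure-relevance ranking: selection = top-5 by relevance, tie->low idx
        order = np.lexsort((np.arange(8), -rel))[:5]
        assert list(res.selected) == [f"f{i}" for i in order]


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_each_step_attains_the_exhaustive_argmax(self, method):
        """Per-step argmax equivalence with a from-scratch criterion oracle
        on seeded random instances (d <= 10, k <= 6)."""
        rng = np.random.default_rng(42)
        params = CriterionParams(beta=0.5, w=1.0, k=6)
        for _ in range(30):
            d = int(rng.integers(4, 11))
            n = int(rng.integers(15, 35))
            states, y = random_discrete_instance(rng, d=d, n=n)
            k = min(int(rng.integers(2, 7)), d)
            p = CriterionParams(beta=params.beta, w=params.w, k=k)
            res = run_instance(method, states, y, p)
            selected: list[int] = []
            for step, fid in enumerate(res.selected):
                scores = oracle_step_scores(method, selected, states, y,
                                            p.beta, p.w, p.k)
                best = max(scores.values())
                i = int(fid[1:])
                assert scores[i] == pytest.approx(best, abs=1e-9), \
                    f"step {step}: {fid} not an argmax"
                # trace total must match the oracle score too
                assert res.trace[step].score == pytest.approx(scores[i],
                                                              abs=1e-9)
                selected.append(i)

    def test_vwmrmr_w0_equals_inmifs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            states, y = random_discrete_instance(rng, d=9, n=30)
            a = run_instance("VWMRmR", states, y, CriterionParams(w=0.0, k=5))
            b = run_instance("INMIFS", states, y, CriterionParams(k=5))
            assert a.selected == b.selected


class TestRedundancyAndInvariances:
    def test_duplicate_of_selected_feature_is_penalized(self):
        """An exact copy of the strongest feature must not beat a weaker but
        non-redundant informative feature under the normalized criteria."""
        rng = np.random.default_rng(12)
        n = 120
        y = rng.integers(0, 3, size=n)
        # f0 separates class 0 from the rest; f2 separates class 1 from 2:
        # complementary signal, low mutual redundancy
        strong = np.where(y == 0, 1, -1)
        strong[rng.choice(n, 8, replace=False)] = 0        # slight noise
        weaker = np.where(y == 1, 1, np.where(y == 2, -1, 0))
        weaker[rng.choice(n, 25, replace=False)] = 0       # noisier signal
        noise = rng.integers(-1, 2, size=n)
        states = np.vstack([strong, strong.copy(), weaker, noise])
        for method in ("mRMR", "NMIFS", "INMIFS", "VWMRmR"):
            res = run_instance(method, states, y, CriterionParams(k=2))
            # both informative signals selected, the exact duplicate never is
            assert set(res.selected) == {"f0", "f2"}, method

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_sample_permutation_invariance(self, method):
        rng = np.random.default_rng(21)
        states, y = random_discrete_instance(rng, d=7, n=40)
        perm = rng.permutation(40)
        a = run_instance(method, states, y, CriterionParams(k=4))
        b = run_instance(method, states[:, perm], y[perm], CriterionParams(k=4))
        assert a.selected == b.selected

    def test_pairwise_cache_matches_direct_recomputation(self):
        rng = np.random.default_rng(33)
        states, y = random_discrete_instance(rng, d=6, n=30)
        data = disc_of(states)
        state = new_state(Method.MRMR, data, labels_from_codes(y))
        row_mi, row_nmi = _pairwise_rows(state, 2)
        for j in range(6):
            assert row_mi[j] == pytest.approx(
                mutual_information(states[2], states[j]), abs=1e-14)
            assert row_nmi[j] == pytest.approx(
                normalized_mi(states[2], states[j]), abs=1e-14)
        assert _pairwise_rows(state, 2)[0] is row_mi  # cached object reused


class TestContracts:
    def test_k_capped_at_feature_count(self):
        rng = np.random.default_rng(3)
        states, y = random_discrete_instance(rng, d=4, n=20)
        res = run_instance("mRMR", states, y, CriterionParams(k=50))
        assert len(res.selected) == 4

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(3)
        states, y = random_discrete_instance(rng, d=4, n=20)
        with pytest.raises(ValueError):
            run_instance("DFS", states, y, CriterionParams(k=2))

    def test_trace_aligned_with_selection(self):
        rng = np.random.default_rng(4)
        states, y = random_discrete_instance(rng, d=6, n=25)
        res = run_instance("NMIFS", states, y, CriterionParams(k=4))
        assert len(res.trace) == len(res.selected) == 4
        assert [t.feature_id for t in res.trace] == list(res.selected)
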