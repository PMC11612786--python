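import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import sitsim
from sitsim import SimParams, choose_mate, mating_schedule, neggs
from sitsim.reproduction import (
    FEMALE,
    MALE,
    expected_neggs,
    mate_and_lay,
    produce_offspring,
    stochastic_round,
)

from conftest import empty_population


class TestMatingSchedule:
    @pytest.mark.parametrize(
        "t_imm, t_gen, n, expected",
        [
            (20, 60, 3, (20, 33, 46)),
            (20, 60, 1, (20,)),
            (30, 60, 2, (30, 45)),
            (20, 60, 4, (20, 30, 40, 50)),
        ],
    )
    def test_thresholds_divide_adult_span(self, t_imm, t_gen, n, expected):
        assert mating_schedule(t_imm, t_gen, n) == expected

    def test_rejects_more_matings_than_adult_days(self):
        with pytest.raises(ValueError):
            mating_schedule(55, 60, 6)

    @given(
        t_imm=st.integers(1, 80),
        span=st.integers(1, 80),
        n=st.integers(1, 10),
    )
    def test_threshold_invariants(self, t_imm, span, n):
        if n > span:
            return
        thr = mating_schedule(t_imm, t_imm + span, n)
        assert len(thr) == n
        assert thr[0] == t_imm
        assert all(b > a for a, b in zip(thr, thr[1:]))
        assert thr[-1] < t_imm + span


class TestChooseMate:
    def test_single_male_always_chosen(self, rng):
        assert choose_mate([5.0], rng) == 0

    def test_frequencies_match_weight_ratios(self, rng):
        # empirical law over 1e5 draws vs exact weights, chi-square
        weights = [1.0, 1.0, 2.0]
        n = 100_000
        counts = np.bincount([choose_mate(weights, rng) for _ in range(n)],
                             minlength=3)
        expected = np.array([0.25, 0.25, 0.5]) * n
        assert stats.chisquare(counts, expected).pvalue > 1e-3

    def test_two_males_binomial_check(self, rng):
        n = 20_000
        second = sum(choose_mate([1.0, 3.0], rng) for _ in range(n))
        se = np.sqrt(n * 0.75 * 0.25)
        assert abs(second - 0.75 * n) < 4 * se

    def test_rejects_empty_or_nonpositive(self, rng):
        with pytest.raises(ValueError):
            choose_mate([], rng)
        with pytest.raises(ValueError):
            choose_mate([1.0, 0.0], rng)


class TestNeggs:
    """Clutch sizes under the three sperm-competition regimes."""

    @pytest.mark.parametrize(
        "history, expected",
        [((1,), 2), ((0, 1), 0), ((1, 0), 2), ((0,), 0), ((1, 1, 1), 2)],
    )
    def test_first_male_precedence(self, history, expected, rng):
        assert neggs(6, 3, "first", history, rng) == expected

    @pytest.mark.parametrize(
        "history, expected",
        [((1,), 2), ((1, 0), 0), ((0, 1), 2), ((0, 0, 0), 0)],
    )
    def test_last_male_precedence(self, history, expected, rng):
        assert neggs(6, 3, "last", history, rng) == expected

    def test_share_regime_expectation(self, rng):
        # moy = 0.5, F/Nmating = 15 -> expectation 7.5, stochastic rounding
        draws = [neggs(45, 3, "share", (1, 0), rng) for _ in range(10_000)]
        assert set(draws) <= {7, 8}
        se = np.sqrt(0.25 / 10_000)
        assert abs(np.mean(draws) - 7.5) < 4 * se

    def test_closed_form_over_enumerated_histories(self):
        # brute force every history of length <= 3 against the definition
        for k in (1, 2, 3):
            for history in itertools.product((0, 1), repeat=k):
                base = 45 / 3
                assert expected_neggs(45, 3, "first", history) == base * history[0]
                assert expected_neggs(45, 3, "last", history) == base * history[-1]
                assert expected_neggs(45, 3, "share", history) == pytest.approx(
                    base * sum(history) / k)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            expected_neggs(6, 3, "first", ())

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            expected_neggs(6, 3, "mixed", (1,))


class TestStochasticRound:
    def test_integers_pass_through_without_randomness(self, rng):
        state = rng.bit_generator.state
        out = stochastic_round(np.array([3.0, 0.0, 15.0]), rng)
        np.testing.assert_array_equal(out, [3, 0, 15])
        assert rng.bit_generator.state == state  # no draw consumed

    def test_expectation_preserved(self, rng):
        x = np.full(50_000, 2.3)
        out = stochastic_round(x, rng)
        assert set(np.unique(out)) <= {2, 3}
        assert abs(out.mean() - 2.3) < 0.01


class TestProduceOffspring:
    def _mother_pop(self, params, contaminated):
        pop = empty_population(params)
        pop.append(
            sex=np.array([FEMALE]), age=np.array([25]),
            generation=np.array([4]),
            contaminated=np.array([contaminated]),
            sterile=np.array([False]), comp=np.array([1.0]),
        )
        return pop

    def test_offspring_state(self, default_params):
        pop = self._mother_pop(default_params, contaminated=False)
        n = produce_offspring(pop, np.array([0]), np.array([10]),
                              pv=1.0, vertical=True)
        assert n == 10
        kids = slice(1, None)
        assert (pop.age[kids] == 0).all()
        assert (pop.generation[kids] == 5).all()
        assert not pop.contaminated[kids].any()  # healthy mother
        assert not pop.sterile[kids].any()

    def test_vertical_transmission_certain(self, default_params):
        pop = self._mother_pop(default_params, contaminated=True)
        produce_offspring(pop, np.array([0]), np.array([10]),
                          pv=1.0, vertical=True)
        assert pop.contaminated[1:].all()
        assert (pop.tsick[1:] == 0).all()

    def test_vertical_transmission_binomial(self, default_params):
        pop = self._mother_pop(default_params, contaminated=True)
        n = 10_000
        produce_offspring(pop, np.array([0]), np.array([n]),
                          pv=0.25, vertical=True)
        hits = int(pop.contaminated[1:].sum())
        se = np.sqrt(n * 0.25 * 0.75)
        assert abs(hits - 0.25 * n) < 4 * se

    def test_offspring_sex_ratio_stochastic_but_even(self, default_params):
        pop = self._mother_pop(default_params, contaminated=False)
        n = 10_000
        produce_offspring(pop, np.array([0]), np.array([n]),
                          pv=0.0, vertical=False)
        females = int((pop.sex[1:] == FEMALE).sum())
        assert abs(females - n / 2) < 4 * np.sqrt(n * 0.25)


class TestMateAndLay:
    def _pair_pop(self, params, male_sterile):
        pop = empty_population(params)
        pop.append(
            sex=np.array([FEMALE, MALE]),
            age=np.array([21, 21]),
            generation=np.array([0, 0]),
            contaminated=np.array([False, False]),
            sterile=np.array([False, male_sterile]),
            comp=np.array([1.0, 1.0]),
        )
        return pop

    def test_fertile_pair_produces_one_clutch(self, default_params):
        pop = self._pair_pop(default_params, male_sterile=False)
        births, pairs = mate_and_lay(pop, default_params, vertical=False)
        assert births == 2  # F/Nmating = 6/3
        assert pop.matings_done[0] == 1
        assert pop.first_fertile[0] == 1

    def test_sterile_partner_no_offspring(self, default_params):
        pop = self._pair_pop(default_params, male_sterile=True)
        births, pairs = mate_and_lay(pop, default_params, vertical=False)
        assert births == 0
        assert pop.matings_done[0] == 1
        assert pop.first_fertile[0] == 0

    def test_no_mature_male_defers_mating(self, default_params):
        pop = self._pair_pop(default_params, male_sterile=False)
        pop.age[1] = 5  # male still immature
        state = pop.rng.bit_generator.state
        births, pairs = mate_and_lay(pop, default_params, vertical=False)
        assert births == 0 and pairs is None
        assert pop.matings_done[0] == 0
        assert pop.rng.bit_generator.state == state  # no randomness consumed

    def test_lifetime_matings_capped(self, default_params):
        pop = self._pair_pop(default_params, male_sterile=False)
        for _ in range(60):
            mate_and_lay(pop, default_params, vertical=False)
            pop.age[:2] += 1
        assert pop.matings_done[0] == default_params.Nmating

    def test_lifetime_fertility_equals_f_when_all_partners_fertile(self):
        # a female mated at every threshold to fertile males recruits F total
        params = SimParams(F=6.0, Nmating=3)
        pop = self._pair_pop(params, male_sterile=False)
        total = 0
        for _ in range(50):
            births, _ = mate_and_lay(pop, params, vertical=False)
            total += births
            pop.age[:2] += 1
        assert total == params.F

    @pytest.mark.parametrize("regime", ["first", "last", "share"])
    def test_cohort_fertility_scales_with_sterile_exposure(self, regime):
        # with a fraction s of matings going to sterile males, expected
        # cohort fertility scales by (1 - s) in every regime over a full
        # schedule (small-population simulation vs closed form)
        params = SimParams(F=6.0, Nmating=3, Csperm=regime, Csterile=1.0)
        reps, n_f = 60, 10
        s = 0.5
        total = 0
        for rep in range(reps):
            pop = empty_population(params, seed=rep)
            pop.append(
                sex=np.array([FEMALE] * n_f + [MALE, MALE]),
                age=np.array([21] * n_f + [21, 21]),
                generation=np.zeros(n_f + 2),
                contaminated=np.zeros(n_f + 2, bool),
                sterile=np.array([False] * n_f + [False, True]),
                comp=np.ones(n_f + 2),
            )
            for _ in range(40):
                births, _ = mate_and_lay(pop, params, vertical=False)
                total += births
                pop.age[pop.generation == 0] += 1
        expected = reps * n_f * params.F * (1 - s)
        sd = np.sqrt(reps * n_f) * params.F * 0.6  # generous envelope
        assert abs(total - expected) < 4 * sd
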