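import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from deafsim.mating import (
    UndefinedAssortmentError,
    form_couples_fast,
    form_couples_matrix,
    is_eligible,
    realized_assortment,
    score_pair,
)
from deafsim.model_core import MatingWeights

from conftest import build_population

UNIT = MatingWeights(w_pheno_h=1, w_pheno_d=1, w_sign_h=1, w_sign_d=1)


class TestScorePair:
    @pytest.mark.parametrize(
        "md,ms,fd,fs,weights,expected",
        [
            # both hearing -> 2 W^H_P, sign irrelevant
            (False, False, False, False, UNIT, 2.0),
            (False, True, False, False, UNIT, 2.0),
            # both deaf, both sign -> 2 (W^D_P + W^D_S)
            (True, True, True, True, UNIT, 4.0),
            # both deaf, not both signing -> 2 W^D_P
            (True, False, True, False, UNIT, 2.0),
            (True, True, True, False, UNIT, 2.0),
            # mixed, both sign -> W^H_S + W^D_S (prose rule)
            (True, True, False, True, UNIT, 2.0),
            (False, True, True, True, MatingWeights(1, 1, 3, 1), 4.0),
            # mixed without shared sign language -> 0
            (True, False, False, False, UNIT, 0.0),
            (True, False, False, True, UNIT, 0.0),
        ],
    )
    def test_branch_enumeration(self, md, ms, fd, fs, weights, expected):
        assert score_pair(md, ms, fd, fs, weights) == expected

    def test_equation_variant_of_mixed_branch(self):
        w = MatingWeights(w_pheno_h=1, w_pheno_d=2, w_sign_h=5, w_sign_d=1,
                          mixed_rule="equation")
        assert score_pair(True, True, False, True, w) == 3.0  # W^D_P + W^D_S

    @given(
        md=st.booleans(), ms=st.booleans(), fd=st.booleans(), fs=st.booleans(),
        wph=st.floats(0, 10), wpd=st.floats(0, 10),
        wsh=st.floats(0, 10), wsd=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_is_symmetric(self, md, ms, fd, fs, wph, wpd, wsh, wsd):
        w = MatingWeights(wph, wpd, wsh, wsd)
        assert score_pair(md, ms, fd, fs, w) == score_pair(fd, fs, md, ms, w)


class TestEligibility:
    def test_positive_score_above_zero_thresholds(self):
        assert is_eligible(2.0, 0.0, 0.0)

    def test_strict_inequality_at_threshold(self):
        assert not is_eligible(0.0, 0.0, 0.0)

    def test_score_must_exceed_both_thresholds(self):
        assert not is_eligible(1.0, 0.5, 1.5)
        assert is_eligible(1.0, 0.5, 1.5, threshold_rule="min")


class TestMatrixMatcher:
    def test_single_compatible_pair(self, rng):
        pop = build_population(male=[True, False])
        couples = form_couples_matrix(pop, UNIT, rng)
        assert couples.n_couples == 1
        assert len(couples.unmatched) == 0

    def test_capacity_bound_with_surplus_males(self, rng):
        pop = build_population(male=[True, True, False])
        couples = form_couples_matrix(pop, UNIT, rng)
        assert couples.n_couples == 1
        assert len(couples.unmatched) == 1
        assert pop.male[couples.unmatched[0]]

    def test_deaf_signer_pairs_form_before_mixed(self, rng):
        # deaf-signer x deaf-signer scores 4 > any mixed pair's 2
        pop = build_population(
            male=[True, True, True, False, False, False],
            env_deaf=[True, True, False, True, True, False],
            knows_sign=[True, True, True, True, True, True],
        )
        for seed in range(20):
            couples = form_couples_matrix(pop, UNIT, np.random.default_rng(seed))
            classes = sorted(couples.couple_classes(pop))
            assert classes == ["DD", "DD", "HH"]

    def test_no_couples_without_one_sex(self, rng):
        pop = build_population(male=[True, True])
        couples = form_couples_matrix(pop, UNIT, rng)
        assert couples.n_couples == 0
        assert len(couples.unmatched) == 2

    def test_ineligible_deaf_left_unmatched(self, rng):
        # purifying-selection weights: deaf-involving scores are 0, not > 0
        w = MatingWeights(w_pheno_h=1, w_pheno_d=0)
        pop = build_population(
            male=[True, True, False, False], env_deaf=[True, False, True, False]
        )
        couples = form_couples_matrix(pop, w, rng)
        assert couples.n_couples == 1
        assert sorted(couples.couple_classes(pop)) == ["HH"]


def _outcome_signature(pop, couples):
    cls = pop.deaf.astype(int) * 2 + pop.knows_sign.astype(int)
    pairs = sorted(zip(cls[couples.male_idx], cls[couples.female_idx]))
    return tuple(pairs)


class TestFastMatcherEquivalence:
    @pytest.mark.parametrize(
        "weights,env_deaf,knows_sign",
        [
            (
                MatingWeights(w_pheno_h=1, w_pheno_d=1, w_sign_h=3, w_sign_d=1),
                [True, True, False, False, True, False, False, False],
                [True, False, True, False, True, True, False, False],
            ),
            (
                MatingWeights(random_mating=True),
                [True, False, False, False, True, False, False, False],
                [False, False, True, False, False, False, True, False],
            ),
        ],
    )
    def test_couple_class_distribution_matches_matrix_oracle(
        self, weights, env_deaf, knows_sign
    ):
        """Chi-square on outcome signatures over repeated paired trials."""
        pop = build_population(
            male=[True] * 4 + [False] * 4, env_deaf=env_deaf, knows_sign=knows_sign
        )
        n_trials = 4000
        counts = {}
        for i in range(n_trials):
            sig = _outcome_signature(
                pop, form_couples_matrix(pop, weights, np.random.default_rng((1, i)))
            )
            counts.setdefault(sig, [0, 0])[0] += 1
            sig = _outcome_signature(
                pop, form_couples_fast(pop, weights, np.random.default_rng((2, i)))
            )
            counts.setdefault(sig, [0, 0])[1] += 1
        table = np.array(list(counts.values()))
        # merge rare categories for chi-square validity
        rare = table.sum(axis=1) < 20
        if rare.any():
            table = np.vstack([table[~rare], table[rare].sum(axis=0)])
        assert (table.sum(axis=1) > 0).all()
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.001

    def test_all_hearing_gives_min_side_couples(self, rng):
        pop = build_population(male=[True] * 5 + [False] * 3)
        couples = form_couples_fast(pop, UNIT, rng)
        assert couples.n_couples == 3

    def test_random_mating_marries_across_phenotypes(self, rng):
        pop = build_population(
            male=[True] * 3 + [False] * 3,
            env_deaf=[True, True, True, False, False, False],
        )
        couples = form_couples_fast(pop, MatingWeights(random_mating=True), rng)
        assert couples.n_couples == 3  # deaf males all marry despite zero scores

    def test_heterogeneous_social_position_falls_back_to_matrix(self):
        pop = build_population(male=[True, True, False, False])
        pop.social_position[:] = [5.0, 0.0, 0.0, 5.0]
        # score 2 exceeds only the (male2, female1) thresholds
        couples = form_couples_fast(pop, UNIT, np.random.default_rng(0))
        assert couples.n_couples == 1
        assert couples.male_idx[0] == 1 and couples.female_idx[0] == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matching_is_a_valid_partial_matching(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        pop = build_population(
            male=rng.random(n) < 0.5,
            env_deaf=(rng.random(n) < 0.3).tolist(),
            knows_sign=(rng.random(n) < 0.5).tolist(),
        )
        couples = form_couples_fast(pop, UNIT, rng)
        assert pop.male[couples.male_idx].all()
        assert (~pop.male[couples.female_idx]).all()
        everyone = np.concatenate([couples.male_idx, couples.female_idx, couples.unmatched])
        assert sorted(everyone) == list(range(n))  # each agent exactly once

    def test_raising_sign_weight_increases_deaf_deaf_couples(self):
        pop = build_population(
            male=[True] * 6 + [False] * 6,
            env_deaf=[True, True, False, False, False, False] * 2,
            knows_sign=[True] * 12,
        )
        low = MatingWeights(w_pheno_h=1, w_pheno_d=1, w_sign_h=1, w_sign_d=0.0)
        high = MatingWeights(w_pheno_h=1, w_pheno_d=1, w_sign_h=1, w_sign_d=5.0)

        def mean_dd(weights):
            total = 0
            for i in range(300):
                c = form_couples_fast(pop, weights, np.random.default_rng((3, i)))
                total += (c.couple_classes(pop) == "DD").sum()
            return total / 300

        assert mean_dd(high) >= mean_dd(low)


class TestRealizedAssortment:
    def test_all_deaf_couples(self, rng):
        pop = build_population(male=[True, False], env_deaf=[True, True])
        couples = form_couples_fast(pop, UNIT, rng)
        assert realized_assortment(couples, pop) == 1.0

    def test_mixed_couple_set(self, make_population):
        from deafsim.mating import CoupleSet

        pop = make_population(
            male=[True, True, True, False, False, False],
            env_deaf=[True, True, True, True, False, False],
        )
        couples = CoupleSet(
            male_idx=np.array([0, 1, 2]),
            female_idx=np.array([3, 4, 5]),
            unmatched=np.array([], dtype=np.int64),
        )
        # one DD couple + two DH couples -> 2 of 4 married deaf have deaf spouses
        assert realized_assortment(couples, pop) == pytest.approx(0.5)

    def test_undefined_without_married_deaf(self, rng):
        pop = build_population(male=[True, False])
        couples = form_couples_fast(pop, UNIT, rng)
        with pytest.raises(UndefinedAssortmentError):
            realized_assortment(couples, pop)
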