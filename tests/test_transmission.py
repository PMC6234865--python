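import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovipass.errors import CapabilityError, ValidationError
from ovipass.profiles import make_geometric_profile, normalize
from ovipass.transmission import (
    MinimalTransmission,
    SimulationConfig,
    ViabilityCriterion,
    analytic_viability_k1,
    brute_force_viability,
    expected_rare_cells,
    fold_difference,
    is_viable,
    minimal_cells_for_all_viable,
    proportion_viable,
    simulate_egg,
    simulate_eggs,
    viability_sweep,
)


class TestEggSampling:
    def test_single_lineage_gets_everything(self):
        rng = np.random.default_rng(0)
        assert simulate_egg(normalize([1.0]), 7, rng).tolist() == [7]

    def test_zero_cells(self, even_pair):
        rng = np.random.default_rng(0)
        assert simulate_egg(even_pair, 0, rng).tolist() == [0, 0]

    def test_counts_sum_to_n(self, six_lineage):
        rng = np.random.default_rng(3)
        eggs = simulate_eggs(six_lineage, 137, 200, rng)
        assert (eggs.sum(axis=1) == 137).all()

    def test_large_sample_near_expectation(self, even_pair):
        # binomial sd = sqrt(N/4); both counts within 5 sd of N/2
        rng = np.random.default_rng(11)
        counts = simulate_egg(even_pair, 10**5, rng)
        sd = math.sqrt(10**5 * 0.25)
        assert abs(counts[0] - 5e4) < 5 * sd

    def test_negative_n_rejected(self, even_pair):
        with pytest.raises(ValidationError):
            simulate_egg(even_pair, -1, np.random.default_rng(0))

    def test_multinomial_matches_sequential_categorical(self):
        # the one-shot multinomial draw is distributionally identical to
        # placing N cells one at a time; compare viability frequencies
        profile = normalize([0.6, 0.3, 0.1])
        rng = np.random.default_rng(5)
        n_cells, reps = 6, 20_000
        seq_draws = rng.choice(3, size=(reps, n_cells), p=profile.as_array())
        seq_counts = np.stack([(seq_draws == i).sum(axis=1) for i in range(3)], axis=1)
        seq_viable = is_viable(seq_counts, 1).mean()
        exact = analytic_viability_k1(profile, n_cells)
        assert abs(seq_viable - exact) < 4 * math.sqrt(exact * (1 - exact) / reps)


class TestViabilityRule:
    @pytest.mark.parametrize(
        "counts, k, expected",
        [
            ([1, 1, 1], 1, True),
            ([0, 5], 1, False),
            ([50, 49], 50, False),
            ([50, 50], 50, True),
        ],
    )
    def test_threshold_rule(self, counts, k, expected):
        assert is_viable(counts, k) is expected

    def test_per_lineage_thresholds(self):
        crit = ViabilityCriterion((1, 50))
        assert is_viable([1, 50], crit)
        assert not is_viable([50, 1], crit)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            is_viable([1, 1, 1], ViabilityCriterion((1, 1)))

    @pytest.mark.parametrize("bad", [0, -3, (1, 0)])
    def test_thresholds_below_one_rejected(self, bad):
        with pytest.raises(ValidationError):
            ViabilityCriterion(bad)


class TestAnalyticOracle:
    @pytest.mark.parametrize(
        "weights, n, expected",
        [
            ([1.0], 1, 1.0),
            ([0.5, 0.5], 3, 0.75),  # 1 - 2 (1/2)^3
            ([1, 1, 1], 3, 6 / 27),  # 3!/3^3 by enumeration
        ],
    )
    def test_known_probabilities(self, weights, n, expected):
        assert analytic_viability_k1(normalize(weights), n) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_n(self, six_lineage):
        values = [analytic_viability_k1(six_lineage, n) for n in range(6, 200, 7)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_splitting_a_lineage_lowers_coverage_probability(self):
        whole = normalize([0.5, 0.5])
        split = normalize([0.5, 0.25, 0.25])
        for n in (3, 10, 40):
            assert analytic_viability_k1(split, n) <= analytic_viability_k1(whole, n)

    def test_permutation_invariance(self, six_lineage):
        perm = six_lineage.permuted([3, 1, 5, 0, 2, 4])
        for n in (10, 100, 700):
            assert analytic_viability_k1(perm, n) == pytest.approx(
                analytic_viability_k1(six_lineage, n), rel=1e-12
            )

    def test_too_many_lineages_raises_capability_error(self):
        with pytest.raises(CapabilityError):
            analytic_viability_k1(make_geometric_profile(26, 2), 10)


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "weights, n, k, expected",
        [
            ([0.5, 0.5], 2, 1, 0.5),  # enumeration of 3 compositions
            ([1.0], 5, 5, 1.0),
            ([0.7, 0.3], 4, 2, 6 * 0.7**2 * 0.3**2),  # only (2,2) is viable
        ],
    )
    def test_tiny_enumerations(self, weights, n, k, expected):
        assert brute_force_viability(normalize(weights), n, k) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_analytic_exhaustively(self):
        # every (L <= 4, N <= 8) instance on uneven profiles, k = 1
        for L, weights in ((2, [3, 1]), (3, [5, 3, 1]), (4, [8, 4, 2, 1])):
            profile = normalize(weights)
            for n in range(0, 9):
                assert brute_force_viability(profile, n, 1) == pytest.approx(
                    analytic_viability_k1(profile, n), abs=1e-12
                )

    def test_guard_on_huge_enumeration(self, six_lineage):
        with pytest.raises(CapabilityError):
            brute_force_viability(six_lineage, 10_000, 1)


class TestSimulatedViability:
    def test_trivial_single_lineage(self):
        point = proportion_viable(normalize([1.0]), 1, 1, iterations=100, seed=0)
        assert point.proportion_viable == 1.0

    @pytest.mark.parametrize("n, exact", [(2, 0.5), (3, 0.75)])
    def test_matches_closed_form_within_mc_error(self, even_pair, n, exact):
        point = proportion_viable(even_pair, n, 1, iterations=10**5, seed=7)
        tol = 4 * math.sqrt(exact * (1 - exact) / 10**5)
        assert abs(point.proportion_viable - exact) < tol

    def test_seed_reproducibility(self, six_lineage):
        a = proportion_viable(six_lineage, 300, 1, seed=42)
        b = proportion_viable(six_lineage, 300, 1, seed=42)
        assert a == b

    def test_viable_count_consistent(self, six_lineage):
        point = proportion_viable(six_lineage, 250, 1, iterations=4321, seed=9)
        assert point.viable_count == round(point.proportion_viable * point.iterations)

    def test_raising_k_never_helps(self, six_lineage):
        # same seed, higher per-lineage requirement -> no more viable eggs
        low = proportion_viable(six_lineage, 2_000, 1, seed=13)
        high = proportion_viable(six_lineage, 2_000, 5, seed=13)
        assert high.proportion_viable <= low.proportion_viable

    def test_permutation_invariance_within_mc_error(self, six_lineage):
        perm = six_lineage.permuted([2, 0, 1, 5, 3, 4])
        i = 10**4
        a = proportion_viable(six_lineage, 400, 1, iterations=i, seed=3)
        b = proportion_viable(perm, 400, 1, iterations=i, seed=3)
        p = analytic_viability_k1(six_lineage, 400)
        tol = 8 * math.sqrt(p * (1 - p) / i)
        assert abs(a.proportion_viable - b.proportion_viable) < tol


class TestViabilitySweep:
    def test_single_lineage_curve_is_flat_one(self):
        cfg = SimulationConfig(iterations=200, cell_grid=(1, 5, 25), seed=0)
        (curve,) = viability_sweep(normalize([1.0]), cfg, 1)
        assert [p.proportion_viable for p in curve.points] == [1.0, 1.0, 1.0]

    def test_two_lineage_curve_tracks_inclusion_exclusion(self):
        profile = normalize([0.9, 0.1])
        i = 10**4
        cfg = SimulationConfig(iterations=i, cell_grid=(5, 25, 50, 80), seed=21)
        (curve,) = viability_sweep(profile, cfg, 1)
        for point in curve.points:
            exact = 1 - 0.9**point.n_cells - 0.1**point.n_cells
            tol = 4 * math.sqrt(max(exact * (1 - exact), 1e-8) / i)
            assert abs(point.proportion_viable - exact) < tol

    def test_bit_identical_given_seed(self, six_lineage):
        cfg = SimulationConfig(iterations=1_000, cell_grid=(10, 110, 310), seed=5)
        a = viability_sweep(six_lineage, cfg, 1)[0].to_frame()
        b = viability_sweep(six_lineage, cfg, 1)[0].to_frame()
        assert a.equals(b)

    def test_grid_must_increase(self):
        with pytest.raises(ValidationError):
            SimulationConfig(cell_grid=(10, 10, 20))


class TestMinimalTransmission:
    def test_single_lineage_minimum_is_one(self):
        result = minimal_cells_for_all_viable(
            normalize([1.0]), 1, iterations=1_000, grid_step=1, seed=0
        )
        assert result.n_min == 1 and result.found

    def test_even_pair_minimum_consistent_with_analytic(self, even_pair):
        # per-egg miss probability is 2^(1-N); all 10^4 eggs viable demands
        # the analytic coverage probability at N_min be very close to 1
        result = minimal_cells_for_all_viable(
            even_pair, 1, iterations=10**4, grid_step=1, seed=2
        )
        assert result.found
        assert 12 <= result.n_min <= 45  # coverage > 0.999 already needs N >= 12
        assert analytic_viability_k1(even_pair, result.n_min) > 0.999
        assert result.recheck_proportion >= 0.999

    def test_unreachable_criterion_returns_sentinel(self, even_pair):
        result = minimal_cells_for_all_viable(
            even_pair,
            ViabilityCriterion(500),
            iterations=100,
            grid_step=20,
            grid_max=200,
            auto_extend=False,
            seed=0,
        )
        assert not result.found and result.n_min is None

    def test_block_early_exit_matches_full_evaluation(self, six_lineage):
        # the blockwise all-viable check must agree with the plain proportion
        result = minimal_cells_for_all_viable(
            six_lineage, 1, iterations=2_000, grid_step=20, seed=8
        )
        point = proportion_viable(six_lineage, result.n_min, 1, iterations=2_000, seed=8)
        assert point.proportion_viable == 1.0

    def test_seed_determinism(self, six_lineage):
        kwargs = dict(criterion=1, iterations=2_000, grid_step=20, seed=17)
        a = minimal_cells_for_all_viable(six_lineage, **kwargs)
        b = minimal_cells_for_all_viable(six_lineage, **kwargs)
        assert a == b


class TestDerivedQuantities:
    def _mt(self, n_min):
        return MinimalTransmission(
            n_min=n_min, found=True, criterion=ViabilityCriterion(1),
            iterations=10, seed=0, grid_step=1, grid_start=1, grid_max=10,
        )

    def test_fold_difference(self):
        assert fold_difference(self._mt(5_000), self._mt(1)) == 5_000
        assert fold_difference(self._mt(7), self._mt(7)) == 1.0

    def test_fold_difference_requires_found(self):
        bad = MinimalTransmission(
            n_min=None, found=False, criterion=ViabilityCriterion(1),
            iterations=10, seed=0, grid_step=1, grid_start=1, grid_max=10,
        )
        with pytest.raises(ValidationError):
            fold_difference(self._mt(5), bad)

    @pytest.mark.parametrize(
        "total, p_min, expected",
        [(10_000, 0.008, 80), (12_000, 0.008, 96), (500, 1.0, 500)],
    )
    def test_expected_rare_cells(self, total, p_min, expected):
        assert expected_rare_cells(total, p_min) == pytest.approx(expected)

    def test_expected_rare_cells_validates_p(self):
        with pytest.raises(ValidationError):
            expected_rare_cells(100, 0.0)


@given(st.integers(min_value=2, max_value=5), st.integers(min_value=0, max_value=7))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_oracles_agree_on_random_instances(n_lineages, n_cells):
    """Property: inclusion-exclusion equals full enumeration wherever both apply."""
    profile = make_geometric_profile(n_lineages, 6.0)
    assert brute_force_viability(profile, n_cells, 1) == pytest.approx(
        analytic_viability_k1(profile, n_cells), abs=1e-12
    )
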