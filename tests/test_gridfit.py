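"""Grid enumeration, clustered likelihood, and fit/profile behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest

import bonecycle as bc
from bonecycle.gridfit import PARAM_NAMES, grid_arrays, profile_table

SMALL_GRID = bc.ParameterGrid(
    r_R=(0.16, 0.22, 0.03),
    r_F=(0.20, 0.26, 0.03),
    f_MAT=(0.01, 0.03, 0.01),
    f_BMD=(0.70, 0.80, 0.10),
    k=(0.85, 0.90, 0.05),
)


def brute_force_count(grid, constrain):
    """Independent enumeration via itertools, no array tricks."""
    axes = [
        [round(grid.values(n)[i], 10) for i in range(len(grid.values(n)))]
        for n in PARAM_NAMES
    ]
    combos = [
        c for c in itertools.product(*axes) if (not constrain) or c[0] < c[1]
    ]
    return len(combos)


class TestEnumeration:
    def test_default_grid_has_12960_combinations(self, default_grid):
        """The r_R < r_F prerequisite cuts 21 600 combinations to 12 960."""
        combos = bc.enumerate_grid(default_grid)
        assert len(combos) == 12960
        assert len(combos) == brute_force_count(default_grid, constrain=True)

    def test_unconstrained_grid_has_21600_combinations(self):
        grid = bc.ParameterGrid(constrain=False)
        combos = bc.enumerate_grid(grid)
        assert len(combos) == 21600
        assert len(combos) == brute_force_count(grid, constrain=False)

    def test_reference_set_is_a_grid_point(self, grid_matrix):
        target = np.array(bc.WEEKLY_TERIPARATIDE_FIT.as_tuple())
        assert (np.abs(grid_matrix - target).max(axis=1) < 1e-9).any()

    def test_single_value_ranges_give_one_combination(self):
        grid = bc.ParameterGrid(
            r_R=(0.19, 0.19, 0.03),
            r_F=(0.23, 0.23, 0.03),
            f_MAT=(0.02, 0.02, 0.01),
            f_BMD=(0.80, 0.80, 0.10),
            k=(0.85, 0.85, 0.05),
        )
        combos = bc.enumerate_grid(grid)
        assert len(combos) == 1
        assert combos[0].as_tuple() == pytest.approx((0.19, 0.23, 0.02, 0.80, 0.85))

    def test_empty_grid_after_constraint_is_an_error(self):
        grid = bc.ParameterGrid(r_R=(0.5, 0.5, 0.1), r_F=(0.2, 0.2, 0.1))
        with pytest.raises(ValueError, match="empty"):
            bc.enumerate_grid(grid)

    def test_enumeration_is_lexicographic(self, grid_matrix):
        order = np.lexsort(grid_matrix.T[::-1])
        assert (order == np.arange(len(grid_matrix))).all()

    def test_growth_criterion_holds_across_entire_grid(self, default_grid):
        """Dominant eigenvalue > 1 exactly when r_F > r_R, at all 12 960 points."""
        for params in bc.enumerate_grid(default_grid):
            assert bc.dominant_growth_rate(params) > 1 or not params.r_R < params.r_F

    def test_formation_marker_declines_after_first_cycle_across_grid(self, grid_matrix):
        """Old bone shrinks on the first cycle everywhere in the search ranges.

        The resorptive outflow r_R * k exceeds the maturation inflow
        f_MAT * (1 - k) throughout the grid, so P1NP(2) < P1NP(1) always;
        the global 18-cycle peak sits at cycle 1 for most, not all,
        combinations (strongly growing corners overtake the start late).
        """
        v_old, _ = bc.simulate_plenary_batch(*grid_matrix.T, 2)
        assert (v_old[:, 1] < v_old[:, 0]).all()


class TestCohortDataset:
    def test_rejects_nonpositive_values_with_line_numbers(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S1", "S1"],
                "outcome": ["P1NP", "P1NP"],
                "week": [4, 12],
                "value": [50.0, -1.0],
            }
        )
        with pytest.raises(ValueError, match="line.*3"):
            bc.CohortDataset(frame)

    def test_rejects_duplicate_visits(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S1", "S1"],
                "outcome": ["NTX", "NTX"],
                "week": [4, 4],
                "value": [30.0, 31.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            bc.CohortDataset(frame)

    def test_csv_round_trip(self, quiet_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        quiet_cohort.to_csv(path)
        back = bc.CohortDataset.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data.sort_values(["subject_id", "outcome", "week"], ignore_index=True),
            quiet_cohort.data,
        )


class TestLikelihood:
    def test_noise_free_recovery_with_unit_scales(self, default_grid):
        """Zero noise, scales fixed at 1: the surface minimum sits at the truth.

        20 random generating grid points; the four structural parameters
        (r_R, r_F, f_MAT, f_BMD) must be uniquely recovered, k may tie.
        """
        arr = grid_arrays(default_grid)
        rng = np.random.default_rng(42)
        unit = bc.OutcomeScales()
        zero_cv = {"P1NP": 0.0, "NTX": 0.0, "BMD": 0.0}
        for idx in rng.choice(len(arr), size=20, replace=False):
            truth = bc.PlenaryParams(*arr[idx])
            data = bc.generate_cohort(
                bc.CohortConfig(
                    n_subjects=2, true_params=truth, true_scales=unit,
                    assay_cv=zero_cv, seed=0,
                )
            )
            result = bc.fit(default_grid, data, scales=unit)
            assert result.best.as_tuple()[:4] == pytest.approx(truth.as_tuple()[:4])
            tied = result.ties[["r_R", "r_F", "f_MAT", "f_BMD"]].to_numpy()
            assert (np.abs(tied - np.array(truth.as_tuple()[:4])) < 1e-9).all()

    def test_duplicating_subjects_preserves_argmin(self, quiet_cohort):
        """The likelihood sums over independent clusters."""
        doubled = quiet_cohort.data.copy()
        doubled["subject_id"] = doubled["subject_id"] + "_dup"
        stacked = bc.CohortDataset(pd.concat([quiet_cohort.data, doubled], ignore_index=True))
        r1 = bc.fit(SMALL_GRID, quiet_cohort)
        r2 = bc.fit(SMALL_GRID, stacked)
        assert r1.best == r2.best

    def test_record_order_invariance(self, quiet_cohort):
        shuffled = bc.CohortDataset(
            quiet_cohort.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        ll1, _ = bc.log_likelihood(bc.WEEKLY_TERIPARATIDE_FIT, quiet_cohort)
        ll2, _ = bc.log_likelihood(bc.WEEKLY_TERIPARATIDE_FIT, shuffled)
        assert ll1 == pytest.approx(ll2, rel=1e-10)

    def test_subject_relabeling_invariance(self, quiet_cohort):
        relabeled = quiet_cohort.data.copy()
        relabeled["subject_id"] = relabeled["subject_id"].str.replace("S", "X")
        ll1, _ = bc.log_likelihood(bc.WEEKLY_TERIPARATIDE_FIT, quiet_cohort)
        ll2, _ = bc.log_likelihood(
            bc.WEEKLY_TERIPARATIDE_FIT, bc.CohortDataset(relabeled)
        )
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_single_likelihood_matches_fit_surface(self, quiet_cohort):
        result = bc.fit(SMALL_GRID, quiet_cohort)
        ll, _ = bc.log_likelihood(result.best, quiet_cohort)
        assert ll == pytest.approx(result.neg2loglik, rel=1e-12)

    def test_profiled_scales_recover_generating_scales(self, quiet_cohort):
        """At the generating parameters the profiled conversion factors
        land near the scales the cohort was generated with."""
        _, scales = bc.log_likelihood(bc.WEEKLY_TERIPARATIDE_FIT, quiet_cohort)
        assert scales.s_P1NP == pytest.approx(250.0, rel=0.05)
        assert scales.s_NTX == pytest.approx(220.0, rel=0.05)
        assert scales.s_BMD == pytest.approx(0.88, rel=0.02)

    def test_missing_visits_still_recover_truth(self):
        """The unbalanced (missing-at-random) likelihood path agrees."""
        data = bc.generate_cohort(
            bc.CohortConfig(n_subjects=40, seed=3, missing_rate=0.15)
        )
        result = bc.fit(SMALL_GRID, data)
        assert result.best.as_tuple() == pytest.approx((0.19, 0.23, 0.02, 0.80, 0.85))


class TestFitResult:
    def test_delta_nonnegative_and_zero_at_best(self, quiet_cohort):
        result = bc.fit(SMALL_GRID, quiet_cohort)
        assert (result.surface["delta"] >= 0).all()
        assert result.surface["delta"].min() == 0.0
        assert len(result.ties) >= 1

    def test_single_combination_grid(self, quiet_cohort):
        grid = bc.ParameterGrid(
            r_R=(0.19, 0.19, 0.03),
            r_F=(0.23, 0.23, 0.03),
            f_MAT=(0.02, 0.02, 0.01),
            f_BMD=(0.80, 0.80, 0.10),
            k=(0.85, 0.85, 0.05),
        )
        result = bc.fit(grid, quiet_cohort)
        assert result.n_evaluated == 1
        assert result.surface["delta"].iloc[0] == 0.0

    def test_profile_minima_are_zero_with_one_row_per_value(self, quiet_cohort):
        result = bc.fit(SMALL_GRID, quiet_cohort)
        for name in PARAM_NAMES:
            prof = profile_table(result, name)
            assert len(prof) == len(SMALL_GRID.values(name))
            assert prof["delta_min"].min() == pytest.approx(0.0, abs=1e-12)

    def test_unknown_profile_parameter_lists_valid_names(self, quiet_cohort):
        result = bc.fit(SMALL_GRID, quiet_cohort)
        with pytest.raises(KeyError, match="r_R"):
            profile_table(result, "bogus")

    def test_k_profile_is_nearly_flat(self, default_grid, quiet_cohort):
        """The initial old-bone proportion barely moves the likelihood.

        Its profile range must be far smaller than every other
        parameter's — the qualitative signature of weak identifiability
        of k.
        """
        result = bc.fit(default_grid, quiet_cohort)
        ranges = {
            name: profile_table(result, name)["delta_min"].max() for name in PARAM_NAMES
        }
        others = min(v for n, v in ranges.items() if n != "k")
        assert ranges["k"] < 0.15 * others
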