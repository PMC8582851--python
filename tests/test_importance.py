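import numpy as np
import pytest

import esvpipe as ep
from esvpipe.errors import DegenerateInputError, DomainError
from esvpipe.importance import FACTOR_GROUPS, FACTOR_NAMES, OOBForest


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((300, 15))
    y = 3.0 * X[:, 0] + 0.2 * rng.standard_normal(300)
    return X, y


class TestGrading:
    @pytest.mark.parametrize(
        "coefficient, level",
        [
            (0.3876, 1),  # dominant driver territory
            (0.31, 1),
            (0.30, 2),    # level 1 is strictly > 0.3
            (0.15, 3),
            (0.05, 4),
            (0.011, 4),
            (0.01, 5),    # level 5 closure: <= 0.01
            (0.0, 5),
            (1.0, 1),
        ],
    )
    def test_boundaries(self, coefficient, level):
        assert ep.grade(coefficient) == level

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            ep.grade(-0.1)
        with pytest.raises(DomainError):
            ep.grade(1.2)


def test_bootstrap_exclusion_tends_to_inverse_e():
    assert ep.bootstrap_exclusion_fraction(1) == 0.0
    big = ep.bootstrap_exclusion_fraction(100000)
    assert big == pytest.approx(np.exp(-1), abs=1e-5)


class TestTuning:
    def test_selected_pair_in_grids_and_deterministic(self, linear_data):
        X, y = linear_data
        cfg = ep.RFConfig(mtry_grid=(1, 4, 8), ntree_grid=(10, 25, 50), seed=1)
        pair1 = ep.tune_rf(X, y, cfg)
        pair2 = ep.tune_rf(X, y, cfg)
        assert pair1 == pair2
        assert pair1[0] in cfg.mtry_grid
        assert pair1[1] in cfg.ntree_grid

    def test_selected_pair_is_near_optimal(self, linear_data):
        X, y = linear_data
        cfg = ep.RFConfig(mtry_grid=(1, 4, 8), ntree_grid=(10, 25, 50), seed=1)
        mtry, ntree = ep.tune_rf(X, y, cfg)
        chosen = OOBForest(50, mtry, cfg.seed).fit(X, y)
        best_full = max(
            OOBForest(50, m, cfg.seed).fit(X, y).oob_r2() for m in cfg.mtry_grid
        )
        assert chosen.oob_r2(first_t=ntree) >= best_full - 2 * cfg.ntree_tolerance

    def test_too_few_observations(self):
        with pytest.raises(DegenerateInputError):
            ep.tune_rf(np.zeros((10, 15)), np.zeros(10), ep.RFConfig())


class TestImportance:
    def test_single_driver_recovered_and_unit_sum(self, linear_data):
        X, y = linear_data
        res = ep.importance(X, y, ep.RFConfig(mtry=5, ntree=50, seed=2))
        assert res.top_factor() == FACTOR_NAMES[0]
        assert sum(res.coefficients.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(c >= 0 for c in res.coefficients.values())
        # group sums partition the unit
        assert sum(res.group_sums.values()) == pytest.approx(1.0, abs=1e-6)
        for group, members in FACTOR_GROUPS.items():
            assert res.group_sums[group] == pytest.approx(
                sum(res.coefficients[f] for f in members)
            )

    def test_deterministic_given_seed(self, linear_data):
        X, y = linear_data
        a = ep.importance(X, y, ep.RFConfig(mtry=5, ntree=30, seed=4))
        b = ep.importance(X, y, ep.RFConfig(mtry=5, ntree=30, seed=4))
        assert a.coefficients == b.coefficients
        assert a.oob_r2 == b.oob_r2

    def test_duplicate_predictor_pair_symmetry(self):
        # two identical copies of the signal share its importance; swapping
        # their column labels leaves the pair-summed importance unchanged
        rng = np.random.default_rng(6)
        X = rng.standard_normal((400, 5))
        X[:, 1] = X[:, 0]
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(400)
        names = [f"f{i}" for i in range(5)]
        res = ep.importance(X, y, ep.RFConfig(mtry=2, ntree=80, seed=7), factor_names=names)
        Xs = X[:, [1, 0, 2, 3, 4]]
        res_swapped = ep.importance(
            Xs, y, ep.RFConfig(mtry=2, ntree=80, seed=7), factor_names=names
        )
        pair = res.coefficients["f0"] + res.coefficients["f1"]
        pair_swapped = res_swapped.coefficients["f0"] + res_swapped.coefficients["f1"]
        assert pair == pytest.approx(pair_swapped, abs=0.05)
        assert pair > 0.8  # the duplicated signal carries nearly all importance

    def test_zero_variance_target_rejected(self):
        X = np.random.default_rng(0).standard_normal((60, 15))
        with pytest.raises(DegenerateInputError):
            ep.importance(X, np.ones(60), ep.RFConfig(mtry=5, ntree=10))


class TestBaseline:
    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 15))
        y = X @ np.arange(1.0, 16.0) + 5.0  # exactly linear, mean far from 0
        cmp = ep.mlr_baseline(X, y, ep.RFConfig(mtry=5, ntree=20, seed=0))
        assert cmp.mlr_r2 == pytest.approx(1.0, abs=1e-10)
        assert cmp.mlr_pct_rmse == pytest.approx(0.0, abs=1e-6)
        assert cmp.mlr_accuracy == pytest.approx(100.0, abs=1e-6)

    def test_six_point_normal_equations_oracle(self):
        # closed-form OLS on a 6-point, 2-predictor dataset
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0], [5.0, 7.0], [6.0, 5.0]])
        y = np.array([3.1, 3.9, 8.2, 9.1, 13.8, 15.2])
        design = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        fitted = design @ beta
        sse = float(((y - fitted) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        expected_r2 = 1 - sse / sst
        expected_rmse = 100.0 * np.sqrt(sse / 6) / y.mean()
        cmp = ep.mlr_baseline(X, y, ep.RFConfig(mtry=1, ntree=20, seed=0))
        assert cmp.mlr_r2 == pytest.approx(expected_r2, rel=1e-9)
        assert cmp.mlr_pct_rmse == pytest.approx(expected_rmse, rel=1e-9)

    def test_rank_deficient_design_flagged(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 4))
        X[:, 3] = X[:, 0] + X[:, 1]  # exact collinearity
        y = X[:, 0] + rng.standard_normal(100)
        cmp = ep.mlr_baseline(X, y, ep.RFConfig(mtry=2, ntree=10, seed=0))
        assert cmp.rank_deficient

    def test_rf_beats_mlr_on_nonlinear_data(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((2000, 15))
        y = 5.0 * (X[:, 0] > 0) * X[:, 1] + X[:, 2] ** 2 + 0.3 * rng.standard_normal(2000)
        cmp = ep.mlr_baseline(X, y, ep.RFConfig(mtry=5, ntree=60, seed=1))
        assert cmp.rf_r2 > cmp.mlr_r2
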