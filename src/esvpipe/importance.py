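"""Random-forest attribution of ESV to its driving factors.

Fits a bagged ensemble of regression trees to per-cell ESV against
the 15 covariates, tunes (mtry, ntree) by out-of-bag (OOB) accuracy,
and converts OOB permutation importances into unit-sum influence
coefficients with a five-level grading.

OOB accuracy is the pseudo-R² 1 − OOB-MSE/var(y): each observation is
predicted only by the trees whose bootstrap resample excluded it
(about (1 − 1/n)ⁿ → e⁻¹ ≈ 36.8% of the sample per tree), giving an
internal, unbiased accuracy estimate with no held-out set.
Permutation importance is the randomForest-style mean increase in
per-tree OOB MSE when one predictor's OOB values are shuffled.

Tree induction is delegated to sklearn's DecisionTreeRegressor; the
bootstrap bookkeeping, OOB prediction, tuning and importance
normalization are implemented here so the OOB quantities follow the
definitions above exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from .errors import DegenerateInputError, DomainError

#: Canonical order of the 15 influencing factors.
FACTOR_NAMES = [
    "elevation",        # X1
    "slope",            # X2
    "temperature",      # X3
    "precipitation",    # X4
    "soil_silt",        # X5
    "soil_clay",        # X6
    "soil_sand",        # X7
    "ndvi",             # X8
    "econ_density",     # X9
    "pop_density",      # X10
    "urbanization",     # X11
    "dist_urban",       # X12
    "dist_settlement",  # X13
    "dist_road",        # X14
    "dist_river",       # X15
]

#: First-level grouping: natural (X1–X8), humanistic (X9–X11), location (X12–X15).
FACTOR_GROUPS = {
    "natural": FACTOR_NAMES[0:8],
    "humanistic": FACTOR_NAMES[8:11],
    "location": FACTOR_NAMES[11:15],
}


@dataclass
class RFConfig:
    """Random-forest hyperparameters and tuning grids.

    mtry is the number of candidate predictors per split; ntree the
    ensemble size. When either is None it is selected by
    :func:`tune_rf`. ntree_tolerance is the pseudo-R² slack allowed
    when shrinking ntree after mtry is fixed.
    """

    mtry: int | None = None
    ntree: int | None = None
    mtry_grid: tuple[int, ...] = tuple(range(1, 16))
    ntree_grid: tuple[int, ...] = (10, 25, 50, 100, 200, 500)
    ntree_tolerance: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry is not None and not (1 <= self.mtry):
            raise DomainError(f"mtry must be >= 1, got {self.mtry}")
        if self.ntree is not None and self.ntree < 1:
            raise DomainError(f"ntree must be >= 1, got {self.ntree}")


def bootstrap_exclusion_fraction(n: int) -> float:
    """Expected fraction of observations absent from one bootstrap resample.

    (1 − 1/n)ⁿ, which tends to e⁻¹ ≈ 0.368 for large n.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    return (1.0 - 1.0 / n) ** n


class OOBForest:
    """Bagged regression trees with explicit out-of-bag bookkeeping.

    Each tree is fit on a bootstrap resample of size n drawn with
    replacement; the complementary OOB rows per tree drive the OOB
    prediction, pseudo-R² and permutation importance.
    """

    def __init__(self, ntree: int, mtry: int, seed: int):
        self.ntree = ntree
        self.mtry = mtry
        self.seed = seed
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OOBForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise DomainError("target contains non-finite values")
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        self._X = X
        self._y = y
        self.trees = []
        self.oob_masks = []
        mtry = min(self.mtry, X.shape[1])
        for _ in range(self.ntree):
            idx = rng.integers(0, n, n)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self.trees.append(tree)
            self.oob_masks.append(oob)
        return self

    def oob_prediction(self, first_t: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Mean OOB prediction per row using the first ``first_t`` trees.

        Returns (predictions, covered-mask); rows never OOB are uncovered.
        """
        t = self.ntree if first_t is None else first_t
        n = self._X.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees[:t], self.oob_masks[:t]):
            if oob.any():
                sums[oob] += tree.predict(self._X[oob])
                counts[oob] += 1
        covered = counts > 0
        pred = np.zeros(n)
        pred[covered] = sums[covered] / counts[covered]
        return pred, covered

    def oob_r2(self, first_t: int | None = None) -> float:
        """OOB pseudo-R² = 1 − OOB-MSE / var(y) over covered rows."""
        pred, covered = self.oob_prediction(first_t)
        y = self._y[covered]
        var = y.var()
        if var == 0:
            raise DegenerateInputError("zero-variance target")
        mse = np.mean((pred[covered] - y) ** 2)
        return 1.0 - mse / var

    def permutation_importance(self, seed: int | None = None) -> np.ndarray:
        """Mean increase in per-tree OOB MSE when each predictor is permuted."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        p = self._X.shape[1]
        increases = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            perm = rng.permutation(Xo.shape[0])
            for f in range(p):
                Xp = Xo.copy()
                Xp[:, f] = Xo[perm, f]
                increases[f] += np.mean((tree.predict(Xp) - yo) ** 2) - base
            n_used += 1
        return increases / max(n_used, 1)


def tune_rf(X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None) -> tuple[int, int]:
    """Two-stage OOB hyperparameter selection.

    Stage 1: with ntree fixed at the grid maximum, pick the mtry with
    the highest OOB pseudo-R² (ties → smaller mtry). Stage 2: with
    that mtry, pick the smallest ntree whose OOB pseudo-R² is within
    ``ntree_tolerance`` of the best over the ntree grid. Deterministic
    given cfg.seed.
    """
    cfg = cfg or RFConfig()
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 50:
        raise DegenerateInputError("need at least 50 observations to tune")
    ntree_max = max(cfg.ntree_grid)
    p = X.shape[1]

    best_mtry, best_r2 = None, -np.inf
    for mtry in cfg.mtry_grid:
        if mtry > p:
            continue
        r2 = OOBForest(ntree_max, mtry, cfg.seed).fit(X, y).oob_r2()
        if r2 > best_r2:
            best_mtry, best_r2 = mtry, r2

    forest = OOBForest(ntree_max, best_mtry, cfg.seed).fit(X, y)
    r2_by_ntree = {t: forest.oob_r2(first_t=t) for t in sorted(cfg.ntree_grid)}
    top = max(r2_by_ntree.values())
    for t in sorted(cfg.ntree_grid):
        if r2_by_ntree[t] >= top - cfg.ntree_tolerance:
            return best_mtry, t
    return best_mtry, ntree_max  # pragma: no cover


def grade(coefficient: float) -> int:
    """Five-level importance grading of a unit-sum influence coefficient.

    Level 1: > 0.3; 2: (0.15, 0.3]; 3: (0.05, 0.15]; 4: (0.01, 0.05];
    5: ≤ 0.01. Lower level = stronger influence.
    """
    if not (0.0 <= coefficient <= 1.0):
        raise DomainError(f"coefficient must be in [0, 1], got {coefficient}")
    if coefficient > 0.3:
        return 1
    if coefficient > 0.15:
        return 2
    if coefficient > 0.05:
        return 3
    if coefficient > 0.01:
        return 4
    return 5


@dataclass
class ImportanceResult:
    """Normalized influence coefficients, group sums, grades, OOB accuracy."""

    coefficients: dict[str, float]
    group_sums: dict[str, float]
    grades: dict[str, int]
    oob_r2: float
    mtry: int
    ntree: int

    def ranking(self) -> list[str]:
        """Factors ordered by decreasing influence coefficient."""
        return sorted(self.coefficients, key=self.coefficients.get, reverse=True)

    def top_factor(self) -> str:
        return self.ranking()[0]


def importance(
    X: np.ndarray,
    y: np.ndarray,
    cfg: RFConfig | None = None,
    factor_names: list[str] | None = None,
) -> ImportanceResult:
    """OOB permutation importance, normalized to unit sum and graded.

    Negative raw importances are clipped to 0 before normalization so
    the coefficients form a proper share vector; group sums over the
    natural / humanistic / location factors partition the unit.
    """
    cfg = cfg or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = factor_names if factor_names is not None else list(FACTOR_NAMES[: X.shape[1]])
    if len(names) != X.shape[1]:
        raise DomainError("factor_names length must match number of predictors")
    if y.var() == 0:
        raise DegenerateInputError("zero-variance target")

    mtry, ntree = cfg.mtry, cfg.ntree
    if mtry is None or ntree is None:
        mtry, ntree = tune_rf(X, y, cfg)

    forest = OOBForest(ntree, mtry, cfg.seed).fit(X, y)
    raw = forest.permutation_importance()
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total == 0:
        raise DegenerateInputError("all permutation importances are zero")
    coef = raw / total

    coefficients = dict(zip(names, map(float, coef)))
    group_sums = {
        g: float(sum(coefficients.get(f, 0.0) for f in members))
        for g, members in FACTOR_GROUPS.items()
    }
    grades = {f: grade(c) for f, c in coefficients.items()}
    return ImportanceResult(
        coefficients=coefficients,
        group_sums=group_sums,
        grades=grades,
        oob_r2=forest.oob_r2(),
        mtry=mtry,
        ntree=ntree,
    )


@dataclass
class BaselineComparison:
    """R² and relative RMSE for the linear baseline and the forest."""

    mlr_r2: float
    mlr_pct_rmse: float
    rf_r2: float
    rf_pct_rmse: float
    rank_deficient: bool = False

    @property
    def mlr_accuracy(self) -> float:
        return 100.0 - self.mlr_pct_rmse

    @property
    def rf_accuracy(self) -> float:
        return 100.0 - self.rf_pct_rmse


def _metrics(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = y - pred
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    pct_rmse = 100.0 * np.sqrt(sse / len(y)) / y.mean()
    return r2, pct_rmse


def mlr_baseline(X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None) -> BaselineComparison:
    """Compare ordinary least squares with the forest on the same observations.

    The linear model is scored in-sample (its fitted values are the
    'simulated' ESV); the forest is scored on its OOB predictions so
    its accuracy is not inflated by resubstitution. %RMSE is
    100·RMSE/mean(y).
    """
    cfg = cfg or RFConfig(mtry=max(1, X.shape[1] // 3), ntree=100)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise DegenerateInputError("need n > p + 1 observations")

    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    rank_deficient = rank < design.shape[1]
    if rank_deficient:
        beta = np.linalg.pinv(design) @ y
        fitted = design @ beta
    else:
        ols = LinearRegression().fit(X, y)
        fitted = ols.predict(X)
    mlr_r2, mlr_rmse = _metrics(y, fitted)

    mtry = cfg.mtry or max(1, X.shape[1] // 3)
    ntree = cfg.ntree or 100
    forest = OOBForest(ntree, mtry, cfg.seed).fit(X, y)
    pred, covered = forest.oob_prediction()
    rf_r2, rf_rmse = _metrics(y[covered], pred[covered])

    return BaselineComparison(
        mlr_r2=mlr_r2,
        mlr_pct_rmse=mlr_rmse,
        rf_r2=rf_r2,
        rf_pct_rmse=rf_rmse,
        rank_deficient=rank_deficient,
    )
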