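"""L1-penalized logistic regression: solver wrapper, λ path, CV tuning.

The estimator minimizes the penalized binomial negative log-likelihood

    (1/n) Σ_i [log(1 + e^{η_i}) − y_i η_i] + λ (α‖β‖₁ + (1−α)‖β‖₂²/2),

η = b₀ + Xβ, with the intercept unpenalized.  α mixes the L1 (Lasso) and L2
(ridge) penalties; α = 1 (the default here) is the pure Lasso, whose
soft-thresholding updates set coefficients exactly to zero and so perform
variable selection.  λ is tuned by stratified k-fold cross-validation on the
held-out binomial deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import _solver
from .preprocess import DesignMatrix

logger = logging.getLogger(__name__)

#: largest |eta| treated as numerically saturated (perfect-separation sniff)
_SEPARATION_ETA = 30.0


class DegenerateDesignError(ValueError):
    """The predictor matrix carries no usable signal (e.g. all zeros)."""


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty: ``alpha`` mixes L1/L2 (1 = Lasso), ``lam`` scales it."""

    alpha: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0.0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


@dataclass
class PenalizedFit:
    """One converged (or flagged) penalized fit on the standardized scale."""

    penalty: PenaltySpec
    intercept: float
    beta: np.ndarray
    n_iter: int
    converged: bool
    max_kkt_violation: float
    separation_warning: bool = False
    objective_trace: np.ndarray | None = None

    @property
    def selected(self) -> np.ndarray:
        return self.beta != 0.0

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.beta
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    selected_lambda: float
    fold_assignment_seed: int
    k_used: int
    rule: str = "min"


def _as_xy(design: DesignMatrix | tuple[np.ndarray, np.ndarray]):
    if isinstance(design, DesignMatrix):
        return design.X, design.y
    X, y = design
    return np.asarray(X, float), np.asarray(y, float)


def fit_lasso_logistic(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray],
    penalty: PenaltySpec,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    warm_start: PenalizedFit | None = None,
    active_mask: np.ndarray | None = None,
    keep_trace: bool = False,
) -> PenalizedFit:
    """Fit one penalized logistic model by cyclic coordinate descent.

    Non-convergence at ``max_iter`` is reported on the returned fit, not
    raised; the KKT residual of the exact objective is always attached.
    """
    X, y = _as_xy(design)
    n, p = X.shape
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size != 2:
        raise ValueError("y must contain both classes coded 0/1")
    ybar = min(max(float(y.mean()), 1e-6), 1.0 - 1e-6)
    if warm_start is not None:
        beta = warm_start.beta.copy()
        b0 = warm_start.intercept
    else:
        beta = np.zeros(p)
        b0 = float(np.log(ybar / (1.0 - ybar)))
    mask = (
        np.ones(p, dtype=bool)
        if active_mask is None
        else np.asarray(active_mask, dtype=bool)
    )
    beta[~mask] = 0.0
    b0, n_iter, converged, kkt, trace = _solver.fit_one(
        np.ascontiguousarray(X.T, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(penalty.lam),
        float(penalty.alpha),
        beta,
        float(b0),
        float(tol),
        int(max_iter),
        mask,
    )
    eta = b0 + X @ beta
    separation = bool(
        penalty.lam * penalty.alpha == 0.0 and np.max(np.abs(eta)) > _SEPARATION_ETA
    )
    if separation:
        logger.warning("possible perfect separation: |eta| reached %.1f", np.max(np.abs(eta)))
    if not converged:
        logger.warning(
            "solver hit max_iter=%d (KKT residual %.2e at lambda=%.3e)",
            max_iter, kkt, penalty.lam,
        )
    return PenalizedFit(
        penalty=penalty,
        intercept=float(b0),
        beta=beta,
        n_iter=int(n_iter),
        converged=bool(converged),
        max_kkt_violation=float(kkt),
        separation_warning=separation,
        objective_trace=trace.copy() if keep_trace else None,
    )


def lambda_max(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray], alpha: float = 1.0
) -> float:
    """Smallest λ at which every coefficient is zero (for the given α)."""
    X, y = _as_xy(design)
    score = np.abs(X.T @ (y - y.mean())) / X.shape[0]
    lmax = float(score.max()) / max(alpha, 1e-3)
    if lmax == 0.0:
        raise DegenerateDesignError("all predictors are orthogonal to the outcome")
    return lmax


def lambda_grid(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray],
    n_lambda: int = 100,
    ratio: float = 1e-3,
    alpha: float = 1.0,
) -> np.ndarray:
    """Log-spaced decreasing grid from λ_max down to ratio·λ_max."""
    lmax = lambda_max(design, alpha)
    if n_lambda == 1:
        return np.array([lmax])
    return np.exp(np.linspace(np.log(lmax), np.log(ratio * lmax), n_lambda))


def fit_path(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray],
    grid: np.ndarray,
    alpha: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> list[PenalizedFit]:
    """Warm-started fits along a decreasing λ grid."""
    X, y = _as_xy(design)
    betas, intercepts, iters, conv, kkts = _solver.fit_path(
        np.ascontiguousarray(X.T, np.float64),
        np.ascontiguousarray(y, np.float64),
        np.ascontiguousarray(grid, np.float64),
        float(alpha),
        float(tol),
        int(max_iter),
    )
    return [
        PenalizedFit(
            penalty=PenaltySpec(alpha=alpha, lam=float(grid[i])),
            intercept=float(intercepts[i]),
            beta=betas[i],
            n_iter=int(iters[i]),
            converged=bool(conv[i]),
            max_kkt_violation=float(kkts[i]),
        )
        for i in range(len(grid))
    ]


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean held-out deviance, −2·mean[y log p + (1−y) log(1−p)]."""
    p = np.clip(prob, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cv_select_lambda(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray],
    k: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
    alpha: float = 1.0,
    rule: str = "min",
    n_lambda: int = 100,
    ratio: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 1_000,
) -> CVResult:
    """Choose λ by stratified k-fold CV on the held-out binomial deviance.

    If the minority class is too small for k folds, k is reduced (with a
    logged warning) so every fold keeps both classes.  ``rule="min"`` takes
    the deviance-minimizing λ (ties resolve to the larger λ);
    ``rule="1se"`` the largest λ within one standard error of the minimum.

    The fold fits use a looser tolerance and a bounded sweep budget than the
    final fit: CV only needs prediction-level accuracy, and the smallest-λ
    end of the path can be quasi-separable at these sample sizes, where a
    high-precision fit is both expensive and pointless.  Refit at the
    selected λ with the full budget afterwards.
    """
    X, y = _as_xy(design)
    if grid is None:
        grid = lambda_grid((X, y), n_lambda=n_lambda, ratio=ratio, alpha=alpha)
    grid = np.asarray(grid, float)
    minority = int(min(np.sum(y == 0), np.sum(y == 1)))
    k_used = min(k, minority)
    if 2 <= k_used < k:
        logger.warning("reducing CV folds from %d to %d (minority class size)", k, k_used)
    if k_used >= 2:
        splitter = StratifiedKFold(n_splits=k_used, shuffle=True, random_state=seed)
    else:
        # a single minority observation cannot be stratified across folds;
        # fall back to plain folds (single-class training folds are handled
        # by the solver's clipped null intercept)
        k_used = min(k, X.shape[0] // 2)
        if k_used < 2:
            raise ValueError("too few observations for cross-validation")
        logger.warning("stratification impossible; using %d unstratified folds", k_used)
        splitter = KFold(n_splits=k_used, shuffle=True, random_state=seed)
    if X.shape[0] < 2 * k_used:
        raise ValueError(f"need n >= 2k for {k_used}-fold CV")
    fold_dev = np.empty((k_used, grid.size))
    for f, (tr, te) in enumerate(splitter.split(X, y)):
        fits = fit_path((X[tr], y[tr]), grid, alpha=alpha, tol=tol, max_iter=max_iter)
        for i, fit in enumerate(fits):
            fold_dev[f, i] = binomial_deviance(y[te], fit.predict_proba(X[te]))
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(k_used)
    i_min = int(np.argmin(mean_dev))  # first index = largest λ on ties
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(within)[0])
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")
    return CVResult(
        lambda_grid=grid,
        cv_deviance=mean_dev,
        cv_se=se_dev,
        selected_lambda=float(grid[i_sel]),
        fold_assignment_seed=seed,
        k_used=k_used,
        rule=rule,
    )
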