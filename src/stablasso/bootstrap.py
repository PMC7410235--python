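"""Bootstrap stability selection for the penalized logistic model.

Penalized estimators do not come with valid p-values or confidence
intervals, so inference is by the non-parametric bootstrap: the tuned Lasso
is refit on B resamples of the rows (drawn with replacement), and each
variable is summarized by

* VIP — variable inclusion probability, the percentage of resamples in
  which its coefficient was nonzero;
* mean OR — the arithmetic mean of exp(coefficient) over *all* resamples,
  with unselected resamples contributing OR = 1 (exp 0), so weakly selected
  variables are shrunk toward the null;
* a percentile confidence interval of the OR draws (2.5th/97.5th
  percentiles for a 95% level, linear interpolation between order
  statistics).

A variable is called stably associated when its VIP reaches a threshold
(80% by default); the direction of association is read off the mean OR.
λ is re-tuned by cross-validation inside every resample by default, so each
resample sees the full estimator; a fixed global λ is available for speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lasso import PenaltySpec, cv_select_lambda, fit_lasso_logistic
from .preprocess import DesignMatrix

logger = logging.getLogger(__name__)


class EmptyEnsembleError(ValueError):
    """The ensemble has no resamples to summarize."""


@dataclass
class BootstrapConfig:
    """Tuning knobs applied inside every resample."""

    cv_folds: int = 10
    n_lambda: int = 100
    lambda_ratio: float = 1e-3
    alpha: float = 1.0
    lambda_rule: str = "min"
    stratified: bool = False
    restandardize: bool = False
    global_lambda: float | None = None
    tol: float = 1e-7
    max_iter: int = 10_000
    cv_tol: float = 1e-5
    cv_max_iter: int = 1_000


@dataclass
class BootstrapEnsemble:
    """B × p selection indicators and OR draws with full seed provenance."""

    B: int
    selection: np.ndarray  # (B, p) of 0/1
    or_draws: np.ndarray  # (B, p), 1.0 where not selected
    lambdas: np.ndarray  # (B,)
    master_seed: int
    redraw_count: int
    column_names: list[str]
    config: BootstrapConfig = field(default_factory=BootstrapConfig)

    def to_tsv(self, directory: str | Path, prefix: str = "ensemble") -> None:
        d = Path(directory)
        pd.DataFrame(self.selection, columns=self.column_names).to_csv(
            d / f"{prefix}_selection.tsv", sep="\t", index_label="resample"
        )
        pd.DataFrame(self.or_draws, columns=self.column_names).to_csv(
            d / f"{prefix}_or.tsv", sep="\t", index_label="resample"
        )
        pd.DataFrame({"lambda": self.lambdas}).to_csv(
            d / f"{prefix}_lambdas.tsv", sep="\t", index_label="resample"
        )


@dataclass
class StabilityRecord:
    """Per-variable stability summary — one report row in machine form."""

    variable: str
    vip: float  # percentage in [0, 100]
    mean_or: float
    ci_low: float
    ci_high: float
    selected: bool
    direction: str  # positive | negative | none


def _resample_indices(
    rng: np.random.Generator, y: np.ndarray, stratified: bool
) -> np.ndarray:
    n = y.size
    if not stratified:
        return rng.integers(0, n, size=n)
    idx = []
    for cls in (0.0, 1.0):
        members = np.flatnonzero(y == cls)
        idx.append(members[rng.integers(0, members.size, size=members.size)])
    return np.concatenate(idx)


def bootstrap_ensemble(
    design: DesignMatrix | tuple[np.ndarray, np.ndarray],
    B: int = 500,
    master_seed: int = 0,
    config: BootstrapConfig | None = None,
) -> BootstrapEnsemble:
    """Refit the CV-tuned Lasso on B bootstrap resamples of the rows.

    Resamples whose outcome collapses to a single class are redrawn (the
    count is recorded).  Columns constant within a resample are frozen at
    coefficient zero for that resample.  Deterministic given ``master_seed``:
    resample b draws from the b-th spawned substream of the master seed.
    """
    config = config or BootstrapConfig()
    if isinstance(design, DesignMatrix):
        X, y, names = design.X, design.y, list(design.column_names)
    else:
        X, y = (np.asarray(a, float) for a in design)
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    n, p = X.shape
    if p == 0:
        raise ValueError("empty design: no predictors")
    if B < 1:
        raise ValueError("B must be >= 1")

    selection = np.zeros((B, p), dtype=np.int8)
    or_draws = np.ones((B, p))
    lambdas = np.zeros(B)
    redraws = 0
    children = np.random.SeedSequence(master_seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        cv_seed = int(children[b].generate_state(1)[0] % (2**31 - 1))
        idx = _resample_indices(rng, y, config.stratified)
        while np.unique(y[idx]).size < 2:
            redraws += 1
            idx = _resample_indices(rng, y, config.stratified)
        Xb, yb = X[idx], y[idx]
        mask = Xb.std(axis=0) > 0.0
        if not mask.all():
            logger.info(
                "resample %d: constant column(s) %s frozen at zero",
                b, [names[j] for j in np.flatnonzero(~mask)],
            )
        if config.restandardize:
            Xb = Xb.copy()
            cols = np.flatnonzero(mask)
            Xb[:, cols] = (Xb[:, cols] - Xb[:, cols].mean(axis=0)) / Xb[:, cols].std(axis=0)
        if config.global_lambda is not None:
            lam = float(config.global_lambda)
        else:
            Xb_cv = Xb[:, mask]
            cv = cv_select_lambda(
                (Xb_cv, yb),
                k=config.cv_folds,
                seed=cv_seed,
                alpha=config.alpha,
                rule=config.lambda_rule,
                n_lambda=config.n_lambda,
                ratio=config.lambda_ratio,
                tol=config.cv_tol,
                max_iter=config.cv_max_iter,
            )
            lam = cv.selected_lambda
        fit = fit_lasso_logistic(
            (Xb, yb),
            PenaltySpec(alpha=config.alpha, lam=lam),
            tol=config.tol,
            max_iter=config.max_iter,
            active_mask=mask,
        )
        selection[b] = (fit.beta != 0.0).astype(np.int8)
        or_draws[b] = np.exp(fit.beta)
        lambdas[b] = lam
    if redraws:
        logger.info("redrew %d single-class resample(s)", redraws)
    return BootstrapEnsemble(
        B=B,
        selection=selection,
        or_draws=or_draws,
        lambdas=lambdas,
        master_seed=master_seed,
        redraw_count=redraws,
        column_names=names,
        config=config,
    )


def summarize_stability(
    ensemble: BootstrapEnsemble,
    vip_threshold: float = 80.0,
    ci_level: float = 95.0,
) -> list[StabilityRecord]:
    """Collapse an ensemble into per-variable VIP / mean OR / percentile CI."""
    if ensemble.B == 0 or ensemble.selection.shape[0] == 0:
        raise EmptyEnsembleError("no resamples to summarize")
    lo_q = (100.0 - ci_level) / 2.0
    hi_q = 100.0 - lo_q
    records = []
    for j, name in enumerate(ensemble.column_names):
        draws = ensemble.or_draws[:, j]
        vip = 100.0 * float(ensemble.selection[:, j].mean())
        mean_or = float(draws.mean())
        ci_low = float(np.percentile(draws, lo_q))  # linear interpolation
        ci_high = float(np.percentile(draws, hi_q))
        selected = vip >= vip_threshold
        if selected and mean_or > 1.0:
            direction = "positive"
        elif selected and mean_or < 1.0:
            direction = "negative"
        else:
            direction = "none"
        records.append(
            StabilityRecord(
                variable=name,
                vip=vip,
                mean_or=mean_or,
                ci_low=ci_low,
                ci_high=ci_high,
                selected=selected,
                direction=direction,
            )
        )
    return records
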