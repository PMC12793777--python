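"""Candidate-grid tuning (RM × feature classes), AICc selection, CV, ROC/AUC.

Model complexity in penalized maxent is governed by the regularization
multiplier (RM) and the admitted feature classes (FC).  The tuning grid
crosses RM values with FC strings, scores every candidate with the
sample-size-corrected Akaike criterion (AICc, Warren–Seifert convention:
the raw density renormalized over the background landscape, parameters
counted as non-zero coefficients), and selects the minimum-AICc candidate
with deterministic tie-breaking.  k-fold cross-validation with freshly
drawn background per fold supplies held-out AUCs and a fold-averaged
prediction map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import EnvStack
from .maxent import FeatureSpec, MaxentModel, SuitabilityMap, fit_maxent, predict, predict_map

__all__ = [
    "CandidateResult",
    "TuningReport",
    "DEFAULT_RM_GRID",
    "DEFAULT_FC_GRID",
    "tuning_grid",
    "roc_auc",
    "aicc",
    "select_best",
    "tune",
    "kfold_cv",
    "draw_background",
]

DEFAULT_RM_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_FC_GRID = ("L", "LQ", "LQH", "LQHP", "LQHPT")


def tuning_grid(
    rm_values=DEFAULT_RM_GRID, fc_values=DEFAULT_FC_GRID
) -> list[tuple[float, str]]:
    """Candidate (RM, FC) pairs in deterministic order (FC outer, RM inner)."""
    rm_values = tuple(rm_values)
    fc_values = tuple(fc_values)
    if not rm_values or not fc_values:
        raise ValueError("tuning grid override must be non-empty")
    return [(rm, fc) for fc in fc_values for rm in rm_values]


@dataclass
class CandidateResult:
    rm: float
    fc: str
    aicc: float | None
    delta_aicc: float | None
    n_params: int
    lnL: float
    mean_cv_auc: float | None = None
    cv_auc_per_fold: list[float] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.aicc is not None and np.isfinite(self.aicc)


@dataclass
class TuningReport:
    candidates: list[CandidateResult]
    best: tuple[float, str]
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rm": c.rm,
                    "fc": c.fc,
                    "k": c.n_params,
                    "lnL": c.lnL,
                    "AICc": c.aicc,
                    "delta_AICc": c.delta_aicc,
                    "mean_cv_auc": c.mean_cv_auc,
                    "sd_cv_auc": (
                        float(np.std(c.cv_auc_per_fold, ddof=0))
                        if c.cv_auc_per_fold
                        else None
                    ),
                }
                for c in self.candidates
            ]
        )


def roc_auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann–Whitney) AUC; ties count 0.5.

    Equals the trapezoidal area under the empirical ROC curve, and the
    probability that a random presence outscores a random background point.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("AUC needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: len(p)].sum()
    return float((r_p - len(p) * (len(p) + 1) / 2.0) / (len(p) * len(b)))


def aicc(
    model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame
) -> tuple[float | None, int, float]:
    """(AICc, k, lnL) of a fitted model under the Warren–Seifert convention.

    Raw scores are renormalized to sum to 1 over the background sample
    standing in for the landscape; lnL sums the log normalized score over
    presences; k counts non-zero coefficients.  AICc is undefined (None)
    when n_presence <= k + 1.
    """
    raw_p = predict(model, presence, "raw")
    raw_b = predict(model, background, "raw")
    total = raw_b.sum()
    lnL = float(np.sum(np.log(raw_p / total)))
    k = model.n_params
    n = len(presence)
    if n <= k + 1:
        return None, k, lnL
    value = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
    return float(value), k, lnL


def select_best(candidates: list[CandidateResult]) -> tuple[float, str]:
    """Minimum-AICc candidate; ties broken by (fewer k, lower rm, grid order).

    Re-writes each candidate's delta_aicc relative to the winner's AICc.
    """
    valid = [(i, c) for i, c in enumerate(candidates) if c.valid]
    if not valid:
        raise ValueError("no valid candidates (all AICc undefined)")
    best_i, best = min(
        valid, key=lambda ic: (ic[1].aicc, ic[1].n_params, ic[1].rm, ic[0])
    )
    min_aicc = best.aicc
    for c in candidates:
        c.delta_aicc = (c.aicc - min_aicc) if c.valid else None
    return (best.rm, best.fc)


def draw_background(
    stack: EnvStack, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Random background sample of valid cells (without replacement, capped)."""
    mask = stack.mask
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("no valid cells to draw background from")
    n = min(n, len(rows))
    idx = rng.choice(len(rows), size=n, replace=False)
    return pd.DataFrame(stack.table(rows[idx], cols[idx]), columns=stack.names)


def tune(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm_values=DEFAULT_RM_GRID,
    fc_values=DEFAULT_FC_GRID,
    hinge_knots: int = 20,
    threshold_knots: int = 20,
    seed: int | None = None,
) -> TuningReport:
    """Fit every grid candidate, score by AICc, pick the winner."""
    results: list[CandidateResult] = []
    for rm, fc in tuning_grid(rm_values, fc_values):
        model = fit_maxent(
            presence, background, rm, classes=fc,
            hinge_knots=hinge_knots, threshold_knots=threshold_knots, seed=seed,
        )
        a, k, lnL = aicc(model, presence, background)
        results.append(
            CandidateResult(rm=rm, fc=fc, aicc=a, delta_aicc=None,
                            n_params=k, lnL=lnL)
        )
    best = select_best(results)
    return TuningReport(candidates=results, best=best, seed=seed)


def kfold_cv(
    presence: pd.DataFrame,
    stack: EnvStack,
    rm: float,
    fc: str,
    k: int = 10,
    n_background: int = 10_000,
    seed: int | None = None,
    transform: str = "cloglog",
    hinge_knots: int = 20,
    threshold_knots: int = 20,
    include_presence_in_background: bool = True,
) -> tuple[list[float], SuitabilityMap, list[MaxentModel]]:
    """k-fold cross-validation with fresh background per fold.

    Presences are partitioned into k seeded folds.  Each fold's model is
    trained on the remaining presences against a freshly drawn background
    sample and evaluated by AUC on the held-out presences scored against
    that same background.  Returns (per-fold AUCs, fold-averaged prediction
    map, fitted fold models).
    """
    n = len(presence)
    if n < k:
        raise ValueError(f"need at least k={k} presences, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    aucs: list[float] = []
    models: list[MaxentModel] = []
    for fold in folds:
        if len(fold) == 0:
            raise ValueError("empty cross-validation fold")
        test_idx = np.zeros(n, dtype=bool)
        test_idx[fold] = True
        train = presence.iloc[~test_idx]
        test = presence.iloc[test_idx]
        bg = draw_background(stack, n_background, rng)
        bg = bg[presence.columns]
        train_bg = (
            pd.concat([bg, train], ignore_index=True)
            if include_presence_in_background
            else bg
        )
        model = fit_maxent(
            train, train_bg, rm, classes=fc,
            hinge_knots=hinge_knots, threshold_knots=threshold_knots, seed=seed,
        )
        models.append(model)
        s_test = predict(model, test, "raw")
        s_bg = predict(model, bg, "raw")
        aucs.append(roc_auc(s_test, s_bg))
    maps = [
        predict_map(mod, stack.subset(list(presence.columns)), transform)
        for mod in models
    ]
    grid = stack.grid
    valid = maps[0].mask
    mean_vals = np.full(grid.shape, grid.nodata)
    mean_vals[valid] = np.mean([mp.values[valid] for mp in maps], axis=0)
    return aucs, SuitabilityMap(grid, mean_vals, transform), models
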