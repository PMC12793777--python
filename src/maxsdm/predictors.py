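"""Pairwise Pearson screening and greedy collinearity pruning of predictors.

Highly collinear predictor pairs (|r| at or above a cutoff, 0.8 by default)
carry nearly redundant information and destabilise variable-importance
estimates, so only one member of each pair is kept.  Which member survives
is controlled by an explicit priority list rather than an ad-hoc judgement
call, making the selection reproducible.  Topographic predictors are
typically exempted from the filter (they contribute terrain information not
captured by macroclimate), which the policy expresses as ``always_keep``;
predictors found uninformative a priori go in ``always_drop``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack

__all__ = ["CorrelationMatrix", "SelectionPolicy", "pearson_matrix",
           "sample_stack_cells", "prune_collinear"]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray                     # symmetric, unit diagonal; NaN = undefined
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variables)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape does not match variables")

    def value(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class SelectionPolicy:
    """How to resolve collinear pairs.

    ``priority`` lists every non-exempt variable, most-preferred first; the
    pruning walk keeps a variable iff it is below the threshold against all
    already-kept non-exempt variables.
    """

    threshold: float = 0.8
    priority: list[str] = field(default_factory=list)
    always_keep: set[str] = field(default_factory=lambda: {"elev", "slope"})
    always_drop: set[str] = field(default_factory=lambda: {"aspect"})

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


def pearson_matrix(samples: pd.DataFrame) -> CorrelationMatrix:
    """Product-moment correlations between all column pairs.

    Requires at least 3 complete rows.  Zero-variance columns yield NaN
    entries (flagged, treated as uncorrelated by the pruner).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if samples.isna().any().any():
        raise ValueError("samples contain missing values; drop nodata rows first")
    variables = list(samples.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = samples.corr(method="pearson").to_numpy()
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=variables, r=r, n_samples=len(samples))


def sample_stack_cells(
    stack: EnvStack, n: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """Predictor values at up to n randomly drawn valid cells (seeded)."""
    mask = stack.mask
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("stack has no valid cells")
    rng = np.random.default_rng(seed)
    if len(rows) > n:
        idx = rng.choice(len(rows), size=n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return pd.DataFrame(stack.table(rows, cols), columns=stack.names)


def prune_collinear(corr: CorrelationMatrix, policy: SelectionPolicy) -> list[str]:
    """Greedy priority-order pruning at the policy's |r| threshold.

    Returns retained variables in priority order, exempt (always_keep)
    variables appended.  Guarantees that no retained non-exempt pair has
    |r| >= threshold.  NaN correlations (zero-variance columns) never block
    retention.
    """
    present = set(corr.variables)
    exempt = policy.always_keep & present
    dropped = policy.always_drop & present
    candidates = present - exempt - dropped
    missing = candidates - set(policy.priority)
    if missing:
        raise ValueError(
            f"policy priority does not cover variables: {sorted(missing)}"
        )

    kept: list[str] = []
    for var in policy.priority:
        if var not in candidates:
            continue
        collides = False
        for other in kept:
            r = corr.value(var, other)
            if not np.isnan(r) and abs(r) >= policy.threshold:
                collides = True
                break
        if not collides:
            kept.append(var)
    kept.extend(v for v in corr.variables if v in exempt)
    return kept
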