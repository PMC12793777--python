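"""Penalized maximum-entropy presence/background model.

The model estimates a probability distribution q(x) over background cells,
q(x) ∝ exp(λ·f(x)), chosen to be as close to uniform as possible (maximum
entropy) subject to the fitted feature expectations matching their empirical
means at presence sites.  The Lagrangian dual of that problem is L1-penalized
maximum likelihood of the Gibbs density over presences:

    maximize  mean_presence[λ·f] − log Σ_background exp(λ·f) − Σ_j β_j |λ_j|

which is convex in λ.  Per-feature penalties β_j scale with the feature's
background standard deviation, shrink with presence sample size, and are
multiplied by a global regularization multiplier (RM) — the knob tuned
during model selection.

Feature classes expand each covariate (min-max scaled to [0, 1] over the
background, values clamped to that range) into:

    L  the scaled covariate itself
    Q  its square
    P  pairwise products of distinct scaled covariates
    H  forward/reverse hinges max(0, x−t)/(1−t), max(0, t−x)/t at evenly
       spaced knots t
    T  step indicators 1(x > t) at evenly spaced thresholds

Raw output is the fitted density over the training background (sums to 1);
the logistic and cloglog transforms map it onto a 0–1 suitability scale
using the fitted distribution's entropy H, so that a background cell with an
average raw score gets suitability 0.5 (logistic) or 1 − 1/e (cloglog).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import EnvStack, GridSpec

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "SuitabilityMap",
    "ConvergenceError",
    "build_features",
    "fit_maxent",
    "predict",
    "predict_map",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
]

VALID_CLASSES = "LQHPT"

# Default per-class base penalties interpolated over presence sample size,
# simplified from the MaxEnt defaults: (sample sizes, betas).
_BETA_SCHEDULE = {
    "L": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "Q": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "P": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "H": ([0, 1], [0.5, 0.5]),
    "T": ([10, 100], [2.0, 1.0]),
}


def beta_class(cls: str, n_presence: int) -> float:
    """Base L1 penalty for a feature class at a given presence count."""
    xs, ys = _BETA_SCHEDULE[cls]
    return float(np.interp(n_presence, xs, ys))


class ConvergenceError(RuntimeError):
    def __init__(self, grad_norm: float):
        super().__init__(
            f"maxent optimizer failed to converge (final gradient norm "
            f"{grad_norm:.3e})"
        )
        self.grad_norm = grad_norm


@dataclass
class FeatureSpec:
    """Feature expansion recipe plus the background scaling statistics."""

    classes: str
    covariates: list[str]
    ranges: dict[str, tuple[float, float]]
    means: dict[str, float] = field(default_factory=dict)
    hinge_knots: int = 20
    threshold_knots: int = 20

    def __post_init__(self) -> None:
        self.classes = "".join(c for c in VALID_CLASSES if c in self.classes.upper())
        bad = set(self.classes) - set(VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        if not self.classes:
            raise ValueError("feature class string must be non-empty")
        if ("H" in self.classes and self.hinge_knots < 2) or (
            "T" in self.classes and self.threshold_knots < 2
        ):
            raise ValueError("hinge/threshold features need at least 2 knots")

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        classes: str,
        hinge_knots: int = 20,
        threshold_knots: int = 20,
    ) -> "FeatureSpec":
        covs = list(background.columns)
        ranges = {
            c: (float(background[c].min()), float(background[c].max()))
            for c in covs
        }
        means = {c: float(background[c].mean()) for c in covs}
        return cls(
            classes=classes,
            covariates=covs,
            ranges=ranges,
            means=means,
            hinge_knots=hinge_knots,
            threshold_knots=threshold_knots,
        )

    def scale(self, values: pd.DataFrame) -> np.ndarray:
        """Min-max scale to [0, 1] with clamping to the background range."""
        out = np.empty((len(values), len(self.covariates)))
        for k, c in enumerate(self.covariates):
            lo, hi = self.ranges[c]
            x = np.asarray(values[c], dtype=float)
            if hi > lo:
                out[:, k] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
            else:
                out[:, k] = 0.5  # zero-range covariate: constant feature
        return out

    def zero_range(self) -> list[str]:
        return [c for c in self.covariates if self.ranges[c][0] == self.ranges[c][1]]


def build_features(
    values: pd.DataFrame, spec: FeatureSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Expand covariates into the design matrix.

    Returns (matrix, feature names, feature class per column).  Column order
    and naming are deterministic: L, Q, P, H, T blocks in covariate order.
    """
    x = spec.scale(values)
    cols: list[np.ndarray] = []
    names: list[str] = []
    classes: list[str] = []
    covs = spec.covariates

    def add(col: np.ndarray, name: str, cls: str) -> None:
        cols.append(col)
        names.append(name)
        classes.append(cls)

    if "L" in spec.classes:
        for k, c in enumerate(covs):
            add(x[:, k], f"L:{c}", "L")
    if "Q" in spec.classes:
        for k, c in enumerate(covs):
            add(x[:, k] ** 2, f"Q:{c}", "Q")
    if "P" in spec.classes:
        for i in range(len(covs)):
            for j in range(i + 1, len(covs)):
                add(x[:, i] * x[:, j], f"P:{covs[i]}*{covs[j]}", "P")
    if "H" in spec.classes:
        m = spec.hinge_knots
        fwd = np.arange(m) / m            # 0, 1/m, ... — knot 0 is linear
        rev = np.arange(1, m + 1) / m     # 1/m, ..., 1
        for k, c in enumerate(covs):
            for t in fwd:
                add(np.maximum(0.0, x[:, k] - t) / (1.0 - t), f"HF:{c}@{t:.4f}", "H")
            for t in rev:
                add(np.maximum(0.0, t - x[:, k]) / t, f"HR:{c}@{t:.4f}", "H")
    if "T" in spec.classes:
        m = spec.threshold_knots
        ts = np.arange(1, m + 1) / (m + 1)
        for k, c in enumerate(covs):
            for t in ts:
                add((x[:, k] > t).astype(float), f"T:{c}@{t:.4f}", "T")

    if not cols:
        return np.empty((len(values), 0)), [], []
    return np.column_stack(cols), names, classes


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model, sufficient to re-predict exactly."""

    feature_spec: FeatureSpec
    feature_names: list[str]
    feature_classes: list[str]
    lambdas: np.ndarray
    linear_predictor_normalizer: float   # max λ·f over training background
    density_normalizer: float            # Σ_bg exp(λ·f − lpn); raw sums to 1
    entropy_H: float                     # entropy of fitted raw distribution
    rm: float
    n_presence: int
    n_background: int
    seed: int | None = None

    @property
    def n_params(self) -> int:
        """Count of non-zero coefficients (|λ| > 1e-8)."""
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    # -- text serialization: enough to re-predict bit-identically ----------

    def to_text(self) -> str:
        import json

        spec = self.feature_spec
        doc = {
            "classes": spec.classes,
            "covariates": spec.covariates,
            "ranges": {c: list(spec.ranges[c]) for c in spec.covariates},
            "means": spec.means,
            "hinge_knots": spec.hinge_knots,
            "threshold_knots": spec.threshold_knots,
            "feature_names": self.feature_names,
            "feature_classes": self.feature_classes,
            "lambdas": [float(v) for v in self.lambdas],
            "linear_predictor_normalizer": self.linear_predictor_normalizer,
            "density_normalizer": self.density_normalizer,
            "entropy_H": self.entropy_H,
            "rm": self.rm,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "seed": self.seed,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "MaxentModel":
        import json

        doc = json.loads(text)
        spec = FeatureSpec(
            classes=doc["classes"],
            covariates=doc["covariates"],
            ranges={c: tuple(v) for c, v in doc["ranges"].items()},
            means=doc["means"],
            hinge_knots=doc["hinge_knots"],
            threshold_knots=doc["threshold_knots"],
        )
        return cls(
            feature_spec=spec,
            feature_names=doc["feature_names"],
            feature_classes=doc["feature_classes"],
            lambdas=np.array(doc["lambdas"], dtype=float),
            linear_predictor_normalizer=doc["linear_predictor_normalizer"],
            density_normalizer=doc["density_normalizer"],
            entropy_H=doc["entropy_H"],
            rm=doc["rm"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
            seed=doc["seed"],
        )

    def save(self, path) -> None:
        with open(str(path), "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(str(path)) as fh:
            return cls.from_text(fh.read())


@dataclass
class SuitabilityMap:
    """Per-cell suitability on a grid; nodata cells hold the grid sentinel."""

    grid: GridSpec
    values: np.ndarray
    transform: str = "cloglog"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability values do not match grid shape")

    @property
    def mask(self) -> np.ndarray:
        v = self.values
        return ~(np.isnan(v) | (v == self.grid.nodata))


def _penalties(
    spec: FeatureSpec,
    feature_classes: list[str],
    bg_sd: np.ndarray,
    rm: float,
    n_presence: int,
) -> np.ndarray:
    base = np.array([beta_class(c, n_presence) for c in feature_classes])
    beta = rm * base * bg_sd / np.sqrt(n_presence)
    # constant features get an effectively infinite penalty (sd 0 floor):
    # they cannot help the likelihood, so pin them via a tiny floor instead
    return np.maximum(beta, 1e-6)


def fit_maxent(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm: float,
    spec: FeatureSpec | None = None,
    classes: str = "LQ",
    hinge_knots: int = 20,
    threshold_knots: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit λ by maximizing the L1-penalized presence log-likelihood.

    The non-smooth L1 term is handled by the standard split λ = λ⁺ − λ⁻
    with non-negativity bounds, giving a smooth bound-constrained convex
    program solved by L-BFGS-B.  Deterministic given inputs.

    Parameters
    ----------
    presence, background
        Covariate tables (same columns).  If the background should contain
        the presence cells — the MaxEnt convention — concatenate before
        calling.
    rm
        Global regularization multiplier (> 0).
    spec
        Pre-built feature recipe; by default built from the background with
        the given classes and knot counts.
    """
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    n_presence = len(presence)
    if n_presence < 5:
        raise ValueError(f"need at least 5 presences, got {n_presence}")
    if spec is None:
        spec = FeatureSpec.from_background(
            background, classes, hinge_knots=hinge_knots,
            threshold_knots=threshold_knots,
        )
    F_bg, names, fclasses = build_features(background, spec)
    F_pr, _, _ = build_features(presence, spec)
    n_bg = len(background)

    if len(spec.covariates) and (presence[spec.covariates].nunique() == 1).all():
        import warnings

        warnings.warn("all presence records are identical", stacklevel=2)

    if F_bg.shape[1] == 0:
        lam = np.zeros(0)
        return _finalize(spec, names, fclasses, lam, F_bg, rm,
                         n_presence, n_bg, seed)

    bg_sd = F_bg.std(axis=0, ddof=0)
    beta = _penalties(spec, fclasses, bg_sd, rm, n_presence)
    mean_pres = F_pr.mean(axis=0)
    k = F_bg.shape[1]

    def neg_ll_and_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = F_bg @ lam
        lse = logsumexp(eta)
        q = np.exp(eta - lse)
        val = lse - mean_pres @ lam
        grad = F_bg.T @ q - mean_pres
        return val, grad

    def obj(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = theta[:k] - theta[k:]
        val, grad = neg_ll_and_grad(lam)
        val += beta @ (theta[:k] + theta[k:])
        return val, np.concatenate([grad + beta, -grad + beta])

    trace: list[float] = []

    res = minimize(
        obj,
        np.zeros(2 * k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        callback=lambda th: trace.append(obj(th)[0]),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    lam = res.x[:k] - res.x[k:]
    lam[np.abs(lam) < 1e-12] = 0.0

    # optimality residual of the L1 problem: distance of the smooth gradient
    # from the subdifferential of the penalty
    _, grad = neg_ll_and_grad(lam)
    resid = np.where(
        lam > 0, grad + beta,
        np.where(lam < 0, grad - beta, np.maximum(np.abs(grad) - beta, 0.0)),
    )
    grad_norm = float(np.max(np.abs(resid)))
    if not res.success and res.status not in (1,) and grad_norm > 1e-2:
        raise ConvergenceError(grad_norm)

    model = _finalize(spec, names, fclasses, lam, F_bg, rm,
                      n_presence, n_bg, seed)
    model.objective_trace = trace  # type: ignore[attr-defined]
    model.grad_norm = grad_norm    # type: ignore[attr-defined]
    return model


def _finalize(
    spec: FeatureSpec,
    names: list[str],
    fclasses: list[str],
    lam: np.ndarray,
    F_bg: np.ndarray,
    rm: float,
    n_presence: int,
    n_bg: int,
    seed: int | None,
) -> MaxentModel:
    eta = F_bg @ lam if F_bg.shape[1] else np.zeros(n_bg)
    lpn = float(eta.max()) if n_bg else 0.0
    w = np.exp(eta - lpn)
    Z = float(w.sum())
    raw = w / Z
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-(raw * np.log(raw)).sum())
    return MaxentModel(
        feature_spec=spec,
        feature_names=names,
        feature_classes=fclasses,
        lambdas=lam,
        linear_predictor_normalizer=lpn,
        density_normalizer=Z,
        entropy_H=H,
        rm=rm,
        n_presence=n_presence,
        n_background=n_bg,
        seed=seed,
    )


TRANSFORMS = ("raw", "logistic", "cloglog")


def predict(
    model: MaxentModel, values: pd.DataFrame, transform: str = "cloglog"
) -> np.ndarray:
    """Suitability at the given covariate values (clamped to training range).

    raw(x)      = exp(λ·f(x) − lpn) / Z           (density over background)
    logistic(x) = e^H·raw / (1 + e^H·raw)
    cloglog(x)  = 1 − exp(−e^H·raw)
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")
    F, _, _ = build_features(values, model.feature_spec)
    eta = F @ model.lambdas if F.shape[1] else np.zeros(len(values))
    raw = np.exp(eta - model.linear_predictor_normalizer) / model.density_normalizer
    if transform == "raw":
        return raw
    s = np.exp(model.entropy_H) * raw
    if transform == "logistic":
        return s / (1.0 + s)
    return 1.0 - np.exp(-s)


def predict_map(
    model: MaxentModel, stack: EnvStack, transform: str = "cloglog"
) -> SuitabilityMap:
    """Predict over every valid cell of a predictor stack."""
    grid = stack.grid
    mask = stack.mask
    rows, cols = np.nonzero(mask)
    table = pd.DataFrame(stack.table(rows, cols), columns=stack.names)
    table = table[model.feature_spec.covariates]
    vals = predict(model, table, transform)
    out = np.full(grid.shape, grid.nodata)
    out[rows, cols] = vals
    return SuitabilityMap(grid, out, transform)


def permutation_importance(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    n_reps: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Percent importance per covariate from AUC drop under permutation.

    Each covariate's column is permuted jointly across presence and
    background rows, scores are recomputed, and the AUC drop relative to
    the unpermuted model is recorded; drops are averaged over replicates,
    floored at zero, and normalized to sum to 100.  The per-replicate
    spread (standard deviation of the raw drop) is reported alongside.
    """
    from .evaluation import roc_auc

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(presence) == 0:
        raise ValueError("importance metric undefined without presences")
    rng = np.random.default_rng(seed)
    covs = model.feature_spec.covariates
    n_p = len(presence)
    combined = pd.concat(
        [presence[covs], background[covs]], ignore_index=True
    )
    base_scores = predict(model, combined, "raw")
    base_auc = roc_auc(base_scores[:n_p], base_scores[n_p:])

    drops = np.zeros((len(covs), n_reps))
    for rep in range(n_reps):
        for i, c in enumerate(covs):
            perm = combined.copy()
            perm[c] = rng.permutation(perm[c].to_numpy())
            s = predict(model, perm, "raw")
            drops[i, rep] = base_auc - roc_auc(s[:n_p], s[n_p:])
    mean_drop = drops.mean(axis=1)
    clipped = np.maximum(mean_drop, 0.0)
    total = clipped.sum()
    pct = 100.0 * clipped / total if total > 0 else np.zeros(len(covs))
    return pd.DataFrame(
        {
            "covariate": covs,
            "importance_pct": pct,
            "mean_auc_drop": mean_drop,
            "sd_auc_drop": drops.std(axis=1, ddof=0),
        }
    )


def _gain(model: MaxentModel, presence: pd.DataFrame) -> float:
    """Unpenalized mean presence log-likelihood relative to uniform."""
    raw = predict(model, presence, "raw")
    return float(np.mean(np.log(raw)) + np.log(model.n_background))


def jackknife_gains(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    classes: str = "LQ",
    rm: float = 1.0,
    **fit_kw,
) -> pd.DataFrame:
    """Training gain with each variable alone, without it, and with all.

    Gain is the fitted model's mean presence log-likelihood minus that of
    the uniform model (log 1/n_background); the full model's gain is
    reported in every row for reference.
    """
    covs = list(background.columns)
    if len(covs) < 2:
        raise ValueError("jackknife needs at least 2 covariates")
    full = fit_maxent(presence, background, rm, classes=classes, **fit_kw)
    full_gain = _gain(full, presence)
    rows = []
    for c in covs:
        only = fit_maxent(
            presence[[c]], background[[c]], rm, classes=classes, **fit_kw
        )
        rest = [v for v in covs if v != c]
        without = fit_maxent(
            presence[rest], background[rest], rm, classes=classes, **fit_kw
        )
        rows.append(
            {
                "covariate": c,
                "gain_only": _gain(only, presence[[c]]),
                "gain_without": _gain(without, presence[rest]),
                "gain_full": full_gain,
            }
        )
    return pd.DataFrame(rows)


def response_curve(
    model: MaxentModel,
    covariate: str,
    n_points: int = 100,
    transform: str = "cloglog",
    kind: str = "mean",
    background: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Suitability as a function of one covariate.

    ``kind='mean'`` holds all other covariates at their background means;
    ``kind='marginal'`` averages predictions over the background rows with
    the target covariate overwritten (requires ``background``).
    """
    spec = model.feature_spec
    if covariate not in spec.covariates:
        raise KeyError(f"covariate {covariate!r} not in model")
    lo, hi = spec.ranges[covariate]
    xs = np.linspace(lo, hi, n_points)
    if kind == "mean":
        base = pd.DataFrame(
            {c: np.full(n_points, spec.means[c]) for c in spec.covariates}
        )
        base[covariate] = xs
        ys = predict(model, base, transform)
    elif kind == "marginal":
        if background is None:
            raise ValueError("marginal curves require the background table")
        ys = np.empty(n_points)
        for i, x in enumerate(xs):
            tbl = background[spec.covariates].copy()
            tbl[covariate] = x
            ys[i] = float(np.mean(predict(model, tbl, transform)))
    else:
        raise ValueError("kind must be 'mean' or 'marginal'")
    return pd.DataFrame({covariate: xs, "suitability": ys})
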