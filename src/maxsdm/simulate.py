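"""Virtual-species simulation: climate-like layers, known truth, occurrences.

The generator emulates the inputs of a country-scale SDM study so the whole
pipeline can be exercised and validated without any downloads: a stack of
spatially autocorrelated, climate-like predictor layers with controllable
pairwise correlations; a known true suitability surface assembled from
unimodal (Gaussian) response functions; presence records sampled
proportional to that truth; and future scenario stacks produced by
additive/multiplicative shifts of selected layers.

Each layer is built as a deterministic mixture of a smooth
latitudinal/longitudinal gradient and moving-average-smoothed white noise.
The standardized fields are orthonormalized (QR) and re-mixed through the
Cholesky factor of the requested correlation matrix, so the realized
pairwise Pearson correlations match the request essentially exactly — a
deliberately stronger guarantee than collinearity-pruning tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .grids import EnvStack, GridSpec, Layer
from .maxent import SuitabilityMap
from .occurrences import Occurrence, OccurrenceSet

__all__ = [
    "VirtualSpeciesConfig",
    "generate_env_stack",
    "true_suitability",
    "sample_occurrences",
    "make_future_stack",
]

# plausible spans for climate-like variables: (mean, full range)
_DEFAULT_LAYER_STATS = {
    "bio1": (16.0, 20.0),     # annual mean temperature, °C
    "bio7": (28.0, 16.0),     # temperature annual range, °C
    "bio12": (1300.0, 1400.0),  # annual precipitation, mm
    "bio15": (65.0, 50.0),    # precipitation seasonality
    "elev": (900.0, 2400.0),  # elevation, m
}


@dataclass
class VirtualSpeciesConfig:
    """All knobs of one simulated study; the seed fixes every draw."""

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 100
    origin_lon: float = 100.0
    origin_lat: float = 32.0
    cell_size: float = 0.05
    layer_names: list[str] = field(
        default_factory=lambda: list(_DEFAULT_LAYER_STATS)
    )
    layer_stats: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LAYER_STATS)
    )
    # requested pairwise Pearson correlations, e.g. {("bio1","bio7"): 0.9}
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    # per-layer Gaussian response: layer -> (optimum, width) in layer units
    response: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"bio1": (18.0, 2.5), "bio12": (1600.0, 450.0)}
    )
    n_presence: int = 200
    smooth_window: int = 9       # moving-average kernel width, cells
    noise_weight: float = 0.35   # noise share of each standardized field
    nodata: float = -9999.0

    def grid(self) -> GridSpec:
        return GridSpec(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            nodata=self.nodata,
        )


def _target_correlation(cfg: VirtualSpeciesConfig) -> np.ndarray:
    k = len(cfg.layer_names)
    c = np.eye(k)
    idx = {n: i for i, n in enumerate(cfg.layer_names)}
    for (a, b), r in cfg.correlations.items():
        if a not in idx or b not in idx:
            raise ValueError(f"correlation refers to unknown layer ({a}, {b})")
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semidefinite")
    return c


def generate_env_stack(cfg: VirtualSpeciesConfig) -> EnvStack:
    """Simulate the predictor stack (deterministic for a given seed)."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    nr, nc = grid.shape
    n_cells = nr * nc
    k = len(cfg.layer_names)

    rowg = np.linspace(-1.0, 1.0, nr)[:, None] * np.ones((1, nc))  # south-high
    colg = np.ones((nr, 1)) * np.linspace(-1.0, 1.0, nc)[None, :]

    fields = np.empty((n_cells, k))
    for i in range(k):
        if i == 0:
            # first layer is temperature-like: strong equatorward gradient
            w_lat, w_lon = 1.0, 0.2
        else:
            w_lat = rng.uniform(-1.0, 1.0)
            w_lon = rng.uniform(-1.0, 1.0)
        noise = uniform_filter(
            rng.standard_normal((nr, nc)), size=cfg.smooth_window, mode="nearest"
        )
        f = (1.0 - cfg.noise_weight) * (w_lat * rowg + w_lon * colg)
        f = f + cfg.noise_weight * noise / max(noise.std(), 1e-12)
        fields[:, i] = f.ravel()

    # exact correlation structure: orthonormalize, then mix by Cholesky
    fields -= fields.mean(axis=0)
    q, _ = np.linalg.qr(fields)
    q *= np.sign(np.sum(q * fields, axis=0))  # keep each field's orientation
    target = _target_correlation(cfg)
    chol = np.linalg.cholesky(target + 1e-12 * np.eye(k))
    mixed = q @ chol.T
    mixed /= mixed.std(axis=0, ddof=0)

    stack = EnvStack(grid)
    for i, name in enumerate(cfg.layer_names):
        mean, span = cfg.layer_stats.get(name, (0.0, 2.0))
        values = (mean + (span / 4.0) * mixed[:, i]).reshape(nr, nc)
        stack.add(Layer(grid, values, name))
    return stack


def true_suitability(stack: EnvStack, cfg: VirtualSpeciesConfig) -> SuitabilityMap:
    """Product of per-layer Gaussian responses, normalized to a max of 1."""
    grid = stack.grid
    suit = np.ones(grid.shape)
    for name, (opt, width) in cfg.response.items():
        if name not in stack:
            raise ValueError(f"response refers to missing layer {name!r}")
        x = stack[name].values
        suit *= np.exp(-0.5 * ((x - opt) / width) ** 2)
    valid = stack.mask
    peak = suit[valid].max()
    if peak > 0:
        suit = suit / peak
    out = np.full(grid.shape, grid.nodata)
    out[valid] = suit[valid]
    return SuitabilityMap(grid, out, "truth")


def sample_occurrences(
    truth: SuitabilityMap,
    n: int,
    seed: int | None = None,
    bias: np.ndarray | None = None,
    species: str = "virtual",
) -> OccurrenceSet:
    """Draw presence cells without replacement with probability ∝ truth × bias.

    One record per drawn cell, jittered uniformly within the cell so records
    behave like point observations rather than cell centers.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    grid = truth.grid
    w = np.where(truth.mask, truth.values, 0.0)
    if bias is not None:
        w = w * bias
    w = np.clip(w, 0.0, None)
    flat = w.ravel()
    positive = np.flatnonzero(flat > 0)
    if len(positive) == 0:
        raise ValueError("true suitability has no positive mass")
    n_draw = min(n, len(positive))
    rng = np.random.default_rng(seed)
    p = flat[positive] / flat[positive].sum()
    chosen = rng.choice(positive, size=n_draw, replace=False, p=p)

    occ = OccurrenceSet(species=species)
    for m, cell in enumerate(chosen):
        i, j = divmod(int(cell), grid.n_cols)
        du, dv = rng.uniform(0.02, 0.98, size=2)
        lon = grid.origin_lon + (j + du) * grid.cell_size
        lat = grid.origin_lat - (i + dv) * grid.cell_size
        occ.records.append(Occurrence(lon, lat, f"sim{m + 1}"))
    return occ


def make_future_stack(
    base: EnvStack, deltas: dict[str, tuple[float, float]]
) -> EnvStack:
    """Scenario stack: layer' = layer × scale + shift for each (scale, shift).

    Layers absent from ``deltas`` are copied unchanged; nodata cells are
    preserved.
    """
    unknown = set(deltas) - set(base.names)
    if unknown:
        raise ValueError(f"deltas refer to unknown layers {sorted(unknown)}")
    out = EnvStack(base.grid)
    for name in base.names:
        layer = base[name]
        if name in deltas:
            scale, shift = deltas[name]
            v = layer.values.copy()
            m = layer.mask
            v[m] = v[m] * scale + shift
            out.add(Layer(base.grid, v, name))
        else:
            out.add(Layer(base.grid, layer.values.copy(), name))
    return out
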