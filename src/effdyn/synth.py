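"""Seeded synthetic region-year production panels with known ground truth.

The generator emulates the statistical structure of a provincial
healthcare-efficiency panel (by default 31 regions x 20 years, three
inputs, two outputs) without mimicking any real geography:

* a latent 3-state efficiency process per region follows a known
  row-stochastic kernel (default: a published provincial transition matrix
  with diagonal persistence 0.72-0.89);
* each state carries a mean radial efficiency level, the top state sitting
  exactly on the frontier so DEA has frontier units to envelop;
* outputs are drawn log-normally with region-level scale heterogeneity, and
  the frontier input requirement is a fixed monotone *convex* function of
  outputs (region-invariant technology), so the implied production set is
  convex and every noise-free frontier unit is BCC-efficient;
* inefficiency enters radially on inputs — inputs are the frontier
  requirement divided by true efficiency — matching the input orientation
  of the DEA stage;
* optional spatial coupling: each step a region copies a random neighbour's
  previous state with the configured probability, producing conditional
  dependence of transitions on the neighbourhood context;
* optional covariate effects tilt the probability mass of upward/downward
  moves linearly in centred covariates, giving the transition regressions a
  recoverable signal.

Identical configs (including seed) produce byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dea import ProductionPanel
from .markov import ReducibleChainError, stationary_of_matrix
from .reference import DEFAULT_STATE_EFFICIENCY_LEVELS, published_transition_matrix
from .spatial import SpatialWeights

__all__ = [
    "COVARIATE_PARAMS",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_panel",
    "generate_adjacency",
    "generate_covariates",
    "frontier_inputs",
    "simulate_states",
]

#: Generation mean and standard deviation of each covariate, on scales a
#: provincial health-resource panel would show (ratio of physicians to
#: nurses, health staff per 10k population, beds per staff member, log GDP
#: per capita).
COVARIATE_PARAMS: dict[str, tuple[float, float]] = {
    "doctor_nurse_ratio": (0.96, 0.24),
    "staff_per_10k": (45.0, 12.0),
    "beds_per_staff": (0.63, 0.09),
    "ln_gdp_pc": (10.2, 0.55),
}

EffectSpec = Union[float, tuple[float, float]]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic panel generator.

    covariate_effects maps a covariate name to its signed effect on the
    upward transition propensity, or to an ``(upward, downward)`` pair; the
    effect is the slope on the *centred raw* covariate, so a linear
    probability model on the raw covariate recovers it directly.
    """

    n_regions: int = 31
    n_years: int = 20
    n_inputs: int = 3
    n_outputs: int = 2
    true_transition: np.ndarray = field(default_factory=published_transition_matrix)
    state_inefficiency_levels: Sequence[float] = DEFAULT_STATE_EFFICIENCY_LEVELS
    noise_sd: float = 0.05
    spatial_coupling: float = 0.0
    adjacency_scheme: str = "grid_lattice"  # or "supplied_edge_list"
    covariate_effects: Mapping[str, EffectSpec] = field(default_factory=dict)
    initial_state_distribution: Optional[Sequence[float]] = None
    start_year: int = 2001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_years < 1:
            raise ValueError("n_regions and n_years must be positive")
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be positive")
        P = np.asarray(self.true_transition, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("true_transition must be square")
        if (P < 0).any() or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("true_transition rows must be nonnegative and sum to 1 within 1e-12")
        self.true_transition = P
        levels = np.asarray(self.state_inefficiency_levels, dtype=float)
        if len(levels) != P.shape[0]:
            raise ValueError("one inefficiency level per state is required")
        if (levels <= 0).any() or (levels > 1).any():
            raise ValueError("state inefficiency levels must lie in (0, 1]")
        if levels[-1] != 1.0:
            raise ValueError("the top state level must be 1.0 so frontier units exist")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.spatial_coupling <= 1.0:
            raise ValueError("spatial_coupling must lie in [0, 1]")
        if self.adjacency_scheme not in ("grid_lattice", "supplied_edge_list"):
            raise ValueError(f"unknown adjacency_scheme: {self.adjacency_scheme!r}")
        unknown = set(self.covariate_effects) - set(COVARIATE_PARAMS)
        if unknown:
            raise ValueError(f"unknown covariates in covariate_effects: {sorted(unknown)}")
        if self.initial_state_distribution is not None:
            d = np.asarray(self.initial_state_distribution, dtype=float)
            if len(d) != P.shape[0] or (d < 0).any() or abs(d.sum() - 1.0) > 1e-12:
                raise ValueError("initial_state_distribution must be a probability vector over states")

    @property
    def n_states(self) -> int:
        return self.true_transition.shape[0]

    @property
    def region_ids(self) -> list[str]:
        width = max(2, len(str(self.n_regions)))
        return [f"R{i + 1:0{width}d}" for i in range(self.n_regions)]

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def effect_pair(self, name: str) -> tuple[float, float]:
        eff = self.covariate_effects.get(name, (0.0, 0.0))
        if np.isscalar(eff):
            return float(eff), 0.0
        up, down = eff
        return float(up), float(down)


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would not."""

    table: pd.DataFrame  # region_id, year, state, true_efficiency
    frontier_spec: dict
    covariates: pd.DataFrame

    @property
    def latent_states(self) -> pd.DataFrame:
        return self.table[["region_id", "year", "state"]]

    @property
    def true_efficiency(self) -> pd.DataFrame:
        return self.table[["region_id", "year", "true_efficiency"]]


def _best_rectangle(n: int) -> tuple[int, int]:
    """Nearest rectangle r x c >= n: minimal unused cells among shapes with
    aspect ratio c/r <= 2, falling back to the unconstrained minimum (then
    the squarest shape) for very small n where no such shape exists."""
    candidates = []
    for r in range(1, int(np.sqrt(n)) + 1):
        c = -(-n // r)  # ceil
        candidates.append((r * c - n, c - r, r, c))
    shaped = [t for t in candidates if t[3] <= 2 * t[2]]
    waste, _, r, c = min(shaped or candidates)
    return r, c


def generate_adjacency(config: SyntheticConfig) -> SpatialWeights:
    """Rook-adjacency lattice over the configured regions.

    Regions fill the nearest rectangle in row-major order; surplus cells are
    dropped, so e.g. 31 regions occupy 31 cells of a 4 x 8 grid.
    """
    n = config.n_regions
    r, c = _best_rectangle(n)
    ids = config.region_ids
    edges = []
    for cell in range(n):
        row, col = divmod(cell, c)
        right = cell + 1
        if col + 1 < c and right < n:
            edges.append((ids[cell], ids[right]))
        below = cell + c
        if below < n:
            edges.append((ids[cell], ids[below]))
    return SpatialWeights(edges, regions=ids)


def _initial_distribution(config: SyntheticConfig) -> np.ndarray:
    if config.initial_state_distribution is not None:
        return np.asarray(config.initial_state_distribution, dtype=float)
    try:
        return stationary_of_matrix(config.true_transition).pi
    except ReducibleChainError:
        k = config.n_states
        return np.full(k, 1.0 / k)


def _tilted_row(row: np.ndarray, s_idx: int, tilt_up: float, tilt_down: float) -> np.ndarray:
    """Shift upward/downward mass of a kernel row by linear tilts.

    The diagonal absorbs the adjustment; block shapes follow the base row,
    with mass placed on the adjacent state when a base block is empty.
    """
    k = len(row)
    up_ix = np.arange(s_idx + 1, k)
    down_ix = np.arange(0, s_idx)
    base_up = row[up_ix].sum() if up_ix.size else 0.0
    base_down = row[down_ix].sum() if down_ix.size else 0.0

    up = float(np.clip(base_up + tilt_up, 0.0, 1.0)) if up_ix.size else 0.0
    down = float(np.clip(base_down + tilt_down, 0.0, 1.0)) if down_ix.size else 0.0
    total = up + down
    if total > 1.0:
        up, down = up / total, down / total

    new = np.zeros(k)
    if up_ix.size:
        if base_up > 0:
            new[up_ix] = row[up_ix] / base_up * up
        else:
            new[s_idx + 1] = up
    if down_ix.size:
        if base_down > 0:
            new[down_ix] = row[down_ix] / base_down * down
        else:
            new[s_idx - 1] = down
    new[s_idx] = 1.0 - up - down
    return new


def _generate_covariate_array(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_regions, n_years, n_covariates) array with region random intercepts."""
    n_r, n_y = config.n_regions, config.n_years
    names = list(COVARIATE_PARAMS)
    out = np.empty((n_r, n_y, len(names)))
    region_fx = rng.standard_normal((n_r, len(names)))
    idio = rng.standard_normal((n_r, n_y, len(names)))
    for c, name in enumerate(names):
        mu, sd = COVARIATE_PARAMS[name]
        vals = mu + sd * (0.5 * region_fx[:, None, c] + np.sqrt(1 - 0.25) * idio[:, :, c])
        if name != "ln_gdp_pc":
            vals = np.maximum(vals, 0.05 * mu)  # ratios and densities stay positive
        out[:, :, c] = vals
    return out


def simulate_states(
    config: SyntheticConfig,
    rng: np.random.Generator,
    weights: Optional[SpatialWeights] = None,
    covariate_array: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Latent state paths (n_regions x n_years, values 1..K).

    Each step a region copies a uniformly chosen neighbour's previous state
    with probability ``spatial_coupling``; otherwise it draws from its own
    kernel row, tilted by the covariate effects evaluated at the origin
    year.
    """
    n_r, n_y, k = config.n_regions, config.n_years, config.n_states
    P = config.true_transition
    names = list(COVARIATE_PARAMS)
    effects = {name: config.effect_pair(name) for name in names}
    any_effect = any(u != 0 or d != 0 for u, d in effects.values())

    neighbor_idx: list[list[int]] = [[] for _ in range(n_r)]
    if config.spatial_coupling > 0:
        if weights is None:
            raise ValueError("spatial_coupling > 0 requires spatial weights")
        pos = {rid: i for i, rid in enumerate(config.region_ids)}
        for r, rid in enumerate(config.region_ids):
            neighbor_idx[r] = [pos[n] for n in weights.neighbors(rid) if n in pos]

    states = np.empty((n_r, n_y), dtype=int)
    init = _initial_distribution(config)
    states[:, 0] = rng.choice(k, size=n_r, p=init) + 1

    for t in range(1, n_y):
        copy_draw = rng.random(n_r)
        for r in range(n_r):
            s = states[r, t - 1]
            if (
                config.spatial_coupling > 0
                and neighbor_idx[r]
                and copy_draw[r] < config.spatial_coupling
            ):
                donor = neighbor_idx[r][rng.integers(len(neighbor_idx[r]))]
                states[r, t] = states[donor, t - 1]
                continue
            row = P[s - 1]
            if any_effect and covariate_array is not None:
                tilt_up = tilt_down = 0.0
                for c, name in enumerate(names):
                    up, down = effects[name]
                    if up or down:
                        z = covariate_array[r, t - 1, c] - COVARIATE_PARAMS[name][0]
                        tilt_up += up * z
                        tilt_down += down * z
                row = _tilted_row(row, s - 1, tilt_up, tilt_down)
            states[r, t] = rng.choice(k, p=row) + 1
    return states


def frontier_inputs(outputs: np.ndarray, frontier_spec: dict) -> np.ndarray:
    """Frontier (minimum) input requirement for given output bundles.

    ``x_k = base_k * (W_k . y / y_base)^{c_k}`` with exponents c_k > 1:
    monotone and convex in outputs, hence a convex production set on which
    the piecewise-linear VRS envelope is exact at observed frontier points.
    """
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    W = np.asarray(frontier_spec["weights"])  # m x s
    exponents = np.asarray(frontier_spec["exponents"])  # m
    x_base = np.asarray(frontier_spec["input_base"])  # m
    y_base = np.asarray(frontier_spec["output_base"])  # s
    agg = (Y / y_base) @ W.T
    return x_base * agg ** exponents


def generate_panel(
    config: SyntheticConfig,
    weights: Optional[SpatialWeights] = None,
) -> tuple[ProductionPanel, SyntheticTruth]:
    """Generate a complete synthetic production panel and its ground truth."""
    if config.adjacency_scheme == "supplied_edge_list" and config.spatial_coupling > 0 and weights is None:
        raise ValueError("supplied_edge_list scheme requires a SpatialWeights object")
    if config.spatial_coupling > 0 and weights is None:
        weights = generate_adjacency(config)

    rng = np.random.default_rng(config.seed)
    n_r, n_y = config.n_regions, config.n_years
    m, s = config.n_inputs, config.n_outputs
    levels = np.asarray(config.state_inefficiency_levels, dtype=float)

    # region-invariant technology, drawn once per config
    frontier_spec = {
        "weights": rng.dirichlet(np.full(s, 2.0), size=m),
        "exponents": rng.uniform(1.10, 1.35, size=m),
        "input_base": 400.0 * (1.0 + 0.5 * np.arange(m)),
        "output_base": 1000.0 / (5.0 ** np.arange(s)),
    }

    covariate_array = _generate_covariate_array(config, rng)
    states = simulate_states(config, rng, weights=weights, covariate_array=covariate_array)
    true_eff = levels[states - 1]

    region_scale = np.exp(rng.normal(0.0, 0.5, size=n_r))
    idio = np.exp(rng.normal(0.0, 0.25, size=(n_r, n_y, s)))
    outputs = frontier_spec["output_base"] * region_scale[:, None, None] * idio

    x_frontier = frontier_inputs(outputs.reshape(-1, s), frontier_spec).reshape(n_r, n_y, m)
    noise = (
        np.exp(rng.normal(0.0, config.noise_sd, size=(n_r, n_y, m)))
        if config.noise_sd > 0
        else np.ones((n_r, n_y, m))
    )
    inputs = x_frontier / true_eff[:, :, None] * noise

    input_cols = [f"x{k + 1}" for k in range(m)]
    output_cols = [f"y{k + 1}" for k in range(s)]
    ids = config.region_ids
    years = config.years
    rows = []
    for r in range(n_r):
        for t in range(n_y):
            row = {"region_id": ids[r], "year": years[t]}
            row.update({c: inputs[r, t, k] for k, c in enumerate(input_cols)})
            row.update({c: outputs[r, t, k] for k, c in enumerate(output_cols)})
            rows.append(row)
    panel = ProductionPanel(pd.DataFrame(rows), input_cols=input_cols, output_cols=output_cols)

    truth_table = pd.DataFrame(
        {
            "region_id": np.repeat(ids, n_y),
            "year": np.tile(years, n_r),
            "state": states.reshape(-1),
            "true_efficiency": true_eff.reshape(-1),
        }
    )
    cov_names = list(COVARIATE_PARAMS)
    cov_df = pd.DataFrame(
        covariate_array.reshape(-1, len(cov_names)),
        columns=cov_names,
    )
    cov_df.insert(0, "year", np.tile(years, n_r))
    cov_df.insert(0, "region_id", np.repeat(ids, n_y))

    truth = SyntheticTruth(table=truth_table, frontier_spec=frontier_spec, covariates=cov_df)
    return panel, truth


def generate_covariates(config: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Covariate table for the transition regressions.

    The covariates are drawn during panel generation (they must precede the
    state path so that configured effects can tilt it); this accessor
    returns them in long format.
    """
    return truth.covariates.copy()
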