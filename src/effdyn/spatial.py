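"""Spatial Markov analysis: neighbour-state lags and conditional transitions.

The neighbourhood indicator of a region-year is the unweighted mean of its
contiguity neighbours' contemporaneous states (the region itself is never
part of its own neighbourhood).  Pooled lag values are cut at their
terciles into low/medium/high neighbourhood contexts, and a separate
transition matrix is estimated for the transitions originating in each
context: the context at origin year t conditions the t -> t+1 transition.
Regions with no neighbours (islands) are excluded from the conditional
analysis with a logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .markov import TransitionEstimate, _transition_pairs
from .states import StatePanel, classify_values

__all__ = [
    "SpatialWeights",
    "ContextPanel",
    "spatial_lag",
    "same_region_lag",
    "assign_contexts",
    "conditional_transitions",
    "context_contrast",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Undirected region adjacency as a set of unordered id pairs.

    ``regions`` is the full region universe; ids appearing in no edge are
    islands and get no spatial lag.
    """

    edges: frozenset
    regions: tuple

    def __init__(self, edges: Iterable[tuple], regions: Optional[Iterable] = None):
        norm = set()
        touched = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on region {a!r}")
            norm.add(frozenset((a, b)))
            touched.update((a, b))
        object.__setattr__(self, "edges", frozenset(norm))
        if regions is None:
            regions = sorted(touched)
        object.__setattr__(self, "regions", tuple(regions))
        unknown = touched - set(self.regions)
        if unknown:
            raise ValueError(f"edge regions not in region universe: {sorted(unknown)}")

    @property
    def islands(self) -> frozenset:
        touched = set()
        for e in self.edges:
            touched.update(e)
        return frozenset(r for r in self.regions if r not in touched)

    def neighbors(self, region) -> list:
        out = []
        for e in self.edges:
            if region in e:
                (other,) = e - {region}
                out.append(other)
        return sorted(out, key=str)

    def to_edge_list(self) -> pd.DataFrame:
        rows = sorted((sorted(e, key=str) for e in self.edges), key=lambda p: (str(p[0]), str(p[1])))
        return pd.DataFrame(rows, columns=["region_a", "region_b"])

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, regions: Optional[Iterable] = None) -> "SpatialWeights":
        pairs = list(df.itertuples(index=False, name=None))
        return cls(pairs, regions=regions)


@dataclass
class ContextPanel:
    """Region-year neighbourhood lag values and discrete contexts."""

    data: pd.DataFrame  # columns: region_id, year, lag_value, context (nullable)
    context_thresholds: Optional[np.ndarray] = None
    scheme: str = "tercile"
    n_islands: int = 0


def _neighbor_map(states: pd.DataFrame, weights: SpatialWeights) -> dict:
    panel_regions = set(states["region_id"].unique())
    missing = panel_regions - set(weights.regions)
    if missing:
        raise ValueError(f"regions missing from spatial weights: {sorted(missing, key=str)}")
    return {r: weights.neighbors(r) for r in panel_regions}


def spatial_lag(states: StatePanel, weights: SpatialWeights) -> ContextPanel:
    """Mean contemporaneous neighbour state per region-year.

    Islands receive an undefined (NaN) lag and are excluded downstream;
    their count is logged.
    """
    df = states.data
    nbrs = _neighbor_map(df, weights)
    wide = df.pivot(index="year", columns="region_id", values="state")

    records = []
    for region, neigh in nbrs.items():
        present = [n for n in neigh if n in wide.columns]
        for year in wide.index[wide[region].notna()]:
            if present:
                vals = wide.loc[year, present].dropna()
                lag = float(vals.mean()) if len(vals) else np.nan
            else:
                lag = np.nan
            records.append({"region_id": region, "year": int(year), "lag_value": lag})
    out = pd.DataFrame.from_records(records).sort_values(["region_id", "year"]).reset_index(drop=True)
    n_islands = len(set(df["region_id"].unique()) & set(weights.islands))
    if n_islands:
        logger.info("spatial lag: %d island region(s) excluded from conditional analysis", n_islands)
    return ContextPanel(data=out, n_islands=n_islands, scheme="lag_only")


def same_region_lag(states: StatePanel, region_groups: Mapping) -> ContextPanel:
    """Lag values with geographic neighbours replaced by same-group members.

    ``region_groups`` maps region_id -> group label; the lag of a region is
    the mean state of the other members of its group in the same year.
    """
    df = states.data
    missing = set(df["region_id"].unique()) - set(region_groups)
    if missing:
        raise ValueError(f"regions missing from region_groups: {sorted(missing, key=str)}")
    groups = pd.Series(region_groups, name="group")
    work = df.merge(groups.rename_axis("region_id").reset_index(), on="region_id")
    gsum = work.groupby(["group", "year"])["state"].agg(["sum", "count"]).reset_index()
    work = work.merge(gsum, on=["group", "year"])
    with np.errstate(invalid="ignore"):
        work["lag_value"] = np.where(
            work["count"] > 1,
            (work["sum"] - work["state"]) / (work["count"] - 1),
            np.nan,
        )
    out = work[["region_id", "year", "lag_value"]].sort_values(["region_id", "year"]).reset_index(drop=True)
    return ContextPanel(data=out, scheme="lag_only")


def assign_contexts(lags: ContextPanel, n_contexts: int = 3) -> ContextPanel:
    """Cut pooled lag values at their terciles into discrete contexts 1..C.

    Uses the same linear-interpolation quantiles and lower-closed boundary
    convention as the efficiency-state classification.
    """
    df = lags.data.copy()
    defined = df["lag_value"].dropna().to_numpy()
    if defined.size == 0:
        raise ValueError("no defined lag values to classify")
    if len(np.unique(defined)) < n_contexts:
        warnings.warn("fewer distinct lag values than contexts; contexts are degenerate",
                      stacklevel=2)
    qs = np.linspace(0, 1, n_contexts + 1)[1:-1]
    if n_contexts == 3:
        qs = np.array([0.33, 0.67])
    thresholds = np.quantile(defined, qs)
    ctx = np.full(len(df), np.nan)
    mask = df["lag_value"].notna().to_numpy()
    ctx[mask] = classify_values(df.loc[mask, "lag_value"].to_numpy(), thresholds)
    df["context"] = pd.array(ctx, dtype="Int64")
    return ContextPanel(
        data=df,
        context_thresholds=thresholds,
        scheme="tercile" if n_contexts == 3 else f"quantile_{n_contexts}",
        n_islands=lags.n_islands,
    )


def conditional_transitions(
    states: StatePanel, contexts: ContextPanel
) -> dict[int, TransitionEstimate]:
    """One transition estimate per neighbourhood context.

    A transition (r, t -> t+1) is assigned to the context of (r, t); pairs
    whose origin context is undefined (islands) are dropped.
    """
    if "context" not in contexts.data.columns:
        raise ValueError("contexts have not been assigned; call assign_contexts first")
    pairs = _transition_pairs(states.data)
    merged = pairs.merge(
        contexts.data[["region_id", "year", "context"]], on=["region_id", "year"], how="left"
    )
    dropped = int(merged["context"].isna().sum())
    if dropped:
        logger.info("conditional transitions: %d origin pairs without context dropped", dropped)
    merged = merged.dropna(subset=["context"])

    k = states.n_states
    out: dict[int, TransitionEstimate] = {}
    all_contexts = sorted(int(c) for c in contexts.data["context"].dropna().unique())
    for c in all_contexts:
        sub = merged[merged["context"] == c]
        counts = np.zeros((k, k), dtype=int)
        for i, j in zip(sub["state"].to_numpy(), sub["next_state"].to_numpy()):
            counts[i - 1, j - 1] += 1
        row_sums = counts.sum(axis=1)
        undefined = frozenset(int(i) for i in np.flatnonzero(row_sums == 0))
        probs = np.full((k, k), np.nan)
        d = row_sums > 0
        probs[d] = counts[d] / row_sums[d, None]
        out[c] = TransitionEstimate(
            counts=counts,
            probabilities=probs,
            n_transitions=int(counts.sum()),
            undefined_rows=undefined,
            threshold_spec=states.threshold_spec,
        )
    return out


KEY_CELLS = ((1, 1), (1, 2), (2, 3), (3, 3))


def context_contrast(per_context: Mapping[int, TransitionEstimate]) -> pd.DataFrame:
    """Long table of per-context cell probabilities with cross-context spreads.

    Undefined cells propagate as missing values.  The ``spread`` column (max
    minus min across contexts) is attached per cell for the key cells
    p11, p12, p23, p33 commonly used to read spatial conditioning.
    """
    if len(per_context) < 2:
        raise ValueError("need at least two contexts to contrast")
    rows = []
    for c, est in sorted(per_context.items()):
        k = est.n_states
        for i in range(k):
            for j in range(k):
                rows.append(
                    {
                        "cell": f"p{i + 1}{j + 1}",
                        "from_state": i + 1,
                        "to_state": j + 1,
                        "context": c,
                        "probability": est.probabilities[i, j],
                        "key_cell": (i + 1, j + 1) in KEY_CELLS,
                    }
                )
    table = pd.DataFrame(rows)
    spread = table.groupby("cell")["probability"].agg(lambda s: np.nanmax(s) - np.nanmin(s)
                                                     if s.notna().any() else np.nan)
    table = table.merge(spread.rename("spread"), on="cell")
    return table.sort_values(["from_state", "to_state", "context"]).reset_index(drop=True)
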