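"""Markov chain analysis of discrete efficiency-state dynamics.

Transition probabilities are maximum-likelihood estimates from pooled
adjacent-year pairs: ``p_ij = n_ij / sum_j n_ij``, counting a transition
only when the same region is observed in consecutive years (gaps break the
chain rather than bridging it).  The stationary distribution ``pi`` solves
``pi P = pi`` with ``sum(pi) = 1`` by a direct linear solve; power iteration
is available as an independent cross-check.  States with no observed
origin-year occupancy yield undefined rows, which are reported, never
imputed — a stationary distribution is refused for such estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .states import StatePanel

__all__ = [
    "TransitionEstimate",
    "StationaryDistribution",
    "ReducibleChainError",
    "UndefinedRowsError",
    "estimate_transitions",
    "stationary",
    "stationary_of_matrix",
    "power_iteration",
    "persistence_report",
    "absorbing_structure",
]


@dataclass
class TransitionEstimate:
    """K x K transition counts and row-normalised probabilities."""

    counts: np.ndarray
    probabilities: np.ndarray
    n_transitions: int
    undefined_rows: frozenset[int]
    threshold_spec: Optional[tuple] = None

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class StationaryDistribution:
    pi: np.ndarray
    irreducible: bool
    aperiodic: bool


class UndefinedRowsError(ValueError):
    """Raised when an operation needs a fully defined transition matrix."""


class ReducibleChainError(ValueError):
    """Raised when no unique stationary distribution exists.

    Carries an absorbing-structure report (communicating classes and which
    of them are closed) in ``self.report``.
    """

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


def _transition_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Origin/destination state pairs for consecutive years within regions."""
    df = df.sort_values(["region_id", "year"])
    nxt = df.groupby("region_id", sort=False).shift(-1)
    mask = nxt["year"] == df["year"] + 1
    pairs = pd.DataFrame(
        {
            "region_id": df["region_id"],
            "year": df["year"],
            "state": df["state"],
            "next_state": nxt["state"],
        }
    )[mask.to_numpy(dtype=bool)]
    pairs["next_state"] = pairs["next_state"].astype(int)
    return pairs


def estimate_transitions(
    states: StatePanel,
    regions: Optional[Iterable] = None,
    year_range: Optional[tuple[int, int]] = None,
) -> TransitionEstimate:
    """Estimate the one-step transition matrix from a state panel.

    Parameters
    ----------
    states
        Discrete state panel from a single classification (thresholds are
        carried along so estimates from different classifications cannot be
        silently mixed downstream).
    regions
        Optional subset of region ids.
    year_range
        Optional inclusive (start, end) window; a transition t -> t+1 is
        included when both years fall inside the window.
    """
    df = states.data
    if regions is not None:
        regions = list(regions)
        if not regions:
            raise ValueError("empty region subset")
        df = df[df["region_id"].isin(regions)]
    if year_range is not None:
        lo, hi = year_range
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if df.empty:
        raise ValueError("subset selects no observations")

    k = states.n_states
    pairs = _transition_pairs(df)
    counts = np.zeros((k, k), dtype=int)
    for i, j in zip(pairs["state"].to_numpy(), pairs["next_state"].to_numpy()):
        counts[i - 1, j - 1] += 1

    row_sums = counts.sum(axis=1)
    undefined = frozenset(int(i) for i in np.flatnonzero(row_sums == 0))
    probs = np.full((k, k), np.nan)
    defined = row_sums > 0
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionEstimate(
        counts=counts,
        probabilities=probs,
        n_transitions=int(counts.sum()),
        undefined_rows=undefined,
        threshold_spec=states.threshold_spec,
    )


def absorbing_structure(P: np.ndarray) -> dict:
    """Communicating classes of the positive-entry digraph of ``P``.

    Returns a report with the strongly connected components and which of
    them are closed (absorbing): once entered, never left.
    """
    P = np.asarray(P, dtype=float)
    g = nx.DiGraph()
    k = P.shape[0]
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if P[i, j] > 0:
                g.add_edge(i, j)
    classes = [sorted(c) for c in nx.strongly_connected_components(g)]
    closed = []
    for cls in classes:
        members = set(cls)
        if all(j in members for i in cls for j in range(k) if P[i, j] > 0):
            closed.append(cls)
    return {
        "n_classes": len(classes),
        "classes": sorted(classes),
        "closed_classes": sorted(closed),
        "irreducible": len(classes) == 1,
    }


def stationary_of_matrix(P: np.ndarray, tol: float = 1e-10) -> StationaryDistribution:
    """Stationary distribution of a row-stochastic matrix.

    Solves the overdetermined system ``(P' - I) pi = 0`` augmented with the
    normalisation row by least squares; for an irreducible chain the
    solution is unique.  Raises :class:`ReducibleChainError` when the chain
    is reducible.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if P.shape != (k, k):
        raise ValueError("transition matrix must be square")
    if np.isnan(P).any():
        raise UndefinedRowsError("transition matrix contains undefined rows")
    row_sums = P.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=5e-4):
        raise ValueError(f"rows must sum to one; got {row_sums}")

    structure = absorbing_structure(P)
    if not structure["irreducible"]:
        raise ReducibleChainError(
            "chain is reducible: no unique stationary distribution", report=structure
        )
    g = nx.DiGraph((i, j) for i in range(k) for j in range(k) if P[i, j] > 0)
    aperiodic = nx.is_aperiodic(g)

    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    # rounding in externally supplied matrices (row sums off by <=5e-4)
    # propagates into the fixed-point residual
    tol_eff = max(tol, 10.0 * float(np.max(np.abs(row_sums - 1.0))), 1e3 * np.finfo(float).eps)
    if np.max(np.abs(pi @ P - pi)) > tol_eff:
        raise RuntimeError("stationary solve failed to satisfy pi P = pi")
    return StationaryDistribution(pi=pi, irreducible=True, aperiodic=aperiodic)


def stationary(estimate: TransitionEstimate) -> StationaryDistribution:
    """Stationary distribution of an estimated transition matrix."""
    if estimate.undefined_rows:
        raise UndefinedRowsError(
            f"rows {sorted(estimate.undefined_rows)} have no observations; "
            "stationary distribution is undefined for this subset"
        )
    return stationary_of_matrix(estimate.probabilities)


def power_iteration(P: np.ndarray, n_iter: int = 10_000) -> np.ndarray:
    """Limit of the chain's marginal distribution, as a cross-check on the solver."""
    P = np.asarray(P, dtype=float)
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(n_iter):
        new = pi @ P
        if np.max(np.abs(new - pi)) < 1e-14:
            return new
        pi = new
    return pi


def persistence_report(
    estimate: TransitionEstimate,
    stationary_dist: Optional[StationaryDistribution] = None,
) -> dict:
    """Mobility summary: diagonal persistence, off-diagonal mass, leaps.

    The mobility index is ``1 - trace(P)/K`` (0 for a frozen chain, (K-1)/K
    for uniform rows).  Cells with zero probability between non-adjacent
    states are flagged as "no cross-tier leap" entries.
    """
    P = estimate.probabilities
    k = estimate.n_states
    defined = [i for i in range(k) if i not in estimate.undefined_rows]
    diag = {i + 1: float(P[i, i]) for i in defined}
    off_mass = {i + 1: float(P[i].sum() - P[i, i]) for i in defined}
    mobility = 1.0 - np.nansum(np.diag(P)) / k if not estimate.undefined_rows else float("nan")
    no_leap = [
        (i + 1, j + 1)
        for i in defined
        for j in range(k)
        if abs(i - j) > 1 and P[i, j] == 0.0
    ]
    report = {
        "diagonal": diag,
        "off_diagonal_mass": off_mass,
        "mobility_index": mobility,
        "no_leap_cells": no_leap,
        "n_transitions": estimate.n_transitions,
        "undefined_rows": sorted(s + 1 for s in estimate.undefined_rows),
    }
    if stationary_dist is not None:
        report["stationary"] = stationary_dist.pi.tolist()
    return report
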