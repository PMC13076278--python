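"""Shared fixtures: an independent DEA oracle and small panel builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from effdyn.states import StatePanel


def bisection_dea_oracle(evaluated_unit, inputs, outputs, returns_to_scale, tol=1e-8):
    """Input-oriented radial score by bisection on theta.

    At each candidate theta the constraint set (a pure feasibility problem
    over the intensity weights, with theta fixed) is checked by a separate
    LP; the minimal feasible theta is located to ``tol``.  This path shares
    no code with the production solver, which optimises theta directly.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(outputs, dtype=float)
    n = X.shape[0]
    o = int(evaluated_unit)

    def feasible(theta: float) -> bool:
        A_ub = np.vstack([X.T, -Y.T])
        b_ub = np.concatenate([theta * X[o], -Y[o]])
        A_eq = np.ones((1, n)) if returns_to_scale == "VRS" else None
        b_eq = np.array([1.0]) if returns_to_scale == "VRS" else None
        res = linprog(
            np.zeros(n), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=[(0, None)] * n, method="highs",
        )
        return res.status == 0

    lo, hi = 0.0, 1.0
    assert feasible(1.0), "self-inclusion must make theta=1 feasible"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def random_dea_instance(rng: np.random.Generator, n_max=6, m_max=2, s_max=2):
    """Small random positive production instance (n x m inputs, n x s outputs)."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    s = int(rng.integers(1, s_max + 1))
    X = rng.uniform(0.5, 10.0, size=(n, m))
    Y = rng.uniform(0.5, 10.0, size=(n, s))
    return X, Y


def make_state_panel(sequences: dict, start_year: int = 2001, k: int = 3) -> StatePanel:
    """State panel from per-region state sequences; None marks a gap year."""
    rows = []
    for rid, seq in sequences.items():
        for t, s in enumerate(seq):
            if s is None:
                continue
            rows.append({"region_id": rid, "year": start_year + t, "state": int(s)})
    df = pd.DataFrame(rows)
    return StatePanel(data=df, thresholds=np.full(k - 1, np.nan), scheme="manual")


@pytest.fixture
def dea_oracle():
    return bisection_dea_oracle


@pytest.fixture
def dea_instance_factory():
    return random_dea_instance


@pytest.fixture
def state_panel_factory():
    return make_state_panel
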