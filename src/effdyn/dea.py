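"""Radial input-oriented data envelopment analysis (DEA).

Implements the envelopment form of the BCC model (variable returns to
scale, VRS) and the CCR model (constant returns to scale, CRS).  For an
evaluated unit *o* with inputs ``x_o`` and outputs ``y_o`` the input-oriented
score is

    theta* = min theta
             s.t.  sum_j lambda_j x_j  <=  theta x_o   (componentwise)
                   sum_j lambda_j y_j  >=  y_o         (componentwise)
                   lambda_j >= 0,
                   sum_j lambda_j = 1   (VRS only)

theta* is pure technical efficiency (PTE) under VRS and overall technical
efficiency (TE) under CRS; scale efficiency is SE = TE / PTE.  Scores are
radial: no second-stage slack maximisation is performed, so slack is
reflected implicitly in the projection onto the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "ProductionPanel",
    "DEASolution",
    "solve_input_oriented",
    "decompose",
    "score_panel",
]

#: Feasibility/optimality tolerance for the envelopment LPs.
LP_TOL = 1e-9

ReturnsToScale = Literal["VRS", "CRS"]


@dataclass
class ProductionPanel:
    """Long-format region-year panel of input and output quantities.

    Parameters
    ----------
    data
        One row per (region_id, year) with strictly positive quantity
        columns.
    input_cols, output_cols
        Names of the input and output quantity columns in ``data``.
    """

    data: pd.DataFrame
    input_cols: Sequence[str]
    output_cols: Sequence[str]

    def __post_init__(self) -> None:
        required = ["region_id", "year", *self.input_cols, *self.output_cols]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        if self.data.duplicated(["region_id", "year"]).any():
            raise ValueError("duplicate (region_id, year) records in panel")
        quantities = self.data[list(self.input_cols) + list(self.output_cols)]
        if not (quantities.to_numpy(dtype=float) > 0).all():
            raise ValueError("all input and output quantities must be strictly positive")

    @property
    def inputs(self) -> np.ndarray:
        return self.data[list(self.input_cols)].to_numpy(dtype=float)

    @property
    def outputs(self) -> np.ndarray:
        return self.data[list(self.output_cols)].to_numpy(dtype=float)


@dataclass
class DEASolution:
    """Radial efficiency score with the optimal intensity weights.

    ``lambdas`` is one optimal vertex; when the optimum is degenerate the
    weights are not unique, but ``theta`` is.
    """

    theta: float
    lambdas: np.ndarray


def _validate_matrices(inputs: np.ndarray, outputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(outputs, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("inputs and outputs must be 2-D (units x quantities)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and outputs must have the same number of units")
    if (X <= 0).any() or (Y <= 0).any():
        raise ValueError("nonpositive quantities are not admissible in radial DEA")
    return X, Y


def solve_input_oriented(
    evaluated_unit: int,
    inputs: np.ndarray,
    outputs: np.ndarray,
    returns_to_scale: ReturnsToScale = "VRS",
) -> DEASolution:
    """Solve the input-oriented envelopment LP for one unit.

    Parameters
    ----------
    evaluated_unit
        Row index of the unit under evaluation; it must be part of the
        reference set, which guarantees feasibility and theta <= 1.
    inputs, outputs
        n x m and n x s matrices of strictly positive quantities.
    returns_to_scale
        "VRS" adds the convexity constraint sum(lambda) = 1 (BCC);
        "CRS" omits it (CCR).
    """
    X, Y = _validate_matrices(inputs, outputs)
    n, m = X.shape
    s = Y.shape[1]
    o = int(evaluated_unit)
    if not 0 <= o < n:
        raise IndexError(f"evaluated_unit {o} outside 0..{n - 1}")
    if returns_to_scale not in ("VRS", "CRS"):
        raise ValueError(f"unknown returns_to_scale: {returns_to_scale!r}")

    # decision vector: [theta, lambda_1 .. lambda_n]
    c = np.zeros(n + 1)
    c[0] = 1.0
    # input rows:  sum_j lambda_j x_jk - theta x_ok <= 0
    A_in = np.hstack([-X[o][:, None], X.T])  # m x (n+1)
    b_in = np.zeros(m)
    # output rows: -sum_j lambda_j y_jk <= -y_ok
    A_out = np.hstack([np.zeros((s, 1)), -Y.T])
    b_out = -Y[o]
    A_ub = np.vstack([A_in, A_out])
    b_ub = np.concatenate([b_in, b_out])
    if returns_to_scale == "VRS":
        A_eq = np.concatenate([[0.0], np.ones(n)])[None, :]
        b_eq = np.array([1.0])
    else:
        A_eq, b_eq = None, None
    bounds = [(None, None)] + [(0.0, None)] * n

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - self-inclusion guarantees feasibility
        raise RuntimeError(f"envelopment LP failed for unit {o}: {res.message}")

    theta = float(res.x[0])
    if theta > 1.0 + 1e-7 or theta <= 0.0:
        raise RuntimeError(f"radial score {theta} outside (0, 1]; LP inconsistency for unit {o}")
    theta = min(theta, 1.0)
    return DEASolution(theta=theta, lambdas=res.x[1:].copy())


def decompose(pte: float, te: float, tol: float = 1e-7) -> float:
    """Scale efficiency SE = TE / PTE (ratio of the CCR and BCC scores)."""
    if not (0.0 < pte <= 1.0 + tol and 0.0 < te <= 1.0 + tol):
        raise ValueError(f"efficiency scores must lie in (0,1]; got pte={pte}, te={te}")
    if te > pte + tol:
        raise ValueError(
            f"CCR score {te} exceeds BCC score {pte} beyond tolerance: "
            "the CRS frontier must envelop the VRS frontier; inspect the LP solves"
        )
    return min(te, pte) / pte


def score_panel(
    panel: ProductionPanel,
    frontier_scope: Literal["per_year", "pooled"] = "per_year",
) -> pd.DataFrame:
    """Score every region-year record of a panel under both BCC and CCR.

    Parameters
    ----------
    panel
        Production panel to score.
    frontier_scope
        "per_year" evaluates each record against the cross-section of its
        own year (contemporaneous frontier, the default); "pooled" evaluates
        against all region-years jointly.

    Returns
    -------
    DataFrame with columns region_id, year, pte, te, se.
    """
    if frontier_scope not in ("per_year", "pooled"):
        raise ValueError(f"unknown frontier_scope: {frontier_scope!r}")

    df = panel.data.reset_index(drop=True)
    X_all = panel.inputs
    Y_all = panel.outputs

    if frontier_scope == "pooled":
        groups: list[tuple[object, np.ndarray]] = [("pooled", np.arange(len(df)))]
    else:
        groups = [(y, np.asarray(ix)) for y, ix in df.groupby("year").indices.items()]

    records = []
    for _, idx in groups:
        X, Y = X_all[idx], Y_all[idx]
        for local, global_i in enumerate(idx):
            pte = solve_input_oriented(local, X, Y, "VRS").theta
            te = solve_input_oriented(local, X, Y, "CRS").theta
            # tiny LP round-off can put te a hair above pte; decompose guards it
            records.append(
                {
                    "region_id": df.at[global_i, "region_id"],
                    "year": df.at[global_i, "year"],
                    "pte": pte,
                    "te": min(te, pte),
                    "se": decompose(pte, te),
                }
            )
    out = pd.DataFrame.from_records(records).sort_values(["region_id", "year"]).reset_index(drop=True)
    return out
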