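"""Linear-probability models for upward/downward efficiency-state mobility.

Outcomes are one-step mobility indicators built from the state panel:
``upward_t = 1`` iff the state at t+1 exceeds the state at t, and
symmetrically for downward moves.  Each model is fit on its at-risk sample
only — regions already in the top state cannot move up and are dropped from
the upward model, bottom-state origins from the downward model.  Covariates
are measured at the origin year t.

Estimation is ordinary least squares with year and region-group indicator
blocks; the covariance is cluster-robust by region with the CR1
small-sample factor G/(G-1) x (N-1)/(N-k).  With singleton clusters this
reduces exactly to the HC1 heteroskedasticity-robust estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .states import StatePanel
from .markov import _transition_pairs

__all__ = [
    "DEFAULT_COVARIATES",
    "TransitionRegressionResult",
    "build_outcomes",
    "fit_lpm",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("doctor_nurse_ratio", "staff_per_10k", "beds_per_staff", "ln_gdp_pc")

Outcome = Literal["upward", "downward"]


@dataclass
class TransitionRegressionResult:
    """Coefficients and cluster-robust inference for one mobility model."""

    outcome: str
    params: pd.Series
    std_errors: pd.Series
    pvalues: pd.Series
    n_obs: int
    n_clusters: int
    r_squared: float
    outcome_definition: str

    def summary_table(self, covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
        """Coefficient/SE table restricted to the substantive covariates."""
        rows = []
        for name in covariates:
            if name not in self.params.index:
                continue
            p = self.pvalues[name]
            stars = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""
            rows.append(
                {
                    "variable": name,
                    "coefficient": self.params[name],
                    "std_error": self.std_errors[name],
                    "p_value": p,
                    "stars": stars,
                }
            )
        return pd.DataFrame(rows)


def build_outcomes(states: StatePanel) -> pd.DataFrame:
    """Mobility indicators for every consecutive-year pair.

    Returns one row per transition pair with columns region_id, year (the
    origin year), state, next_state, upward, downward plus at-risk flags
    ``at_risk_up`` (origin below the top state) and ``at_risk_down`` (origin
    above the bottom state).
    """
    pairs = _transition_pairs(states.data).reset_index(drop=True)
    k = states.n_states
    pairs["upward"] = (pairs["next_state"] > pairs["state"]).astype(int)
    pairs["downward"] = (pairs["next_state"] < pairs["state"]).astype(int)
    pairs["at_risk_up"] = (pairs["state"] < k).astype(int)
    pairs["at_risk_down"] = (pairs["state"] > 1).astype(int)
    return pairs


def _cluster_covariance(X: np.ndarray, resid: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """CR1 sandwich: bread = (X'X)^-1, meat summed over cluster score blocks."""
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in np.unique(clusters):
        Xg = X[clusters == g]
        ug = resid[clusters == g]
        score = Xg.T @ ug
        meat += np.outer(score, score)
    n_clusters = len(np.unique(clusters))
    c = (n_clusters / (n_clusters - 1)) * ((n - 1) / (n - k))
    return c * bread @ meat @ bread


def fit_lpm(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: Outcome = "upward",
    covariate_cols: Sequence[str] = DEFAULT_COVARIATES,
    region_groups: Optional[Mapping] = None,
    year_fe: bool = True,
    region_fe: Literal["group", "province", "none"] = "group",
    cluster_col: str = "region_id",
) -> TransitionRegressionResult:
    """Fit one linear-probability mobility model on its at-risk sample.

    Parameters
    ----------
    outcomes
        Output of :func:`build_outcomes`.
    covariates
        DataFrame with region_id, year and the covariate columns, matched to
        the origin year of each transition.
    outcome
        "upward" or "downward"; selects both the dependent variable and the
        at-risk restriction.
    region_groups
        region_id -> group label, required when ``region_fe="group"``.
    region_fe
        "group" uses region-group dummies (default), "province" uses one
        dummy per region, "none" omits the block.
    """
    if outcome not in ("upward", "downward"):
        raise ValueError(f"unknown outcome: {outcome!r}")
    at_risk_col = "at_risk_up" if outcome == "upward" else "at_risk_down"

    df = outcomes.merge(covariates, on=["region_id", "year"], how="left")
    df = df[df[at_risk_col] == 1]
    n_missing = int(df[list(covariate_cols)].isna().any(axis=1).sum())
    if n_missing:
        logger.info("fit_lpm(%s): dropping %d rows with missing covariates", outcome, n_missing)
        df = df.dropna(subset=list(covariate_cols))
    if df.empty:
        raise ValueError("empty at-risk estimation sample")

    y = df[outcome].to_numpy(dtype=float)
    blocks = [df[list(covariate_cols)].to_numpy(dtype=float)]
    names = list(covariate_cols)

    if year_fe:
        dummies = pd.get_dummies(df["year"], prefix="year", drop_first=True, dtype=float)
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns)
    if region_fe == "group":
        if region_groups is None:
            raise ValueError('region_fe="group" requires region_groups')
        grp = df["region_id"].map(dict(region_groups))
        if grp.isna().any():
            missing = sorted(df.loc[grp.isna(), "region_id"].unique(), key=str)
            raise ValueError(f"regions without a group: {missing}")
        dummies = pd.get_dummies(grp, prefix="group", drop_first=True, dtype=float)
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns)
    elif region_fe == "province":
        dummies = pd.get_dummies(df["region_id"], prefix="region", drop_first=True, dtype=float)
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns)

    X = np.column_stack([np.ones(len(df)), *blocks])
    names = ["const"] + names

    clusters = df[cluster_col].to_numpy()
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least two clusters for cluster-robust inference")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    ols = sm.OLS(y, X).fit()
    V = _cluster_covariance(X, ols.resid, clusters)
    se = np.sqrt(np.diag(V))
    n_clusters = len(np.unique(clusters))
    t = np.divide(ols.params, se, out=np.zeros_like(se), where=se > 0)
    pvals = 2 * scipy.stats.t.sf(np.abs(t), df=n_clusters - 1)

    definition = (
        "1 if state(t+1) > state(t), origin below top state"
        if outcome == "upward"
        else "1 if state(t+1) < state(t), origin above bottom state"
    )
    return TransitionRegressionResult(
        outcome=outcome,
        params=pd.Series(ols.params, index=names),
        std_errors=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        n_obs=int(len(df)),
        n_clusters=n_clusters,
        r_squared=0.0 if np.var(y) == 0 else float(ols.rsquared),
        outcome_definition=definition,
    )
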