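"""Discretisation of continuous efficiency scores into relative states.

Pure technical efficiency is cut at pooled percentile thresholds — terciles
(33rd/67th) for the main analysis, quartiles (25th/50th/75th) as a
robustness scheme — so a state records a region-year's *relative* position
in the pooled score distribution, not an absolute efficiency level.

Boundary convention: intervals are closed on the left, so a score exactly
equal to a threshold belongs to the state above it, and the top state is
``[t_{K-1}, inf)``.  This keeps classification deterministic and monotone
and places frontier mass (scores tied at 1.0) in the top state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["StatePanel", "compute_thresholds", "classify", "classify_values"]

Scheme = Literal["tercile", "quartile"]

_SCHEME_QUANTILES = {
    "tercile": (0.33, 0.67),
    "quartile": (0.25, 0.50, 0.75),
}


@dataclass
class StatePanel:
    """Region-year discrete efficiency states with their threshold provenance.

    ``threshold_spec`` carries the scheme name and the pooled cut points so
    that downstream transition estimates can refuse to mix classifications
    produced under different thresholds.
    """

    data: pd.DataFrame  # columns: region_id, year, state
    thresholds: np.ndarray
    scheme: str

    @property
    def n_states(self) -> int:
        return len(self.thresholds) + 1

    @property
    def threshold_spec(self) -> tuple:
        return (self.scheme, tuple(np.round(self.thresholds, 12)))


def compute_thresholds(scores, scheme: Scheme = "tercile") -> np.ndarray:
    """Percentile cut points of the pooled score distribution.

    Quantiles use linear interpolation of the empirical distribution.  With
    heavy mass points (e.g. many scores at exactly 1.0) adjacent thresholds
    can coincide; a degeneracy warning is emitted but the thresholds are
    returned as-is.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute thresholds from an empty score sample")
    if scheme not in _SCHEME_QUANTILES:
        raise ValueError(f"unknown scheme: {scheme!r}")
    qs = _SCHEME_QUANTILES[scheme]
    if len(np.unique(scores)) < len(qs) + 1:
        warnings.warn(
            "fewer distinct scores than states; classification will be degenerate",
            stacklevel=2,
        )
    thresholds = np.quantile(scores, qs)  # linear interpolation
    if np.any(np.diff(thresholds) < 0):  # pragma: no cover - quantiles are monotone
        raise RuntimeError("thresholds are not nondecreasing")
    return thresholds


def classify_values(values, thresholds: np.ndarray) -> np.ndarray:
    """Map scores to integer states 1..K under the lower-closed convention."""
    values = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(thresholds, dtype=float), values, side="right") + 1


def classify(scores_panel: pd.DataFrame, thresholds: np.ndarray, scheme: str = "tercile",
             score_col: str = "pte") -> StatePanel:
    """Classify an efficiency panel into discrete states.

    Parameters
    ----------
    scores_panel
        DataFrame with region_id, year and the score column (default
        ``pte``); scores must lie in (0, 1].
    thresholds
        Cut points from :func:`compute_thresholds` on the pooled sample the
        panel belongs to — re-classifying a subset must reuse the pooled
        thresholds so states stay comparable.
    """
    scores = scores_panel[score_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)) or np.any(scores <= 0) or np.any(scores > 1 + 1e-9):
        raise ValueError("scores must lie in (0, 1]")
    states = classify_values(scores, thresholds)
    data = scores_panel[["region_id", "year"]].copy()
    data["state"] = states.astype(int)

    k = len(thresholds) + 1
    shares = np.bincount(states, minlength=k + 1)[1:] / len(states)
    if k == 3 and (np.any(shares < 0.25) or np.any(shares > 0.42)):
        warnings.warn(
            f"tercile state shares {np.round(shares, 3)} outside [0.25, 0.42]; "
            "a mass point in the score distribution is likely",
            stacklevel=2,
        )
    return StatePanel(data=data, thresholds=np.asarray(thresholds, dtype=float), scheme=scheme)
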