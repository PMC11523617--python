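"""Pollution-pressure variables for urban community gardens.

Each garden in the survey is scored for proximity-weighted exposure to three
pollution sources:

* atmospheric — summed air-quality quartile scores for NO2, PM2.5 and PM10
  emissions divided by the distance to the nearest highway,
  ``Var_atmo = (qNO2 + qPM2.5 + qPM10) / dH``;
* agricultural — squared area of the nearest agricultural zone divided by the
  distance to it, ``Var_agri = surface**2 / dA``;
* industrial — reciprocal distance to the nearest industrial area,
  ``Var_indus = 1 / dI``.

Raw variables are then min–max normalized across the garden set so that each
variable spans [0, 1] within its pollution context.  Distances are in metres
and quartile scores are integers in {1, 2, 3, 4} (1 = lowest-emission quartile
of gardens, 4 = highest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

POLLUTION_GROUPS = ("AGRI", "INDUS", "ATMO")

__all__ = [
    "POLLUTION_GROUPS",
    "GardenRecord",
    "quartile_scores",
    "compute_var_atmo",
    "var_atmo_from_score",
    "compute_var_agri",
    "compute_var_indus",
    "minmax_normalize",
    "pollution_variables",
    "agrees_with_printed",
]


@dataclass
class GardenRecord:
    """One garden's pollution-source geometry and air-quality scores."""

    garden_id: str
    pollution_group: str
    q_no2: int
    q_pm25: int
    q_pm10: int
    d_highway: float  # m
    d_agri: float  # m
    d_indus: float  # m
    agri_surface: float  # same length unit squared

    def __post_init__(self) -> None:
        if self.pollution_group not in POLLUTION_GROUPS:
            raise ValueError(f"pollution_group must be one of {POLLUTION_GROUPS}")
        for name in ("q_no2", "q_pm25", "q_pm10"):
            if getattr(self, name) not in (1, 2, 3, 4):
                raise ValueError(f"{name} must be an integer quartile score in 1..4")
        for name in ("d_highway", "d_agri", "d_indus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.agri_surface < 0:
            raise ValueError("agri_surface must be nonnegative")


def quartile_scores(values) -> np.ndarray:
    """Quartile rank (1–4) of each garden's emission level.

    Ranks are computed with average-rank ties and cut at the 25/50/75
    percentiles of the ranks, lower bound inclusive: a rank exactly on a
    boundary stays in the lower quartile, and an all-equal input yields
    score 1 everywhere.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("quartile_scores requires at least one finite value and no NaN/inf")
    if x.size < 4:
        warnings.warn("fewer than 4 gardens: quartile scores are degenerate", stacklevel=2)
    ranks = rankdata(x)
    cuts = np.percentile(ranks, [25, 50, 75])
    return (1 + (ranks[:, None] > cuts[None, :]).sum(axis=1)).astype(int)


def var_atmo_from_score(score_sum, d_highway):
    """Atmospheric pollution variable from a pre-summed air-quality score."""
    d = np.asarray(d_highway, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d_highway must be strictly positive")
    return np.asarray(score_sum, dtype=float) / d


def compute_var_atmo(q_no2, q_pm25, q_pm10, d_highway):
    """Raw atmospheric variable ``(qNO2 + qPM2.5 + qPM10) / dH``."""
    for name, q in (("q_no2", q_no2), ("q_pm25", q_pm25), ("q_pm10", q_pm10)):
        if not np.all(np.isin(np.asarray(q), (1, 2, 3, 4))):
            raise ValueError(f"{name} must be a quartile score in 1..4")
    score = np.asarray(q_no2) + np.asarray(q_pm25) + np.asarray(q_pm10)
    return var_atmo_from_score(score, d_highway)


def compute_var_agri(agri_surface, d_agri):
    """Raw agricultural variable ``surface**2 / dA``."""
    s = np.asarray(agri_surface, dtype=float)
    d = np.asarray(d_agri, dtype=float)
    if np.any(s < 0):
        raise ValueError("agri_surface must be nonnegative")
    if np.any(d <= 0):
        raise ValueError("d_agri must be strictly positive")
    return s**2 / d


def compute_var_indus(d_indus):
    """Raw industrial variable ``1 / dI``."""
    d = np.asarray(d_indus, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d_indus must be strictly positive")
    return 1.0 / d


def minmax_normalize(raw_values) -> np.ndarray:
    """Map a variable to [0, 1] via ``(x - min) / (max - min)``.

    A degenerate input (max == min) maps everything to 0 with a warning.
    """
    x = np.asarray(raw_values, dtype=float)
    if x.size < 2:
        raise ValueError("min-max normalization needs at least 2 gardens")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("max == min: normalized values defined as 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def pollution_variables(gardens: pd.DataFrame) -> pd.DataFrame:
    """Per-garden raw and normalized pollution variables.

    Expects columns ``garden_id``, ``d_highway``, ``d_indus`` and either the
    individual quartile scores (``q_no2``, ``q_pm25``, ``q_pm10``) or their
    pre-summed ``score_atmo``.  ``var_agri`` is computed from ``agri_surface``
    and ``d_agri`` when a surface column is present; otherwise an existing
    ``var_agri`` column is carried through unchanged (the survey table prints
    the variable but not the underlying surface).
    """
    g = gardens.reset_index(drop=True)
    out = pd.DataFrame({"garden_id": g["garden_id"]})
    if {"q_no2", "q_pm25", "q_pm10"}.issubset(g.columns):
        out["var_atmo"] = compute_var_atmo(g["q_no2"], g["q_pm25"], g["q_pm10"], g["d_highway"])
    elif "score_atmo" in g.columns:
        out["var_atmo"] = var_atmo_from_score(g["score_atmo"], g["d_highway"])
    else:
        raise ValueError("gardens need q_no2/q_pm25/q_pm10 or score_atmo")
    if "agri_surface" in g.columns:
        out["var_agri"] = compute_var_agri(g["agri_surface"], g["d_agri"])
    elif "var_agri" in g.columns:
        out["var_agri"] = g["var_agri"].astype(float)
    elif "var_agri_printed" in g.columns:
        out["var_agri"] = g["var_agri_printed"].astype(float)
    else:
        out["var_agri"] = np.nan
    out["var_indus"] = compute_var_indus(g["d_indus"])
    for col in ("var_atmo", "var_agri", "var_indus"):
        vals = out[col].to_numpy()
        out[col + "_norm"] = (
            minmax_normalize(vals) if np.isfinite(vals).all() else np.full(len(vals), np.nan)
        )
    return out


def agrees_with_printed(computed, printed, decimals: int = 4) -> np.ndarray:
    """Whether a computed value matches a printed one at printed precision.

    Printed tables mix rounding conventions (round-half and truncation), so
    agreement is defined as within one unit in the last printed digit.
    """
    tol = 10.0 ** (-decimals) * (1 + 1e-9)
    return np.abs(np.asarray(computed, dtype=float) - np.asarray(printed, dtype=float)) <= tol
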