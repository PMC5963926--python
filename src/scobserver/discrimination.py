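"""Categorical judgment stage.

The observer picks the category with maximal posterior probability given
the sensory measurement m.  Because the category likelihood ratio is
monotone in m, the decision rule collapses to a single criterion: report
cw iff m >= c, where c is located once per parameter set by bisection on
the posterior odds (c = 0 for a symmetric prior with p_cat = 0.5).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .observer_core import Category, Grid, ObserverParams, category_prior_density

__all__ = [
    "PsychometricCurve",
    "category_likelihood",
    "decision_criterion",
    "decide",
    "psychometric",
    "psychometric_curve",
]

_DEFAULT_GRID = Grid()


def category_likelihood(
    m: float,
    category,
    params: ObserverParams,
    noise_level: int,
    grid: Grid | None = None,
) -> float:
    """Choice likelihood p(m | C) = integral of p(m|theta) p(theta|C) dtheta."""
    grid = grid or _DEFAULT_GRID
    if not np.isfinite(m):
        raise ValueError("m must be finite")
    if abs(m) > grid.half_span:
        raise ValueError(f"measurement m={m} lies outside the grid (+/-{grid.half_span})")
    cat = Category.parse(category)
    sd = params.sigma_s[noise_level]
    prior = category_prior_density(grid.values, cat, params.alpha, params.beta)
    if sd == 0.0:
        # likelihood collapses to the prior density at m
        return float(category_prior_density(m, cat, params.alpha, params.beta))
    like = np.exp(-0.5 * ((m - grid.values) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return grid.integrate(like * prior)


def _log_posterior_odds(m, params, noise_level, grid):
    lcw = category_likelihood(m, Category.CW, params, noise_level, grid)
    lccw = category_likelihood(m, Category.CCW, params, noise_level, grid)
    return np.log(lcw * params.p_cat) - np.log(lccw * (1.0 - params.p_cat))


def decision_criterion(
    params: ObserverParams, noise_level: int, grid: Grid | None = None
) -> float:
    """m-value where the posterior odds cross 1 (decide cw iff m >= c).

    For the mirror-symmetric prior with p_cat = 0.5 the criterion is exactly
    0; otherwise it is bracketed and found by bisection.
    """
    grid = grid or _DEFAULT_GRID
    if params.p_cat == 0.5:
        return 0.0
    lo, hi = -grid.half_span * 0.9, grid.half_span * 0.9
    f = lambda m: _log_posterior_odds(m, params, noise_level, grid)
    c = brentq(f, lo, hi, xtol=1e-10)
    return 0.0 if abs(c) < 1e-9 else float(c)


def decide(
    m,
    params: ObserverParams,
    noise_level: int,
    grid: Grid | None = None,
    criterion: float | None = None,
):
    """Deterministic category mapping of the measurement; ties at c go to cw."""
    if criterion is None:
        criterion = decision_criterion(params, noise_level, grid)
    m = np.asarray(m, dtype=float)
    cats = np.where(m >= criterion, int(Category.CW), int(Category.CCW))
    if cats.ndim == 0:
        return Category(int(cats))
    return cats


def psychometric(
    theta,
    params: ObserverParams,
    noise_level: int,
    lapse_rate: float = 0.0,
    grid: Grid | None = None,
    criterion: float | None = None,
):
    """Probability of a cw report as a function of true orientation.

    Computed by marginalizing the deterministic decision rule over the
    sensory measurement distribution on the m grid (midpoint quadrature of
    the indicator), then mixed with lapses.  A lapse flips the report with
    probability ``lapse_rate`` (independent of the stimulus), so the
    reported probability is lapse_rate + (1 - 2*lapse_rate) * p_model;
    lapse_rate = 0.5 is pure guessing.
    """
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must lie in [0, 1]")
    grid = grid or _DEFAULT_GRID
    if criterion is None:
        criterion = decision_criterion(params, noise_level, grid)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    sd = params.sigma_s[noise_level]
    if sd == 0.0:
        p_model = (theta_arr >= criterion).astype(float)
    else:
        m = grid.values
        mask = m >= criterion
        dens = np.exp(-0.5 * ((m[None, :] - theta_arr[:, None]) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi)
        )
        p_model = dens[:, mask].sum(axis=1) * grid.step
        p_model = np.clip(p_model, 0.0, 1.0)
    p = lapse_rate + (1.0 - 2.0 * lapse_rate) * p_model
    return p if np.ndim(theta) else float(p[0])


def psychometric_closed_form(
    theta, params: ObserverParams, noise_level: int, lapse_rate: float = 0.0,
    criterion: float = 0.0,
):
    """Gaussian-tail fast path: with a threshold rule, p_model = Phi((theta-c)/sigma_s)."""
    sd = params.sigma_s[noise_level]
    theta = np.asarray(theta, dtype=float)
    if sd == 0.0:
        p_model = (theta >= criterion).astype(float)
    else:
        p_model = ndtr((theta - criterion) / sd)
    return lapse_rate + (1.0 - 2.0 * lapse_rate) * p_model


@dataclasses.dataclass(frozen=True)
class PsychometricCurve:
    """Predicted p(cw report | theta) on a set of orientations."""

    theta_values: np.ndarray
    p_cw: np.ndarray
    noise_level: int
    lapse_rate: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"theta_deg": self.theta_values, "p_cw": self.p_cw})


def psychometric_curve(
    params: ObserverParams,
    noise_level: int,
    theta_values=None,
    lapse_rate: float = 0.0,
    grid: Grid | None = None,
) -> PsychometricCurve:
    if theta_values is None:
        theta_values = np.arange(-21.0, 21.0 + 1e-9, 3.0)
    theta_values = np.asarray(theta_values, dtype=float)
    p = psychometric(theta_values, params, noise_level, lapse_rate, grid)
    return PsychometricCurve(theta_values, np.atleast_1d(p), noise_level, lapse_rate)
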