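"""Downstream predictions: inconsistent trials, and consistency without conditioning.

Two analyses sit on top of the fitted observer model.  First, the small
fraction of trials whose reported estimate contradicts the reported
category is predicted as the union of two non-perceptual error sources:
lapses (a wrong button press, or a misremembered category cue in
the known-category design) and motor noise deflecting the reported
estimate across the boundary.  Second, the fraction of inconsistent
trials an observer would produce *without* conditioning the estimate on
the preceding judgment — the probability that the sensory measurement m
and its memory recall mm fall on opposite sides of the boundary — which
quantifies the consistency benefit of the self-consistent strategy.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import multivariate_normal

from .estimation import ObserverModel, motor_convolve
from .observer_core import Category, Grid, ObserverParams
from .synthetic_data import ExperimentDesign, make_design

__all__ = [
    "InconsistencyPrediction",
    "predict_inconsistent_lapse",
    "predict_inconsistent_motor",
    "predict_inconsistent_fraction",
    "inconsistency_without_conditioning",
]


@dataclasses.dataclass
class InconsistencyPrediction:
    """Predicted inconsistent-trial fractions and their decomposition.

    Fractions are arrays over (noise level, design orientation).  The two
    components use the independence union rule — a lapse flips the report
    with probability lapse_rate while the motor deflection acts on
    whichever conditional the trial follows — and sum exactly to the total.
    ``lapse_density``/``motor_density`` are the predicted estimate
    densities restricted to inconsistent outcomes (renormalized),
    aggregated uniformly over the design.
    """

    experiment: str
    theta_values: np.ndarray
    noise_levels: np.ndarray
    lapse_fraction: np.ndarray
    motor_fraction: np.ndarray
    grid: Grid
    lapse_density: np.ndarray
    motor_density: np.ndarray

    @property
    def total_fraction(self) -> np.ndarray:
        return self.lapse_fraction + self.motor_fraction

    @property
    def overall_fraction(self) -> float:
        return float(np.mean(self.total_fraction))

    @property
    def lapse_share(self) -> float:
        return float(np.mean(self.lapse_fraction)) / max(self.overall_fraction, 1e-300)

    @property
    def motor_share(self) -> float:
        return float(np.mean(self.motor_fraction)) / max(self.overall_fraction, 1e-300)


def _side_mass(density: np.ndarray, grid: Grid, sign: int) -> float:
    """Mass of a density on the sign-side open half-line."""
    mask = grid.values * sign > 0
    return float(density[mask].sum() * grid.step)


def _convolved_conditional(model: ObserverModel, theta, level, cat, variant) -> np.ndarray:
    dens = model.distribution(theta, level, variant)
    return motor_convolve(dens, model.params.sigma_0).conditional(cat), dens.weight(cat)


def _predict_tables(
    params: ObserverParams,
    lapse_rate: float,
    experiment,
    design: ExperimentDesign | None = None,
    grid: Grid | None = None,
) -> InconsistencyPrediction:
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must lie in [0, 1]")
    design = design or make_design(experiment)
    model = ObserverModel(params, grid)
    g = model.grid
    thetas = np.asarray(design.orientations, dtype=float)
    L, T = design.n_levels, len(thetas)
    lapse_frac = np.zeros((L, T))
    motor_frac = np.zeros((L, T))
    lapse_dens = np.zeros(g.n)
    motor_dens = np.zeros(g.n)
    flip = lapse_rate  # a lapse is a report flip
    known = design.known_category
    for lvl in range(L):
        for j, th in enumerate(thetas):
            if known:
                cats = (
                    [(Category.from_sign(th), 1.0)]
                    if th != 0
                    else [(Category.CW, 0.5), (Category.CCW, 0.5)]
                )
                for cat, w in cats:
                    right, _ = _convolved_conditional(model, th, lvl, cat, "known_category")
                    wrong, _ = _convolved_conditional(model, th, lvl, cat.opposite, "known_category")
                    x = _side_mass(right, g, -cat.sign)  # motor crossing on correct-cue trials
                    y = _side_mass(wrong, g, -cat.sign)  # estimate follows the wrong cue
                    lapse_frac[lvl, j] += w * lapse_rate * y
                    motor_frac[lvl, j] += w * (1.0 - lapse_rate) * x
                    lapse_restricted = np.where(g.values * cat.sign < 0, wrong, 0.0)
                    motor_restricted = np.where(g.values * cat.sign < 0, right, 0.0)
                    lapse_dens += w * lapse_rate * lapse_restricted
                    motor_dens += w * (1.0 - lapse_rate) * motor_restricted
            else:
                dens = model.distribution(th, lvl, "self_consistent")
                conv = motor_convolve(dens, params.sigma_0)
                for cat in (Category.CW, Category.CCW):
                    w = conv.weight(cat)
                    cond = conv.conditional(cat)
                    x = _side_mass(cond, g, -cat.sign)
                    lapse_frac[lvl, j] += w * flip * (1.0 - x)
                    motor_frac[lvl, j] += w * (1.0 - flip) * x
                    # lapse-inconsistent estimates follow the internal judgment
                    lapse_dens += w * flip * np.where(g.values * cat.sign > 0, cond, 0.0)
                    motor_dens += w * (1.0 - flip) * np.where(g.values * cat.sign < 0, cond, 0.0)
    for d in (lapse_dens, motor_dens):
        tot = d.sum() * g.step
        if tot > 0:
            d /= tot
    return InconsistencyPrediction(
        experiment=str(design.experiment),
        theta_values=thetas,
        noise_levels=np.arange(L),
        lapse_fraction=lapse_frac,
        motor_fraction=motor_frac,
        grid=g,
        lapse_density=lapse_dens,
        motor_density=motor_dens,
    )


def predict_inconsistent_lapse(
    params: ObserverParams, lapse_rate: float, experiment, design=None, grid=None
) -> InconsistencyPrediction:
    """Lapse-driven component of the inconsistent-trial prediction."""
    pred = _predict_tables(params, lapse_rate, experiment, design, grid)
    return dataclasses.replace(
        pred, motor_fraction=np.zeros_like(pred.motor_fraction), motor_density=np.zeros(pred.grid.n)
    )


def predict_inconsistent_motor(
    params: ObserverParams, experiment, design=None, grid=None
) -> InconsistencyPrediction:
    """Motor-crossing component (computed at zero lapse)."""
    if params.sigma_0 < 0:
        raise ValueError("sigma_0 must be >= 0")
    pred = _predict_tables(params, 0.0, experiment, design, grid)
    return dataclasses.replace(
        pred, lapse_fraction=np.zeros_like(pred.lapse_fraction), lapse_density=np.zeros(pred.grid.n)
    )


def predict_inconsistent_fraction(
    params: ObserverParams, lapse_rate: float, experiment, design=None, grid=None
) -> InconsistencyPrediction:
    """Design-weighted inconsistent-trial prediction with both components."""
    return _predict_tables(params, lapse_rate, experiment, design, grid)


def inconsistency_without_conditioning(theta, sigma_s: float, sigma_m: float):
    """P(sign(m) != sign(mm)) for an observer that does not condition.

    m ~ N(theta, sigma_s), mm ~ N(m, sigma_m): jointly Gaussian with
    correlation rho = sigma_s / sqrt(sigma_s^2 + sigma_m^2).  At theta = 0
    this is the classic orthant probability 1/2 - arcsin(rho)/pi.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    if sigma_m < 0:
        raise ValueError("sigma_m must be >= 0")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if sigma_m == 0.0:
        out = np.zeros_like(theta_arr)
        return out if np.ndim(theta) else 0.0
    cov = np.array(
        [
            [sigma_s**2, sigma_s**2],
            [sigma_s**2, sigma_s**2 + sigma_m**2],
        ]
    )
    out = np.empty(theta_arr.shape)
    for i, t in enumerate(theta_arr):
        both_neg = multivariate_normal(mean=[t, t], cov=cov).cdf([0.0, 0.0])
        both_pos = multivariate_normal(mean=[-t, -t], cov=cov).cdf([0.0, 0.0])
        out[i] = 1.0 - both_neg - both_pos
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(theta) else float(out[0])
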