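"""Synthetic trial generation for the three experiment designs.

The generator draws from exactly the generative chain the analysis
assumes: sensory measurement -> categorical judgment (or given category)
-> noisy memory recall -> posterior-mean estimate -> motor noise, with
stimulus-independent lapses at the response stage.  Ground-truth columns
(m, mm, internal judgment, lapse flag) are retained so parameter-recovery
tests can condition on them.

Designs follow the published task structure: 15 orientations from -21 to
+21 degrees in steps of 3, three stimulus-noise levels, 40 trials per
cell (1800 trials for Experiment 1).  Experiment 2 adds an explicit prior
cue (same trial statistics; typically simulated with a narrower prior),
Experiment 3 provides an always-correct category cue, and the boundary
variants shift the boundary (+/-6 degrees) or remove it at estimation
time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .estimation import ObserverModel
from .observer_core import Category, Grid, ObserverParams
from .trials import TrialTable, read_trials, write_trials

__all__ = [
    "ExperimentDesign",
    "make_design",
    "default_params",
    "simulate_trials",
    "read_trials",
    "write_trials",
]

_DESIGN_ORIENTATIONS = tuple(float(t) for t in range(-21, 22, 3))

_EXPERIMENTS = {
    "1": dict(prior_cue=False, known_category=False, boundary_mode="none", boundary_shifts=(0.0,)),
    "2": dict(prior_cue=True, known_category=False, boundary_mode="none", boundary_shifts=(0.0,)),
    "3": dict(prior_cue=True, known_category=True, boundary_mode="none", boundary_shifts=(0.0,)),
    "boundary_present": dict(
        prior_cue=False, known_category=False, boundary_mode="none", boundary_shifts=(0.0,)
    ),
    "boundary_absent": dict(
        prior_cue=False,
        known_category=False,
        boundary_mode="absent_at_estimate",
        boundary_shifts=(0.0,),
    ),
    "boundary_shift": dict(
        prior_cue=False,
        known_category=False,
        boundary_mode="shifted",
        boundary_shifts=(-6.0, 0.0, 6.0),
    ),
}


@dataclasses.dataclass(frozen=True)
class ExperimentDesign:
    experiment: str
    orientations: tuple[float, ...] = _DESIGN_ORIENTATIONS
    stimulus_noise_sd: tuple[float, ...] = (0.0, 6.0, 18.0)
    trials_per_cell: int = 40
    prior_cue: bool = False
    known_category: bool = False
    boundary_mode: str = "none"
    boundary_shifts: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.boundary_mode not in ("none", "absent_at_estimate", "shifted"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def n_levels(self) -> int:
        return len(self.stimulus_noise_sd)

    @property
    def n_trials(self) -> int:
        return (
            len(self.orientations)
            * self.n_levels
            * self.trials_per_cell
            * len(self.boundary_shifts)
        )


def make_design(experiment, **overrides) -> ExperimentDesign:
    """Paper-default design for an experiment id, with optional overrides."""
    key = str(experiment)
    if key not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment id {experiment!r}; choose from {sorted(_EXPERIMENTS)}")
    kwargs = dict(_EXPERIMENTS[key])
    kwargs.update(overrides)
    return ExperimentDesign(experiment=key, **kwargs)


def default_params() -> ObserverParams:
    """Canonical synthetic observer used across tests and examples.

    Sensory noise grows with stimulus noise (3, 5, 8 degrees for array SDs
    0, 6, 18), modest memory noise, a prior wider than the true +/-21
    stimulus range (as fitted observers show), the average measured motor
    noise of 4.3 degrees, and a 4% lapse rate.
    """
    return ObserverParams(
        sigma_s=(3.0, 5.0, 8.0),
        sigma_m=2.0,
        alpha=25.0,
        beta=12.0,
        sigma_0=4.3,
        lapse_rate=0.04,
    )


def simulate_trials(
    design: ExperimentDesign,
    params: ObserverParams,
    lapse_rate: float | None = None,
    seed: int = 0,
    observer_variant: str = "self_consistent",
    cue_error_rate: float | None = None,
    grid: Grid | None = None,
    boundary_recall_step: float = 1.0,
) -> TrialTable:
    """Simulate a full trial table for one design.

    Independent per-stage random streams (measurement, memory, lapse,
    motor, category assignment) are derived from the master seed, so a
    change in one stage's draws never shifts another's.

    ``observer_variant`` selects the estimator ('self_consistent' or
    'independent').  ``lapse_rate`` defaults to ``params.lapse_rate``; a
    lapse flips the reported category while the estimate still follows the
    internal judgment (Experiments 1/2) or, with ``cue_error_rate``
    (default: the lapse rate), misremembers — hence inverts — the category
    cue in Experiment 3.  For the boundary-absent design
    the recalled boundary (SD ``params.sigma_b``) is discretized to
    ``boundary_recall_step`` degrees so estimate mappings can be cached.
    """
    if observer_variant not in ("self_consistent", "independent"):
        raise ValueError(f"unknown observer_variant {observer_variant!r}")
    if len(params.sigma_s) != design.n_levels:
        raise ValueError("params.sigma_s length must match the design's noise levels")
    lam = params.lapse_rate if lapse_rate is None else float(lapse_rate)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lapse rate must lie in [0, 1]")
    cue_err = lam if cue_error_rate is None else float(cue_error_rate)

    model = ObserverModel(params, grid)
    gridv = model.grid.values

    cells = [
        (lvl, th, sh)
        for sh in design.boundary_shifts
        for lvl in range(design.n_levels)
        for th in design.orientations
    ]
    n = len(cells) * design.trials_per_cell
    level = np.repeat([c[0] for c in cells], design.trials_per_cell)
    theta = np.repeat([c[1] for c in cells], design.trials_per_cell)
    shift = np.repeat([c[2] for c in cells], design.trials_per_cell)

    streams = np.random.SeedSequence(seed).spawn(5)
    rng_meas, rng_mem, rng_lapse, rng_motor, rng_assign = (
        np.random.default_rng(s) for s in streams
    )

    sigma_s = np.asarray(params.sigma_s)[level]
    m = theta + sigma_s * rng_meas.standard_normal(n)
    mm = m + params.sigma_m * rng_mem.standard_normal(n)

    lapse_flag = rng_lapse.random(n) < (cue_err if design.known_category else lam)
    guess = np.where(rng_assign.random(n) < 0.5, 1, -1)

    if design.known_category:
        true_cat = np.where(theta > 0, 1, np.where(theta < 0, -1, guess))
        cond_cat = np.where(lapse_flag, -true_cat, true_cat)  # misremembered cue is wrong
        report_cat = true_cat  # the recorded category is the (correct) cue
        internal_cat = cond_cat
        mapping_variant = "known_category"
    else:
        crit = np.array([model.criterion(lv) for lv in range(design.n_levels)])[level]
        internal_cat = np.where(m >= crit + shift, 1, -1)  # judgment at the (shifted) boundary
        cond_cat = internal_cat
        report_cat = np.where(lapse_flag, -internal_cat, internal_cat)  # lapse = wrong button
        mapping_variant = observer_variant

    # boundary recall offsets (prior re-centring) for the boundary-absent design
    if design.boundary_mode == "absent_at_estimate" and (params.sigma_b or 0.0) > 0:
        b = rng_assign.normal(0.0, params.sigma_b, n)
        b = np.round(b / boundary_recall_step) * boundary_recall_step
    else:
        b = np.zeros(n)

    est_core = np.empty(n)
    keys = {(lv, c, s, bb) for lv, c, s, bb in zip(level, cond_cat, shift, b)}
    for lv, c, s, bb in keys:
        mask = (level == lv) & (cond_cat == c) & (shift == s) & (b == bb)
        mapping = model.estimate_mapping(
            int(lv),
            Category(int(c)),
            mapping_variant,
            criterion=float(model.criterion(int(lv)) + s),
            prior_center=float(s + bb),
        )
        est_core[mask] = np.interp(mm[mask], gridv, mapping)

    estimate = est_core + params.sigma_0 * rng_motor.standard_normal(n)

    df = pd.DataFrame(
        {
            "experiment": design.experiment,
            "noise_level": level.astype(int),
            "theta_deg": theta,
            "report_category": np.where(report_cat > 0, "cw", "ccw"),
            "estimate_deg": estimate,
            "m_deg": m,
            "mm_deg": mm,
            "internal_category": np.where(internal_cat > 0, "cw", "ccw"),
            "lapse": lapse_flag,
            "boundary_shift_deg": shift,
        }
    )
    return TrialTable(df)
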