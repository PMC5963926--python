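"""Estimation stage of the task sequence.

After the categorical judgment, the observer estimates the stimulus
orientation from a noisy memory recall mm of the sensory measurement m.
The self-consistent observer conditions this inference on its own choice:
the likelihood marginalizes only over measurements m that led to that
choice, and the stimulus prior is truncated to the chosen side.  The
estimate is the posterior mean (squared-error loss), a deterministic,
monotone mapping of mm; predicted estimate distributions are obtained by
pushing the conditional recall distribution through that mapping.

The decide-restricted recall density has a closed form.  Writing
sigma_t^2 = sigma_s^2 + sigma_m^2 and using the Gaussian product rule,

    q(mm | theta, chat) = Int_{side} N(mm; m, sigma_m) N(m; theta, sigma_s) dm
                        = N(mm; theta, sigma_t) * Phi(+/-(mu(mm) - c)/tau),

with mu(mm) = (sigma_m^2 theta + sigma_s^2 mm)/sigma_t^2 and
tau = sigma_s sigma_m / sigma_t.  Summed over the two choices this
reconstructs the unrestricted Gaussian exactly (partition identity).  A
direct quadrature route over the m grid is retained for cross-checking.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import log_ndtr, ndtr

from .discrimination import decision_criterion, psychometric_closed_form
from .observer_core import (
    Category,
    Grid,
    ObserverParams,
    category_prior_density,
    unconditional_prior,
)

__all__ = [
    "EstimateDensity",
    "ObserverModel",
    "conditional_measurement_density",
    "conditioned_posterior",
    "estimate",
    "estimate_distribution",
    "estimate_distribution_boundary_variants",
    "motor_convolve",
    "bias_curve",
    "VARIANTS",
]

VARIANTS = ("self_consistent", "known_category", "independent")
_LOG_SQRT2PI = 0.5 * math.log(2.0 * math.pi)
_TINY_MASS = 1e-12


@dataclasses.dataclass(frozen=True)
class EstimateDensity:
    """Predicted estimate densities p(theta_hat | theta, chat) on a grid.

    ``p_cw``/``p_ccw`` are each normalized conditional densities (or zero
    arrays when the corresponding choice has negligible probability);
    ``weight_cw``/``weight_ccw`` are the mixing probabilities p(chat|theta).
    """

    theta_true: float
    noise_level: int
    grid: Grid
    p_cw: np.ndarray
    p_ccw: np.ndarray
    weight_cw: float
    weight_ccw: float
    variant: str
    motor_convolved: bool = False

    @property
    def mixture(self) -> np.ndarray:
        return self.weight_cw * self.p_cw + self.weight_ccw * self.p_ccw

    def conditional(self, category) -> np.ndarray:
        return self.p_cw if Category.parse(category) is Category.CW else self.p_ccw

    def weight(self, category) -> float:
        return self.weight_cw if Category.parse(category) is Category.CW else self.weight_ccw

    def conditional_mean(self, category) -> float:
        dens = self.conditional(category)
        return self.grid.mean(dens)

    def mixture_mean(self) -> float:
        return self.grid.mean(self.mixture)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta_hat_deg": self.grid.values,
                "p_cw": self.p_cw,
                "p_ccw": self.p_ccw,
                "mixture": self.mixture,
            }
        )


def _log_gauss(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT2PI


def _restricted_recall_density(x, theta, sigma_s, sigma_m, sign, criterion):
    """Closed-form q(x | theta, side) for the decide-restricted recall."""
    if sigma_s == 0.0:
        # measurement equals theta; the whole probability mass follows one choice
        side = 1 if theta >= criterion else -1
        if side != sign:
            return np.zeros_like(np.asarray(x, dtype=float))
        if sigma_m == 0.0:
            raise ValueError("degenerate (sigma_s = sigma_m = 0) density has no grid form")
        return np.exp(_log_gauss(np.asarray(x, dtype=float), theta, sigma_m))
    st2 = sigma_s**2 + sigma_m**2
    st = math.sqrt(st2)
    x = np.asarray(x, dtype=float)
    base = np.exp(_log_gauss(x, theta, st))
    if sigma_m == 0.0:
        ind = (x >= criterion) if sign > 0 else (x < criterion)
        return base * ind
    tau = sigma_s * sigma_m / st
    mu = (sigma_m**2 * theta + sigma_s**2 * x) / st2
    return base * ndtr(sign * (mu - criterion) / tau)


def conditional_measurement_density(
    theta: float,
    category,
    params: ObserverParams,
    noise_level: int,
    grid: Grid | None = None,
    criterion: float | None = None,
    method: str = "closed",
):
    """Unnormalized p(mm | theta, chat) on the grid, plus its mass p(chat|theta).

    The density integrates to the choice probability, so one pass yields
    both the conditional recall distribution and the psychometric value.
    ``method="quadrature"`` integrates the truncated sensory Gaussian
    against the memory kernel on the m grid (independent cross-check).
    """
    grid = grid or Grid()
    cat = Category.parse(category)
    if criterion is None:
        criterion = decision_criterion(params, noise_level, grid)
    sigma_s = params.sigma_s[noise_level]
    sigma_m = params.sigma_m
    if method == "closed":
        q = _restricted_recall_density(grid.values, theta, sigma_s, sigma_m, cat.sign, criterion)
    elif method == "quadrature":
        m = grid.values
        mask = (m >= criterion) if cat.sign > 0 else (m < criterion)
        sens = np.exp(_log_gauss(m, theta, sigma_s)) * mask
        if sigma_m == 0.0:
            q = sens
        else:
            mem = np.exp(_log_gauss(grid.values[:, None], m[None, :], sigma_m))
            q = mem @ sens * grid.step
    else:
        raise ValueError(f"unknown method {method!r}")
    return q, grid.integrate(q)


def _pushforward(masses: np.ndarray, mapping: np.ndarray, grid: Grid) -> np.ndarray:
    """Push cell masses on the mm grid through a monotone mapping.

    Mass-preserving CDF transport: the mapping is read at the input cell
    edges and each cell's mass is spread linearly over its image interval,
    so the result is the change-of-variables density without aliasing.
    Plateaus of the mapping collapse their mass into the single output
    cell containing the plateau value.  ``masses`` may be 1-D or
    (n_rows, n) for a batch sharing one mapping.  Returns densities on
    ``grid``.
    """
    was_1d = np.ndim(masses) == 1
    masses = np.atleast_2d(masses)
    cum = np.concatenate([np.zeros((masses.shape[0], 1)), np.cumsum(masses, axis=1)], axis=1)
    edges = grid.edges
    # image of the input cell edges under the (monotone) mapping
    xk = np.maximum.accumulate(np.interp(edges, grid.values, mapping))
    idx = np.clip(np.searchsorted(xk, edges, side="left"), 1, xk.size - 1)
    x0, x1 = xk[idx - 1], xk[idx]
    span = x1 - x0
    frac = np.clip(np.where(span > 0, (edges - x0) / np.where(span > 0, span, 1.0), 1.0), 0.0, 1.0)
    cdf = cum[:, idx - 1] + frac[None, :] * (cum[:, idx] - cum[:, idx - 1])
    cdf = np.where(edges[None, :] < xk[0], 0.0, cdf)
    cdf = np.where(edges[None, :] >= xk[-1], cum[:, -1:], cdf)
    dens = np.diff(cdf, axis=1) / grid.step
    return dens[0] if was_1d else dens


class ObserverModel:
    """Binds a parameter vector to numeric grids and caches the heavy pieces.

    The cached objects are the decision criterion per noise level and the
    posterior-mean estimate mapping theta_hat(mm) per (level, category,
    variant, boundary geometry).  All predicted distributions and the joint
    likelihood are assembled from these.
    """

    def __init__(self, params: ObserverParams, grid: Grid | None = None):
        self.params = params
        self.grid = grid or Grid()
        self._criterion: dict[int, float] = {}
        self._mappings: dict[tuple, np.ndarray] = {}

    # -- decision stage -------------------------------------------------
    def criterion(self, noise_level: int) -> float:
        if noise_level not in self._criterion:
            self._criterion[noise_level] = decision_criterion(self.params, noise_level, self.grid)
        return self._criterion[noise_level]

    def choice_probability(self, theta, noise_level: int, lapse_rate: float = 0.0):
        """p(chat = cw | theta) from the threshold rule (Gaussian tail)."""
        return psychometric_closed_form(
            theta, self.params, noise_level, lapse_rate, self.criterion(noise_level)
        )

    # -- posterior and estimate mapping --------------------------------
    def _log_prior(self, category, variant: str, prior_center: float) -> np.ndarray:
        v = self.grid.values - prior_center
        p = self.params
        if variant == "independent":
            prior = unconditional_prior(v, p.alpha, p.beta, p.p_cat)
        else:
            prior = category_prior_density(v, category, p.alpha, p.beta)
        with np.errstate(divide="ignore"):
            return np.log(prior)

    def _log_likelihood_matrix(
        self, category, noise_level: int, variant: str, criterion: float
    ) -> np.ndarray:
        """log p(mm | theta, ...) over (mm rows, theta columns)."""
        p = self.params
        sigma_s = p.sigma_s[noise_level]
        sigma_m = p.sigma_m
        st2 = sigma_s**2 + sigma_m**2
        st = math.sqrt(st2)
        x = self.grid.values[:, None]
        th = self.grid.values[None, :]
        if st == 0.0:
            logl = np.full((self.grid.n, self.grid.n), -np.inf)
            np.fill_diagonal(logl, 0.0)
            return logl
        logl = _log_gauss(x, th, st)
        if variant == "self_consistent":
            sign = Category.parse(category).sign
            if sigma_s == 0.0:
                ok = (th >= criterion) if sign > 0 else (th < criterion)
                logl = np.where(np.broadcast_to(ok, logl.shape), logl, -np.inf)
            elif sigma_m == 0.0:
                ok = (x >= criterion) if sign > 0 else (x < criterion)
                logl = np.where(np.broadcast_to(ok, logl.shape), logl, -np.inf)
            else:
                tau = sigma_s * sigma_m / st
                mu = (sigma_m**2 * th + sigma_s**2 * x) / st2
                logl = logl + log_ndtr(sign * (mu - criterion) / tau)
        return logl

    def estimate_mapping(
        self,
        noise_level: int,
        category,
        variant: str = "self_consistent",
        criterion: float | None = None,
        prior_center: float = 0.0,
    ) -> np.ndarray:
        """theta_hat(mm) on the mm grid: the posterior-mean estimator.

        Monotone nondecreasing by construction of the model; enforced
        numerically (violations beyond rounding raise a warning).  Grid
        rows whose posterior underflows to zero everywhere (recalls far on
        the inconsistent side) are filled from the nearest valid neighbor.
        """
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        cat = Category.parse(category)
        if criterion is None:
            criterion = self.criterion(noise_level)
        key = (noise_level, cat, variant, round(criterion, 9), round(prior_center, 9))
        if key in self._mappings:
            return self._mappings[key]
        logl = self._log_likelihood_matrix(cat, noise_level, variant, criterion)
        logpost = logl + self._log_prior(cat, variant, prior_center)[None, :]
        rowmax = logpost.max(axis=1)
        valid = np.isfinite(rowmax)
        w = np.exp(logpost[valid] - rowmax[valid, None])
        th = self.grid.values
        mapping = np.full(self.grid.n, np.nan)
        mapping[valid] = (w * th[None, :]).sum(axis=1) / w.sum(axis=1)
        if not valid.all():
            if not valid.any():
                raise ValueError("posterior mass is zero on the whole grid")
            # fill degenerate rows from the nearest computed value
            idx = np.arange(self.grid.n)
            good = idx[valid]
            mapping = np.interp(idx, good, mapping[valid])
        viol = np.min(np.diff(mapping))
        if viol < -1e-6:
            warnings.warn(
                f"estimate mapping not monotone (min step {viol:.2e}); clamping",
                RuntimeWarning,
                stacklevel=2,
            )
        mapping = np.maximum.accumulate(mapping)
        self._mappings[key] = mapping
        return mapping

    def posterior(
        self,
        mm: float,
        category,
        noise_level: int,
        variant: str = "self_consistent",
        criterion: float | None = None,
        prior_center: float = 0.0,
    ) -> np.ndarray:
        """Normalized posterior p(theta | mm, chat) on the theta grid."""
        cat = Category.parse(category)
        if criterion is None:
            criterion = self.criterion(noise_level)
        p = self.params
        sigma_s = p.sigma_s[noise_level]
        th = self.grid.values
        st = math.sqrt(sigma_s**2 + p.sigma_m**2)
        with np.errstate(divide="ignore"):
            if variant == "self_consistent":
                if sigma_s == 0.0:
                    # m = theta exactly: the restriction acts on theta itself
                    dens = np.exp(_log_gauss(mm, th, st)) if st > 0 else _delta_row(mm, self.grid)
                    side = (th >= criterion) if cat.sign > 0 else (th < criterion)
                    logl_v = np.log(dens * side)
                else:
                    logl_v = np.log(
                        _restricted_likelihood_of_theta(
                            mm, th, sigma_s, p.sigma_m, cat.sign, criterion
                        )
                    )
            else:
                logl_v = _log_gauss(mm, th, st) if st > 0 else np.log(_delta_row(mm, self.grid))
            logpost = logl_v + self._log_prior(cat, variant, prior_center)
        mx = logpost.max()
        if not np.isfinite(mx):
            raise ValueError("posterior mass is zero on the whole grid (grid misconfiguration)")
        post = np.exp(logpost - mx)
        return post / self.grid.integrate(post)

    def estimate(
        self,
        mm,
        category,
        noise_level: int,
        variant: str = "self_consistent",
        criterion: float | None = None,
        prior_center: float = 0.0,
    ):
        """Posterior-mean estimate for one or many recall values."""
        mm_arr = np.atleast_1d(np.asarray(mm, dtype=float))
        out = np.empty(mm_arr.shape)
        for i, x in enumerate(mm_arr):
            post = self.posterior(x, category, noise_level, variant, criterion, prior_center)
            out[i] = self.grid.mean(post)
        return out if np.ndim(mm) else float(out[0])

    # -- predicted estimate distributions -------------------------------
    def recall_density(
        self, theta: float, category, noise_level: int, variant: str, criterion: float
    ) -> tuple[np.ndarray, float]:
        """Conditional recall density feeding the estimator, with its mass."""
        if variant == "known_category":
            p = self.params
            st = math.sqrt(p.sigma_s[noise_level] ** 2 + p.sigma_m**2)
            q = (
                np.exp(_log_gauss(self.grid.values, theta, st))
                if st > 0
                else _delta_row(theta, self.grid)
            )
            return q, 1.0
        return conditional_measurement_density(
            theta, category, self.params, noise_level, self.grid, criterion
        )

    def distribution(
        self, theta: float, noise_level: int, variant: str = "self_consistent"
    ) -> EstimateDensity:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        c = self.criterion(noise_level)
        conds: dict[Category, np.ndarray] = {}
        weights: dict[Category, float] = {}
        for cat in (Category.CW, Category.CCW):
            if variant == "known_category":
                if theta == 0.0:
                    w = 0.5
                elif Category.from_sign(theta) is cat:
                    w = 1.0
                else:
                    w = 0.0
                q, _ = self.recall_density(theta, cat, noise_level, variant, c)
            else:
                q, w = self.recall_density(theta, cat, noise_level, variant, c)
            weights[cat] = float(w)
            # the known-category conditional is defined for either cue, so it is
            # computed even at zero mixture weight (needed for wrong-cue lapses)
            if variant != "known_category" and w <= _TINY_MASS:
                conds[cat] = np.zeros(self.grid.n)
                continue
            mapping = self.estimate_mapping(noise_level, cat, variant, criterion=c)
            masses = q * self.grid.step
            masses = masses / masses.sum()
            conds[cat] = _pushforward(masses, mapping, self.grid)
        # weights from the truncated densities already sum to ~1 for the
        # self-consistent and independent variants; renormalize exactly.
        if variant != "known_category":
            tot = weights[Category.CW] + weights[Category.CCW]
            weights = {k: v / tot for k, v in weights.items()}
        return EstimateDensity(
            theta_true=theta,
            noise_level=noise_level,
            grid=self.grid,
            p_cw=conds[Category.CW],
            p_ccw=conds[Category.CCW],
            weight_cw=weights[Category.CW],
            weight_ccw=weights[Category.CCW],
            variant=variant,
        )

    def boundary_variant_distribution(
        self,
        theta: float,
        noise_level: int,
        sigma_b: float = 0.0,
        shift: float = 0.0,
        n_nodes: int = 21,
    ) -> EstimateDensity:
        """Self-consistent density under a shifted and/or noisily recalled boundary.

        ``shift`` moves the boundary used for both the implicit judgment
        (truncation and choice weights) and the conditioned prior, while the
        stimulus stays in the original frame.  ``sigma_b`` adds Gaussian
        recall noise to the boundary position used by the conditioned prior
        at estimation time (the judgment itself is made with the boundary
        still in view); integrated by Gauss-Hermite quadrature.
        """
        if sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if not np.isfinite(shift):
            raise ValueError("shift must be finite")
        variant = "boundary_noise" if sigma_b > 0 else "boundary_shift"
        if sigma_b == 0.0 and shift == 0.0:
            base = self.distribution(theta, noise_level, "self_consistent")
            return dataclasses.replace(base, variant=variant)
        if sigma_b > 0:
            nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
            offsets = math.sqrt(2.0) * sigma_b * nodes
            wts = wts / math.sqrt(math.pi)
            # keep the recalled boundary within the grid's useful range; the
            # trimmed extreme nodes carry negligible Gauss-Hermite weight
            keep = np.abs(offsets) <= self.grid.half_span / 2.0
            offsets, wts = offsets[keep], wts[keep] / wts[keep].sum()
        else:
            offsets, wts = np.array([0.0]), np.array([1.0])
        p = self.params
        sigma_s = p.sigma_s[noise_level]
        w_cw = float(psychometric_closed_form(theta, p, noise_level, 0.0, shift))
        conds = {}
        for cat in (Category.CW, Category.CCW):
            w = w_cw if cat is Category.CW else 1.0 - w_cw
            if w <= _TINY_MASS:
                conds[cat] = np.zeros(self.grid.n)
                continue
            q = _restricted_recall_density(
                self.grid.values, theta, sigma_s, p.sigma_m, cat.sign, shift
            )
            masses = q * self.grid.step
            masses = masses / masses.sum()
            acc = np.zeros(self.grid.n)
            for b, wb in zip(offsets, wts):
                mapping = self.estimate_mapping(
                    noise_level, cat, "self_consistent", criterion=shift, prior_center=shift + b
                )
                acc += wb * _pushforward(masses, mapping, self.grid)
            conds[cat] = acc
        return EstimateDensity(
            theta_true=theta,
            noise_level=noise_level,
            grid=self.grid,
            p_cw=conds[Category.CW],
            p_ccw=conds[Category.CCW],
            weight_cw=w_cw,
            weight_ccw=1.0 - w_cw,
            variant=variant,
        )


def _delta_row(center: float, grid: Grid) -> np.ndarray:
    dens = np.zeros(grid.n)
    dens[int(np.argmin(np.abs(grid.values - center)))] = 1.0 / grid.step
    return dens


def _restricted_likelihood_of_theta(mm, th, sigma_s, sigma_m, sign, criterion):
    """q(mm | theta, side) evaluated as a function of theta at fixed mm."""
    st2 = sigma_s**2 + sigma_m**2
    st = math.sqrt(st2)
    base = np.exp(_log_gauss(mm, th, st))
    if sigma_m == 0.0:
        ind = 1.0 if ((mm >= criterion) if sign > 0 else (mm < criterion)) else 0.0
        return base * ind
    tau = sigma_s * sigma_m / st
    mu = (sigma_m**2 * th + sigma_s**2 * mm) / st2
    return base * ndtr(sign * (mu - criterion) / tau)


# ---------------------------------------------------------------------------
# module-level wrappers (one transient model each; heavy users should hold an
# ObserverModel so the estimate mappings stay cached)
# ---------------------------------------------------------------------------

def conditioned_posterior(
    mm: float,
    category,
    params: ObserverParams,
    noise_level: int,
    grid: Grid | None = None,
    variant: str = "self_consistent",
) -> np.ndarray:
    return ObserverModel(params, grid).posterior(mm, category, noise_level, variant)


def estimate(
    mm,
    category,
    params: ObserverParams,
    noise_level: int,
    grid: Grid | None = None,
    variant: str = "self_consistent",
):
    return ObserverModel(params, grid).estimate(mm, category, noise_level, variant)


def estimate_distribution(
    theta: float,
    params: ObserverParams,
    noise_level: int,
    variant: str = "self_consistent",
    grid: Grid | None = None,
) -> EstimateDensity:
    return ObserverModel(params, grid).distribution(theta, noise_level, variant)


def estimate_distribution_boundary_variants(
    theta: float,
    params: ObserverParams,
    noise_level: int,
    sigma_b: float = 0.0,
    shift: float = 0.0,
    grid: Grid | None = None,
) -> EstimateDensity:
    return ObserverModel(params, grid).boundary_variant_distribution(
        theta, noise_level, sigma_b, shift
    )


def motor_convolve(density: EstimateDensity, sigma_0: float) -> EstimateDensity:
    """Convolve every conditional with the Gaussian motor kernel.

    Mass may cross the boundary afterwards.  Double convolution is refused.
    """
    if sigma_0 < 0:
        raise ValueError("sigma_0 must be >= 0")
    if density.motor_convolved:
        raise ValueError("density is already motor-convolved")
    if sigma_0 == 0.0:
        return dataclasses.replace(density, motor_convolved=True)
    sig = sigma_0 / density.grid.step
    smooth = lambda d: gaussian_filter1d(d, sig, mode="constant", truncate=8.0)
    return dataclasses.replace(
        density,
        p_cw=smooth(density.p_cw),
        p_ccw=smooth(density.p_ccw),
        motor_convolved=True,
    )


def bias_curve(
    params: ObserverParams,
    noise_level: int,
    variant: str = "self_consistent",
    correct_only: bool = True,
    theta_values=None,
    grid: Grid | None = None,
    model: ObserverModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean signed estimation bias, folded across the two boundary sides.

    For each |theta| the bias is the mean of (theta_hat - theta) under the
    conditional (correct choice only when ``correct_only``) or the mixture
    density, signed so that positive means repulsion away from the boundary,
    averaged over the mirrored +/-theta pair.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    model = model or ObserverModel(params, grid)
    if theta_values is None:
        theta_values = np.arange(0.0, 21.0 + 1e-9, 3.0)
    theta_values = np.asarray(theta_values, dtype=float)
    biases = np.empty(theta_values.shape)
    for i, t in enumerate(theta_values):
        folded = []
        for th in {t, -t}:
            dens = model.distribution(th, noise_level, variant)
            cat = Category.from_sign(th) if th != 0 else Category.CW
            target = dens.conditional(cat) if correct_only else dens.mixture
            sign = 1.0 if cat is Category.CW else -1.0
            folded.append(sign * (dens.grid.mean(target) - th))
        biases[i] = float(np.mean(folded))
    return theta_values, biases
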