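"""Building blocks of the generative observer model.

The model lives in a boundary-relative frame: orientations are measured in
degrees relative to the discrimination boundary, positive = clockwise (cw).
This module houses the parameter container, the category-conditioned
stimulus prior (uniform core with a cosine fall-off), and Gaussian noise
kernels evaluated on explicit numeric grids.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings

import numpy as np

__all__ = [
    "Category",
    "Grid",
    "ObserverParams",
    "CategoryPrior",
    "category_prior_density",
    "unconditional_prior",
    "gaussian_kernel",
    "prior_half_width",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


class Category(enum.IntEnum):
    """Categorical judgment, signed so that cw <-> +1 and ccw <-> -1.

    "Consistent with cw" means orientation > 0 throughout the package.
    """

    CW = 1
    CCW = -1

    @property
    def label(self) -> str:
        return "cw" if self is Category.CW else "ccw"

    @property
    def sign(self) -> int:
        return int(self.value)

    @property
    def opposite(self) -> "Category":
        return Category.CCW if self is Category.CW else Category.CW

    @classmethod
    def from_sign(cls, x: float) -> "Category":
        """Map a signed quantity to a category; 0 maps to CW (fixed tie rule)."""
        return cls.CW if x >= 0 else cls.CCW

    @classmethod
    def parse(cls, value) -> "Category":
        if isinstance(value, Category):
            return value
        if isinstance(value, str):
            v = value.strip().lower()
            if v == "cw":
                return cls.CW
            if v == "ccw":
                return cls.CCW
            raise ValueError(f"unknown category label {value!r}")
        return cls.CW if float(value) > 0 else cls.CCW


@dataclasses.dataclass(frozen=True)
class Grid:
    """Uniform numeric grid in degrees, offset half a step from 0.

    Points sit at +/-(step/2 + k*step), so 0 itself is a cell edge and never
    a sample point; densities with a jump at the boundary are integrated by
    the midpoint rule without straddling the discontinuity.
    """

    half_span: float = 80.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (self.step > 0 and self.half_span > self.step):
            raise ValueError("grid requires 0 < step < half_span")
        pos = np.arange(self.step / 2.0, self.half_span, self.step)
        values = np.concatenate([-pos[::-1], pos])
        values.setflags(write=False)
        object.__setattr__(self, "_values", values)

    @property
    def values(self) -> np.ndarray:
        return self._values  # type: ignore[attr-defined]

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def edges(self) -> np.ndarray:
        v = self.values
        return np.concatenate([v - self.step / 2.0, [v[-1] + self.step / 2.0]])

    def integrate(self, density: np.ndarray) -> float:
        """Midpoint-rule integral of a density sampled on the grid."""
        return float(np.sum(density) * self.step)

    def mean(self, density: np.ndarray) -> float:
        mass = np.sum(density)
        if mass <= 0:
            raise ValueError("cannot take the mean of a zero-mass density")
        return float(np.sum(self.values * density) / mass)

    def covers(self, extent: float) -> bool:
        return self.half_span >= extent


@dataclasses.dataclass(frozen=True)
class ObserverParams:
    """Full observer parameter vector.

    sigma_s
        Sensory-noise SDs in degrees, one per stimulus-noise level.
    sigma_m
        Working-memory recall noise SD in degrees (shared across levels).
    alpha, beta
        Conditioned stimulus prior: uniform over ``alpha`` degrees from the
        boundary with a cosine fall-off to zero over a further ``beta``
        degrees.  The half-density prior width is wp = alpha + 2*beta/3.
    sigma_0
        Motor (reproduction) noise SD in degrees; measured separately and
        held fixed during fitting.
    lapse_rate
        Probability that a non-perceptual error flips the categorical
        report; estimated from the psychometric functions, not part of
        the six fitted parameters.
    sigma_b
        Optional boundary-recall noise SD (boundary-absent variant only).
    p_cat
        Prior probability of the cw category (0.5 in all designs).
    """

    sigma_s: tuple[float, ...]
    sigma_m: float
    alpha: float
    beta: float
    sigma_0: float = 4.3
    lapse_rate: float = 0.0
    sigma_b: float | None = None
    p_cat: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_s", tuple(float(s) for s in np.atleast_1d(self.sigma_s)))
        if any(s < 0 for s in self.sigma_s):
            raise ValueError("sensory noise SDs must be >= 0")
        if self.sigma_m < 0 or self.sigma_0 < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.sigma_b is not None and self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if not 0.0 < self.p_cat < 1.0:
            raise ValueError("p_cat must lie strictly inside (0, 1)")

    @property
    def n_levels(self) -> int:
        return len(self.sigma_s)

    @property
    def prior_width(self) -> float:
        """wp, the angle where the conditioned prior falls to half its core value."""
        return prior_half_width(self.alpha, self.beta)

    def sigma_total(self, noise_level: int) -> float:
        """SD of the memory recall mm about the true orientation."""
        return math.hypot(self.sigma_s[noise_level], self.sigma_m)

    def replace(self, **kwargs) -> "ObserverParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigma_s"] = list(self.sigma_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def prior_half_width(alpha: float, beta: float) -> float:
    return alpha + 2.0 * beta / 3.0


def _check_prior_params(alpha: float, beta: float) -> None:
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("alpha must be finite and > 0")
    if not np.isfinite(beta) or beta < 0:
        raise ValueError("beta must be finite and >= 0")


def category_prior_density(theta, category, alpha: float, beta: float):
    """Conditioned stimulus prior p(theta | C), in probability per degree.

    For C = cw the density is uniform on (0, alpha], falls as
    cos(pi*(theta - alpha)/(2*beta)) on (alpha, alpha + beta], and is zero
    elsewhere; ccw is the exact mirror image.  Normalization is analytic:
    the integral of the core plus the quarter-cosine ramp is
    alpha + 2*beta/pi.  The half-density point sits at alpha + 2*beta/3.
    """
    _check_prior_params(alpha, beta)
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    cat = Category.parse(category)
    x = theta * cat.sign
    norm = alpha + 2.0 * beta / math.pi
    dens = np.zeros_like(x)
    core = (x > 0) & (x <= alpha)
    dens[core] = 1.0 / norm
    if beta > 0:
        ramp = (x > alpha) & (x <= alpha + beta)
        dens[ramp] = np.cos(math.pi * (x[ramp] - alpha) / (2.0 * beta)) / norm
    return dens if dens.ndim else float(dens)


def unconditional_prior(theta, alpha: float, beta: float, p_cat: float = 0.5):
    """Category-marginalized stimulus prior p(theta) = sum_C p(theta|C) p(C)."""
    _check_prior_params(alpha, beta)
    if not 0.0 < p_cat < 1.0:
        raise ValueError("p_cat must lie strictly inside (0, 1)")
    return p_cat * category_prior_density(theta, Category.CW, alpha, beta) + (
        1.0 - p_cat
    ) * category_prior_density(theta, Category.CCW, alpha, beta)


@dataclasses.dataclass(frozen=True)
class CategoryPrior:
    """Conditioned stimulus prior with its defining angles."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check_prior_params(self.alpha, self.beta)

    @property
    def half_width(self) -> float:
        return prior_half_width(self.alpha, self.beta)

    def density(self, theta, category) -> np.ndarray:
        return category_prior_density(theta, category, self.alpha, self.beta)

    def mixture(self, theta, p_cat: float = 0.5) -> np.ndarray:
        return unconditional_prior(theta, self.alpha, self.beta, p_cat)


def gaussian_kernel(center: float, sd: float, grid: Grid) -> np.ndarray:
    """Gaussian density on a grid; sd = 0 degenerates to a grid delta.

    The delta carries mass 1, i.e. density 1/step at the nearest grid point.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    v = grid.values
    if sd == 0.0:
        dens = np.zeros(grid.n)
        dens[int(np.argmin(np.abs(v - center)))] = 1.0 / grid.step
        return dens
    if abs(center) + 4.0 * sd > grid.half_span:
        warnings.warn(
            "Gaussian kernel extends beyond the grid; tail mass is truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.exp(-0.5 * ((v - center) / sd) ** 2) / (sd * _SQRT2PI)
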