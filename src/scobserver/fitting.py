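"""Joint maximum-likelihood fitting of the observer model to trial tables.

The joint likelihood of a trial is the product of the choice probability
and the motor-convolved conditional estimate density evaluated at the
reported estimate,

    log L = sum_i [ log P(chat_i | rho, theta_i) + log p(thetahat_i | chat_i, rho, theta_i) ],

maximized over the six free parameters (three sensory noise SDs, memory
noise, and the two prior angles alpha, beta) with multi-start Nelder-Mead
on log-transformed parameters.  Motor noise is measured separately and
held fixed.  Trials whose estimate contradicts the reported category are
excluded; because the convolved density then loses the excluded mass, the
conditional density is renormalized over the consistent half-line (a
config switch disables this for comparison).  Known-category trials
(Experiment 3) use the unrestricted recall density and contribute no
choice term.

The fitter is exposed as a scikit-learn style estimator (``ObserverMLE``)
so it composes with sklearn model-selection utilities; ``fit_observer``
is the thin functional wrapper.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.special import expit, ndtr
from sklearn.base import BaseEstimator

from .estimation import ObserverModel, _pushforward, _restricted_recall_density, _log_gauss
from .observer_core import Category, Grid, ObserverParams
from .trials import TrialTable

__all__ = [
    "FitResult",
    "ObserverMLE",
    "classify_consistency",
    "joint_loglikelihood",
    "extract_lapse_rate",
    "fit_observer",
    "bootstrap_ci",
    "RESTART_RANGES",
]

# log-uniform initialization brackets for the six free parameters (degrees)
RESTART_RANGES = {"sigma_s": (1.0, 20.0), "sigma_m": (0.5, 30.0), "alpha": (10.0, 40.0), "beta": (1.0, 30.0)}


def probit_informed_start(table: TrialTable, n_levels: int) -> np.ndarray:
    """Data-driven starting point (log scale) for the Nelder-Mead restarts.

    Sensory noise SDs come from per-level probit slopes of the reported
    categories; memory noise and the prior angles start at the geometric
    midpoints of their restart brackets.
    """
    df = table.df
    sig = []
    for lvl in range(n_levels):
        sub = df[df["noise_level"] == lvl]
        if len(sub) == 0:
            sig.append(math.sqrt(RESTART_RANGES["sigma_s"][0] * RESTART_RANGES["sigma_s"][1]))
            continue
        rates = sub.groupby("theta_deg")["report_category"].apply(lambda s: (s == "cw").mean())
        th = rates.index.to_numpy(dtype=float)
        pr = np.clip(rates.to_numpy(dtype=float), 0.02, 0.98)
        slope = np.polyfit(th, _ndtri(pr), 1)[0] if len(th) > 1 else 0.0
        lo, hi = RESTART_RANGES["sigma_s"]
        sig.append(float(np.clip(1.0 / max(slope, 1e-3), lo, hi)))
    mids = [
        math.sqrt(RESTART_RANGES["sigma_m"][0] * RESTART_RANGES["sigma_m"][1]),
        math.sqrt(RESTART_RANGES["alpha"][0] * RESTART_RANGES["alpha"][1]),
        math.sqrt(RESTART_RANGES["beta"][0] * RESTART_RANGES["beta"][1]),
    ]
    return np.log(np.array(sig + mids))


def _ndtri(p):
    from scipy.special import ndtri

    return ndtri(p)


def classify_consistency(table: TrialTable) -> tuple[TrialTable, TrialTable]:
    """Partition trials by sign agreement of reported category and estimate."""
    mask = table.consistent_mask
    return table.subset(mask), table.subset(~mask)


def _experiment_variant(exp_id: str, variant: str) -> str:
    return "known_category" if str(exp_id) == "3" else variant


def _conditional_density_matrix(
    model: ObserverModel, thetas: np.ndarray, lvl: int, cat: Category, var: str, criterion: float
) -> np.ndarray:
    """Motor-convolved p(theta_hat | theta, conditioning category) rows per theta."""
    grid = model.grid
    params = model.params
    sigma_s = params.sigma_s[lvl]
    if var == "known_category":
        st = math.hypot(sigma_s, params.sigma_m)
        q = np.exp(_log_gauss(grid.values[None, :], thetas[:, None], st))
    else:
        q = np.stack(
            [
                _restricted_recall_density(grid.values, t, sigma_s, params.sigma_m, cat.sign, criterion)
                for t in thetas
            ]
        )
    masses = q * grid.step
    tot = masses.sum(axis=1, keepdims=True)
    masses = np.divide(masses, tot, out=np.zeros_like(masses), where=tot > 1e-300)
    mapping = model.estimate_mapping(lvl, cat, var, criterion=criterion)
    dens = _pushforward(masses, mapping, grid)
    if params.sigma_0 > 0:
        dens = gaussian_filter1d(
            dens, params.sigma_0 / grid.step, axis=1, mode="constant", truncate=8.0
        )
    return dens


def joint_loglikelihood(
    table: TrialTable,
    params: ObserverParams,
    lapse_rate: float = 0.0,
    grid: Grid | None = None,
    variant: str = "self_consistent",
    renormalize: bool = True,
    min_density: float = 1e-6,
    model: ObserverModel | None = None,
) -> float:
    """Joint log-likelihood of the (consistent) trials under the model.

    Each trial contributes the probability of its (reported category,
    reported estimate) pair.  Because inconsistent trials are excluded
    before fitting, the likelihood is the conditional density of a
    *consistent* trial: a lapse-aware mixture over the internal judgment,

        f_chat(x) = (1-lambda) psi_chat d_chat(x) + lambda psi_-chat d_-chat(x),

    on chat's half-line, where psi is the lapse-free choice probability
    and d the motor-convolved conditional estimate density, normalized by
    the total consistency probability (``renormalize=False`` drops the
    normalizer).  Known-category trials replace psi by the cue assignment
    probability and lambda by the cue-memory error rate, and contribute no
    separate choice factor.  At lambda = 0 this reduces to choice factor x
    half-line-renormalized conditional density.  Densities are computed
    per unique (variant, level, theta) cell; observed estimates are read
    off by interpolation and floored at ``min_density`` (with a warning).
    """
    model = model or ObserverModel(params, grid)
    grid = model.grid
    df = table.df
    if len(df) == 0:
        raise ValueError("empty trial table")
    gridv = grid.values
    lam = float(lapse_rate)
    ll = 0.0
    floored = 0
    exp_var = df["experiment"].map(lambda e: _experiment_variant(e, variant)).to_numpy()
    rep_sign = table.report_sign
    theta = df["theta_deg"].to_numpy()
    est = df["estimate_deg"].to_numpy()
    level = df["noise_level"].to_numpy()
    pos, neg = gridv > 0, gridv < 0

    for var in np.unique(exp_var):
        for lvl in np.unique(level):
            sel = (exp_var == var) & (level == lvl)
            if not sel.any():
                continue
            lvl = int(lvl)
            c = model.criterion(lvl)
            uth, inv = np.unique(theta[sel], return_inverse=True)
            if var == "known_category":
                psi_cw = np.where(uth > 0, 1.0, np.where(uth < 0, 0.0, 0.5))
            else:
                psi_cw = np.clip(model.choice_probability(uth, lvl), 1e-12, 1 - 1e-12)
            d_cw = _conditional_density_matrix(model, uth, lvl, Category.CW, var, c)
            d_ccw = _conditional_density_matrix(model, uth, lvl, Category.CCW, var, c)
            # consistent-trial joint densities on each report's half-line
            f_cw = (1 - lam) * psi_cw[:, None] * d_cw + lam * (1 - psi_cw)[:, None] * d_ccw
            f_ccw = (1 - lam) * (1 - psi_cw)[:, None] * d_ccw + lam * psi_cw[:, None] * d_cw
            logz = np.zeros(len(uth))
            if renormalize:
                z = f_cw[:, pos].sum(axis=1) * grid.step + f_ccw[:, neg].sum(axis=1) * grid.step
                logz = np.log(np.maximum(z, 1e-300))
            s = rep_sign[sel]
            x = est[sel]
            vals = np.empty(sel.sum())
            for j in range(len(uth)):
                for sign, f in ((1, f_cw), (-1, f_ccw)):
                    rmask = (inv == j) & (s == sign)
                    if rmask.any():
                        vals[rmask] = np.interp(x[rmask], gridv, f[j])
            low = vals < min_density
            floored += int(low.sum())
            vals = np.maximum(vals, min_density)
            ll += float(np.sum(np.log(vals) - logz[inv]))
    if floored:
        warnings.warn(
            f"{floored} trial(s) had predicted estimate density below the "
            f"floor {min_density}; floored",
            RuntimeWarning,
            stacklevel=2,
        )
    return ll


def extract_lapse_rate(table: TrialTable, n_starts: int = 3, seed: int = 0) -> float:
    """Lapse rate from lapse-augmented cumulative-Gaussian psychometric fits.

    One (mu, sigma) per noise level, a single shared lapse, fit by maximum
    likelihood to the reported categories of *all* trials (consistent and
    inconsistent alike).  The lapse is the report-flip probability, so the
    psychometric is lambda + (1 - 2*lambda) * Phi((theta - mu)/sigma) and
    lambda is identified on [0, 0.5] (0.5 = random responding).
    """
    df = table.df
    cells = df.groupby(["noise_level", "theta_deg"]).agg(
        n=("report_category", "size"),
        k=("report_category", lambda s: int((s == "cw").sum())),
    )
    levels = sorted(df["noise_level"].unique())
    if df["theta_deg"].nunique() < 2:
        raise ValueError("need at least 2 distinct orientations to fit a psychometric")
    th = {l: cells.loc[l].index.to_numpy(dtype=float) for l in levels}
    nn = {l: cells.loc[l]["n"].to_numpy(dtype=float) for l in levels}
    kk = {l: cells.loc[l]["k"].to_numpy(dtype=float) for l in levels}

    def nll(u):
        lam = 0.5 * expit(u[0])
        total = 0.0
        for i, l in enumerate(levels):
            mu, sig = u[1 + 2 * i], math.exp(min(max(u[2 + 2 * i], -5.0), 6.0))
            p = lam + (1.0 - 2.0 * lam) * ndtr((th[l] - mu) / sig)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            total -= float(np.sum(kk[l] * np.log(p) + (nn[l] - kk[l]) * np.log(1 - p)))
        return total

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        u0 = np.concatenate(
            [[-4.0 + 2.0 * s], np.ravel([[0.0, math.log(3.0 + 4.0 * s)] for _ in levels])]
        )
        if s > 0:
            u0[1:] += rng.normal(0, 0.3, len(u0) - 1)
        res = minimize(nll, u0, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    return float(0.5 * expit(best.x[0]))


@dataclasses.dataclass
class FitResult:
    """Outcome of a joint maximum-likelihood fit."""

    params: ObserverParams
    loglik: float
    lapse_rate: float
    n_trials: int
    n_excluded: int
    restarts: list[dict]
    ci: dict | None = None
    config: dict | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "lapse_rate": self.lapse_rate,
            "n_trials": self.n_trials,
            "n_excluded": self.n_excluded,
            "restarts": self.restarts,
            "ci": self.ci,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class ObserverMLE(BaseEstimator):
    """Maximum-likelihood observer fit as a scikit-learn style estimator.

    Parameters
    ----------
    variant : 'self_consistent' or 'independent'
        Estimation model fitted to non-Experiment-3 trials (Experiment 3
        trials always use the known-category formulation).
    sigma_0 : float
        Motor noise SD in degrees, measured externally and held fixed.
    lapse_rate : float or None
        If None, extracted from the psychometric functions of the full
        table before fitting; otherwise used as given.
    n_restarts, max_iter, fatol, xatol
        Multi-start Nelder-Mead budget.  Twenty restarts reproduce the
        published procedure; tests use fewer.  ``informed_start`` prepends
        one extra start whose sensory noise comes from probit slopes of
        the choice data (see :func:`probit_informed_start`).
    grid_step, grid_half_span : float
        Resolution/extent (degrees) of the internal fit grid.
    renormalize : bool
        Renormalize conditional estimate densities over the consistent
        half-line after motor convolution (inconsistent trials being
        excluded from the likelihood).
    random_state : int or None
        Seeds the restart initializations.

    Attributes (after ``fit``)
    --------------------------
    params_ : ObserverParams
    loglik_ : float
    lapse_rate_ : float
    restarts_ : list of per-restart diagnostics
    n_excluded_ : int
    """

    def __init__(
        self,
        variant: str = "self_consistent",
        sigma_0: float = 4.3,
        lapse_rate: float | None = None,
        n_restarts: int = 20,
        max_iter: int = 2000,
        fatol: float = 1e-3,
        xatol: float = 1e-3,
        grid_step: float = 0.4,
        grid_half_span: float = 60.0,
        renormalize: bool = True,
        min_density: float = 1e-6,
        p_cat: float = 0.5,
        informed_start: bool = True,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.sigma_0 = sigma_0
        self.lapse_rate = lapse_rate
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.informed_start = informed_start
        self.fatol = fatol
        self.xatol = xatol
        self.grid_step = grid_step
        self.grid_half_span = grid_half_span
        self.renormalize = renormalize
        self.min_density = min_density
        self.p_cat = p_cat
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    @staticmethod
    def _as_table(X) -> TrialTable:
        if isinstance(X, TrialTable):
            return X
        if isinstance(X, pd.DataFrame):
            return TrialTable(X.copy())
        raise TypeError("X must be a TrialTable or a trial DataFrame")

    def _grid(self) -> Grid:
        return Grid(self.grid_half_span, self.grid_step)

    def _params_from_x(self, x: np.ndarray, k: int) -> ObserverParams:
        v = np.exp(x)
        return ObserverParams(
            sigma_s=tuple(v[:k]),
            sigma_m=float(v[k]),
            alpha=float(v[k + 1]),
            beta=float(v[k + 2]),
            sigma_0=self.sigma_0,
            p_cat=self.p_cat,
        )

    def _objective(self, table: TrialTable, k: int, lapse: float):
        grid = self._grid()

        def fun(x):
            if np.any(np.abs(x) > 8.0):
                return 1e12
            try:
                params = self._params_from_x(x, k)
            except ValueError:
                return 1e12
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return -joint_loglikelihood(
                    table,
                    params,
                    lapse,
                    grid=grid,
                    variant=self.variant,
                    renormalize=self.renormalize,
                    min_density=self.min_density,
                )

        return fun

    def _draw_x0(self, rng: np.random.Generator, k: int) -> np.ndarray:
        lo_s, hi_s = RESTART_RANGES["sigma_s"]
        lo_m, hi_m = RESTART_RANGES["sigma_m"]
        lo_a, hi_a = RESTART_RANGES["alpha"]
        lo_b, hi_b = RESTART_RANGES["beta"]
        draws = [rng.uniform(math.log(lo_s), math.log(hi_s), k)]
        draws.append([rng.uniform(math.log(lo_m), math.log(hi_m))])
        draws.append([rng.uniform(math.log(lo_a), math.log(hi_a))])
        draws.append([rng.uniform(math.log(lo_b), math.log(hi_b))])
        return np.concatenate(draws)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None, x0_extra: np.ndarray | None = None):
        table = self._as_table(X)
        if len(table) == 0:
            raise ValueError("cannot fit an empty trial table")
        k = int(table.df["noise_level"].max()) + 1
        lapse = self.lapse_rate
        if lapse is None:
            try:
                lapse = extract_lapse_rate(table)
            except ValueError:
                lapse = 0.0
        consistent, inconsistent = classify_consistency(table)
        if len(consistent) == 0:
            raise ValueError("no consistent trials to fit")
        fun = self._objective(consistent, k, lapse)
        rng = np.random.default_rng(self.random_state)
        restarts = []
        starts = [self._draw_x0(rng, k) for _ in range(self.n_restarts)]
        if self.informed_start:
            starts = [probit_informed_start(table, k)] + starts
        if x0_extra is not None:
            starts = [np.asarray(x0_extra, dtype=float)] + starts
        for x0 in starts:
            res = minimize(
                fun,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": self.max_iter,
                    "fatol": self.fatol,
                    "xatol": self.xatol,
                    "adaptive": True,
                },
            )
            restarts.append(
                {"loglik": -float(res.fun), "x": res.x.tolist(), "converged": bool(res.success)}
            )
        if not restarts:
            raise ValueError("no restarts were run (n_restarts < 1?)")
        best = max(restarts, key=lambda r: r["loglik"])
        if not np.isfinite(best["loglik"]):
            raise RuntimeError(f"no restart converged to a finite likelihood: {restarts}")
        self.params_ = self._params_from_x(np.asarray(best["x"]), k)
        self.loglik_ = best["loglik"]
        self.lapse_rate_ = float(lapse)
        self.restarts_ = restarts
        self.n_excluded_ = len(inconsistent)
        self.n_trials_ = len(consistent)
        self.n_levels_ = k
        return self

    def loglikelihood(self, X, params: ObserverParams | None = None) -> float:
        table = self._as_table(X)
        params = params or self.params_
        consistent, _ = classify_consistency(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return joint_loglikelihood(
                consistent,
                params,
                self.lapse_rate_ if hasattr(self, "lapse_rate_") else 0.0,
                grid=self._grid(),
                variant=self.variant,
                renormalize=self.renormalize,
                min_density=self.min_density,
            )

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per consistent trial."""
        table = self._as_table(X)
        consistent, _ = classify_consistency(table)
        return self.loglikelihood(table) / max(len(consistent), 1)

    def predict(self, X) -> np.ndarray:
        """Expected reported estimate per trial given (theta, level, report)."""
        table = self._as_table(X)
        model = ObserverModel(self.params_, self._grid())
        df = table.df
        out = np.empty(len(df))
        cache: dict[tuple, float] = {}
        for i, (exp, lvl, th, repc) in enumerate(
            zip(df["experiment"], df["noise_level"], df["theta_deg"], df["report_category"])
        ):
            var = _experiment_variant(exp, self.variant)
            key = (var, int(lvl), float(th), repc)
            if key not in cache:
                dens = model.distribution(float(th), int(lvl), var)
                cat = Category.parse(repc)
                cond = dens.conditional(cat)
                if self.renormalize:
                    side = model.grid.values * cat.sign > 0
                    cond = np.where(side, cond, 0.0)
                cache[key] = model.grid.mean(cond) if cond.sum() > 0 else 0.0
            out[i] = cache[key]
        return out

    def bootstrap(
        self, X, n_boot: int = 100, n_restarts: int = 2, random_state: int | None = None
    ) -> pd.DataFrame:
        """Percentile 95% intervals from within-cell trial resampling."""
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        table = self._as_table(X)
        df = table.df
        rng = np.random.default_rng(self.random_state if random_state is None else random_state)
        point = _params_vector(self.params_)
        x_point = np.log(point)
        cells = [g.index.to_numpy() for _, g in df.groupby(["noise_level", "theta_deg"])]
        rows = []
        for _ in range(n_boot):
            idx = np.concatenate([rng.choice(c, size=len(c), replace=True) for c in cells])
            resampled = df.loc[idx].reset_index(drop=True)
            sub = ObserverMLE(**{**self.get_params(), "n_restarts": n_restarts,
                                 "lapse_rate": self.lapse_rate_,
                                 "random_state": int(rng.integers(2**31))})
            sub.fit(TrialTable(resampled), x0_extra=x_point)
            rows.append(_params_vector(sub.params_))
        boot = np.asarray(rows)
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        lo = np.minimum(lo, point)  # percentile intervals must contain the point fit
        hi = np.maximum(hi, point)
        names = _params_names(self.params_)
        ci = pd.DataFrame({"parameter": names, "point": point, "lo": lo, "hi": hi})
        self.ci_ = ci
        return ci


def _params_vector(p: ObserverParams) -> np.ndarray:
    return np.array(list(p.sigma_s) + [p.sigma_m, p.alpha, p.beta])


def _params_names(p: ObserverParams) -> list[str]:
    return [f"sigma_s[{i}]" for i in range(p.n_levels)] + ["sigma_m", "alpha", "beta"]


def fit_observer(table: TrialTable, ci: bool = False, n_boot: int = 100, **kwargs) -> FitResult:
    """Functional wrapper: fit and package a FitResult."""
    est = ObserverMLE(**kwargs)
    est.fit(table)
    intervals = None
    if ci:
        frame = est.bootstrap(table, n_boot=n_boot)
        intervals = {
            r.parameter: [float(r.lo), float(r.hi)] for r in frame.itertuples()
        }
    return FitResult(
        params=est.params_,
        loglik=est.loglik_,
        lapse_rate=est.lapse_rate_,
        n_trials=est.n_trials_,
        n_excluded=est.n_excluded_,
        restarts=est.restarts_,
        ci=intervals,
        config=est.get_params(),
    )


def bootstrap_ci(table: TrialTable, fitted: ObserverMLE, n_boot: int = 100, **kwargs):
    """Module-level convenience around :meth:`ObserverMLE.bootstrap`."""
    return fitted.bootstrap(table, n_boot=n_boot, **kwargs)
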