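"""Generalized-Bayesian fitting of the two-pathway model to incidence data.

The state-space posterior combines three sources of information: a
partially informative (box-uniform) prior, the stochastic system law of
the latent cell paths ``(X, U)``, and the Poisson observation likelihood
of the age-grouped case counts.  Fitting alternates:

1. *Data augmentation*: simulate K candidate latent paths from the system
   model at the current parameters, weight each by the observation
   likelihood of the incidence it implies, and resample (weighted
   bootstrap / SIR).
2. *Conditional parameter updates*: posterior modes of the Poisson-count
   parameters (initiation and mutation rates: events / exposure) and of
   the multinomial birth/death parameters from the selected path, each
   projected into the prior box; the last-stage transformation rates
   ``(alpha_3, beta_4)`` are updated by bounded maximization of the
   incidence likelihood.
3. *Recycling* until the estimate sequence stabilizes; posterior means of
   the retained draws are reported as the estimates.

Because the expected case counts depend on the parameters only through
the expected cell numbers, the observed-data posterior mode is directly
computable without augmentation; a seeded global bounded optimization of
that posterior (`map_fit`) initializes the recycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize, minimize_scalar

from .incidence import (
    IncidenceTable,
    age_group_probabilities,
    deviance,
    information_criteria,
    poisson_loglik,
)
from .model import (
    POLYP_STAGE_I,
    POLYP_STAGE_J,
    ModelParameters,
    make_default_params,
)

__all__ = [
    "PriorSpec",
    "GibbsConfig",
    "FitResult",
    "LatentPaths",
    "default_prior",
    "log_prior",
    "map_fit",
    "augment_latents",
    "weighted_resample",
    "conditional_update_theta1",
    "conditional_update_theta2",
    "gibbs_fit",
    "predict_incidence",
    "THETA_NAMES",
    "theta_from_params",
    "params_from_theta",
]

# The 15 free parameters of the expected-number likelihood.  Death rates of
# the proliferating stages are reference constants (the incidence surface
# identifies birth and death only through their difference for the
# constant-rate stages, and is weakly informative about the split for the
# growth-limited ones); the Gibbs multinomial updates refine them.
THETA_NAMES = (
    "lambda_I", "lambda_J",
    "alpha1", "alpha2", "alpha3",
    "beta1", "beta2", "beta3", "beta4",
    "b_I2", "delta1", "gamma_I3",
    "b_J3", "delta2", "gamma_J4",
)


@dataclass(frozen=True)
class PriorSpec:
    """Box-uniform ("partially informative") prior: constant density inside
    the open box, zero outside.  Bounds are per-model-unit rates."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bound for {name} must have lo < hi")

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.bounds[name]
        return lo < value < hi  # open intervals: boundary counts as outside

    def project(self, name: str, value: float, shrink: float = 1.0e-6) -> float:
        """Project a value into the (open) box, nudged off the boundary."""
        lo, hi = self.bounds[name]
        width = hi - lo
        return float(min(max(value, lo + shrink * width), hi - shrink * width))

    def midpoint(self, name: str) -> float:
        """Geometric midpoint (rates are scale parameters)."""
        lo, hi = self.bounds[name]
        return math.sqrt(lo * hi)


# Reference death rates of the proliferating stages (per unit), used to
# derive birth rates from net proliferation where only the difference is
# identified: d = b - gamma at the published point estimates.
_D_REF = {"d_I2": 3.8e-3, "d_I3": 3.0e-3, "d_J3": 6.8e-3, "d_J4": 6.0e-3}


def default_prior() -> PriorSpec:
    """Biologically motivated bounds for every free parameter.

    Initiation intensities, proliferation and growth-limiting bounds follow
    the published constraints; the mutation-rate brackets are one-decade
    intervals around the published magnitudes (the printed mutation bounds
    exclude the published estimates themselves and cannot be meant
    literally).
    """
    g2_box = (1.0e-4, 2.0e-2)
    return PriorSpec(bounds={
        "lambda_I": (1.0, 1000.0),
        "lambda_J": (1.0, 1000.0),
        "alpha1": (1.0e-6, 1.0e-3),
        "alpha2": (1.0e-5, 1.0e-2),
        "alpha3": (1.0e-8, 1.0e-4),
        "beta1": (1.0e-6, 1.0e-3),
        "beta2": (1.0e-5, 1.0e-2),
        "beta3": (1.0e-4, 1.0e-1),
        "beta4": (1.0e-8, 1.0e-4),
        "b_I2": (_D_REF["d_I2"] + g2_box[0], _D_REF["d_I2"] + g2_box[1]),
        "delta1": (1.0e-5, 5.0e-3),
        "gamma_I3": (1.0e-2, 0.5),
        "b_J3": (_D_REF["d_J3"] + g2_box[0], _D_REF["d_J3"] + g2_box[1]),
        "delta2": (1.0e-5, 5.0e-3),
        "gamma_J4": (1.0e-2, 0.5),
    })


def theta_from_params(params: ModelParameters) -> Dict[str, float]:
    return {
        "lambda_I": params.lambda_I,
        "lambda_J": params.lambda_J,
        "alpha1": params.alpha[0], "alpha2": params.alpha[1], "alpha3": params.alpha[2],
        "beta1": params.beta[0], "beta2": params.beta[1],
        "beta3": params.beta[2], "beta4": params.beta[3],
        "b_I2": params.b_I[POLYP_STAGE_I],
        "delta1": params.delta1,
        "gamma_I3": params.gamma_I[2],
        "b_J3": params.b_J[POLYP_STAGE_J],
        "delta2": params.delta2,
        "gamma_J4": params.gamma_J[3],
    }


def params_from_theta(theta: Dict[str, float],
                      template: Optional[ModelParameters] = None) -> ModelParameters:
    """Build a full parameter set from the 15 free parameters, taking death
    rates of the proliferating stages from the template (default: published
    point estimates)."""
    tpl = template if template is not None else make_default_params()
    d_I = tpl.d_I.copy()
    d_J = tpl.d_J.copy()
    b_I = tpl.b_I.copy()
    b_J = tpl.b_J.copy()
    b_I[POLYP_STAGE_I] = theta["b_I2"]
    b_I[2] = theta["gamma_I3"] + d_I[2]
    b_J[POLYP_STAGE_J] = theta["b_J3"]
    b_J[3] = theta["gamma_J4"] + d_J[3]
    return tpl.with_updates(
        lambda_I=theta["lambda_I"], lambda_J=theta["lambda_J"],
        alpha=np.array([theta["alpha1"], theta["alpha2"], theta["alpha3"]]),
        beta=np.array([theta["beta1"], theta["beta2"], theta["beta3"], theta["beta4"]]),
        b_I=b_I, d_I=d_I, b_J=b_J, d_J=d_J,
        delta1=theta["delta1"], delta2=theta["delta2"],
    )


def log_prior(params, prior: Optional[PriorSpec] = None) -> float:
    """0 inside the prior box (constant reference density), -inf outside."""
    prior = prior if prior is not None else default_prior()
    theta = theta_from_params(params) if isinstance(params, ModelParameters) else params
    for name, value in theta.items():
        if name in prior.bounds and not prior.contains(name, value):
            return -np.inf
    return 0.0


# ---- fast batched expected-number incidence likelihood -----------------------
#
# The chain ODE is linear with a single exp(-delta t) time dependence;
# a fixed-step RK4 vectorized over parameter draws evaluates the group
# onset integrals fast enough for global optimization.


try:  # optional acceleration: identical arithmetic either way
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=True)
def _rk4_curves_kernel(theta, need_idx, h, n_steps, dI2, dJ3,
                       out_CI, out_CJ):  # pragma: no cover - numba kernel
    S = theta.shape[1]
    for s in range(S):
        lamI, lamJ = theta[0, s], theta[1, s]
        a1, a2 = theta[2, s], theta[3, s]
        b1, b2, b3 = theta[5, s], theta[6, s], theta[7, s]
        bI2, del1, gI3 = theta[9, s], theta[10, s], theta[11, s]
        bJ3, del2, gJ4 = theta[12, s], theta[13, s], theta[14, s]
        u = np.zeros(9)      # I1 I2 I3 J1 J2 J3 J4 C_I3 C_J4
        k = np.zeros((4, 9))
        for step in range(n_steps):
            t0 = step * h
            for stage in range(4):
                if stage == 0:
                    tt = t0
                    v = u
                elif stage == 1:
                    tt = t0 + 0.5 * h
                    v = u + 0.5 * h * k[0]
                elif stage == 2:
                    tt = t0 + 0.5 * h
                    v = u + 0.5 * h * k[1]
                else:
                    tt = t0 + h
                    v = u + h * k[2]
                gI2 = bI2 * np.exp(-del1 * tt) - dI2
                gJ3v = bJ3 * np.exp(-del2 * tt) - dJ3
                k[stage, 0] = lamI
                k[stage, 1] = a1 * v[0] + gI2 * v[1]
                k[stage, 2] = a2 * v[1] + gI3 * v[2]
                k[stage, 3] = lamJ
                k[stage, 4] = b1 * v[3]
                k[stage, 5] = b2 * v[4] + gJ3v * v[5]
                k[stage, 6] = b3 * v[5] + gJ4 * v[6]
                k[stage, 7] = v[2]
                k[stage, 8] = v[6]
            for i in range(9):
                u[i] = u[i] + (h / 6.0) * (k[0, i] + 2.0 * k[1, i]
                                           + 2.0 * k[2, i] + k[3, i])
            for j in range(need_idx.shape[0]):
                if need_idx[j] == step + 1:
                    out_CI[s, j] = u[7]
                    out_CJ[s, j] = u[8]


def _expected_curves_batch(theta_mat: np.ndarray, bounds_units: np.ndarray,
                           lag: float, h: float = 0.5):
    """Cumulative last-stage integrals at the (lagged) group boundaries.

    theta_mat: (15, S) parameter draws (natural scale).
    Returns (C_I3, C_J4) of shape (S, len(bounds_units)) where
    C(t) = int_0^{max(t - lag, 0)} u_last(s) ds, from a fixed-step RK4 of
    the expected-number chain.
    """
    theta_mat = np.ascontiguousarray(theta_mat, dtype=float)
    S = theta_mat.shape[1]
    t_max = float(bounds_units[-1])
    n_steps = int(round(t_max / h))
    need = np.clip(bounds_units - lag, 0.0, None)
    need_idx = np.round(need / h).astype(np.int64)
    if not np.allclose(need_idx * h, need, atol=1.0e-9):
        raise ValueError("group boundaries minus lag must be multiples of the step h")
    out_CI = np.zeros((S, len(bounds_units)))
    out_CJ = np.zeros((S, len(bounds_units)))
    with np.errstate(over="ignore", invalid="ignore"):
        _rk4_curves_kernel(theta_mat, need_idx, h, n_steps,
                           _D_REF["d_I2"], _D_REF["d_J3"], out_CI, out_CJ)
    zero_mask = need_idx == 0
    out_CI[:, zero_mask] = 0.0
    out_CJ[:, zero_mask] = 0.0
    return out_CI, out_CJ


def _tau_from_curves(alpha3, beta4, C_I3, C_J4, n):
    """Expected cases per group from the cumulative last-stage integrals.

    alpha3/beta4 may be scalars or (S,) arrays; C_* are (S, m+1).
    Returns tau of shape (S, m).
    """
    a3 = np.atleast_1d(np.asarray(alpha3, dtype=float))[:, None]
    b4 = np.atleast_1d(np.asarray(beta4, dtype=float))[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        w1 = a3 * C_I3
        w2 = b4 * C_J4
        s1 = np.exp(-w1)
        s2 = np.exp(-w2)
        Q1 = s1[:, :-1] - s1[:, 1:]
        Q2 = s2[:, :-1] - s2[:, 1:]
        QT = Q1 + Q2 - Q1 * Q2
    return np.asarray(n, dtype=float)[None, :] * QT


def _incidence_loglik_batch(theta_mat: np.ndarray, table: IncidenceTable,
                            bounds_units: np.ndarray, lag: float,
                            h: float = 0.5, n_scale: float = 1.0) -> np.ndarray:
    C_I3, C_J4 = _expected_curves_batch(theta_mat, bounds_units, lag, h)
    tau = _tau_from_curves(theta_mat[4], theta_mat[8], C_I3, C_J4,
                           table.n * n_scale)
    y = table.y.astype(float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(tau > 0, y * np.log(np.where(tau > 0, tau, 1.0)) - tau,
                      np.where(y > 0, -np.inf, 0.0))
    out = np.sum(ll, axis=1)
    out[~np.isfinite(out)] = -np.inf
    return out


@dataclass
class MapResult:
    params: ModelParameters
    theta: Dict[str, float]
    loglik: float
    n_evaluations: int
    success: bool


def map_fit(table: IncidenceTable, prior: Optional[PriorSpec] = None,
            template: Optional[ModelParameters] = None, seed: int = 0,
            maxiter: int = 200, popsize: int = 18, tol: float = 1.0e-8,
            h: float = 0.5, n_scale: float = 1.0, n_starts: int = 1) -> MapResult:
    """Posterior mode of the 15 identifiable parameters by seeded global
    bounded optimization (differential evolution in log10 space, polished
    with L-BFGS-B) of the expected-number incidence likelihood.

    The likelihood surface carries long ridges (only products of rates
    along a pathway are well identified), so ``n_starts`` independent
    restarts with derived seeds are run and the best mode kept.
    """
    prior = prior if prior is not None else default_prior()
    tpl = template if template is not None else make_default_params()
    upy = tpl.units_per_year
    bounds_units = table.boundaries * upy
    lag = tpl.p_detect_lag
    log_bounds = [tuple(np.log10(prior.bounds[name])) for name in THETA_NAMES]
    n_eval = [0]

    def neg_ll(x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xm = x[:, None] if single else x
        theta_mat = 10.0 ** xm
        n_eval[0] += theta_mat.shape[1]
        ll = _incidence_loglik_batch(theta_mat, table, bounds_units, lag, h, n_scale)
        val = -ll
        val[~np.isfinite(val)] = 1.0e25
        return float(val[0]) if single else val

    lo = np.array([b[0] for b in log_bounds])
    hi = np.array([b[1] for b in log_bounds])

    def neg_ll_clipped(x):
        return neg_ll(np.clip(x, lo, hi))

    x_best, f_best, any_success = None, np.inf, False
    for start in range(max(n_starts, 1)):
        result = differential_evolution(
            neg_ll, log_bounds, seed=seed + 1000003 * start, maxiter=maxiter,
            popsize=popsize, tol=tol, init="sobol", vectorized=True,
            updating="deferred", polish=False,
        )
        x_s, f_s = result.x, result.fun
        # deep local polish: simplex walk along the likelihood ridges, then
        # a gradient finish
        nm = minimize(neg_ll_clipped, x_s, method="Nelder-Mead",
                      options={"maxfev": 20000, "xatol": 1e-8,
                               "fatol": 1e-10, "adaptive": True})
        if nm.fun < f_s:
            x_s, f_s = np.clip(nm.x, lo, hi), nm.fun
        lbfgs = minimize(neg_ll, x_s, method="L-BFGS-B", bounds=log_bounds,
                         options={"maxiter": 500})
        if lbfgs.fun < f_s:
            x_s, f_s = lbfgs.x, lbfgs.fun
        any_success = any_success or bool(result.success or lbfgs.success)
        if f_s < f_best:
            x_best, f_best = x_s, f_s
    theta = {name: prior.project(name, 10.0 ** xi)
             for name, xi in zip(THETA_NAMES, x_best)}
    params = params_from_theta(theta, tpl)
    return MapResult(params=params, theta=theta, loglik=-float(f_best),
                     n_evaluations=n_eval[0], success=any_success)


# ---- data augmentation (weighted bootstrap) ----------------------------------


@dataclass
class LatentPaths:
    """K candidate latent paths with the sufficient statistics of their
    transition counts, plus the SIR weights and the selected candidate."""

    K: int
    dt: float
    cohort_size: float            # persons superposed per candidate path
    t: np.ndarray                 # (m+1,)
    I2: np.ndarray                # (K, m+1) polyp-stage counts
    I3: np.ndarray
    J3: np.ndarray
    J4: np.ndarray
    B_I2: np.ndarray              # (K, m) per-step births/deaths of polyp stages
    D_I2: np.ndarray
    B_J3: np.ndarray
    D_J3: np.ndarray
    M0_I: np.ndarray              # (K,) total initiations
    M0_J: np.ndarray
    M_I: np.ndarray               # (K, 3) total stage mutations
    M_J: np.ndarray               # (K, 4)
    exp_I: np.ndarray             # (K, 3) exposures sum_t I_l(t) dt
    exp_J: np.ndarray             # (K, 4)
    B_I3: np.ndarray              # (K,) total last-stage births/deaths
    D_I3: np.ndarray
    B_J4: np.ndarray
    D_J4: np.ndarray
    log_weights: np.ndarray       # (K,)
    weights: np.ndarray           # normalized
    ess: float = 0.0
    selected: np.ndarray = field(default_factory=lambda: np.array([0]))

    def cum_last_stage(self) -> Tuple[np.ndarray, np.ndarray]:
        """Running integrals int_0^t count_last ds per candidate (left sums)."""
        cI = np.concatenate(
            [np.zeros((self.K, 1)), np.cumsum(self.I3[:, :-1] * self.dt, axis=1)], axis=1)
        cJ = np.concatenate(
            [np.zeros((self.K, 1)), np.cumsum(self.J4[:, :-1] * self.dt, axis=1)], axis=1)
        return cI, cJ


def _simulate_paths_batch(params: ModelParameters, K: int, n_steps: int,
                          rng: np.random.Generator, dt: float = 1.0,
                          cohort_size: float = 1.0) -> LatentPaths:
    """Simulate K candidate latent paths of a cohort of ``cohort_size``
    persons (superposition of independent person processes: initiation
    intensity scales with the cohort, per-cell rates do not)."""
    if cohort_size != 1.0:
        params = params.with_updates(lambda_I=params.lambda_I * cohort_size,
                                     lambda_J=params.lambda_J * cohort_size)
    nI, nJ = params.k1 - 1, params.k2 - 1
    I = np.zeros((K, nI), dtype=np.int64)
    J = np.zeros((K, nJ), dtype=np.int64)
    paths = {name: np.zeros((K, n_steps + 1), dtype=np.int64)
             for name in ("I2", "I3", "J3", "J4")}
    steps = {name: np.zeros((K, n_steps), dtype=np.int64)
             for name in ("B_I2", "D_I2", "B_J3", "D_J3")}
    M0_I = np.zeros(K, dtype=np.int64)
    M0_J = np.zeros(K, dtype=np.int64)
    M_I = np.zeros((K, nI), dtype=np.int64)
    M_J = np.zeros((K, nJ), dtype=np.int64)
    exp_I = np.zeros((K, nI))
    exp_J = np.zeros((K, nJ))
    B_I3 = np.zeros(K, dtype=np.int64)
    D_I3 = np.zeros(K, dtype=np.int64)
    B_J4 = np.zeros(K, dtype=np.int64)
    D_J4 = np.zeros(K, dtype=np.int64)

    for step in range(n_steps):
        t = step * dt
        bI = params.birth_rates_I(t)
        bJ = params.birth_rates_J(t)
        exp_I += I * dt
        exp_J += J * dt
        m0I = rng.poisson(params.lambda_I * dt, K)
        m0J = rng.poisson(params.lambda_J * dt, K)
        M0_I += m0I
        M0_J += m0J
        BI = np.zeros((K, nI), dtype=np.int64)
        DI = np.zeros((K, nI), dtype=np.int64)
        for l in range(nI):
            pb, pd_ = bI[l] * dt, params.d_I[l] * dt
            if pb > 0 or pd_ > 0:
                draw = rng.multinomial(I[:, l], [pb, pd_, 1.0 - pb - pd_])
                BI[:, l], DI[:, l] = draw[:, 0], draw[:, 1]
        BJ = np.zeros((K, nJ), dtype=np.int64)
        DJ = np.zeros((K, nJ), dtype=np.int64)
        for r in range(nJ):
            pb, pd_ = bJ[r] * dt, params.d_J[r] * dt
            if pb > 0 or pd_ > 0:
                draw = rng.multinomial(J[:, r], [pb, pd_, 1.0 - pb - pd_])
                BJ[:, r], DJ[:, r] = draw[:, 0], draw[:, 1]
        mI = rng.poisson(I * params.alpha * dt)
        mJ = rng.poisson(J * params.beta * dt)
        M_I += mI
        M_J += mJ
        I = I + BI - DI
        I[:, 0] += m0I
        I[:, 1:] += mI[:, :-1]
        J = J + BJ - DJ
        J[:, 0] += m0J
        J[:, 1:] += mJ[:, :-1]
        steps["B_I2"][:, step] = BI[:, POLYP_STAGE_I]
        steps["D_I2"][:, step] = DI[:, POLYP_STAGE_I]
        steps["B_J3"][:, step] = BJ[:, POLYP_STAGE_J]
        steps["D_J3"][:, step] = DJ[:, POLYP_STAGE_J]
        B_I3 += BI[:, -1]
        D_I3 += DI[:, -1]
        B_J4 += BJ[:, -1]
        D_J4 += DJ[:, -1]
        paths["I2"][:, step + 1] = I[:, POLYP_STAGE_I]
        paths["I3"][:, step + 1] = I[:, -1]
        paths["J3"][:, step + 1] = J[:, POLYP_STAGE_J]
        paths["J4"][:, step + 1] = J[:, -1]

    return LatentPaths(
        K=K, dt=dt, cohort_size=cohort_size, t=dt * np.arange(n_steps + 1),
        I2=paths["I2"], I3=paths["I3"], J3=paths["J3"], J4=paths["J4"],
        B_I2=steps["B_I2"], D_I2=steps["D_I2"],
        B_J3=steps["B_J3"], D_J3=steps["D_J3"],
        M0_I=M0_I, M0_J=M0_J, M_I=M_I, M_J=M_J, exp_I=exp_I, exp_J=exp_J,
        B_I3=B_I3, D_I3=D_I3, B_J4=B_J4, D_J4=D_J4,
        log_weights=np.zeros(K), weights=np.full(K, 1.0 / K),
    )


def _path_tau(latents: LatentPaths, params: ModelParameters,
              table: IncidenceTable, n_scale: float = 1.0) -> np.ndarray:
    """Expected cases per group implied by each candidate path (treated as
    cohort-representative): per-person omega_i from the realized cohort
    last-stage counts divided by the cohort size."""
    upy = params.units_per_year
    bounds_units = table.boundaries * upy
    lag = params.p_detect_lag
    cI, cJ = latents.cum_last_stage()
    idx = np.round(np.clip(bounds_units - lag, 0.0, None) / latents.dt).astype(int)
    idx = np.minimum(idx, cI.shape[1] - 1)
    return _tau_from_curves(params.alpha[-1], params.beta[-1],
                            cI[:, idx] / latents.cohort_size,
                            cJ[:, idx] / latents.cohort_size,
                            table.n * n_scale)


def augment_latents(params: ModelParameters, table: IncidenceTable, K: int,
                    rng: np.random.Generator, n_select: int = 1,
                    n_scale: float = 1.0, cohort_size: float = 1.0e5) -> LatentPaths:
    """Data-augmentation step: K candidate latent paths from the system
    model, weighted by the Poisson observation likelihood and resampled
    with replacement (weighted bootstrap).

    Paths are simulated at cohort scale (``cohort_size`` persons
    superposed) so that the early age groups, where a single person's
    last-stage counts are almost surely zero, still carry information."""
    if K < 1:
        raise ValueError("K must be >= 1")
    upy = params.units_per_year
    n_steps = int(round(table.boundaries[-1] * upy / 1.0))
    latents = _simulate_paths_batch(params, K, n_steps, rng, dt=1.0,
                                    cohort_size=cohort_size)
    tau = _path_tau(latents, params, table, n_scale)
    # Age groups whose realized cohort path carries no last-stage cell time
    # (typically the infant groups) would zero every weight; there the
    # expected-number tau stands in -- the observation layer depends on the
    # path only through the expected numbers to first order, so the
    # substitution contributes a candidate-independent factor.
    theta_mat = np.array([[theta_from_params(params)[name]]
                          for name in THETA_NAMES])
    bounds_units = table.boundaries * upy
    CI_e, CJ_e = _expected_curves_batch(theta_mat, bounds_units,
                                        params.p_detect_lag)
    tau_exp = _tau_from_curves(params.alpha[-1], params.beta[-1],
                               CI_e, CJ_e, table.n * n_scale)[0]
    tau = np.where(tau > 0, tau, tau_exp[None, :])
    y = table.y.astype(float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = np.where(tau > 0, y * np.log(np.where(tau > 0, tau, 1.0)) - tau,
                      np.where(y > 0, -np.inf, 0.0)).sum(axis=1)
    lw = np.where(np.isfinite(lw), lw, -np.inf)
    latents.log_weights = lw
    latents.selected, latents.weights = weighted_resample(lw, n_select, rng)
    latents.ess = float(1.0 / np.sum(latents.weights ** 2))
    return latents


def weighted_resample(log_weights: np.ndarray, size: int,
                      rng: np.random.Generator):
    """Weighted-bootstrap (SIR) resampling: indices drawn with replacement
    proportional to exp(log_weights).  Returns (indices, normalized weights);
    raises when every weight is zero."""
    lw = np.asarray(log_weights, dtype=float)
    finite = np.isfinite(lw)
    if not finite.any():
        raise RuntimeError(
            "all augmentation weights are zero; increase K or improve the "
            "current parameter values"
        )
    w = np.zeros_like(lw)
    w[finite] = np.exp(lw[finite] - lw[finite].max())
    w /= w.sum()
    return rng.choice(len(w), size=size, replace=True, p=w), w


# ---- conditional posterior updates -------------------------------------------


def _polyp_mode(B_t: np.ndarray, count_t: np.ndarray, dt: float,
                delta_bounds: Tuple[float, float]) -> Tuple[float, float]:
    """Mode of (b, delta) for a growth-limited stage from its per-step birth
    counts: births in step t are ~Poisson(count_t * b * exp(-delta t) * dt).
    The profile over b is closed-form; delta is maximized on its bracket."""
    t = dt * np.arange(len(B_t))
    total_B = float(B_t.sum())
    if total_B <= 0 or count_t.sum() <= 0:
        return np.nan, np.nan

    def prof_neg(log_delta: float) -> float:
        delta = math.exp(log_delta)
        expo = float(np.sum(count_t * np.exp(-delta * t)) * dt)
        if expo <= 0:
            return np.inf
        b = total_B / expo
        return -(total_B * math.log(b) - delta * float(np.sum(B_t * t)) - total_B)

    res = minimize_scalar(prof_neg, bounds=(math.log(delta_bounds[0]),
                                            math.log(delta_bounds[1])),
                          method="bounded")
    delta = math.exp(res.x)
    b = total_B / float(np.sum(count_t * np.exp(-delta * t)) * dt)
    return b, delta


def conditional_update_theta1(latents: LatentPaths, prior: PriorSpec,
                              params: ModelParameters) -> ModelParameters:
    """Posterior modes of the initiation, mutation and birth/death
    parameters given the selected latent path, projected into the prior box.

    Poisson-count parameters take the events/exposure mode; birth and
    death rates take the multinomial proportion mode; the growth-limited
    polyp stages take the profile mode of (b, delta).  Zero-exposure
    updates are skipped.
    """
    sel = latents.selected
    dt = latents.dt
    T = float(latents.t[-1] - latents.t[0])
    theta = theta_from_params(params)

    m0I = float(latents.M0_I[sel].mean())
    m0J = float(latents.M0_J[sel].mean())
    theta["lambda_I"] = prior.project("lambda_I", m0I / (T * latents.cohort_size))
    theta["lambda_J"] = prior.project("lambda_J", m0J / (T * latents.cohort_size))

    for l, name in ((0, "alpha1"), (1, "alpha2")):
        expo = float(latents.exp_I[sel, l].mean())
        if expo > 0:
            theta[name] = prior.project(name, float(latents.M_I[sel, l].mean()) / expo)
    for r, name in ((0, "beta1"), (1, "beta2"), (2, "beta3")):
        expo = float(latents.exp_J[sel, r].mean())
        if expo > 0:
            theta[name] = prior.project(name, float(latents.M_J[sel, r].mean()) / expo)

    new_d = {"d_I3": params.d_I[2], "d_J4": params.d_J[3],
             "d_I2": params.d_I[POLYP_STAGE_I], "d_J3": params.d_J[POLYP_STAGE_J]}
    # constant-rate last stages: multinomial proportion modes
    expo = float(latents.exp_I[sel, 2].mean())
    if expo > 0 and latents.B_I3[sel].mean() > 0:
        b = float(latents.B_I3[sel].mean()) / expo
        d = float(latents.D_I3[sel].mean()) / expo
        gamma = prior.project("gamma_I3", b - d)
        theta["gamma_I3"] = gamma
        new_d["d_I3"] = max(b - gamma, 0.0)
    expo = float(latents.exp_J[sel, 3].mean())
    if expo > 0 and latents.B_J4[sel].mean() > 0:
        b = float(latents.B_J4[sel].mean()) / expo
        d = float(latents.D_J4[sel].mean()) / expo
        gamma = prior.project("gamma_J4", b - d)
        theta["gamma_J4"] = gamma
        new_d["d_J4"] = max(b - gamma, 0.0)
    # growth-limited polyp stages
    expo = float(latents.exp_I[sel, POLYP_STAGE_I].mean())
    if expo > 0:
        b, delta = _polyp_mode(latents.B_I2[sel].mean(axis=0),
                               latents.I2[sel, :-1].mean(axis=0), dt,
                               prior.bounds["delta1"])
        if np.isfinite(b):
            theta["b_I2"] = prior.project("b_I2", b)
            theta["delta1"] = prior.project("delta1", delta)
        new_d["d_I2"] = float(latents.D_I2[sel].sum(axis=1).mean()) / expo
    expo = float(latents.exp_J[sel, POLYP_STAGE_J].mean())
    if expo > 0:
        b, delta = _polyp_mode(latents.B_J3[sel].mean(axis=0),
                               latents.J3[sel, :-1].mean(axis=0), dt,
                               prior.bounds["delta2"])
        if np.isfinite(b):
            theta["b_J3"] = prior.project("b_J3", b)
            theta["delta2"] = prior.project("delta2", delta)
        new_d["d_J3"] = float(latents.D_J3[sel].sum(axis=1).mean()) / expo

    template = params.with_updates(
        d_I=np.array([params.d_I[0], new_d["d_I2"], new_d["d_I3"]]),
        d_J=np.array([params.d_J[0], params.d_J[1], new_d["d_J3"], new_d["d_J4"]]),
    )
    return params_from_theta(theta, template)


def conditional_update_theta2(params: ModelParameters, table: IncidenceTable,
                              latents: LatentPaths, prior: PriorSpec,
                              n_scale: float = 1.0) -> ModelParameters:
    """Mode of the last-stage transformation rates (alpha_3, beta_4) given
    the selected latent path, by bounded 2-D maximization of the Poisson
    incidence likelihood (omega_i is linear in the rate, so the path enters
    only through its cumulative last-stage integrals)."""
    upy = params.units_per_year
    bounds_units = table.boundaries * upy
    lag = params.p_detect_lag
    cI, cJ = latents.cum_last_stage()
    idx = np.round(np.clip(bounds_units - lag, 0.0, None) / latents.dt).astype(int)
    idx = np.minimum(idx, cI.shape[1] - 1)
    CI = cI[latents.selected, :][:, idx].mean(axis=0)[None, :] / latents.cohort_size
    CJ = cJ[latents.selected, :][:, idx].mean(axis=0)[None, :] / latents.cohort_size
    y = table.y.astype(float)
    n_eff = table.n * n_scale

    def neg_ll(x):
        a3, b4 = 10.0 ** x
        tau = _tau_from_curves(a3, b4, CI, CJ, n_eff)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(tau > 0, y * np.log(np.where(tau > 0, tau, 1.0)) - tau,
                          np.where(y > 0, -np.inf, 0.0)).sum()
        return -ll if np.isfinite(ll) else 1.0e25

    bnds = [tuple(np.log10(prior.bounds["alpha3"])),
            tuple(np.log10(prior.bounds["beta4"]))]
    x0 = np.array([np.log10(params.alpha[-1]), np.log10(params.beta[-1])])
    x0 = np.clip(x0, [b[0] for b in bnds], [b[1] for b in bnds])
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bnds)
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"(alpha3, beta4) update failed to converge: {res.message}")
    a3 = prior.project("alpha3", 10.0 ** res.x[0])
    b4 = prior.project("beta4", 10.0 ** res.x[1])
    alpha = params.alpha.copy()
    beta = params.beta.copy()
    alpha[-1] = a3
    beta[-1] = b4
    return params.with_updates(alpha=alpha, beta=beta)


# ---- the multi-level Gibbs driver --------------------------------------------


@dataclass
class GibbsConfig:
    """Settings of the multi-level Gibbs fit.

    K: candidate latent paths per augmentation step.
    n_iter / burn_in: recycles per chain and discarded warm-up recycles.
    chains: independent chains with dispersed seeds.
    init: "map" (seeded global optimization of the expected-number
    posterior) or "midpoint" (geometric midpoint of the prior box).
    n_scale: at-risk adjustment factor applied to the table's n column
    (1.0 fits the printed counts).
    """

    K: int = 100
    n_iter: int = 80
    burn_in: int = 30
    chains: int = 2
    init: str = "map"
    de_maxiter: int = 150
    de_popsize: int = 18
    de_starts: int = 2
    h: float = 0.5
    n_scale: float = 1.0
    cohort_size: float = 1.0e5
    convergence_tol: float = 1.0e-3
    convergence_window: int = 5
    n_select: int = 1


@dataclass
class FitResult:
    """Posterior draws, estimates and goodness of fit of one model fit."""

    params: ModelParameters            # at the posterior means
    params_map: Optional[ModelParameters]
    draws: pd.DataFrame                # columns: chain, iteration, theta...
    summary: pd.DataFrame              # mean, sd per parameter
    dev: float
    aic: float
    bic: float
    p: int
    n_points: int
    tau: np.ndarray
    loglik: float
    ess: np.ndarray
    rhat: Optional[pd.Series]
    converged: bool
    seed: int
    config: GibbsConfig

    def predicted_table(self, table: IncidenceTable) -> IncidenceTable:
        return table.with_predicted(self.tau)


def _running_mean_stabilized(draw_mat: np.ndarray, tol: float, window: int) -> bool:
    """True when every component of the running-mean sequence changed by
    less than ``tol`` (relative) over the last ``window`` recycles."""
    n = draw_mat.shape[0]
    if n < window + 2:
        return False
    cums = np.cumsum(draw_mat, axis=0) / np.arange(1, n + 1)[:, None]
    recent = cums[-(window + 1):]
    denom = np.maximum(np.abs(recent[-1]), 1.0e-300)
    rel = np.abs(np.diff(recent, axis=0)) / denom
    return bool(np.all(rel < tol))


def gibbs_fit(table: IncidenceTable, prior: Optional[PriorSpec] = None,
              config: Optional[GibbsConfig] = None, seed: int = 0) -> FitResult:
    """Fit the two-pathway model by the multi-level Gibbs procedure.

    Runs the (optional) MAP initialization, then per chain alternates
    data augmentation, conditional Theta_1 updates and the (alpha_3,
    beta_4) maximization, retaining post-burn-in draws.  Estimates are the
    sample means of the retained draws; deviance, AIC and BIC are
    evaluated at the estimates with the stated (p, n) convention.
    """
    prior = prior if prior is not None else default_prior()
    config = config if config is not None else GibbsConfig()
    if config.burn_in >= config.n_iter:
        raise ValueError("burn_in must be < n_iter")

    template = make_default_params()
    if config.init == "map":
        map_res = map_fit(table, prior, template, seed=seed,
                          maxiter=config.de_maxiter, popsize=config.de_popsize,
                          h=config.h, n_scale=config.n_scale,
                          n_starts=config.de_starts)
        init_params = map_res.params
        params_map = map_res.params
    elif config.init == "midpoint":
        theta0 = {name: prior.midpoint(name) for name in THETA_NAMES}
        init_params = params_from_theta(theta0, template)
        params_map = None
    else:
        raise ValueError(f"unknown init strategy {config.init!r}")

    seed_seq = np.random.SeedSequence(seed)
    chain_seeds = seed_seq.spawn(config.chains)
    rows = []
    ess_hist = []
    stabilized = []
    for chain, child in enumerate(chain_seeds):
        rng = np.random.default_rng(child)
        params = init_params
        chain_draws = []
        for it in range(config.n_iter):
            latents = augment_latents(params, table, config.K, rng,
                                      n_select=config.n_select,
                                      n_scale=config.n_scale,
                                      cohort_size=config.cohort_size)
            params = conditional_update_theta1(latents, prior, params)
            params = conditional_update_theta2(params, table, latents, prior,
                                               n_scale=config.n_scale)
            theta = theta_from_params(params)
            rows.append({"chain": chain, "iteration": it, **theta})
            chain_draws.append([theta[name] for name in THETA_NAMES])
            ess_hist.append(latents.ess)
        chain_mat = np.asarray(chain_draws)[config.burn_in:]
        stabilized.append(_running_mean_stabilized(
            chain_mat, config.convergence_tol, config.convergence_window))

    draws = pd.DataFrame(rows)
    kept = draws[draws["iteration"] >= config.burn_in]
    means = kept[list(THETA_NAMES)].mean()
    sds = kept[list(THETA_NAMES)].std(ddof=1)
    summary = pd.DataFrame({"mean": means, "sd": sds})

    # every retained draw must respect the prior box
    for name in THETA_NAMES:
        lo, hi = prior.bounds[name]
        values = kept[name].to_numpy()
        if np.any(values <= lo) or np.any(values >= hi):
            raise AssertionError(f"retained draw escaped the prior box for {name}")

    rhat = None
    if config.chains >= 2 and len(kept) >= 4 * config.chains:
        try:
            import arviz as az

            n_kept = config.n_iter - config.burn_in
            rhat_vals = {}
            for name in THETA_NAMES:
                arr = kept.sort_values(["chain", "iteration"])[name].to_numpy()
                arr = arr.reshape(config.chains, n_kept)
                rhat_vals[name] = float(az.rhat(arr))
            rhat = pd.Series(rhat_vals)
        except Exception:
            rhat = None

    params_mean = params_from_theta(means.to_dict(), init_params)
    risk = age_group_probabilities(params_mean, table)
    tau = table.n * config.n_scale * risk.QT
    dev = deviance(table, tau)
    p_free = len(THETA_NAMES)
    aic, bic = information_criteria(dev, p_free, len(table))
    ll = poisson_loglik(table, tau)
    return FitResult(
        params=params_mean, params_map=params_map, draws=draws, summary=summary,
        dev=dev, aic=aic, bic=bic, p=p_free, n_points=len(table), tau=tau,
        loglik=ll, ess=np.asarray(ess_hist), rhat=rhat,
        converged=all(stabilized), seed=seed, config=config,
    )


def predict_incidence(fit: FitResult, table: IncidenceTable,
                      force: bool = False,
                      quantiles: Sequence[float] = (0.05, 0.95)) -> pd.DataFrame:
    """Predicted cases per group at the posterior-mean parameters, with a
    draw-wise predictive spread.  Refuses a non-converged fit unless
    ``force`` is set."""
    if not fit.converged and not force:
        raise RuntimeError("fit did not converge; pass force=True to predict anyway")
    params = fit.params
    upy = params.units_per_year
    bounds_units = table.boundaries * upy
    kept = fit.draws[fit.draws["iteration"] >= fit.config.burn_in]
    theta_mat = kept[list(THETA_NAMES)].to_numpy().T
    out = pd.DataFrame({
        "age_lo": table.age_lo, "age_hi": table.age_hi,
        "n": table.n, "y": table.y,
    })
    risk = age_group_probabilities(params, table)
    out["predicted"] = table.n * fit.config.n_scale * risk.QT
    if theta_mat.shape[1] >= 2:
        C_I3, C_J4 = _expected_curves_batch(theta_mat, bounds_units,
                                            params.p_detect_lag, fit.config.h)
        tau_draws = _tau_from_curves(theta_mat[4], theta_mat[8], C_I3, C_J4,
                                     table.n * fit.config.n_scale)
        for q in quantiles:
            out[f"predicted_q{int(round(100 * q))}"] = np.quantile(tau_draws, q, axis=0)
    return out
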