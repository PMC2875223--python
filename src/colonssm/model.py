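"""Parameter and state containers and expected cell numbers.

The model describes sporadic human colon carcinogenesis as two competing
multistage pathways acting on a pool of normal colon stem cells:

* the chromosomal-instability (CIN / LOH) pathway, a 4-stage chain of
  initiated cells ``I_1 -> I_2 -> I_3 -> tumor``, and
* the microsatellite-instability (MSI) pathway, a 5-stage chain
  ``J_1 -> J_2 -> J_3 -> J_4 -> tumor``.

Normal stem cells seed the first stage of each pathway at constant
intensities ``lambda_I`` and ``lambda_J`` (expected initiations per model
time unit, the product of the stem-cell pool size and the per-cell
initiation rate).  Each intermediate stage carries per-cell birth, death
and (asymmetric) mutation rates; mutation produces one daughter of the
next stage without depleting the current stage.  The polyp-forming stages
(``I_2`` and ``J_3``) have a growth-limited birth rate
``b(t) = b * exp(-delta * t)``, reflecting that adenomas only grow to a
maximum size.

One model time unit defaults to 3 calendar months; all rates are per cell
per time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "ModelParameters",
    "PopulationState",
    "ExpectedState",
    "ExpectedSeries",
    "DegenerateRatesError",
    "make_default_params",
    "stage_rates",
    "expected_numbers",
    "expected_numbers_closed_form",
    "expected_numbers_ode",
    "DEFAULT_STEM_CELLS",
]

# Stem-cell pool size used to convert the per-cell initiation rates of the
# normal compartment into the initiation intensities lambda = N * rate.
DEFAULT_STEM_CELLS = 1.0e8

# Index (0-based, within stages 1..k-1) of the polyp-forming stage whose
# birth rate is growth-limited: I_2 on the CIN pathway, J_3 on the MSI one.
POLYP_STAGE_I = 1
POLYP_STAGE_J = 2


class DegenerateRatesError(ValueError):
    """Raised when the distinct-rate closed form is requested but the net
    proliferation rates of a pathway are tied; use ``expected_numbers_ode``
    (or the confluent closed form) instead."""


@dataclass(frozen=True)
class ModelParameters:
    """All rates of the two-pathway model, per cell per model time unit.

    Arrays are indexed by stage: ``alpha[l-1]`` is the mutation rate
    ``I_l -> I_{l+1}`` for ``l = 1..k1-1``; likewise ``beta`` for the MSI
    stages.  ``b_I``/``d_I`` are birth and death rates of the ``I_l``
    cells; the net proliferation rate ``gamma = b - d`` is always derived,
    never stored.  ``delta1``/``delta2`` are the growth-limiting decay
    constants of the polyp stages ``I_2`` and ``J_3``.
    """

    lambda_I: float
    lambda_J: float
    alpha: np.ndarray
    beta: np.ndarray
    b_I: np.ndarray
    d_I: np.ndarray
    b_J: np.ndarray
    d_J: np.ndarray
    delta1: float = 0.0
    delta2: float = 0.0
    k1: int = 4
    k2: int = 5
    dt_months: float = 3.0
    p_detect_lag: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "b_I", "d_I", "b_J", "d_J"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.alpha.shape != (self.k1 - 1,):
            raise ValueError(f"alpha must have length k1-1={self.k1 - 1}")
        if self.beta.shape != (self.k2 - 1,):
            raise ValueError(f"beta must have length k2-1={self.k2 - 1}")
        for name in ("b_I", "d_I"):
            if getattr(self, name).shape != (self.k1 - 1,):
                raise ValueError(f"{name} must have length k1-1={self.k1 - 1}")
        for name in ("b_J", "d_J"):
            if getattr(self, name).shape != (self.k2 - 1,):
                raise ValueError(f"{name} must have length k2-1={self.k2 - 1}")
        if self.lambda_I < 0 or self.lambda_J < 0 or self.delta1 < 0 or self.delta2 < 0:
            raise ValueError("rates must be nonnegative")
        for name in ("alpha", "beta", "b_I", "d_I", "b_J", "d_J"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            if np.any(arr >= 1.0):
                raise ValueError(f"{name} must be < 1 per time unit")
        # multinomial validity for the unit-step transition law
        if np.any((self.b_I + self.d_I + self.alpha) > 1.0):
            raise ValueError("(b_I + d_I + alpha) must be <= 1 per time unit")
        if np.any((self.b_J + self.d_J + self.beta) > 1.0):
            raise ValueError("(b_J + d_J + beta) must be <= 1 per time unit")
        if self.dt_months <= 0:
            raise ValueError("dt_months must be positive")
        if self.p_detect_lag < 0:
            raise ValueError("p_detect_lag must be nonnegative")

    # ---- derived quantities -------------------------------------------------

    @property
    def gamma_I(self) -> np.ndarray:
        """Net proliferation rates b - d of the I stages (at t = 0)."""
        return self.b_I - self.d_I

    @property
    def gamma_J(self) -> np.ndarray:
        return self.b_J - self.d_J

    @property
    def units_per_year(self) -> float:
        return 12.0 / self.dt_months

    @property
    def is_time_homogeneous(self) -> bool:
        """True when no growth-limiting decay is active."""
        return (self.delta1 == 0.0 or self.b_I[POLYP_STAGE_I] == 0.0) and (
            self.delta2 == 0.0 or self.b_J[POLYP_STAGE_J] == 0.0
        )

    def birth_rates_I(self, t: float) -> np.ndarray:
        """Birth rates of the I stages at time t (growth-limited polyp stage)."""
        b = self.b_I.copy()
        if self.delta1 > 0.0:
            b[POLYP_STAGE_I] *= np.exp(-self.delta1 * t)
        return b

    def birth_rates_J(self, t: float) -> np.ndarray:
        b = self.b_J.copy()
        if self.delta2 > 0.0:
            b[POLYP_STAGE_J] *= np.exp(-self.delta2 * t)
        return b

    def with_updates(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Counts of initiated cells at one time point.

    The normal stem-cell pool is deterministic and folded into the
    initiation intensities, so only the staged counts are carried.
    """

    t: float
    I: np.ndarray  # counts of I_1..I_{k1-1}
    J: np.ndarray  # counts of J_1..J_{k2-1}

    def __post_init__(self):
        self.I = np.asarray(self.I, dtype=np.int64)
        self.J = np.asarray(self.J, dtype=np.int64)
        if np.any(self.I < 0) or np.any(self.J < 0):
            raise ValueError("cell counts must be nonnegative")

    @classmethod
    def zero(cls, params: ModelParameters, t: float = 0.0) -> "PopulationState":
        return cls(t=t, I=np.zeros(params.k1 - 1, dtype=np.int64),
                   J=np.zeros(params.k2 - 1, dtype=np.int64))


@dataclass
class ExpectedState:
    """Expected numbers u_I(l, t), u_J(r, t) at a single time."""

    t: float
    uI: np.ndarray
    uJ: np.ndarray


@dataclass
class ExpectedSeries:
    """Expected numbers on a time grid, plus the running integrals of the
    last-stage counts needed for the tumor-onset intensities."""

    t: np.ndarray
    uI: np.ndarray  # shape (m, k1-1)
    uJ: np.ndarray  # shape (m, k2-1)
    cum_I_last: np.ndarray  # int_0^t u_I(k1-1, s) ds
    cum_J_last: np.ndarray

    def at(self, index: int) -> ExpectedState:
        return ExpectedState(t=float(self.t[index]), uI=self.uI[index], uJ=self.uJ[index])


# ---- default parameters (published point estimates) --------------------------


def make_default_params(n_stem_cells: float = DEFAULT_STEM_CELLS) -> ModelParameters:
    """Point estimates of all rates for the two pathways.

    Mutation rates of the normal compartment (1.4e-6 for CIN, 8.3e-7 for
    MSI per cell per unit) are converted to initiation intensities with
    the stem-cell pool size ``n_stem_cells``.  Death rates are derived as
    birth minus net proliferation.
    """
    alpha0, beta0 = 1.4e-6, 8.3e-7
    alpha = np.array([2.2e-4, 3.2e-3, 1.2e-6])
    beta = np.array([3.5e-4, 1.4e-3, 9.3e-3, 7.7e-6])
    b_I = np.array([0.0, 7.4e-3, 1.9e-2])
    gamma_I = np.array([0.0, 3.6e-3, 1.6e-2])
    b_J = np.array([0.0, 0.0, 9.6e-3, 2.6e-2])
    gamma_J = np.array([0.0, 0.0, 2.8e-3, 2.0e-2])
    return ModelParameters(
        lambda_I=n_stem_cells * alpha0,
        lambda_J=n_stem_cells * beta0,
        alpha=alpha,
        beta=beta,
        b_I=b_I,
        d_I=b_I - gamma_I,
        b_J=b_J,
        d_J=b_J - gamma_J,
        delta1=8.3e-5,
        delta2=1.6e-3,
    )


def stage_rates(params: ModelParameters, t: float):
    """Per-stage (birth, death, mutation) rates at time ``t``.

    Mutation and death rates are time-constant; the birth rates of the
    polyp-forming stages decay as ``b * exp(-delta * t)``.

    Returns
    -------
    ((b_I, d_I, alpha), (b_J, d_J, beta)) arrays indexed by stage.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    return (
        (params.birth_rates_I(t), params.d_I.copy(), params.alpha.copy()),
        (params.birth_rates_J(t), params.d_J.copy(), params.beta.copy()),
    )


# ---- expected numbers ---------------------------------------------------------
#
# The expected numbers satisfy the linear chain
#     d u_1 / dt = lambda           + gamma_1(t) u_1
#     d u_l / dt = alpha_{l-1} u_{l-1} + gamma_l(t) u_l ,   l >= 2,
# with u(0) = 0 (individuals normal at birth).  Mutation is asymmetric, so
# a stage loses no cells to the next stage.


def _divided_difference_exp(nodes: np.ndarray, t: float) -> float:
    """Divided difference of x -> exp(x*t) over ``nodes`` (confluent form).

    Evaluated via the Opitz identity as the corner entry of the exponential
    of the upper-bidiagonal matrix with the nodes on the diagonal; exact
    for repeated nodes, where the divided difference becomes a derivative.
    """
    m = len(nodes)
    if m == 1:
        return float(np.exp(nodes[0] * t))
    Z = np.diag(np.asarray(nodes, dtype=float)) + np.diag(np.ones(m - 1), k=1)
    return float(expm(Z * t)[0, -1])


def _chain_closed_form(lam: float, alphas: np.ndarray, gammas: np.ndarray,
                       t: float, strict_distinct: bool = False) -> np.ndarray:
    """Expected numbers of a constant-rate mutation chain at time t.

    u_l(t) = lam * prod(alphas[:l-1]) * exp[.t]{gamma_1, ..., gamma_l, 0},
    the nested convolution of stage exponentials integrated against the
    constant immigration stream.  With ``strict_distinct`` the partial
    fraction expansion over pairwise-distinct nonzero rates is used and a
    :class:`DegenerateRatesError` is raised on ties.
    """
    k = len(gammas)
    u = np.zeros(k)
    for l in range(1, k + 1):
        nodes = np.append(gammas[:l], 0.0)
        coef = lam * float(np.prod(alphas[: l - 1])) if l > 1 else lam
        if coef == 0.0:
            u[l - 1] = 0.0
            continue
        if strict_distinct:
            scale = max(1.0e-12, float(np.max(np.abs(nodes))))
            diffs = np.abs(nodes[:, None] - nodes[None, :])
            np.fill_diagonal(diffs, np.inf)
            if diffs.min() < 1.0e-12 * scale:
                raise DegenerateRatesError(
                    "net proliferation rates are not pairwise distinct (or a "
                    "rate is zero); use expected_numbers_ode or the confluent "
                    "closed form"
                )
            terms = [
                np.exp(nu * t) / np.prod(nu - np.delete(nodes, i))
                for i, nu in enumerate(nodes)
            ]
            u[l - 1] = coef * float(np.sum(terms))
        else:
            u[l - 1] = coef * _divided_difference_exp(nodes, t)
    return u


def expected_numbers_closed_form(params: ModelParameters, t: float,
                                 strict_distinct: bool = False) -> ExpectedState:
    """Closed-form expected numbers for time-homogeneous parameters.

    Requires no growth-limiting decay (``delta1 = delta2 = 0`` or zero
    polyp birth rate).  The default (confluent) evaluation is exact for
    repeated or zero net-proliferation rates; ``strict_distinct=True``
    selects the classical partial-fraction form valid only for pairwise
    distinct nonzero rates, raising :class:`DegenerateRatesError` otherwise.
    """
    if not params.is_time_homogeneous:
        raise ValueError(
            "closed form requires time-homogeneous rates (delta1 = delta2 = 0); "
            "use expected_numbers_ode"
        )
    uI = _chain_closed_form(params.lambda_I, params.alpha, params.gamma_I, t,
                            strict_distinct)
    uJ = _chain_closed_form(params.lambda_J, params.beta, params.gamma_J, t,
                            strict_distinct)
    return ExpectedState(t=t, uI=uI, uJ=uJ)


def _expected_rhs(params: ModelParameters):
    nI, nJ = params.k1 - 1, params.k2 - 1
    alpha, beta = params.alpha, params.beta
    d_I, d_J = params.d_I, params.d_J

    def rhs(t, u):
        uI = u[:nI]
        uJ = u[nI: nI + nJ]
        gI = params.birth_rates_I(t) - d_I
        gJ = params.birth_rates_J(t) - d_J
        duI = gI * uI
        duI[0] += params.lambda_I
        duI[1:] += alpha[:-1] * uI[:-1]
        duJ = gJ * uJ
        duJ[0] += params.lambda_J
        duJ[1:] += beta[:-1] * uJ[:-1]
        return np.concatenate([duI, duJ, [uI[-1], uJ[-1]]])

    return rhs


def expected_numbers_ode(params: ModelParameters, t_grid: Sequence[float],
                         rtol: float = 1.0e-11, atol: float = 1.0e-12) -> ExpectedSeries:
    """Expected numbers by high-accuracy numeric integration.

    Handles time-varying (growth-limited) birth rates and tied
    proliferation rates; serves as the oracle for the closed form.  The
    last two integrated states carry the running integrals of the
    last-stage expected counts, from which the tumor-onset intensities
    are built.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a nonempty 1-d array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    nI, nJ = params.k1 - 1, params.k2 - 1
    t0 = 0.0
    ts = t_grid if t_grid[0] == t0 else np.concatenate([[t0], t_grid])
    sol = solve_ivp(
        _expected_rhs(params), (t0, ts[-1]), np.zeros(nI + nJ + 2),
        t_eval=ts, method="DOP853", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"expected-number integration failed: {sol.message}")
    y = sol.y if t_grid[0] == t0 else sol.y[:, 1:]
    return ExpectedSeries(
        t=t_grid,
        uI=y[:nI].T.copy(),
        uJ=y[nI: nI + nJ].T.copy(),
        cum_I_last=y[nI + nJ].copy(),
        cum_J_last=y[nI + nJ + 1].copy(),
    )


def expected_numbers(params: ModelParameters, t: float) -> ExpectedState:
    """Expected numbers at time ``t``: closed form when the parameters are
    time-homogeneous, numeric integration otherwise."""
    if params.is_time_homogeneous:
        return expected_numbers_closed_form(params, t)
    if t == 0.0:
        nI, nJ = params.k1 - 1, params.k2 - 1
        return ExpectedState(t=0.0, uI=np.zeros(nI), uJ=np.zeros(nJ))
    series = expected_numbers_ode(params, np.array([t]))
    return series.at(0)
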