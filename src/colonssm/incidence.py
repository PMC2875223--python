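"""Tumor-onset probabilities per age group and the Poisson observation model.

Detectable tumors from pathway ``i`` arise as a nonhomogeneous Poisson
process whose cumulative intensity is, to first order in the last-stage
mutation rate,

    omega_1(t) = alpha_3 * int_0^{t - lag} E[I_3(s)] ds        (CIN)
    omega_2(t) = beta_4  * int_0^{t - lag} E[J_4(s)] ds        (MSI)

with ``lag`` the detection convention: a newly created malignant cell
needs at least one model time unit to grow into a detectable tumor.  The
probability that a person normal at birth has a *first* detectable tumor
from pathway i inside age group j = (t_{j-1}, t_j] is then

    Q_i(j) = exp(-omega_i(t_{j-1})) - exp(-omega_i(t_j)),

and with the two pathways acting independently the any-pathway probability
is the inclusion-exclusion combination

    Q_T(j) = Q_1(j) + Q_2(j) - Q_1(j) Q_2(j)  ~  Q_1(j) + Q_2(j).

Observed case counts y_j given n_j persons at risk are Binomial(n_j,
Q_T(j)), in practice Poisson with mean tau_j = n_j * Q_T(j); the Poisson
deviance of a fit and the derived AIC/BIC are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import ModelParameters, expected_numbers_ode

__all__ = [
    "IncidenceTable",
    "TumorRisk",
    "cumulative_intensity",
    "age_group_probabilities",
    "expected_cases",
    "poisson_loglik",
    "deviance",
    "information_criteria",
    "time_to_tumor_density",
]


@dataclass
class IncidenceTable:
    """Age-grouped incidence: per row the age interval [age_lo, age_hi) in
    years, the number of persons at risk n and the observed cases y."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    n: np.ndarray
    y: np.ndarray
    predicted: Optional[np.ndarray] = None

    def __post_init__(self):
        self.age_lo = np.asarray(self.age_lo, dtype=float)
        self.age_hi = np.asarray(self.age_hi, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.predicted is not None:
            self.predicted = np.asarray(self.predicted, dtype=float)
        m = len(self.age_lo)
        for name in ("age_hi", "n", "y"):
            if len(getattr(self, name)) != m:
                raise ValueError("all columns must have equal length")
        if np.any(self.age_hi <= self.age_lo):
            raise ValueError("age intervals must have age_hi > age_lo")
        if np.any(self.age_lo[1:] < self.age_hi[:-1]):
            raise ValueError("age intervals must be non-overlapping and increasing")
        if np.any(self.y < 0) or np.any(self.n < 0):
            raise ValueError("n and y must be nonnegative")
        if np.any(self.y > self.n):
            raise ValueError("observed cases cannot exceed persons at risk")

    def __len__(self) -> int:
        return len(self.age_lo)

    @property
    def boundaries(self) -> np.ndarray:
        """Group boundaries in years: [t_0, t_1, ..., t_m]."""
        return np.concatenate([[self.age_lo[0]], self.age_hi])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"age_lo": self.age_lo, "age_hi": self.age_hi, "n": self.n, "y": self.y}
        )
        if self.predicted is not None:
            df["predicted"] = self.predicted
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceTable":
        missing = {"age_lo", "age_hi", "n", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"incidence table is missing columns: {sorted(missing)}")
        return cls(
            age_lo=df["age_lo"].to_numpy(),
            age_hi=df["age_hi"].to_numpy(),
            n=df["n"].to_numpy(),
            y=df["y"].to_numpy(),
            predicted=df["predicted"].to_numpy() if "predicted" in df.columns else None,
        )

    def with_predicted(self, tau: np.ndarray) -> "IncidenceTable":
        return IncidenceTable(self.age_lo, self.age_hi, self.n, self.y,
                              predicted=np.asarray(tau, dtype=float))


@dataclass
class TumorRisk:
    """Per-age-group onset probabilities and, when a table is attached,
    expected case counts tau_j = n_j * Q_T(j)."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    Q1: np.ndarray
    Q2: np.ndarray
    QT: np.ndarray
    QT_additive: np.ndarray  # the small-probability approximation Q1 + Q2
    omega_grid_t_years: np.ndarray = field(default=None)
    omega1: np.ndarray = field(default=None)
    omega2: np.ndarray = field(default=None)
    tau: Optional[np.ndarray] = None


def _omega_series(params: ModelParameters, t_max_units: float, n_sub: int = 4):
    """Cumulative onset intensities on a uniform grid of model units.

    Grid spacing is 1/n_sub of a model unit, chosen so that both the group
    boundaries (integer units) and the lagged times land on grid nodes.
    """
    lag = params.p_detect_lag
    m = int(math.ceil(t_max_units * n_sub)) + 1
    t = np.arange(m + 1) / n_sub
    series = expected_numbers_ode(params, t)
    # omega_i(t) = rate_last * C_last(t - lag), zero before the lag
    t_shift = np.clip(t - lag, 0.0, None)
    cI = np.interp(t_shift, t, series.cum_I_last)
    cJ = np.interp(t_shift, t, series.cum_J_last)
    omega1 = params.alpha[-1] * cI
    omega2 = params.beta[-1] * cJ
    return t, omega1, omega2, series


def cumulative_intensity(params: ModelParameters, t):
    """Cumulative detectable-tumor intensities (omega_1, omega_2) at model
    time(s) ``t`` (model units).  Nondecreasing in t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    t_max = float(t_arr.max()) if t_arr.max() > 0 else 1.0
    grid, om1, om2, _ = _omega_series(params, t_max)
    w1 = np.interp(t_arr, grid, om1)
    w2 = np.interp(t_arr, grid, om2)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(w1[0]), float(w2[0])
    return w1, w2


def _first_onset_probabilities(omega_bounds: np.ndarray) -> np.ndarray:
    """First-event probabilities of a nonhomogeneous Poisson process inside
    consecutive intervals, from omega at the interval boundaries."""
    surv = np.exp(-omega_bounds)
    return surv[:-1] - surv[1:]


def age_group_probabilities(params: ModelParameters, age_groups,
                            table: Optional[IncidenceTable] = None) -> TumorRisk:
    """Pathway-specific and combined first-tumor probabilities per age group.

    ``age_groups`` is a sequence of (age_lo, age_hi) pairs in years (or an
    :class:`IncidenceTable`), contiguous and increasing.
    """
    if isinstance(age_groups, IncidenceTable):
        table = age_groups if table is None else table
        age_lo, age_hi = age_groups.age_lo, age_groups.age_hi
    else:
        pairs = np.asarray(age_groups, dtype=float)
        age_lo, age_hi = pairs[:, 0], pairs[:, 1]
    if np.any(np.diff(age_lo) <= 0) or np.any(age_hi <= age_lo):
        raise ValueError("age group boundaries must be increasing")
    upy = params.units_per_year
    bounds_units = np.concatenate([[age_lo[0]], age_hi]) * upy
    grid, om1, om2, _ = _omega_series(params, float(bounds_units[-1]))
    w1 = np.interp(bounds_units, grid, om1)
    w2 = np.interp(bounds_units, grid, om2)
    Q1 = _first_onset_probabilities(w1)
    Q2 = _first_onset_probabilities(w2)
    QT = Q1 + Q2 - Q1 * Q2
    risk = TumorRisk(
        age_lo=age_lo, age_hi=age_hi, Q1=Q1, Q2=Q2, QT=QT,
        QT_additive=Q1 + Q2,
        omega_grid_t_years=grid / upy, omega1=om1, omega2=om2,
    )
    if table is not None:
        risk.tau = table.n * QT
    return risk


def expected_cases(params: ModelParameters, table: IncidenceTable) -> np.ndarray:
    """Expected case counts tau_j = n_j * Q_T(j) for each age group."""
    risk = age_group_probabilities(params, table)
    return risk.tau


def poisson_loglik(table, tau) -> float:
    """Poisson log likelihood sum_j [y_j log tau_j - tau_j - log y_j!].

    Returns -inf (flagged via a warning-free sentinel) when some tau_j = 0
    with y_j > 0.
    """
    y = table.y if isinstance(table, IncidenceTable) else np.asarray(table, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(y) == 0:
        return 0.0
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    y = np.asarray(y, dtype=float)
    if np.any((tau == 0) & (y > 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(np.where(tau > 0, tau, 1.0)), 0.0)
    from scipy.special import gammaln

    return float(np.sum(terms - tau - gammaln(y + 1.0)))


def deviance(table, tau) -> float:
    """Poisson deviance 2 sum_j [y_j log(y_j / tau_j) - (y_j - tau_j)].

    A group with y_j = 0 contributes 2 tau_j (continuity limit); tau_j = 0
    with y_j > 0 yields +inf.
    """
    y = table.y if isinstance(table, IncidenceTable) else np.asarray(table, dtype=float)
    y = np.asarray(y, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(y) == 0:
        return 0.0
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    if np.any((tau == 0) & (y > 0)):
        return np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.where(y > 0, np.log(np.where(y > 0, y, 1.0) / np.where(tau > 0, tau, 1.0)), 0.0)
    return float(2.0 * np.sum(np.where(y > 0, y * logr, 0.0) - (y - tau)))


def information_criteria(dev: float, p: int, n_points: int):
    """(AIC, BIC) from a deviance: AIC = Dev + 2p, BIC = Dev + p log(n)."""
    if p < 0:
        raise ValueError("p must be nonnegative")
    aic = dev + 2.0 * p
    bic = dev + p * (math.log(n_points) if n_points > 0 else 0.0)
    return aic, bic


def time_to_tumor_density(params: ModelParameters, age_grid_years) -> np.ndarray:
    """Density (per year) of time to first detectable tumor on an age grid.

    f(t) = exp(-omega_1(t) - omega_2(t)) * d(omega_1 + omega_2)/dt; its
    integral over the grid equals the probability of a first tumor by the
    grid end and is therefore <= 1.
    """
    ages = np.asarray(age_grid_years, dtype=float)
    upy = params.units_per_year
    t_units = ages * upy
    grid, om1, om2, series = _omega_series(params, float(t_units.max()) if len(ages) else 1.0)
    w1 = np.interp(t_units, grid, om1)
    w2 = np.interp(t_units, grid, om2)
    # d omega_i / dt = rate_last * u_last(t - lag), per model unit
    lag = params.p_detect_lag
    t_shift = np.clip(t_units - lag, 0.0, None)
    uI3 = np.interp(t_shift, series.t, series.uI[:, -1])
    uJ4 = np.interp(t_shift, series.t, series.uJ[:, -1])
    hazard_per_unit = params.alpha[-1] * uI3 + params.beta[-1] * uJ4
    return np.exp(-(w1 + w2)) * hazard_per_unit * upy
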