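"""Exact forward simulation of the two-pathway birth-death-mutation system.

Over one step (t, t + dt] the transition law is, conditionally on the
current counts:

* initiations  M0_I ~ Poisson(lambda_I dt),  M0_J ~ Poisson(lambda_J dt);
* per stage l: (B_l, D_l) ~ Multinomial(I_l; b_l(t) dt, d_l dt) births and
  deaths (each cell divides, dies, or does neither);
* per stage l: M_l ~ Poisson(I_l alpha_l dt) asymmetric mutations to the
  next stage, independent of the birth/death draws.

Counts update by the exact accounting identity
    I_l(t+dt) = I_l(t) + B_l - D_l + M_{l-1},   with M_0 := M0_I,
so trajectories conserve cells step by step and never go negative.

The RNG stream order per step is fixed (initiations I then J; multinomials
per I stage low to high, then per J stage; mutations per I stage, then per
J stage) so that a seed reproduces a trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import ModelParameters, PopulationState

__all__ = [
    "TransitionCounts",
    "Trajectory",
    "TumorOnset",
    "simulate_step",
    "simulate_trajectory",
    "simulate_tumor_onset",
    "simulate_incidence",
]


@dataclass
class TransitionCounts:
    """Augmented transition variables for one step (t, t + dt]."""

    M0_I: int
    M0_J: int
    B_I: np.ndarray
    D_I: np.ndarray
    M_I: np.ndarray
    B_J: np.ndarray
    D_J: np.ndarray
    M_J: np.ndarray

    def __post_init__(self):
        for name in ("B_I", "D_I", "M_I", "B_J", "D_J", "M_J"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))


@dataclass
class Trajectory:
    """One realization of the staged cell counts and transition counts."""

    t: np.ndarray           # times, length m+1
    I: np.ndarray            # (m+1, k1-1) counts
    J: np.ndarray            # (m+1, k2-1)
    counts: list             # m TransitionCounts
    params: ModelParameters
    seed: Optional[int] = None
    dt: float = 1.0

    def state(self, index: int) -> PopulationState:
        return PopulationState(t=float(self.t[index]), I=self.I[index], J=self.J[index])

    def to_tidy_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Tidy export: one row per (replicate, t, variable)."""
        rows = []
        for m, tm in enumerate(self.t):
            for l in range(self.I.shape[1]):
                rows.append((replicate, tm, f"I{l + 1}", self.I[m, l]))
            for r in range(self.J.shape[1]):
                rows.append((replicate, tm, f"J{r + 1}", self.J[m, r]))
        return pd.DataFrame(rows, columns=["replicate", "t", "variable", "count"])


def _check_step_validity(params: ModelParameters, t: float, dt: float):
    (bI, dI, _), (bJ, dJ, _) = (
        (params.birth_rates_I(t), params.d_I, params.alpha),
        (params.birth_rates_J(t), params.d_J, params.beta),
    )
    for label, b, d in (("I", bI, dI), ("J", bJ, dJ)):
        s = (b + d) * dt
        bad = np.nonzero(s > 1.0)[0]
        if bad.size:
            stage = bad[0] + 1
            raise ValueError(
                f"(birth + death) * dt = {s[bad[0]]:.3g} > 1 for stage "
                f"{label}_{stage}; reduce dt or the rates"
            )


def simulate_step(state: PopulationState, params: ModelParameters, dt: float,
                  rng: np.random.Generator):
    """One exact transition step; returns (new_state, TransitionCounts)."""
    t = state.t
    _check_step_validity(params, t, dt)
    bI, bJ = params.birth_rates_I(t), params.birth_rates_J(t)

    # stream order: initiations, multinomials (I low->high, then J), mutations
    m0I = int(rng.poisson(params.lambda_I * dt))
    m0J = int(rng.poisson(params.lambda_J * dt))

    nI = len(state.I)
    BI = np.zeros(nI, dtype=np.int64)
    DI = np.zeros(nI, dtype=np.int64)
    for l in range(nI):
        pb, pd_ = bI[l] * dt, params.d_I[l] * dt
        if state.I[l] > 0 and (pb > 0 or pd_ > 0):
            draw = rng.multinomial(state.I[l], [pb, pd_, 1.0 - pb - pd_])
            BI[l], DI[l] = draw[0], draw[1]
    nJ = len(state.J)
    BJ = np.zeros(nJ, dtype=np.int64)
    DJ = np.zeros(nJ, dtype=np.int64)
    for r in range(nJ):
        pb, pd_ = bJ[r] * dt, params.d_J[r] * dt
        if state.J[r] > 0 and (pb > 0 or pd_ > 0):
            draw = rng.multinomial(state.J[r], [pb, pd_, 1.0 - pb - pd_])
            BJ[r], DJ[r] = draw[0], draw[1]

    MI = rng.poisson(state.I * params.alpha * dt).astype(np.int64)
    MJ = rng.poisson(state.J * params.beta * dt).astype(np.int64)

    newI = state.I + BI - DI
    newI[0] += m0I
    newI[1:] += MI[:-1]
    newJ = state.J + BJ - DJ
    newJ[0] += m0J
    newJ[1:] += MJ[:-1]

    counts = TransitionCounts(M0_I=m0I, M0_J=m0J, B_I=BI, D_I=DI, M_I=MI,
                              B_J=BJ, D_J=DJ, M_J=MJ)
    return PopulationState(t=t + dt, I=newI, J=newJ), counts


def simulate_trajectory(params: ModelParameters, t0: float, tM: float,
                        dt: float = 1.0,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> Trajectory:
    """Simulate the staged counts from the all-zero state at ``t0`` to ``tM``."""
    if t0 >= tM:
        raise ValueError("t0 must be < tM")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = int(round((tM - t0) / dt))
    t = t0 + dt * np.arange(m + 1)
    nI, nJ = params.k1 - 1, params.k2 - 1
    I = np.zeros((m + 1, nI), dtype=np.int64)
    J = np.zeros((m + 1, nJ), dtype=np.int64)
    counts = []
    state = PopulationState.zero(params, t=t0)
    for step in range(m):
        state, c = simulate_step(state, params, dt, rng)
        I[step + 1] = state.I
        J[step + 1] = state.J
        counts.append(c)
    return Trajectory(t=t, I=I, J=J, counts=counts, params=params, seed=seed, dt=dt)


@dataclass
class TumorOnset:
    """Detectable-tumor events along one trajectory."""

    t: np.ndarray            # detection times (grid of the trajectory)
    new_T1: np.ndarray       # tumors detected per step, CIN pathway
    new_T2: np.ndarray       # tumors detected per step, MSI pathway

    @property
    def T1(self) -> np.ndarray:
        """Cumulative CIN tumor count process."""
        return np.cumsum(self.new_T1)

    @property
    def T2(self) -> np.ndarray:
        return np.cumsum(self.new_T2)

    def first_onset_time(self) -> float:
        """Time of the first detectable tumor from either pathway (inf if none)."""
        total = self.new_T1 + self.new_T2
        idx = np.nonzero(total > 0)[0]
        return float(self.t[idx[0]]) if idx.size else np.inf


def simulate_tumor_onset(traj: Trajectory, params: ModelParameters,
                         rng: Optional[np.random.Generator] = None,
                         seed: Optional[int] = None) -> TumorOnset:
    """Draw detectable-tumor events given a trajectory.

    Malignant transformations of last-stage cells in step s occur as
    Poisson(rate_last * count_last(s) * dt) and become detectable one
    ``p_detect_lag`` later (thinning on the discrete grid with intensity
    constant within a step).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dt = traj.dt
    lag_steps = int(round(params.p_detect_lag / dt))
    m = len(traj.t)
    new1 = np.zeros(m, dtype=np.int64)
    new2 = np.zeros(m, dtype=np.int64)
    # transformations originate from last-stage counts at each step start
    origin1 = rng.poisson(params.alpha[-1] * traj.I[:-1, -1] * dt)
    origin2 = rng.poisson(params.beta[-1] * traj.J[:-1, -1] * dt)
    for s in range(m - 1):
        detect = s + 1 + lag_steps - 1  # created during step s, detectable after lag
        if detect < m:
            new1[detect] += origin1[s]
            new2[detect] += origin2[s]
    return TumorOnset(t=traj.t, new_T1=new1, new_T2=new2)


def simulate_incidence(params: ModelParameters, risk_schedule, seed=None,
                       rng: Optional[np.random.Generator] = None):
    """Generate a synthetic incidence table.

    ``risk_schedule`` is an :class:`IncidenceTable` (its n column is used)
    or a sequence of ((age_lo, age_hi), n_j) pairs in years.  Cases are
    drawn independently per group as y_j ~ Binomial(n_j, Q_T(j)) with
    Q_T(j) from the expected-number onset model.
    """
    from .incidence import IncidenceTable, age_group_probabilities

    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(risk_schedule, IncidenceTable):
        groups = np.column_stack([risk_schedule.age_lo, risk_schedule.age_hi])
        n = risk_schedule.n
    else:
        groups = np.asarray([g for g, _ in risk_schedule], dtype=float)
        n = np.asarray([nj for _, nj in risk_schedule], dtype=np.int64)
    risk = age_group_probabilities(params, groups)
    if np.any(risk.QT < 0) or np.any(risk.QT > 1):
        raise ValueError("Q_T outside [0, 1]")
    y = rng.binomial(n, risk.QT)
    table = IncidenceTable(age_lo=groups[:, 0], age_hi=groups[:, 1], n=n, y=y)
    table.provenance = {"seed": seed, "params": params}
    return table
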