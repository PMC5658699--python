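"""Integration of the full antibiotic–ribosome model and recovery-time metrics.

The model (per-minute rates, arbitrary concentration units)::

    dC/dt    = k1*C/(v1 + C) - kf*C*A_in - ku*C + kb*CA
    dA_in/dt = kin*A_out - kout*A_in - kf*C*A_in + kb*CA + kr*CA'
    A_out    = prescribed by the dose profile (algebraic)
    dCA/dt   = kf*C*A_in - kb*CA - kd*CA
    dCA'/dt  = kd*CA - kr*CA'
    dN/dt    = mu0*C/(v + C) * N * (1 - N/nm)

Recovery is quantified relative to the end of treatment: at the cell level as
the first time the ribosome synthesis derivative dC/dt reaches half its
post-treatment maximum, and at the population level as the first time the
density reaches ``fold`` (default 2) times its value at treatment end.
Recovery times not reached within the simulated horizon are *censored* and
returned as ``None``, never as the horizon value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .doses import DoseProfile, total_exposure
from .params import FullModelParams, ModelState, default_initial_state

__all__ = [
    "Trajectory",
    "RecoveryResult",
    "IntegrationError",
    "simulate_full_model",
    "recovery_time_cell",
    "recovery_time_pop",
    "accumulation_closed_form",
    "analyze_recovery",
    "DEFAULT_PRE_DOSE",
]

#: Drug-free pre-equilibration phase before dosing starts (min), mirroring the
#: clean-media growth phase of the experimental protocol.
DEFAULT_PRE_DOSE = 30.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite state."""


@dataclass
class Trajectory:
    """Simulation output on a fixed time grid.

    Attributes
    ----------
    times : ndarray
        Strictly increasing absolute times (min); t = 0 is simulation start.
    c, a_in, a_out, ca, ca_prime, n : ndarray
        State components at each time point.
    dcdt, dndt : ndarray
        Right-hand-side derivatives of C and N evaluated at the stored states
        (used by the recovery-time metrics and bookkeeping checks).
    treatment_end : float
        Absolute time of the end of the final dose.
    """

    times: np.ndarray
    c: np.ndarray
    a_in: np.ndarray
    a_out: np.ndarray
    ca: np.ndarray
    ca_prime: np.ndarray
    n: np.ndarray
    dcdt: np.ndarray
    dndt: np.ndarray
    treatment_end: float
    exposure: float = 0.0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.c):
            raise ValueError("times and states must have the same length")
        if not (self.times[0] <= self.treatment_end <= self.times[-1]):
            raise ValueError("treatment_end must lie within the simulated window")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def state_at(self, t: float) -> ModelState:
        """Linearly interpolated state at absolute time ``t``."""
        comps = [np.interp(t, self.times, arr) for arr in
                 (self.c, self.a_in, self.a_out, self.ca, self.ca_prime, self.n)]
        return ModelState(*(max(0.0, x) for x in comps))

    def post_treatment_mask(self) -> np.ndarray:
        return self.times >= self.treatment_end - 1e-9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "C": self.c,
                "Ain": self.a_in,
                "Aout": self.a_out,
                "CA": self.ca,
                "CAprime": self.ca_prime,
                "N": self.n,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        treatment_end: float,
        params: FullModelParams | None = None,
    ) -> "Trajectory":
        """Rebuild a trajectory from the tidy CSV schema.

        Derivatives are recomputed from the model right-hand side when
        ``params`` is given, otherwise by central finite differences.
        """
        df = pd.read_csv(path)
        required = ["time", "C", "Ain", "Aout", "CA", "CAprime", "N"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        t = df["time"].to_numpy(float)
        arrs = {k: df[k].to_numpy(float) for k in required[1:]}
        if params is not None:
            dcdt, dndt = _derivatives(params, arrs["C"], arrs["Ain"], arrs["Aout"],
                                      arrs["CA"], arrs["N"])
        else:
            dcdt = np.gradient(arrs["C"], t)
            dndt = np.gradient(arrs["N"], t)
        return cls(
            times=t, c=arrs["C"], a_in=arrs["Ain"], a_out=arrs["Aout"],
            ca=arrs["CA"], ca_prime=arrs["CAprime"], n=arrs["N"],
            dcdt=dcdt, dndt=dndt, treatment_end=float(treatment_end),
        )


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery times from one simulation (None = censored at the horizon)."""

    rt_cell: float | None
    rt_pop: float | None
    exposure: float
    censor_horizon: float

    @property
    def cell_censored(self) -> bool:
        return self.rt_cell is None

    @property
    def pop_censored(self) -> bool:
        return self.rt_pop is None


def _derivatives(p: FullModelParams, c, a_in, a_out, ca, n):
    syn = p.k1 * c / (p.v1 + c)
    bind = p.kf * c * a_in
    dcdt = syn - bind - p.ku * c + p.kb * ca
    dndt = p.mu0 * c / (p.v + c) * n * (1.0 - n / p.nm)
    return dcdt, dndt


def _make_rhs(p: FullModelParams, aout_fn: Callable[[float], float]):
    def rhs(t: float, y: np.ndarray):
        c, a_in, ca, cap, n = y
        a_out = aout_fn(t)
        syn = p.k1 * c / (p.v1 + c)
        bind = p.kf * c * a_in
        dc = syn - bind - p.ku * c + p.kb * ca
        dain = p.kin * a_out - p.kout * a_in - bind + p.kb * ca + p.kr * cap
        dca = bind - p.kb * ca - p.kd * ca
        dcap = p.kd * ca - p.kr * cap
        dn = p.mu0 * c / (p.v + c) * n * (1.0 - n / p.nm)
        return (dc, dain, dca, dcap, dn)

    return rhs


def simulate_full_model(
    params: FullModelParams,
    dose: DoseProfile,
    init: ModelState | None = None,
    horizon: float = 2000.0,
    output_step: float = 1.0,
    pre_dose: float = DEFAULT_PRE_DOSE,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full model under a dose profile.

    The dosing clock starts at ``pre_dose`` minutes of drug-free growth (the
    pre-equilibration phase); ``horizon`` is the total simulated time from
    t = 0 and must extend beyond the end of the final dose.  The integrator is
    restarted at every dose-profile discontinuity so pulse edges are sharp.
    Tiny negative excursions (within solver tolerance) are clipped to zero.
    """
    if init is None:
        init = default_initial_state(params)
    if output_step <= 0:
        raise ValueError("output_step must be > 0")
    if pre_dose < 0:
        raise ValueError("pre_dose must be >= 0")
    t_end_dose = pre_dose + dose.treatment_end
    if horizon <= t_end_dose:
        raise ValueError(
            f"horizon ({horizon}) must exceed the end of treatment ({t_end_dose})"
        )

    def aout_fn(t: float) -> float:
        return float(dose.concentration_at(t - pre_dose))

    rhs = _make_rhs(params, aout_fn)

    grid = np.arange(0.0, horizon + 0.5 * output_step, output_step)
    grid = grid[grid <= horizon + 1e-9]
    seg_edges = sorted({0.0, horizon}
                       | {pre_dose + b for b in dose.breakpoints() if pre_dose + b < horizon})
    seg_edges = [e for e in seg_edges if 0.0 <= e <= horizon]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = np.asarray(init.as_ode_vector(), dtype=float)
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        if t1 - t0 <= 1e-12:
            continue
        in_seg = grid[(grid > t0 + 1e-12) & (grid < t1 - 1e-12)]
        t_eval = np.unique(np.concatenate(([t0], in_seg, [t1])))
        sol = solve_ivp(rhs, (t0, t1), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment [{t0:g}, {t1:g}] min: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            bad = t_eval[np.argmax(~np.isfinite(sol.y).all(axis=0))]
            raise IntegrationError(f"non-finite state at t = {bad:g} min")
        times_out.append(sol.t)
        states_out.append(sol.y)
        y = sol.y[:, -1].copy()
        y[y < 0] = 0.0

    t_all = np.concatenate(times_out)
    y_all = np.concatenate(states_out, axis=1)
    # drop duplicate segment-edge samples
    keep = np.concatenate(([True], np.diff(t_all) > 1e-12))
    t_all = t_all[keep]
    y_all = y_all[:, keep]
    y_all = np.clip(y_all, 0.0, None)

    a_out = np.array([aout_fn(t) for t in t_all])
    c, a_in, ca, cap, n = y_all
    dcdt, dndt = _derivatives(params, c, a_in, a_out, ca, n)
    return Trajectory(
        times=t_all, c=c, a_in=a_in, a_out=a_out, ca=ca, ca_prime=cap, n=n,
        dcdt=dcdt, dndt=dndt, treatment_end=t_end_dose,
        exposure=total_exposure(dose),
    )


def _first_crossing(times: np.ndarray, values: np.ndarray, threshold: float) -> float | None:
    """First time (linear interpolation) at which values >= threshold.

    Ties are broken by the earliest crossing.  Returns None if never reached.
    """
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    frac = (threshold - v0) / (v1 - v0)
    return float(t0 + frac * (t1 - t0))


def recovery_time_cell(traj: Trajectory, derivative_tol: float = 1e-12) -> float | None:
    """Cell-level recovery time: first post-treatment time at which dC/dt
    reaches half its post-treatment maximum, relative to treatment end.

    Censored (None) when the maximal post-treatment synthesis derivative is
    not positive (e.g. a flat or decaying ribosome pool).
    """
    mask = traj.post_treatment_mask()
    if mask.sum() < 2:
        raise ValueError("trajectory does not extend beyond treatment end")
    t = traj.times[mask]
    dc = traj.dcdt[mask]
    peak = float(dc.max())
    if peak <= derivative_tol:
        return None
    crossing = _first_crossing(t, dc, 0.5 * peak)
    if crossing is None:  # unreachable: the peak itself is >= half-peak
        return None
    return max(0.0, crossing - traj.treatment_end)


def recovery_time_pop(traj: Trajectory, fold: float = 2.0) -> float | None:
    """Population recovery time: first post-treatment time at which the
    density reaches ``fold`` times its value at treatment end.

    ``fold`` may be the viability-adjusted cutoff 2 - X.  Censored (None) if
    the threshold is not reached within the horizon.
    """
    if fold <= 1.0:
        raise ValueError("fold must be > 1")
    mask = traj.post_treatment_mask()
    if mask.sum() < 2:
        raise ValueError("trajectory does not extend beyond treatment end")
    n_ref = traj.state_at(traj.treatment_end).n
    if n_ref <= 0:
        raise ValueError("population density at treatment end must be > 0")
    t = traj.times[mask]
    n = traj.n[mask]
    crossing = _first_crossing(t, n, fold * n_ref)
    if crossing is None:
        return None
    return max(0.0, crossing - traj.treatment_end)


def accumulation_closed_form(
    kin: float, kout: float, aout0: float, duration: float, linear: bool = False
) -> float:
    """Intracellular antibiotic at the end of a rectangular dose, transport only.

    Neglecting target binding, influx/efflux alone give
    ``A_in(D) = (kin/kout) * A_out * (1 - exp(-kout*D))``, which for small
    ``kout*D`` reduces to the linear accumulation law ``kin * A_out * D``
    (intracellular drug proportional to total exposure).  ``linear=True`` (or
    ``kout = 0``) returns the linear form.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if kin < 0 or kout < 0:
        raise ValueError("rates must be >= 0")
    if linear or kout == 0.0:
        return kin * aout0 * duration
    return (kin / kout) * aout0 * (1.0 - math.exp(-kout * duration))


def analyze_recovery(traj: Trajectory, fold: float = 2.0) -> RecoveryResult:
    """Bundle both recovery metrics and the exposure for one trajectory."""
    return RecoveryResult(
        rt_cell=recovery_time_cell(traj),
        rt_pop=recovery_time_pop(traj, fold=fold),
        exposure=traj.exposure,
        censor_horizon=traj.horizon,
    )
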