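"""Periodic (multi-dose) treatment simulations and the T2/RT1 transition scan.

A periodic regimen is specified by the pulse concentration A, the pulse length
T1, the drug-free gap T2 and the number of pulses N_dose.  RT_n is the
population recovery time measured from the end of the final pulse; RT_1 is the
recovery time of the corresponding single pulse.  Sweeping T2 reveals a sharp
drop in RT_n once the gap exceeds the single-dose recovery time: doses spaced
more frequently than RT_1 hit cells that have not yet detoxified and compound,
doses spaced further apart act independently and RT_n collapses to RT_1.

Multi-dose regimens with long gaps let the population grow through many
doublings before the final dose, so these analyses run in the exponential
growth regime (carrying capacity far above any density reached); otherwise
the culture would saturate and the post-treatment doubling that defines RT_n
would be unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doses import DoseProfile, total_exposure
from .kinetics import recovery_time_pop, simulate_full_model, DEFAULT_PRE_DOSE
from .params import FullModelParams, ModelState

__all__ = ["PeriodicResult", "TransitionResult", "simulate_periodic", "transition_scan"]

#: Carrying capacity used in the exponential-growth regime: far above any
#: density reachable within a scan, so the logistic term is inert while the
#: solver still cannot overflow.
_EXPONENTIAL_NM = 1e280

#: Absolute inoculum density for periodic analyses (arbitrary density units).
_PERIODIC_N0 = 0.01


@dataclass(frozen=True)
class PeriodicResult:
    """Recovery times for one periodic regimen (None = censored)."""

    rt1: float | None
    rt_n: float | None
    ratio: float | None  # T2 / RT1
    exposure: float

    def __post_init__(self) -> None:
        if self.ratio is not None and self.ratio < 0:
            raise ValueError("T2/RT1 ratio must be >= 0")


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of a T2 sweep at fixed pulse parameters."""

    ratio: float | None  # transition T2 / RT1; None if no transition found
    rt1: float
    t2_grid: np.ndarray
    rt_n: np.ndarray  # NaN where censored
    jump_factor: float

    @property
    def found(self) -> bool:
        return self.ratio is not None


def _exponential_setup(
    params: FullModelParams, init: ModelState | None
) -> tuple[FullModelParams, ModelState]:
    p = params.replace(nm=_EXPONENTIAL_NM)
    if init is None:
        init = ModelState(
            c=max(1e-9, p.untreated_ribosome_level()),
            a_in=0.0, a_out=0.0, ca=0.0, ca_prime=0.0, n=_PERIODIC_N0,
        )
    return p, init


def simulate_periodic(
    params: FullModelParams,
    profile: DoseProfile,
    horizon: float | None = None,
    init: ModelState | None = None,
    output_step: float = 1.0,
    pre_dose: float = DEFAULT_PRE_DOSE,
    fold: float = 2.0,
    **solver_kw,
) -> PeriodicResult:
    """Simulate a periodic regimen and report RT_n next to its single-dose RT_1.

    By default the simulation extends well past the end of the final pulse so
    that uncensored recovery times are resolved; pass ``horizon`` (total
    simulated time) to override.  For ``n_doses = 1`` the regimen reduces to a
    single rectangular dose and RT_n equals RT_1 by construction.
    """
    if profile.shape != "periodic":
        raise ValueError("simulate_periodic requires a periodic dose profile")
    p, init = _exponential_setup(params, init)

    single = profile.single_dose()
    traj1 = simulate_full_model(
        p, single, init=init,
        horizon=pre_dose + single.treatment_end + 6000.0,
        output_step=output_step, pre_dose=pre_dose, **solver_kw,
    )
    rt1 = recovery_time_pop(traj1, fold=fold)

    if profile.n_doses == 1:
        rt_n = rt1
    else:
        if horizon is None:
            base = 6000.0 if rt1 is None else max(600.0, 3.0 * rt1 * profile.n_doses)
            horizon = pre_dose + profile.treatment_end + base
        traj_n = simulate_full_model(
            p, profile, init=init, horizon=horizon,
            output_step=output_step, pre_dose=pre_dose, **solver_kw,
        )
        rt_n = recovery_time_pop(traj_n, fold=fold)

    ratio = None if rt1 is None or rt1 <= 0 else profile.interval / rt1
    return PeriodicResult(rt1=rt1, rt_n=rt_n, ratio=ratio, exposure=total_exposure(profile))


def transition_scan(
    params: FullModelParams,
    a0: float,
    t1: float,
    n_doses: int = 5,
    t2_grid: np.ndarray | None = None,
    n_grid: int = 13,
    span: tuple[float, float] = (0.2, 5.0),
    jump_factor: float = 2.0,
    output_step: float = 2.0,
    pre_dose: float = DEFAULT_PRE_DOSE,
    fold: float = 2.0,
    **solver_kw,
) -> TransitionResult:
    """Locate the sharp transition in multi-dose outcome as T2 is swept.

    RT_n is computed over a T2 grid (by default ``n_grid`` logarithmically
    spaced points spanning ``span`` times RT_1).  The transition is located at
    the largest drop in RT_n between adjacent grid points (reported as the
    interval midpoint divided by RT_1) and is only accepted when the overall
    response is genuinely bimodal: the largest finite RT_n must exceed the
    smallest by more than ``jump_factor``, otherwise the scan reports "no
    transition" (``ratio = None``).  Censored points are excluded pairwise.
    """
    p, init = _exponential_setup(params, None)
    single = DoseProfile(shape="rectangular", a0=a0, duration=t1)
    traj1 = simulate_full_model(
        p, single, init=init,
        horizon=pre_dose + t1 + 6000.0,
        output_step=output_step, pre_dose=pre_dose, **solver_kw,
    )
    rt1 = recovery_time_pop(traj1, fold=fold)
    if rt1 is None or rt1 <= 0:
        raise ValueError("single-dose recovery time is censored or zero; "
                         "choose a dose with a finite RT_1")

    if t2_grid is None:
        t2_grid = rt1 * np.geomspace(span[0], span[1], n_grid)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if t2_grid.size < 2:
        raise ValueError("t2_grid must contain at least two points")

    rt_n = np.full(t2_grid.size, np.nan)
    for i, t2 in enumerate(t2_grid):
        profile = DoseProfile(shape="periodic", a0=a0, duration=t1,
                              interval=float(t2), n_doses=n_doses)
        post_n = max(600.0, 3.0 * rt1 * n_doses)
        traj = simulate_full_model(
            p, profile, init=init,
            horizon=pre_dose + profile.treatment_end + post_n,
            output_step=output_step, pre_dose=pre_dose, **solver_kw,
        )
        rt = recovery_time_pop(traj, fold=fold)
        rt_n[i] = np.nan if rt is None else rt

    finite = np.isfinite(rt_n)
    ratio: float | None = None
    if finite.sum() >= 2 and np.nanmax(rt_n) > jump_factor * np.nanmin(rt_n):
        best_drop = 0.0
        for i in range(t2_grid.size - 1):
            if not (finite[i] and finite[i + 1]):
                continue
            drop = rt_n[i] - rt_n[i + 1]
            if drop > best_drop:
                best_drop = drop
                ratio = float(0.5 * (t2_grid[i] + t2_grid[i + 1]) / rt1)
    return TransitionResult(ratio=ratio, rt1=float(rt1), t2_grid=t2_grid,
                            rt_n=rt_n, jump_factor=jump_factor)
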