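"""In-silico experiment orchestration: exposure collapse, parameter
perturbations, cell–population recovery correlation, and the motif panel.

Each runner sweeps dose conditions through the kinetic model, collects
recovery times in a tidy table, and summarizes the result (exponential
collapse fit, paired perturbation rows, squared Pearson correlation, or
per-motif efflux sensitivities).  Censored recovery times are flagged and
excluded from fits, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doses import DoseProfile, total_exposure
from .kinetics import analyze_recovery, simulate_full_model, DEFAULT_PRE_DOSE
from .motifs import (
    MOTIF_KINDS,
    MotifParams,
    efflux_sensitivity,
    make_motif,
    recovery_time_motif,
    simulate_motif,
)
from .params import FullModelParams

__all__ = [
    "SweepResult",
    "PerturbationResult",
    "CorrelationResult",
    "MotifPanelResult",
    "run_exposure_collapse",
    "run_perturbation_experiment",
    "run_cell_pop_correlation",
    "run_motif_panel",
    "DEFAULT_CONC_GRID",
    "DEFAULT_DURATION_GRID",
]

logger = logging.getLogger("paedyn")

#: Default sweep grids mirroring the experimental design: streptomycin-like
#: concentrations 2-12 µg/ml and treatment durations 30-120 min.
DEFAULT_CONC_GRID = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
DEFAULT_DURATION_GRID = (30.0, 60.0, 90.0, 120.0)


@dataclass
class SweepResult:
    """Rows of one dose sweep plus the exponential-collapse fit.

    ``fit`` holds intercept and slope of the regression of ln RT_pop on total
    exposure and its R²; R² is NaN when the regression is degenerate (fewer
    than two uncensored exposures).
    """

    rows: pd.DataFrame
    fit: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValueError("sweep produced no rows")
        r2 = self.fit.get("r_squared")
        if r2 is not None and np.isfinite(r2) and not 0.0 <= r2 <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class PerturbationResult:
    """Two sweeps differing only in one named parameter, matched by exposure."""

    parameter: str
    low: float
    high: float
    rows: pd.DataFrame  # columns: shape, a0, duration, exposure, rt_pop_low, rt_pop_high, ...


@dataclass
class CorrelationResult:
    """Paired (RT_cell, RT_pop) values and their squared Pearson correlation."""

    pairs: pd.DataFrame
    r_squared: float


@dataclass
class MotifPanelResult:
    """Per-motif recovery times at two efflux rates plus sensitivities."""

    rows: pd.DataFrame  # columns: motif, a0, duration, exposure, kout, rt, censored
    sensitivity: dict[str, float]


def _sweep_rows(
    params: FullModelParams,
    conc_grid: Sequence[float],
    duration_grid: Sequence[float],
    shapes: Sequence[str],
    fold: float,
    output_step: float,
    post_window: float,
    pre_dose: float,
) -> pd.DataFrame:
    records = []
    for shape in shapes:
        for a0 in conc_grid:
            for d in duration_grid:
                dose = DoseProfile(shape=shape, a0=float(a0), duration=float(d))
                traj = simulate_full_model(
                    params, dose,
                    horizon=pre_dose + dose.treatment_end + post_window,
                    output_step=output_step, pre_dose=pre_dose,
                )
                res = analyze_recovery(traj, fold=fold)
                censored = res.pop_censored or res.cell_censored
                logger.info(
                    "sweep shape=%s a0=%g D=%g exposure=%g rt_pop=%s rt_cell=%s censored=%s",
                    shape, a0, d, res.exposure, res.rt_pop, res.rt_cell, censored,
                )
                records.append({
                    "shape": shape, "a0": a0, "duration": d,
                    "t2": 0.0, "n_doses": 1,
                    "exposure": res.exposure,
                    "rt_pop": np.nan if res.rt_pop is None else res.rt_pop,
                    "rt_cell": np.nan if res.rt_cell is None else res.rt_cell,
                    "censored": censored,
                })
    return pd.DataFrame.from_records(records)


def _collapse_fit(rows: pd.DataFrame) -> dict[str, float]:
    ok = rows["rt_pop"].notna() & (rows["rt_pop"] > 0)
    x = rows.loc[ok, "exposure"].to_numpy(float)
    y = np.log(rows.loc[ok, "rt_pop"].to_numpy(float))
    if np.unique(x).size < 2:
        return {"intercept": np.nan, "slope": np.nan, "r_squared": np.nan,
                "n_points": int(ok.sum())}
    res = stats.linregress(x, y)
    return {"intercept": float(res.intercept), "slope": float(res.slope),
            "r_squared": float(res.rvalue**2), "n_points": int(ok.sum())}


def run_exposure_collapse(
    params: FullModelParams,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID,
    duration_grid: Sequence[float] = DEFAULT_DURATION_GRID,
    shapes: Sequence[str] = ("rectangular",),
    fold: float = 2.0,
    output_step: float = 1.0,
    post_window: float = 2000.0,
    pre_dose: float = DEFAULT_PRE_DOSE,
) -> SweepResult:
    """Sweep concentration × duration (× shape) and fit the exposure collapse.

    Regresses ln RT_pop on total exposure over the uncensored rows; all rows
    censored is an error.
    """
    if len(conc_grid) == 0 or len(duration_grid) == 0:
        raise ValueError("grids must be nonempty")
    rows = _sweep_rows(params, conc_grid, duration_grid, shapes, fold,
                       output_step, post_window, pre_dose)
    if rows["rt_pop"].isna().all():
        raise ValueError("all recovery times censored; extend the horizon "
                         "or reduce the doses")
    return SweepResult(rows=rows, fit=_collapse_fit(rows))


def run_perturbation_experiment(
    params: FullModelParams,
    perturbation: str,
    low: float,
    high: float,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID,
    duration_grid: Sequence[float] = DEFAULT_DURATION_GRID,
    **sweep_kw,
) -> PerturbationResult:
    """Paired sweeps differing only in one rate constant (kd, kout or k1 in
    the perturbation analysis), keyed by total exposure."""
    if perturbation not in params.to_dict():
        raise ValueError(f"unknown parameter {perturbation!r}")
    if low == high:
        raise ValueError("low and high values must differ")
    sweeps = {}
    for label, value in (("low", low), ("high", high)):
        sweep = run_exposure_collapse(
            params.replace(**{perturbation: value}),
            conc_grid, duration_grid, **sweep_kw,
        )
        sweeps[label] = sweep.rows
    keys = ["shape", "a0", "duration", "exposure"]
    merged = sweeps["low"][keys + ["rt_pop", "rt_cell", "censored"]].merge(
        sweeps["high"][keys + ["rt_pop", "rt_cell", "censored"]],
        on=keys, suffixes=("_low", "_high"),
    )
    return PerturbationResult(parameter=perturbation, low=low, high=high, rows=merged)


def run_cell_pop_correlation(
    params: FullModelParams,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID,
    duration_grid: Sequence[float] = DEFAULT_DURATION_GRID,
    sweep: SweepResult | None = None,
    **sweep_kw,
) -> CorrelationResult:
    """Squared Pearson correlation between RT_cell and RT_pop over a sweep.

    An existing ``sweep`` (with rt_cell and rt_pop columns) can be reused to
    avoid re-simulating.  Requires at least five uncensored pairs.
    """
    if sweep is None:
        sweep = run_exposure_collapse(params, conc_grid, duration_grid, **sweep_kw)
    rows = sweep.rows
    ok = rows["rt_pop"].notna() & rows["rt_cell"].notna()
    pairs = rows.loc[ok, ["exposure", "rt_cell", "rt_pop"]].reset_index(drop=True)
    if len(pairs) < 5:
        raise ValueError(f"only {len(pairs)} uncensored pairs; need >= 5")
    r = stats.pearsonr(pairs["rt_cell"], pairs["rt_pop"]).statistic
    return CorrelationResult(pairs=pairs, r_squared=float(r**2))


def run_motif_panel(
    base: MotifParams,
    exposure_grid: Sequence[float] | None = None,
    kout_pair: tuple[float, float] = (0.01, 0.001),
    duration: float = 60.0,
    horizon: float = 12000.0,
    output_step: float = 1.0,
) -> MotifPanelResult:
    """Recovery times for the three motifs at two efflux rates, with the
    efflux-inhibition sensitivity of each motif."""
    if exposure_grid is None:
        exposure_grid = (120.0, 240.0, 360.0, 480.0, 600.0)
    kout_high, kout_low = max(kout_pair), min(kout_pair)
    records = []
    sens: dict[str, float] = {}
    for kind in MOTIF_KINDS:
        mparams = make_motif(kind, base)
        for kout in (kout_high, kout_low):
            pk = mparams.replace(kout=kout)
            for e in exposure_grid:
                dose = DoseProfile(shape="rectangular", a0=float(e) / duration,
                                   duration=duration)
                traj = simulate_motif(pk, dose, horizon=horizon,
                                      output_step=output_step)
                rt = recovery_time_motif(traj)
                logger.info("motif=%s kout=%g exposure=%g rt=%s", kind, kout, e, rt)
                records.append({
                    "motif": kind, "a0": dose.a0, "duration": duration,
                    "exposure": e, "kout": kout,
                    "rt": np.nan if rt is None else rt,
                    "censored": rt is None,
                })
        sens[kind] = efflux_sensitivity(
            mparams, exposure_grid, kout_high=kout_high, kout_low=kout_low,
            duration=duration, horizon=horizon, output_step=output_step,
        )
    return MotifPanelResult(rows=pd.DataFrame.from_records(records), sensitivity=sens)
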