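"""Seeded synthetic datasets with the statistical structure of the assays.

Generators emulate (i) normalized population-fluorescence recovery traces
under transient dosing, including the contribution of dead-but-fluorescent
cells, (ii) Hill-shaped growth-rate dose responses, (iii) EtBr accumulation
curves of the efflux assay, and (iv) Poisson-sampled CFU viability decay
curves.  Noise is multiplicative lognormal (signals are positive and scatter
grows with the mean); every generator is a pure function of its parameters
and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import DoseResponseData, EffluxAssayData
from .doses import DoseProfile
from .kinetics import simulate_full_model, DEFAULT_PRE_DOSE
from .params import FullModelParams

__all__ = [
    "NoiseSpec",
    "default_kill_rate",
    "gen_fluorescence_experiment",
    "gen_dose_response",
    "gen_etbr_curves",
    "gen_viability_curves",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-scatter specification for the generators.

    cv is the coefficient of variation of multiplicative lognormal noise
    (default 5%, matching typical replicate scatter of plate/microfluidic
    time courses); the lognormal is mean-1 so noise does not bias the signal.
    """

    cv: float = 0.05
    seed: int = 0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.cv == 0:
            return np.ones(size)
        sigma2 = math.log(1.0 + self.cv**2)
        return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


def default_kill_rate(a0: float, slope: float = 5e-4, threshold: float = 2.0) -> float:
    """Stand-in kill-rate curve lambda(A0) (1/min): linear above a no-kill
    threshold (~IC50).  Only the qualitative increasing shape is emulated."""
    return max(0.0, a0 - threshold) * slope


def gen_fluorescence_experiment(
    params: FullModelParams,
    doses: Sequence[DoseProfile],
    noise: NoiseSpec,
    viability_lambda: Callable[[float], float] | Mapping[float, float] | None = None,
    f0: float = 1.0,
    output_step: float = 5.0,
    post_window: float = 600.0,
    pre_dose: float = DEFAULT_PRE_DOSE,
) -> pd.DataFrame:
    """Normalized population-fluorescence recovery traces for a set of doses.

    For each dose the full model is simulated; a killed fraction
    ``X = 1 - exp(-lambda(A0) * D)`` contributes constant fluorescence while
    the viable fraction follows the simulated density, so the noise-free
    normalized signal is ``X + (1 - X) * N(t)/N(D)``.  Lognormal noise is
    applied per replicate and time point, and each trace is re-normalized to
    its value at treatment end (time 0 of the output clock).

    Returns tidy rows (condition, replicate, time, signal) with time measured
    from the end of treatment in minutes.
    """
    if viability_lambda is None:
        lam_of = default_kill_rate
    elif isinstance(viability_lambda, Mapping):
        lam_of = lambda a0: float(viability_lambda.get(a0, 0.0))  # noqa: E731
    else:
        lam_of = viability_lambda
    rng = noise.rng()
    rows = []
    for dose in doses:
        traj = simulate_full_model(
            params, dose,
            horizon=pre_dose + dose.treatment_end + post_window,
            output_step=output_step, pre_dose=pre_dose,
        )
        mask = traj.post_treatment_mask()
        t = traj.times[mask] - traj.treatment_end
        n = traj.n[mask]
        n_end = n[0]
        lam = lam_of(dose.a0)
        x = 1.0 - math.exp(-lam * dose.treatment_end)
        clean = (x + (1.0 - x) * n / n_end) * f0
        condition = f"{dose.shape}_A0={dose.a0:g}_D={dose.treatment_end:g}"
        for rep in range(noise.replicates):
            noisy = clean * noise.draw(rng, clean.shape)
            noisy = noisy / noisy[0]
            rows.append(pd.DataFrame({
                "condition": condition,
                "replicate": rep,
                "time": t,
                "signal": noisy,
            }))
    return pd.concat(rows, ignore_index=True)


def gen_dose_response(
    mu_max: float,
    ic50: float,
    n: float,
    conc_grid: Sequence[float],
    noise: NoiseSpec,
) -> DoseResponseData:
    """Hill dose–response growth rates with replicate-averaged lognormal noise.

    Each concentration appears ``noise.replicates`` times in the output (one
    noisy draw per replicate), matching the layout of a plate-reader gradient.
    """
    conc = np.asarray(list(conc_grid), dtype=float)
    rng = noise.rng()
    concs, mus = [], []
    for a in conc:
        mu = mu_max * ic50**n / (ic50**n + a**n)
        draws = mu * noise.draw(rng, noise.replicates)
        concs.extend([a] * noise.replicates)
        mus.extend(draws.tolist())
    return DoseResponseData(np.asarray(concs), np.asarray(mus))


def gen_etbr_curves(
    kin: float,
    kout_grid: Sequence[float],
    etotal: float,
    noise: NoiseSpec,
    times: Sequence[float] | None = None,
    ein0: float = 0.0,
    cccp_saturating: float = 25.0,
) -> list[EffluxAssayData]:
    """EtBr accumulation curves for a ladder of efflux rates.

    ``kout = 0`` stands for the saturating-CCCP condition (efflux fully
    inhibited) and is labelled with ``cccp_saturating`` µg/ml; other rates are
    labelled 0 µg/ml.  One curve per kout, each with lognormal noise on the
    positive part of the signal.
    """
    if times is None:
        times = np.arange(0.0, 301.0, 10.0)
    t = np.asarray(list(times), dtype=float)
    rng = noise.rng()
    curves = []
    for kout in kout_grid:
        r = kin + kout
        asym = etotal if r == 0 else kin / r * etotal
        clean = asym + (ein0 - asym) * np.exp(-r * t)
        noisy = np.clip(clean * noise.draw(rng, t.shape), 0.0, None)
        curves.append(EffluxAssayData(
            times=t, ein_norm=noisy,
            cccp_conc=cccp_saturating if kout == 0 else 0.0,
        ))
    return curves


def gen_viability_curves(
    lambda_grid: Mapping[float, float],
    duration_grid: Sequence[float],
    n_reps: int = 6,
    seed: int = 0,
    n0: float = 500.0,
) -> pd.DataFrame:
    """Poisson-sampled CFU decay curves, one per antibiotic concentration.

    ``lambda_grid`` maps antibiotic concentration to its kill rate (1/min);
    counts at each sampling time are Poisson around ``n0 * exp(-lambda t)``.
    Returns tidy rows (time, cfu, concentration, replicate).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(list(duration_grid), dtype=float)
    rows = []
    for conc, lam in lambda_grid.items():
        if lam < 0:
            raise ValueError("kill rates must be >= 0")
        mean = n0 * np.exp(-lam * t)
        for rep in range(n_reps):
            counts = rng.poisson(mean)
            rows.append(pd.DataFrame({
                "time": t,
                "cfu": counts,
                "concentration": conc,
                "replicate": rep,
            }))
    return pd.concat(rows, ignore_index=True)
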