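"""Data-reduction procedures for plate-reader and CFU assays.

Implements growth-rate extraction from OD time courses, the Hill dose–response
fit ``mu(A) = mu_max * IC50^n / (IC50^n + A^n)``, the two-compartment ethidium
bromide (EtBr) accumulation fit used to estimate membrane influx/efflux rates,
the exponential CFU viability-decay fit, the viability-adjusted doubling
cutoff (2 - X), and twofold-crossing recovery-time extraction from normalized
signal traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseData",
    "HillFit",
    "EffluxAssayData",
    "EffluxFit",
    "FitError",
    "growth_rate_from_timeseries",
    "fit_hill_ic50",
    "fit_efflux_rates",
    "viability_adjusted_cutoff",
    "viability_from_cfu",
    "recovery_time_from_signal",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or yields invalid rates."""


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class DoseResponseData:
    """Per-condition growth rates (1/min) versus antibiotic concentration (µg/ml)."""

    concentrations: np.ndarray
    growth_rates: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        mu = np.asarray(self.growth_rates, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "growth_rates", mu)
        if conc.shape != mu.shape:
            raise ValueError("concentrations and growth_rates must have equal length")
        if (conc < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not np.isclose(conc, 0.0).any():
            raise ValueError("dose–response data must include the untreated (0) condition")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"concentration": self.concentrations,
                             "growth_rate": self.growth_rates})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseData":
        return cls(df["concentration"].to_numpy(float), df["growth_rate"].to_numpy(float))


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill dose–response parameters."""

    mu_max: float  # maximal growth rate (1/min)
    ic50: float  # half-maximal inhibitory concentration (µg/ml)
    n: float  # Hill coefficient
    goodness: float  # root-mean-square residual (1/min)

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        a = np.asarray(conc, dtype=float)
        return self.mu_max * self.ic50 ** self.n / (self.ic50 ** self.n + a ** self.n)


@dataclass(frozen=True)
class EffluxAssayData:
    """OD-normalized intracellular EtBr signal time course (a.u.)."""

    times: np.ndarray  # minutes
    ein_norm: np.ndarray
    cccp_conc: float = 0.0  # efflux-inhibitor concentration (µg/ml)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.ein_norm, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ein_norm", s)
        if t.shape != s.shape:
            raise ValueError("times and ein_norm must have equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (s < 0).any():
            raise ValueError("signals must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "signal": self.ein_norm,
                             "cccp": self.cccp_conc})


@dataclass(frozen=True)
class EffluxFit:
    """Fitted EtBr transport rates (1/min) and total EtBr pool (a.u.)."""

    kin: float
    kout: float
    etotal: float
    goodness: float


# -------------------------------------------------------------- growth rates
def growth_rate_from_timeseries(
    times: Sequence[float],
    densities: Sequence[float],
    min_window: int = 5,
) -> float:
    """Exponential growth rate (1/min) from an OD/density time course.

    Fits log-density against time over every contiguous window of at least
    ``min_window`` points and returns the slope of the best window: highest
    R² among windows with positive slope, ties broken toward longer then
    earlier windows (the iteratively located linear region of increase).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(densities, dtype=float)
    if t.size != d.size:
        raise ValueError("times and densities must have equal length")
    if t.size < min_window + 1:
        raise ValueError(f"need at least {min_window + 1} points")
    if (d <= 0).any():
        raise ValueError("densities must be > 0 (log fit)")
    logd = np.log(d)

    best: tuple[float, int, float] | None = None  # (r2, length, -start) ordering key
    best_slope = None
    n = t.size
    for i in range(n - min_window + 1):
        for j in range(i + min_window, n + 1):
            tw, yw = t[i:j], logd[i:j]
            slope, intercept = np.polyfit(tw, yw, 1)
            if slope <= 0:
                continue
            resid = yw - (slope * tw + intercept)
            ss_tot = float(np.sum((yw - yw.mean()) ** 2))
            r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
            key = (round(r2, 12), j - i, -i)
            if best is None or key > best:
                best = key
                best_slope = float(slope)
    if best_slope is None:
        raise FitError("no window with positive growth; series is not increasing")
    return best_slope


# ------------------------------------------------------------------ Hill fit
def fit_hill_ic50(data: DoseResponseData) -> HillFit:
    """Nonlinear least-squares Hill fit of growth rate versus concentration.

    Initialization follows the assay convention: mu_max from the untreated
    condition, IC50 from the concentration whose growth rate is nearest half
    the untreated rate, and n = 1.  Unweighted residuals.
    """
    conc = data.concentrations
    mu = data.growth_rates
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations (including 0)")

    mu0 = float(np.mean(mu[np.isclose(conc, 0.0)]))
    nonzero = conc > 0
    ic50_init = float(conc[nonzero][np.argmin(np.abs(mu[nonzero] - 0.5 * mu0))])
    if ic50_init <= 0:
        ic50_init = float(np.median(conc[nonzero]))

    model = lmfit.Model(
        lambda a, mu_max, ic50, n: mu_max * ic50**n / (ic50**n + a**n),
        independent_vars=["a"],
    )
    p = model.make_params(
        mu_max=dict(value=max(mu0, 1e-12), min=1e-12),
        ic50=dict(value=ic50_init, min=1e-9),
        n=dict(value=1.0, min=1e-3, max=20.0),
    )
    result = model.fit(mu, p, a=conc)
    if not result.success:
        raise FitError(
            f"Hill fit did not converge (init mu_max={mu0:g}, ic50={ic50_init:g}, n=1); "
            f"residual norm {np.linalg.norm(result.residual):g}"
        )
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return HillFit(
        mu_max=float(result.params["mu_max"].value),
        ic50=float(result.params["ic50"].value),
        n=float(result.params["n"].value),
        goodness=rms,
    )


# --------------------------------------------------------------- EtBr efflux
def _etbr_model(t, kin, kout, etotal, ein0):
    r = kin + kout
    asym = np.where(r > 0, kin / np.maximum(r, 1e-300) * etotal, etotal)
    return asym + (ein0 - asym) * np.exp(-r * t)


def fit_efflux_rates(
    data: EffluxAssayData,
    reference_kin: float | None = None,
    etotal: float | None = None,
    assume_no_efflux: bool = False,
) -> EffluxFit:
    """Fit the two-compartment EtBr accumulation model to one time course.

    The model ``E_in(t) = a*E_tot + (E_in(0) - a*E_tot)*exp(-(kin+kout)*t)``
    with ``a = kin/(kin+kout)`` exposes only an asymptote and a rate, so one
    of three constraints must pin the third degree of freedom:

    * ``assume_no_efflux=True`` — kout fixed to 0 (the saturating-CCCP
      reference condition); kin and E_total are then identifiable.
    * ``reference_kin`` — kin fixed to the value from such a reference curve;
      kout and E_total float.
    * ``etotal`` — the total EtBr pool fixed to its known assay value; kin and
      kout float.

    E_in(0) is pinned to the first sample.  Raises ``FitError`` on
    non-convergence or a negative rate estimate, and ``ValueError`` when no
    constraint is supplied (the free three-parameter problem is structurally
    unidentifiable from a single curve).
    """
    t = data.times - data.times[0]
    s = data.ein_norm
    if t.size < 8:
        raise ValueError("need at least 8 time points")
    if reference_kin is None and etotal is None and not assume_no_efflux:
        raise ValueError(
            "unidentifiable fit: supply reference_kin (from a high-CCCP curve), "
            "a known etotal, or assume_no_efflux=True"
        )

    ein0 = float(s[0])
    plateau = float(np.mean(s[-max(3, t.size // 5):]))
    span = max(abs(plateau - ein0), 1e-6)
    # crude rate guess from the 1 - 1/e point of the transient
    frac = np.clip(np.abs(s - ein0) / span, 1e-6, 1 - 1e-9)
    with np.errstate(divide="ignore"):
        tau_idx = np.argmin(np.abs(frac - (1 - np.exp(-1.0))))
    r_init = 1.0 / max(float(t[tau_idx]), float(t[1]))

    model = lmfit.Model(_etbr_model, independent_vars=["t"])
    p = model.make_params()
    p["ein0"].set(value=ein0, vary=False)
    if assume_no_efflux:
        p["kout"].set(value=0.0, vary=False)
        p["kin"].set(value=r_init, min=0.0)
        p["etotal"].set(value=max(plateau, 1e-9), min=1e-12,
                        vary=etotal is None)
        if etotal is not None:
            p["etotal"].set(value=etotal, vary=False)
    elif reference_kin is not None:
        if reference_kin <= 0:
            raise ValueError("reference_kin must be > 0")
        p["kin"].set(value=reference_kin, vary=False)
        p["kout"].set(value=max(r_init - reference_kin, 0.1 * reference_kin), min=0.0)
        if etotal is not None:
            p["etotal"].set(value=etotal, vary=False)
        else:
            p["etotal"].set(value=max(plateau, 1e-9), min=1e-12)
    else:  # etotal fixed, both rates float
        p["etotal"].set(value=float(etotal), vary=False)
        a_init = np.clip(plateau / max(float(etotal), 1e-12), 1e-3, 1 - 1e-3)
        p["kin"].set(value=a_init * r_init, min=0.0)
        p["kout"].set(value=(1 - a_init) * r_init, min=0.0)

    result = model.fit(s, p, t=t)
    if not result.success:
        raise FitError(f"EtBr fit did not converge: {result.message}")
    kin_v = float(result.params["kin"].value)
    kout_v = float(result.params["kout"].value)
    et_v = float(result.params["etotal"].value)
    if kin_v < 0 or kout_v < 0:
        raise FitError(f"negative rate estimate (kin={kin_v:g}, kout={kout_v:g})")
    return EffluxFit(kin=kin_v, kout=kout_v, etotal=et_v,
                     goodness=float(np.sqrt(np.mean(result.residual**2))))


# ------------------------------------------------------------ viability, RT
def viability_adjusted_cutoff(killed_fraction: float) -> float:
    """Fold-increase of total signal when the viable fraction doubles.

    If a fraction X of cells is killed but still fluoresces, a doubling of the
    viable cells raises the total signal by the factor 2 - X.  X = 1 is a
    degenerate cutoff of 1 (no viable cells) and is flagged with a warning.
    """
    x = float(killed_fraction)
    if not 0.0 <= x <= 1.0:
        raise ValueError("killed fraction X must be in [0, 1]")
    if x == 1.0:
        warnings.warn("killed fraction X = 1: cutoff degenerates to 1 "
                      "(no viable cells)", RuntimeWarning, stacklevel=2)
    return 2.0 - x


def viability_from_cfu(times: Sequence[float], cfu_counts: Sequence[float]) -> float:
    """Exponential decay rate lambda (1/min) from CFU counts.

    Counts are normalized to the initial density and fit to
    ``exp(-lambda * t)`` by nonlinear least squares (robust to zero counts at
    late times).  The killed fraction after a dose of duration D is then
    ``X = 1 - exp(-lambda * D)``.  A non-decaying series warns and floors the
    rate at 0.
    """
    t = np.asarray(times, dtype=float)
    counts = np.asarray(cfu_counts, dtype=float)
    if t.size != counts.size or t.size < 2:
        raise ValueError("need matching times and counts with >= 2 points")
    order = np.argsort(t)
    t, counts = t[order], counts[order]
    if counts[0] <= 0:
        raise ValueError("initial CFU count must be > 0")
    y = counts / counts[0]

    model = lmfit.Model(lambda t, lam: np.exp(-lam * t), independent_vars=["t"])
    pos = y > 0
    lam_init = 0.0
    if pos.sum() >= 2 and t[pos][-1] > 0:
        lam_init = max(0.0, float(-np.polyfit(t[pos], np.log(y[pos]), 1)[0]))
    p = model.make_params(lam=dict(value=max(lam_init, 1e-6)))
    result = model.fit(y, p, t=t - t[0])
    lam = float(result.params["lam"].value)
    if lam < 0:
        warnings.warn("CFU counts do not decay; viability rate floored at 0",
                      RuntimeWarning, stacklevel=2)
        lam = 0.0
    return lam


def recovery_time_from_signal(
    times: Sequence[float],
    signal: Sequence[float],
    fold: float = 2.0,
) -> float | None:
    """First interpolated crossing of ``fold`` by a normalized signal trace.

    The signal is assumed normalized to its value at t = times[0] (end of
    treatment); an initial dip below 1 before recovery is tolerated — the
    crossing is simply the first time the trace reaches ``fold``.  Returns
    None (censored) if the threshold is never reached.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.size == 0:
        raise ValueError("empty signal series")
    if t.size != s.size:
        raise ValueError("times and signal must have equal length")
    above = s >= fold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0] - t[0])
    frac = (fold - s[i - 1]) / (s[i] - s[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t[0])
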