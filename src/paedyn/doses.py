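"""Extracellular antibiotic dose profiles and total-exposure integrals.

A dose profile prescribes ``A_out(t)`` on the dosing clock (t = 0 is the start
of the first dose).  Four shapes are supported:

* ``rectangular`` — ``A0`` for ``t < D``, then 0.
* ``triangular`` — symmetric linear ramp 0 → A0 → 0 peaking at ``t = D/2``.
* ``exponential`` — ``A0 * exp(-k t)`` for ``t < D`` with the decay constant
  chosen so that ``A_out(D) = 0.01 * A0``, then 0.
* ``periodic`` — ``n_doses`` rectangular pulses of length ``duration`` (T1)
  separated by drug-free gaps of length ``interval`` (T2).

Total antibiotic exposure is the time integral of ``A_out`` up to the end of
the final pulse; recovery times in this package are measured from that moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping

import numpy as np

__all__ = [
    "DoseProfile",
    "SHAPES",
    "total_exposure",
    "profile_with_exposure",
]

SHAPES = ("rectangular", "triangular", "exponential", "periodic")

#: Exponential profiles decay to this fraction of A0 at t = D.
EXP_RESIDUAL_FRACTION = 0.01


@dataclass(frozen=True)
class DoseProfile:
    """Time-dependent extracellular antibiotic concentration.

    Parameters
    ----------
    shape : str
        One of ``rectangular``, ``triangular``, ``exponential``, ``periodic``.
    a0 : float
        Peak (rectangular/triangular/periodic) or initial (exponential)
        concentration, in concentration units (µg/ml for real drugs).
    duration : float
        Single-dose duration D in minutes (T1 for periodic profiles).
    interval : float
        Drug-free gap T2 between pulses (periodic only), minutes.
    n_doses : int
        Number of pulses (periodic only).
    """

    shape: str
    a0: float
    duration: float
    interval: float = 0.0
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown dose shape {self.shape!r}; expected one of {SHAPES}")
        if self.a0 < 0:
            raise ValueError("peak concentration a0 must be >= 0")
        if self.duration <= 0:
            raise ValueError("dose duration must be > 0")
        if self.shape == "periodic":
            if self.interval < 0:
                raise ValueError("inter-dose interval must be >= 0")
            if self.n_doses < 1:
                raise ValueError("n_doses must be >= 1")

    # ------------------------------------------------------------------ timing
    @property
    def treatment_end(self) -> float:
        """End of the final pulse on the dosing clock (min)."""
        if self.shape == "periodic":
            return self.n_doses * self.duration + (self.n_doses - 1) * self.interval
        return self.duration

    def breakpoints(self) -> list[float]:
        """Times where A_out(t) is discontinuous or kinked (for the integrator)."""
        if self.shape == "periodic":
            pts: list[float] = []
            period = self.duration + self.interval
            for i in range(self.n_doses):
                pts.extend([i * period, i * period + self.duration])
            return sorted(set(pts))
        if self.shape == "triangular":
            return [0.0, self.duration / 2.0, self.duration]
        return [0.0, self.duration]

    # ------------------------------------------------------------- evaluation
    def concentration_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """A_out at time ``t`` on the dosing clock (vectorized)."""
        t_arr = np.asarray(t, dtype=float)
        out = np.zeros_like(t_arr)
        d = self.duration
        if self.shape == "rectangular":
            out = np.where((t_arr >= 0) & (t_arr < d), self.a0, 0.0)
        elif self.shape == "triangular":
            up = (t_arr >= 0) & (t_arr <= d / 2)
            down = (t_arr > d / 2) & (t_arr < d)
            out = np.where(up, self.a0 * t_arr / (d / 2), out)
            out = np.where(down, self.a0 * (d - t_arr) / (d / 2), out)
        elif self.shape == "exponential":
            k = self.decay_constant()
            inside = (t_arr >= 0) & (t_arr < d)
            out = np.where(inside, self.a0 * np.exp(-k * np.clip(t_arr, 0, None)), 0.0)
        else:  # periodic
            period = d + self.interval
            within = (t_arr >= 0) & (t_arr < self.treatment_end)
            phase = np.mod(t_arr, period if period > 0 else 1.0)
            out = np.where(within & (phase < d), self.a0, 0.0)
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out

    def decay_constant(self) -> float:
        """Decay rate of the exponential shape: ln(1/residual)/D."""
        if self.shape != "exponential":
            raise ValueError("decay_constant only defined for exponential profiles")
        return math.log(1.0 / EXP_RESIDUAL_FRACTION) / self.duration

    def single_dose(self) -> "DoseProfile":
        """The n_doses = 1 reduction of a periodic profile (identity otherwise)."""
        if self.shape != "periodic":
            return self
        return replace(self, n_doses=1, interval=0.0)

    # ------------------------------------------------------------------ config
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"shape": self.shape, "a0": self.a0, "duration": self.duration}
        if self.shape == "periodic":
            d["interval"] = self.interval
            d["n_doses"] = self.n_doses
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "DoseProfile":
        known = {"shape", "a0", "duration", "interval", "n_doses"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown dose keys: {sorted(unknown)}")
        return cls(**dict(data))


def total_exposure(profile: DoseProfile) -> float:
    """Exact time integral of A_out over the full dosing window (conc·min).

    Closed forms per shape: ``A0*D`` (rectangular), ``A0*D/2`` (triangular),
    ``A0*(1 - residual)*D/ln(1/residual)`` (exponential, residual = 0.01),
    and ``n_doses * A0 * T1`` (periodic — all pulses counted).
    """
    a0, d = profile.a0, profile.duration
    if profile.shape == "rectangular":
        return a0 * d
    if profile.shape == "triangular":
        return a0 * d / 2.0
    if profile.shape == "exponential":
        k = profile.decay_constant()
        return a0 * (1.0 - EXP_RESIDUAL_FRACTION) / k
    return profile.n_doses * a0 * d


def profile_with_exposure(shape: str, exposure: float, duration: float) -> DoseProfile:
    """Build a profile of the given shape and duration with a target exposure.

    Solves the closed-form exposure expression for the peak concentration, so
    that profiles of different shapes can be matched dose-for-dose by total
    antibiotic exposure.
    """
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    if shape == "rectangular":
        a0 = exposure / duration
    elif shape == "triangular":
        a0 = 2.0 * exposure / duration
    elif shape == "exponential":
        k = math.log(1.0 / EXP_RESIDUAL_FRACTION) / duration
        a0 = exposure * k / (1.0 - EXP_RESIDUAL_FRACTION)
    else:
        raise ValueError(f"cannot solve exposure for shape {shape!r}")
    return DoseProfile(shape=shape, a0=a0, duration=duration)
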