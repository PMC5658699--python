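"""Parameter sets and state containers for the antibiotic–ribosome kinetic model.

The full model tracks free ribosomes ``C``, intracellular and extracellular
antibiotic (``A_in``, ``A_out``), the reversible ribosome–antibiotic complex
``CA``, a degradation intermediate ``CA'`` that slowly releases antibiotic back
into the cytoplasm, and the population density ``N`` growing logistically at a
ribosome-dependent rate.  All rate constants are per minute; concentrations and
densities are in arbitrary units (the model is dimensionless apart from time).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "FullModelParams",
    "ModelState",
    "DEFAULT_PARAMS",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class FullModelParams:
    """Rate constants of the six-component antibiotic–ribosome model.

    Parameters
    ----------
    k1 : float
        Maximal ribosome synthesis rate (conc/min) of the saturable
        (positive-feedback) synthesis term ``k1*C/(v1 + C)``.
    v1 : float
        Half-saturation constant of ribosome synthesis (conc).
    kf : float
        Antibiotic–ribosome binding rate (1/(conc*min)).
    kb : float
        Complex dissociation rate (1/min).
    ku : float
        Basal ribosome turnover rate (1/min).
    kd : float
        Antibiotic-mediated complex degradation rate (1/min).
    kr : float
        Antibiotic release rate from the degradation intermediate (1/min).
    kin : float
        Antibiotic influx rate across the membrane (1/min).
    kout : float
        Antibiotic efflux rate (1/min); the detoxification rate.
    mu0 : float
        Maximal population growth rate (1/min).
    v : float
        Half-saturation of growth versus ribosome concentration (conc).
        Kept independent of ``v1``; setting them equal is a configuration
        choice, not a model assumption.
    nm : float
        Carrying capacity of the logistic population term (density units).
    """

    k1: float = 0.2
    v1: float = 4.0
    kf: float = 0.01
    kb: float = 0.01
    ku: float = 0.03
    kd: float = 0.1
    kr: float = 0.01
    kin: float = 0.01
    kout: float = 0.01
    mu0: float = 0.035
    v: float = 2.0
    nm: float = 1.0

    def __post_init__(self) -> None:
        for name in _FIELD_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not value == value:
                raise ValueError(f"parameter {name!r} must be a finite number")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        if self.nm <= 0:
            raise ValueError("carrying capacity nm must be > 0")
        if self.v1 <= 0:
            raise ValueError("half-saturation v1 must be > 0")
        if self.v <= 0:
            raise ValueError("half-saturation v must be > 0")

    def untreated_ribosome_level(self) -> float:
        """Nontrivial drug-free fixed point ``C* = k1/ku - v1`` of the ribosome
        equation (0.0 if the parameters admit only the trivial fixed point)."""
        if self.ku == 0:
            raise ValueError("ku = 0 has no finite drug-free fixed point")
        return max(0.0, self.k1 / self.ku - self.v1)

    def growth_rate(self, c: float) -> float:
        """Ribosome-dependent specific growth rate ``mu0*C/(v + C)`` (1/min)."""
        return self.mu0 * c / (self.v + c)

    def doubling_time(self) -> float:
        """Untreated population doubling time (min) at the drug-free fixed point."""
        import math

        mu = self.growth_rate(self.untreated_ribosome_level())
        if mu <= 0:
            return float("inf")
        return math.log(2.0) / mu

    def replace(self, **changes: float) -> "FullModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FullModelParams":
        unknown = set(data) - set(_FIELD_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(FullModelParams))

#: Baseline parameter set used throughout the package.  kd, kout and k1 take
#: the reference values of the perturbation analysis (kd=0.1, kout=0.01,
#: k1=0.2); the remaining constants were chosen once so that the untreated
#: doubling time is ~35 min and recovery times grow smoothly and monotonically
#: with total antibiotic exposure.  This set is a documented stand-in for the
#: original study's appendix table, which is not reproduced here.
DEFAULT_PARAMS = FullModelParams()


@dataclass(frozen=True)
class ModelState:
    """One snapshot of the full model state (all components >= 0)."""

    c: float
    a_in: float
    a_out: float
    ca: float
    ca_prime: float
    n: float

    def __post_init__(self) -> None:
        for name in ("c", "a_in", "a_out", "ca", "ca_prime", "n"):
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name!r} must be >= 0")

    def as_ode_vector(self) -> list[float]:
        """Integrated variables (A_out is algebraic, set by the dose profile)."""
        return [self.c, self.a_in, self.ca, self.ca_prime, self.n]


def default_initial_state(params: FullModelParams, n0_fraction: float = 0.01) -> ModelState:
    """Drug-free pre-equilibrated initial condition.

    Ribosomes start at the untreated fixed point (exponentially growing
    cells), no antibiotic anywhere, and the population at ``n0_fraction`` of
    carrying capacity.
    """
    c0 = max(1e-9, params.untreated_ribosome_level())
    return ModelState(c=c0, a_in=0.0, a_out=0.0, ca=0.0, ca_prime=0.0, n=n0_fraction * params.nm)


def load_params(path: str | Path) -> FullModelParams:
    """Read a parameter set from a YAML or JSON config file (one key per field)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if "model" in data and isinstance(data["model"], Mapping):
        data = data["model"]
    return FullModelParams.from_dict(data)


def dump_params(params: FullModelParams, path: str | Path) -> None:
    """Write a parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
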