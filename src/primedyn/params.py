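"""Model parameters for a population subject to priming and a triggering stress.

The parameter set describes one microbial population growing at intrinsic
rate ``g_I``, receiving a priming stimulus during ``[t_P, t_TS)`` (growth
reduced by the cost fraction ``c_P`` if the population is primeable), and a
triggering stress of duration ``TD`` starting at ``t_TS``. The stress acts as
an added mortality: ``m_I`` during a response lag of length ``L``, then a
linear decline with normalized slope ``s_R`` down to the response floor
``m_R``. ``K`` is the environmental carrying capacity used by the logistic
and community models; ``S0`` the initial population size. Time is an
abstract unit ``t``; rates are per ``t``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "load_params",
    "save_params",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


# keys accepted in config files; m_R may be given directly or via m_R_ratio
_CONFIG_KEYS = ("g_I", "c_P", "s_R", "m_I", "m_R", "m_R_ratio", "L", "t_P", "t_TS", "TD", "K", "S0")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, timings and costs of one population.

    Defaults are the standard fixture of a nonprimed population:
    ``m_I = 2 g_I`` (a 5% net decline per time step under stress, mirroring
    the 5% per-step growth), ``m_R = 0.25 m_I`` and a response buildup of
    ``(m_I - m_R)/(s_R m_I) = 25 t`` after a lag of ``L = 5 t``.
    """

    g_I: float = 0.0488
    c_P: float = 0.3
    s_R: float = 0.03
    m_I: float = 0.0976
    m_R: float = 0.0244
    L: float = 5.0
    t_P: float = 30.0
    t_TS: float = 50.0
    TD: float = 75.0
    K: float = 10_000.0
    S0: float = 100.0

    def __post_init__(self) -> None:
        if not (self.g_I >= 0.0 and math.isfinite(self.g_I)):
            raise ParameterError(f"g_I must be a finite rate >= 0, got {self.g_I}")
        if not (0.0 <= self.c_P < 1.0):
            raise ParameterError(f"c_P must lie in [0, 1), got {self.c_P}")
        if self.s_R <= 0.0:
            raise ParameterError(f"s_R must be > 0, got {self.s_R}")
        if self.m_I < 0.0:
            raise ParameterError(f"m_I must be >= 0, got {self.m_I}")
        if not (0.0 <= self.m_R <= self.m_I):
            raise ParameterError(
                f"m_R must satisfy 0 <= m_R <= m_I, got m_R={self.m_R}, m_I={self.m_I}"
            )
        if self.m_I > 0.0 and self.m_R <= 0.0:
            raise ParameterError("m_R must be > 0 when m_I > 0")
        if self.L < 0.0:
            raise ParameterError(f"L must be >= 0, got {self.L}")
        if self.t_P > self.t_TS:
            raise ParameterError(
                f"priming must start before the triggering stress: t_P={self.t_P} > t_TS={self.t_TS}"
            )
        if self.TD < 0.0:
            raise ParameterError(f"TD must be >= 0, got {self.TD}")
        if self.S0 <= 0.0:
            raise ParameterError(f"S0 must be > 0, got {self.S0}")
        if not self.K > 0.0:  # math.inf allowed (unbounded growth)
            raise ParameterError(f"K must be > 0 (or inf), got {self.K}")

    # -- derived quantities -------------------------------------------------

    @property
    def buildup(self) -> float:
        """Duration of the naive mortality decline, (m_I - m_R)/(s_R m_I)."""
        if self.m_I == 0.0:
            return 0.0
        return (self.m_I - self.m_R) / (self.s_R * self.m_I)

    @property
    def t_TE(self) -> float:
        return self.t_TS + self.TD

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(data) - set(_CONFIG_KEYS)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        if "m_R" in data and "m_R_ratio" in data:
            raise ParameterError("give either m_R or m_R_ratio, not both")
        values = {k: float(v) for k, v in data.items() if k != "m_R_ratio"}
        if "m_R_ratio" in data:
            m_I = values.get("m_I", cls.m_I)
            values["m_R"] = float(data["m_R_ratio"]) * m_I
        return cls(**values)

    def hash(self) -> str:
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def default_parameters(**overrides: Any) -> ModelParameters:
    """The standard nonprimed-population fixture, optionally overridden."""
    return ModelParameters(**overrides)


def load_params(path: str | Path) -> ModelParameters:
    """Load parameters from a flat YAML key-value file.

    Missing keys fall back to the defaults; unknown keys are rejected.
    An empty file yields the full default fixture.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"config must be a flat key-value mapping, got {type(data).__name__}")
    return ModelParameters.from_dict(data)


def save_params(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
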