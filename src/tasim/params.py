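"""Parameter and state containers for the toxin-antitoxin circuit.

All concentrations are numbers of molecules per cell volume, treated as
dimensionless counts; times are in minutes and rates in 1/min throughout.
The plasmid copy number ``g`` is a non-negative real so that continuous
copy-number scans are expressible; event schedules typically use integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "CircuitParams",
    "CompetitorParams",
    "CircuitState",
    "ExtendedState",
    "DEFAULT_PARAMS",
    "DEFAULT_COMPETITOR",
]


def _check_nonneg_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")
        if v < 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class CircuitParams:
    """Rate constants of the base toxin-antitoxin circuit.

    Attributes
    ----------
    alpha_m, alpha_s :
        mRNA / sRNA synthesis rates [per gene copy per min].
    beta_m, beta_s :
        mRNA / sRNA first-order degradation rates [1/min].
    alpha_p, beta_p :
        protein synthesis rate [1/min per mRNA] and degradation rate [1/min].
    h_plus, h_minus :
        mRNA-sRNA complex binding [1/(conc min)] and unbinding [1/min] rates.
    beta_c :
        complex degradation rate [1/min].
    g :
        plasmid copy number per cell volume [copies].
    """

    alpha_m: float = 1.0
    beta_m: float = 0.2
    alpha_s: float = 6.0
    beta_s: float = 1.0
    alpha_p: float = 5.0
    beta_p: float = 0.035
    h_plus: float = 20.0
    h_minus: float = 1.0
    beta_c: float = 0.1
    g: float = 6.0

    def __post_init__(self) -> None:
        _check_nonneg_finite(self)

    def with_g(self, g: float) -> "CircuitParams":
        return replace(self, g=float(g))

    def replace(self, **kwargs) -> "CircuitParams":
        return replace(self, **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_m, self.beta_m, self.alpha_s, self.beta_s,
             self.alpha_p, self.beta_p, self.h_plus, self.h_minus,
             self.beta_c, self.g],
            dtype=np.float64,
        )

    FIELD_ORDER = ("alpha_m", "beta_m", "alpha_s", "beta_s", "alpha_p",
                   "beta_p", "h_plus", "h_minus", "beta_c", "g")


@dataclass(frozen=True)
class CompetitorParams:
    """Rates of the competitor mRNA that sequesters the antitoxin sRNA.

    ``alpha_2``/``beta_2`` are synthesis and degradation of the competitor
    mRNA; ``k_plus``/``k_minus`` bind/unbind the competitor-sRNA complex,
    degraded at ``beta_c2``.
    """

    alpha_2: float = 4.0
    beta_2: float = 0.6
    k_plus: float = 60.0
    k_minus: float = 1.0
    beta_c2: float = 0.1

    def __post_init__(self) -> None:
        _check_nonneg_finite(self)

    def replace(self, **kwargs) -> "CompetitorParams":
        return replace(self, **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_2, self.beta_2, self.k_plus, self.k_minus, self.beta_c2],
            dtype=np.float64,
        )

    FIELD_ORDER = ("alpha_2", "beta_2", "k_plus", "k_minus", "beta_c2")


@dataclass(frozen=True)
class CircuitState:
    """Concentrations of the four base species (molecules per cell volume)."""

    m: float = 0.0
    s: float = 0.0
    c: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg_finite(self)

    def to_array(self) -> np.ndarray:
        return np.array([self.m, self.s, self.c, self.p], dtype=np.float64)

    @classmethod
    def from_array(cls, y) -> "CircuitState":
        m, s, c, p = (float(v) for v in y)
        return cls(m=m, s=s, c=c, p=p)


@dataclass(frozen=True)
class ExtendedState(CircuitState):
    """Base species plus competitor mRNA (m2) and its sRNA complex (c2)."""

    m2: float = 0.0
    c2: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.m, self.s, self.c, self.p, self.m2, self.c2],
                        dtype=np.float64)

    @classmethod
    def from_array(cls, y) -> "ExtendedState":
        m, s, c, p, m2, c2 = (float(v) for v in y)
        return cls(m=m, s=s, c=c, p=p, m2=m2, c2=c2)


#: Canonical literature-derived parameter set (the worked default).
DEFAULT_PARAMS = CircuitParams()

#: Competitor rates of the worked induction example.
DEFAULT_COMPETITOR = CompetitorParams()
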