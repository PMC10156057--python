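"""Size-dependent survival selection on daughter filaments.

A selective environment assigns each daughter filament of ``x`` cells a
probability of surviving fragmentation.  The canonical form is a shifted,
scaled sigmoid

    p_s(x) = c / (1 + exp(-a (x - b))) - d,

clamped to [0, 1].  The steepness ``a`` controls how quickly survival
improves with filament size and the offset ``b`` sets the survival of
unicellular daughters.  Two named presets are provided: ``E_B`` (a=0.4,
b=0), where binary fission is the fittest fragmentation mode, and ``E_C``
(a=0.89, b=-4), where complete dissociation is fittest.

A group-level trait ``s_g`` carried by cells rescales survival
multiplicatively: a fragment whose cells have mean trait ``s̄_g`` survives
with probability ``clamp(p_s(x) * (1 + s̄_g), 0, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Environment",
    "LifeCycle",
    "Traits",
    "survival_probability",
    "effective_survival",
]

#: Default scale and shift shared by all preset environments.
DEFAULT_C = 1.7
DEFAULT_D = 0.9

_VARIANTS = ("sigmoid", "modified_sigmoid", "linear")


@dataclass(frozen=True)
class Environment:
    """A selective regime: parameters of the survival function.

    Parameters
    ----------
    a : float
        Steepness — how fast survival rises with daughter size.
    b : float
        Location offset in cells; sets survival of small daughters.
    c : float
        Scale of the sigmoid (must be positive).
    d : float
        Downward shift; the sigmoid saturates at ``c - d``.
    variant : str
        Functional form, one of ``sigmoid`` (default), ``linear``
        (``clamp(a * (x - b), 0, 1)``; ``c`` and ``d`` ignored) or
        ``modified_sigmoid`` (accepted but has no defined parameterisation
        in this release; evaluating it raises ``NotImplementedError``).
    """

    a: float
    b: float
    c: float = DEFAULT_C
    d: float = DEFAULT_D
    variant: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown survival-function variant {self.variant!r}; "
                f"expected one of {_VARIANTS}"
            )
        for name in ("a", "b", "c", "d"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"environment parameter {name} must be finite")
        if self.variant == "sigmoid" and self.c <= 0:
            raise ValueError("sigmoid scale c must be positive")

    @classmethod
    def preset(cls, name: str) -> "Environment":
        """Return a named preset environment (``"E_B"`` or ``"E_C"``)."""
        try:
            return _PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown environment preset {name!r}; known: {sorted(_PRESETS)}"
            ) from None


_PRESETS = {
    "E_B": Environment(a=0.4, b=0.0),
    "E_C": Environment(a=0.89, b=-4.0),
}


@dataclass(frozen=True)
class LifeCycle:
    """An even-fragmentation life cycle: grow to ``N`` cells, split into
    ``k`` daughters of ``N/k`` cells each.

    ``k`` must divide ``N`` and satisfy ``2 <= k <= N`` (``k = 1`` would
    never fragment).
    """

    N: int
    k: int

    def __post_init__(self) -> None:
        if self.N < 2 or self.k < 2:
            raise ValueError(f"need N >= 2 and k >= 2, got N={self.N}, k={self.k}")
        if self.k > self.N:
            raise ValueError(f"daughter count k={self.k} exceeds adult size N={self.N}")
        if self.N % self.k != 0:
            raise ValueError(f"k={self.k} does not divide N={self.N}")

    @property
    def daughter_size(self) -> int:
        """Size ``x = N/k`` of each daughter filament, in cells."""
        return self.N // self.k

    @classmethod
    def fragmentation_modes(cls, N: int) -> list["LifeCycle"]:
        """All even-split life cycles for adult size ``N`` (divisors k >= 2)."""
        return [cls(N, k) for k in range(2, N + 1) if N % k == 0]


@dataclass(frozen=True)
class Traits:
    """A mutant phenotype.

    ``s_c`` modifies the cell reproductive rate (cells divide at rate
    ``lambda_c * (1 + s_c)``); ``s_g`` modifies daughter-filament survival
    (multiplies ``p_s`` by ``1 + s_g``).  The evolutionary mutation kernel
    bounds both to [-0.2, 0.2]; the fields themselves accept any finite
    value.
    """

    s_c: float = 0.0
    s_g: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s_c) and math.isfinite(self.s_g)):
            raise ValueError("traits must be finite")


ANCESTOR = Traits(0.0, 0.0)


def survival_probability(x, env: Environment):
    """Probability that a daughter filament of ``x`` cells survives.

    Accepts a scalar or array ``x`` (cells, >= 1) and returns values
    clamped to [0, 1].  For the sigmoid variant the raw form
    ``c/(1+exp(-a(x-b))) - d`` can stray outside [0, 1] for extreme
    parameters; probabilities are clamped so the codomain stays valid.
    """
    xs = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xs)):
        raise ValueError("daughter size x must be finite")
    if np.any(xs < 1):
        raise ValueError("daughter size x must be >= 1 cell")
    if env.variant == "sigmoid":
        raw = env.c / (1.0 + np.exp(-env.a * (xs - env.b))) - env.d
    elif env.variant == "linear":
        raw = env.a * (xs - env.b)
    else:
        raise NotImplementedError(
            "the modified_sigmoid variant has no defined parameterisation "
            "in this release"
        )
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def effective_survival(x, env: Environment, sg_bar: float):
    """Survival probability of a fragment whose cells have mean group
    trait ``sg_bar``: ``clamp(p_s(x) * (1 + sg_bar), 0, 1)``."""
    if not math.isfinite(sg_bar):
        raise ValueError("sg_bar must be finite")
    out = np.clip(survival_probability(x, env) * (1.0 + sg_bar), 0.0, 1.0)
    return float(out) if np.isscalar(x) or np.ndim(out) == 0 else out
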