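"""Kinetic parameter containers for the APC/C-Cdc20 degradation models.

The one-substrate model tracks eleven molecular species: free APC/C-Cdc20
(``A``), free substrate carrying 0..4 ubiquitins (``S0``..``S4``), and
APC/C-bound substrate carrying 0..4 ubiquitins (``AS0``..``AS4``). All
reactions follow mass-action kinetics; a substrate carrying four ubiquitins
is degraded by the proteasome whether bound or free.

Units: concentrations in nM, time in seconds. ``k_a`` is per (nM s); all
other rate constants are per second; ``p_A`` is nM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

MAX_UB = 4  # degradation is triggered at four ubiquitins

ApcMode = Literal["linear", "constant"]
DeubVariant = Literal["none", "all", "free_only", "bound_only", "mono_only"]

_DEUB_VARIANTS = ("none", "all", "free_only", "bound_only", "mono_only")
_APC_MODES = ("linear", "constant")


def _check_nonneg(name: str, value: float) -> None:
    if not (value >= 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants and initial conditions for the one-substrate model.

    Parameters
    ----------
    k_a
        Association rate constant of APC/C-Cdc20 and free substrate,
        per (nM s).
    k_d
        Dissociation rate constant of the enzyme-substrate complex, per s.
    k_c
        Ubiquitin-transfer (catalytic) rate constant, per s.
    e
        Proteasomal degradation rate constant acting on species with four
        ubiquitins, per s. The default 1000/s makes degradation effectively
        instantaneous once the fourth ubiquitin is attached.
    p_A
        Linear APC/C-Cdc20 accumulation rate, nM/s (``apc_mode="linear"``).
    A_const
        Constant APC/C-Cdc20 level, nM (``apc_mode="constant"`` only).
    S0_init
        Initial free unmodified substrate, nM.
    apc_mode
        ``"linear"``: A(0)=0 and free APC/C is produced at rate ``p_A``.
        ``"constant"``: A(0)=A_const with no production; total APC/C is
        conserved.
    deub_variant
        Which species are subject to deubiquitination (one ubiquitin removed
        per event at rate ``k_dub``): ``"none"``, ``"all"`` (every
        ubiquitinated species), ``"free_only"`` (S1..S4), ``"bound_only"``
        (AS1..AS4) or ``"mono_only"`` (S1 and AS1 only).
    k_dub
        Deubiquitination rate constant, per s. Ignored when
        ``deub_variant="none"``.
    """

    k_a: float = 0.01
    k_d: float = 1.0
    k_c: float = 1.0
    e: float = 1000.0
    p_A: float = 0.06
    A_const: float = 100.0
    S0_init: float = 200.0
    apc_mode: ApcMode = "linear"
    deub_variant: DeubVariant = "none"
    k_dub: float = 0.0
    max_ub: int = field(default=MAX_UB)

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d", "k_c", "e", "p_A", "A_const", "S0_init", "k_dub"):
            _check_nonneg(name, getattr(self, name))
        if self.apc_mode not in _APC_MODES:
            raise ValueError(f"apc_mode must be one of {_APC_MODES}, got {self.apc_mode!r}")
        if self.deub_variant not in _DEUB_VARIANTS:
            raise ValueError(
                f"deub_variant must be one of {_DEUB_VARIANTS}, got {self.deub_variant!r}"
            )
        if self.max_ub != MAX_UB:
            raise ValueError(f"max_ub is fixed at {MAX_UB}")

    def with_(self, **kwargs) -> "RateParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown RateParameters fields: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TwoSubstrateParameters:
    """Parameters for two substrates S and C sharing one APC/C-Cdc20 pool.

    Both substrates bind free APC/C with the shared ``k_a`` and start at the
    same concentration (200 nM each by default); each has its own
    dissociation and catalytic rate constants.

    Scenarios encode how C is the "better" substrate:

    - ``affinity``: C binds ten-fold tighter (k_d_C = k_d_S / 10,
      k_c_C = k_c_S).
    - ``catalytic``: C is ubiquitinated ten-fold faster once bound
      (k_c_C = 10 * k_c_S, k_d_C = k_d_S).
    - ``custom``: k_d_C / k_c_C given explicitly.
    """

    k_a: float = 0.01
    k_d_S: float = 1.0
    k_c_S: float = 1.0
    k_d_C: float = 1.0
    k_c_C: float = 1.0
    e: float = 1000.0
    p_A: float = 0.06
    A_const: float = 100.0
    S_init: float = 200.0
    C_init: float = 200.0
    apc_mode: ApcMode = "linear"
    scenario: str = "custom"

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d_S", "k_c_S", "k_d_C", "k_c_C", "e", "p_A",
                     "A_const", "S_init", "C_init"):
            _check_nonneg(name, getattr(self, name))
        if self.apc_mode not in _APC_MODES:
            raise ValueError(f"apc_mode must be one of {_APC_MODES}, got {self.apc_mode!r}")
        if self.scenario not in ("affinity", "catalytic", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def affinity(cls, k_c_S: float, k_d_S: float, **shared) -> "TwoSubstrateParameters":
        """C binds ten-fold tighter than S: k_d_C = k_d_S / 10."""
        return cls(k_c_S=k_c_S, k_d_S=k_d_S, k_c_C=k_c_S, k_d_C=k_d_S / 10.0,
                   scenario="affinity", **shared)

    @classmethod
    def catalytic(cls, k_c_S: float, k_d_S: float, **shared) -> "TwoSubstrateParameters":
        """C is ubiquitinated ten-fold faster than S: k_c_C = 10 * k_c_S."""
        return cls(k_c_S=k_c_S, k_d_S=k_d_S, k_c_C=10.0 * k_c_S, k_d_C=k_d_S,
                   scenario="catalytic", **shared)

    def substrate_params(self, which: str) -> RateParameters:
        """One-substrate RateParameters for substrate ``which`` alone."""
        if which == "S":
            kd, kc, s0 = self.k_d_S, self.k_c_S, self.S_init
        elif which == "C":
            kd, kc, s0 = self.k_d_C, self.k_c_C, self.C_init
        else:
            raise ValueError("which must be 'S' or 'C'")
        return RateParameters(k_a=self.k_a, k_d=kd, k_c=kc, e=self.e,
                              p_A=self.p_A, A_const=self.A_const,
                              S0_init=s0, apc_mode=self.apc_mode)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TwoSubstrateParameters":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown TwoSubstrateParameters fields: {sorted(unknown)}")
        return cls(**d)
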