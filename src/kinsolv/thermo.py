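"""Transition-state-theory conversions between solvation activation
energies and relative rate constants.

Sign convention: a positive ddG‡_solv means the transition state is
destabilized by the solvent relative to the reactants, so the liquid-phase
reaction is *slower* than the gas-phase one; log10(k_liq/k_gas) =
-ddG‡_solv / (R T ln 10).  At 298 K one log10 unit corresponds to
R·T·ln 10 ≈ 1.3636 kcal/mol, so |ddG‡_solv| = 40 kcal/mol is about 29
orders of magnitude in the rate ratio and 10 kcal/mol about 7.

The temperature dependence uses the constant-enthalpy linear form
ddG(T) = ddH298 - T·(ddH298 - ddG298)/T0, valid for moderate temperatures
(roughly 250-400 K); ddH can be recovered from ddG at 297/298/299 K by a
central finite difference of the Gibbs-Helmholtz relation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .errors import UsageError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoContext",
    "SolvationSet",
    "ddG_activation",
    "ddH_activation",
    "log10_rate_ratio_liq_gas",
    "log10_rate_ratio_two_solvents",
    "extrapolate_ddG",
    "ddH_from_gradient",
    "dG_rel_error",
    "kcal_per_log10",
]

#: universal gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 1.98720425864083e-3


@dataclass(frozen=True)
class ThermoContext:
    """Gas constant, reference temperature, and working temperature."""

    R: float = GAS_CONSTANT_KCAL
    T0: float = 298.0
    T: float = 298.0

    def __post_init__(self):
        if self.T <= 0 or self.T0 <= 0:
            raise UsageError(f"temperatures must be positive (T={self.T}, T0={self.T0})")

    def at(self, T: float) -> "ThermoContext":
        return ThermoContext(R=self.R, T0=self.T0, T=T)


@dataclass
class SolvationSet:
    """Solvation free energies/enthalpies of a transition state and its
    reactant(s), kcal/mol.  For a bimolecular reaction the reactant terms
    are summed."""

    dG_TS: float
    dH_TS: float
    dG_reactants: Sequence[float]
    dH_reactants: Sequence[float]

    def __post_init__(self):
        if len(self.dG_reactants) == 0 or len(self.dH_reactants) == 0:
            raise UsageError("a SolvationSet needs at least one reactant")


def ddG_activation(s: SolvationSet) -> float:
    """ddG‡_solv = dG_solv(TS) - sum of dG_solv(reactants)."""
    return s.dG_TS - sum(s.dG_reactants)


def ddH_activation(s: SolvationSet) -> float:
    """ddH‡_solv = dH_solv(TS) - sum of dH_solv(reactants)."""
    return s.dH_TS - sum(s.dH_reactants)


def kcal_per_log10(ctx: ThermoContext = ThermoContext()) -> float:
    """kcal/mol per log10 unit of a rate ratio: R·T·ln 10."""
    return ctx.R * ctx.T * math.log(10.0)


def log10_rate_ratio_liq_gas(ddG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """log10(k_liq/k_gas) from ddG‡_solv; positive ddG slows the liquid."""
    return -ddG / kcal_per_log10(ctx)


def log10_rate_ratio_two_solvents(
    ddG1: float, ddG2: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """log10(k_s1/k_s2) = -(ddG1 - ddG2) / (R·T·ln 10); antisymmetric under
    swapping the solvents and exactly additive with the gas/liquid form."""
    return log10_rate_ratio_liq_gas(ddG1, ctx) - log10_rate_ratio_liq_gas(ddG2, ctx)


def extrapolate_ddG(
    ddG298: float, ddH298: float, T: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """Linear (constant ddH, constant ddS) extrapolation of ddG‡_solv to T.

    ddG(T) = ddH298 - T·(ddH298 - ddG298)/T0.  Warns, but still computes,
    outside the 250-400 K range where the linear form is considered valid.
    """
    if T <= 0:
        raise UsageError(f"temperature must be positive, got {T}")
    if not 250.0 <= T <= 400.0:
        warnings.warn(
            f"T = {T} K is outside the moderate temperature range (250-400 K) "
            "where the linear extrapolation is considered valid",
            stacklevel=2,
        )
    return ddH298 - T * (ddH298 - ddG298) / ctx.T0


def ddH_from_gradient(
    ddG_Tm1: float,
    ddG_T: float,
    ddG_Tp1: float,
    T: float,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """ddH‡_solv from ddG‡_solv at T-1, T, T+1 K (Gibbs-Helmholtz central
    difference): ddH = ddG(T) - T·(ddG(T+1) - ddG(T-1))/2.

    Exact whenever ddG is linear in T, so it inverts ``extrapolate_ddG``.
    """
    del ctx  # the stencil needs no constants; kept for interface symmetry
    return ddG_T - T * (ddG_Tp1 - ddG_Tm1) / 2.0


def dG_rel_error(
    k_rel_expt: float, k_rel_calc: float, T: float = 298.0,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """Relative-rate error on the free-energy scale:
    -R·T·(ln k_rel,expt - ln k_rel,calc), kcal/mol."""
    if k_rel_expt <= 0 or k_rel_calc <= 0:
        raise UsageError("rate ratios must be positive")
    return -ctx.R * T * (math.log(k_rel_expt) - math.log(k_rel_calc))
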