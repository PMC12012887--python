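"""Multicellular realizations: Lotka-Volterra consortium controllers.

The layered autocatalytic motif maps onto a microbial consortium by letting
two controller strains N1 and N2 play the roles of the two controller
species, with the logistic free-capacity factor ``phi = 1 - (sum of weighted
densities)/N_m`` standing in for the shared free resource (common nutrients
in the growth medium).  Term for term:

==============================  =========================================
intracellular motif             population realization
==============================  =========================================
``alpha1* z1 r``                intrinsic logistic growth ``mu1 N1 phi``
``- theta x_n z1``              killing of N1 by the output, ``-theta1 x_n N1``
``alpha2* x_n z2 r``            output-induced growth ``rho_xn x_n N2 phi``
``- gamma_c2 z2``               dilution ``- gamma N2``
==============================  =========================================

Balancing N1's death rate against N2's doubling rate yields a set-point that
depends only on the controller strains' parameters: with first-order growth
induction the regulated output solves

    theta1 rho x*^2 + gamma rho x* - mu1 gamma = 0.

Three circuit templates are provided: the generic two-strain consortium
around an arbitrary process, the three-strain population-control circuit
(two controller strains regulate a target strain through two orthogonal
AHL quorum-sensing channels), and the four-strain coculture-composition
circuit that regulates the density *ratio* of two process strains.
Time is in hours, densities and AHL levels in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, InputError
from .model import CircuitModel

__all__ = [
    "ConsortiumParams",
    "PopulationControlParams",
    "CocultureRatioParams",
    "consortium_circuit",
    "consortium_setpoint",
    "population_control_circuit",
    "population_control_setpoint",
    "coculture_ratio_circuit",
    "population_ratio_setpoint",
    "EXTINCTION_FRACTION",
    "extinct_populations",
]

#: Populations below this fraction of carrying capacity are reported as
#: excluded (competitive-exclusion diagnostics); the integrator never clamps.
EXTINCTION_FRACTION = 1e-9


def _growth_response(x: float, K: float | None) -> float:
    """First-order growth induction, optionally saturating with scale K.

    ``x`` for ``K=None`` (pure first-order); ``x/(1 + x/K)`` otherwise,
    which reduces to the first-order law when ``K`` is far above the
    operating range.
    """
    if K is None:
        return x
    return x / (1.0 + x / K)


@dataclass(frozen=True)
class ConsortiumParams:
    """Two controller strains closing an integral loop around a process.

    ``c`` holds the Lotka-Volterra competition coefficients ``c_ji`` of the
    process populations on the controller strains (per process population);
    the controller strains' mutual and self coefficients are unity (two
    strains of the same species sharing one carrying capacity ``N_m``).
    """

    mu1: float
    theta1: float
    rho_xn: float
    N_m: float
    gamma: float = 0.0
    c: tuple[float, ...] = ()
    growth_hill_K: float | None = None

    def __post_init__(self):
        if not (self.mu1 > 0 and self.theta1 > 0 and self.rho_xn > 0 and self.N_m > 0):
            raise InputError("mu1, theta1, rho_xn, N_m must all be > 0")
        if self.gamma < 0:
            raise InputError("gamma must be >= 0")


def consortium_circuit(
    process_rhs: Callable[[np.ndarray, float, float], np.ndarray] | None = None,
    process_states: Sequence[str] = ("x1",),
    n_process_populations: int = 0,
    output: str = "x1",
    **overrides: float,
) -> CircuitModel:
    """Generic consortium controller around an n-species process network.

    States ``[N1, N2, <process...>]``.  ``process_rhs(x, N1, N2)`` returns
    the process derivatives; the default process is the single-species
    actuation plant ``dx1 = k N1 - gamma_p1 x1`` (X1 produced as a direct
    result of N1's growth, e.g. a constitutively secreted quorum-sensing
    molecule).  The first ``n_process_populations`` process states are cell
    densities that load the shared carrying capacity through the
    coefficients ``c_1..c_m`` (``c_jj`` of the controller strains is fixed
    at 1; supplying anything else is a configuration error).
    """
    defaults = dict(
        mu1=0.8, theta1=0.1, rho_xn=0.5, N_m=1000.0, gamma=0.2,
        k=0.01, gamma_p1=1.0, growth_hill_K=0.0,
    )
    for i in range(n_process_populations):
        defaults[f"c_{i + 1}"] = 1.0
    for key in overrides:
        if key.startswith("c_") and key not in defaults:
            raise ConfigurationError(
                f"competition coefficient {key!r} exceeds the declared "
                f"{n_process_populations} process population(s)"
            )
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params = {**defaults, **overrides}

    names = list(process_states)
    out_idx = 2 + names.index(output)

    if process_rhs is None:
        if names != ["x1"]:
            raise ConfigurationError("default process is single-species ('x1')")

        def process_rhs(x, N1, N2, p):
            return np.array([p["k"] * N1 - p["gamma_p1"] * x[0]])
    else:
        user_rhs = process_rhs

        def process_rhs(x, N1, N2, p):
            return np.asarray(user_rhs(x, N1, N2), float)

    def phi(y, p):
        load = y[0] + y[1]
        for i in range(n_process_populations):
            load += p[f"c_{i + 1}"] * y[2 + i]
        return 1.0 - load / p["N_m"]

    def rhs(t, y, p):
        N1, N2 = y[0], y[1]
        x = y[2:]
        xn = y[out_idx]
        ph = phi(y, p)
        K = p["growth_hill_K"] or None
        dN1 = N1 * (p["mu1"] * ph - p["theta1"] * xn - p["gamma"])
        dN2 = N2 * (p["rho_xn"] * _growth_response(xn, K) * ph - p["gamma"])
        dx = process_rhs(x, N1, N2, p)
        return np.concatenate(([dN1, dN2], dx))

    return CircuitModel(
        name="consortium",
        state_names=["N1", "N2"] + names,
        params=params,
        rhs=rhs,
        derived={"phi": phi,
                 "N_tot": lambda y, p: y[0] + y[1]
                 + sum(y[2 + i] for i in range(n_process_populations))},
        output=output,
    )


def consortium_setpoint(mu1: float, theta1: float, rho_xn: float, gamma: float) -> float:
    """Regulated output level encoded by the controller strains.

    Positive root of ``theta1 rho x^2 + gamma rho x - mu1 gamma = 0``.
    Independent of the process network, the carrying capacity and the
    competition coefficients.  Requires ``gamma > 0``: the dilution term
    plays the role of the buffer species' turnover, without which no
    positive set-point is encoded.
    """
    if not gamma > 0:
        raise DomainError("set-point is defined for gamma > 0 only")
    a = theta1 * rho_xn
    b = gamma * rho_xn
    c = -mu1 * gamma
    return (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)


# ---------------------------------------------------------------------------
# Three-strain population control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationControlParams:
    """Three strains, two AHL channels: N1/N2 regulate the density of N3.

    A3 (secreted by the target strain N3) kills N1 at gain ``theta1`` and
    induces N2's growth at gain ``rho3`` — the sensing channel.  A1
    (secreted by N1) induces N3's growth at gain ``rho1`` — the actuation
    channel.  ``N_m3`` may differ from the controller strains' capacity.
    """

    mu1: float = 0.8
    theta1: float = 0.2
    rho1: float = 1.0
    rho3: float = 0.5
    sigma1: float = 0.01
    delta1: float = 5.0
    sigma3: float = 0.01
    delta3: float = 5.0
    N_m: float = 1000.0
    N_m3: float = 3000.0
    c13: float = 1.0
    c31: float = 1.0
    gamma: float = 0.1

    def __post_init__(self):
        for name in ("mu1", "theta1", "rho1", "rho3", "sigma1", "delta1",
                     "sigma3", "delta3", "N_m", "N_m3"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0")
        if self.c13 < 0 or self.c31 < 0 or self.gamma < 0:
            raise InputError("c13, c31, gamma must be >= 0")


def population_control_circuit(**overrides: float) -> CircuitModel:
    """Closed-loop three-strain circuit; states ``[N1, N2, N3, a1, a3]``.

    AHL levels follow birth-death dynamics whose birth rate is proportional
    to the density of the source strain.  The regulated quantity is the
    steady A3 level (and through it N3's density); it is insensitive to
    N3's growth parameters and to ``c13``, ``c31``, ``N_m3``.
    """
    defaults = {f.name: getattr(PopulationControlParams(), f.name)
                for f in PopulationControlParams.__dataclass_fields__.values()}
    defaults["growth_hill_K"] = 0.0
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params = {**defaults, **overrides}

    def rhs(t, y, p):
        N1, N2, N3, a1, a3 = y
        K = p["growth_hill_K"] or None
        phi_c = 1.0 - (N1 + N2 + p["c13"] * N3) / p["N_m"]
        phi_3 = 1.0 - (p["c31"] * (N1 + N2) + N3) / p["N_m3"]
        dN1 = N1 * (p["mu1"] * phi_c - p["theta1"] * a3 - p["gamma"])
        dN2 = N2 * (p["rho3"] * _growth_response(a3, K) * phi_c - p["gamma"])
        dN3 = N3 * (p["rho1"] * _growth_response(a1, K) * phi_3 - p["gamma"])
        da1 = p["sigma1"] * N1 - p["delta1"] * a1
        da3 = p["sigma3"] * N3 - p["delta3"] * a3
        return np.array([dN1, dN2, dN3, da1, da3])

    return CircuitModel(
        name="population_control",
        state_names=["N1", "N2", "N3", "a1", "a3"],
        params=params,
        rhs=rhs,
        derived={"N_tot": lambda y, p: y[0] + y[1] + y[2]},
        output="a3",
    )


def population_control_setpoint(params: dict | None = None, **overrides) -> dict:
    """Closed-form regulated levels of the three-strain circuit.

    Returns ``a3`` (the sensed AHL steady state, from the same quadratic as
    the generic consortium set-point with ``rho = rho3``) and the target
    density ``N3 = delta3 a3 / sigma3`` it encodes.
    """
    p = {f.name: getattr(PopulationControlParams(), f.name)
         for f in PopulationControlParams.__dataclass_fields__.values()}
    if params:
        p.update(params)
    p.update(overrides)
    a3 = consortium_setpoint(p["mu1"], p["theta1"], p["rho3"], p["gamma"])
    return {"a3": a3, "N3": p["delta3"] * a3 / p["sigma3"]}


# ---------------------------------------------------------------------------
# Four-strain coculture composition control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CocultureRatioParams:
    """Four strains, four AHL channels: regulate the ratio N3/N4.

    Wiring (all channels are constitutively secreted AHLs, one per strain):

    * actuation — A1 (from N1) induces N3's growth at ``rho1``; A2 (from
      N2) induces N4's growth at ``rho2``;
    * sensing — A4 (from N4) induces N1's growth at ``rho4``; A3 (from N3)
      induces N2's growth at ``rho3``;
    * cross-antagonism — A3 kills N1 at ``theta13``; A4 kills N2 at
      ``theta24`` (the toxin legs that let the two controller strains
      encode a ratio rather than a single level).

    The process strains are diluted at rate ``gamma``; the controller
    strains are retained (``retentive_controller``), which is what makes
    the composition control perfect rather than approximate.
    """

    rho1: float = 2.0
    rho2: float = 2.0
    rho3: float = 0.5
    rho4: float = 2.0
    theta13: float = 0.2
    theta24: float = 0.2
    sigma: tuple[float, float, float, float] = (0.05, 0.05, 0.05, 0.05)
    delta: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 10.0)
    N_m: float = 1000.0
    N_mp: float = 1000.0
    c_cp: float = 1.0
    c_pc: float = 1.0
    gamma: float = 0.1
    retentive_controller: bool = True

    def __post_init__(self):
        for name in ("rho1", "rho2", "rho3", "rho4", "theta13", "theta24",
                     "N_m", "N_mp"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0")
        if any(s <= 0 for s in self.sigma) or any(d <= 0 for d in self.delta):
            raise InputError("AHL secretion and decay rates must be > 0")
        if self.gamma < 0 or self.c_cp < 0 or self.c_pc < 0:
            raise InputError("gamma and competition coefficients must be >= 0")


def coculture_ratio_circuit(**overrides) -> CircuitModel:
    """Closed-loop four-strain circuit; states ``[N1..N4, a1..a4]``.

    Controller strains N1/N2 share capacity ``N_m`` (process strains load
    it with coefficient ``c_cp``); process strains N3/N4 share ``N_mp``
    (controller load coefficient ``c_pc``).  Setting
    ``retentive_controller=0`` also dilutes N1/N2, which degrades the
    perfect ratiometric adaptation into an approximate one.
    """
    base = CocultureRatioParams()
    defaults: dict[str, float] = dict(
        rho1=base.rho1, rho2=base.rho2, rho3=base.rho3, rho4=base.rho4,
        theta13=base.theta13, theta24=base.theta24,
        N_m=base.N_m, N_mp=base.N_mp, c_cp=base.c_cp, c_pc=base.c_pc,
        gamma=base.gamma, retentive_controller=1.0,
    )
    for i in range(4):
        defaults[f"sigma{i + 1}"] = base.sigma[i]
        defaults[f"delta{i + 1}"] = base.delta[i]
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params = {**defaults, **{k: float(v) for k, v in overrides.items()}}

    def rhs(t, y, p):
        N1, N2, N3, N4, a1, a2, a3, a4 = y
        phi_c = 1.0 - (N1 + N2 + p["c_cp"] * (N3 + N4)) / p["N_m"]
        phi_p = 1.0 - (p["c_pc"] * (N1 + N2) + N3 + N4) / p["N_mp"]
        g_ctl = 0.0 if p["retentive_controller"] else p["gamma"]
        dN1 = N1 * (p["rho4"] * a4 * phi_c - p["theta13"] * a3 - g_ctl)
        dN2 = N2 * (p["rho3"] * a3 * phi_c - p["theta24"] * a4 - g_ctl)
        dN3 = N3 * (p["rho1"] * a1 * phi_p - p["gamma"])
        dN4 = N4 * (p["rho2"] * a2 * phi_p - p["gamma"])
        da = [p[f"sigma{i + 1}"] * y[i] - p[f"delta{i + 1}"] * y[4 + i]
              for i in range(4)]
        return np.array([dN1, dN2, dN3, dN4, *da])

    return CircuitModel(
        name="coculture_ratio",
        state_names=["N1", "N2", "N3", "N4", "a1", "a2", "a3", "a4"],
        params=params,
        rhs=rhs,
        derived={
            "N_tot": lambda y, p: float(np.sum(y[:4])),
            "ratio": lambda y, p: y[2] / y[3] if y[3] > 0 else np.nan,
        },
        output="ratio",
    )


def population_ratio_setpoint(params: dict | CocultureRatioParams | None = None,
                              **overrides) -> float:
    """Commanded composition ratio ``Gamma = N3*/N4*``.

    Dividing the two controller-strain equilibrium relations eliminates the
    shared capacity factor and gives ``a3*/a4* = sqrt(rho4 theta24 /
    (rho3 theta13))``; converting AHL levels back to source densities yields

        Gamma = (delta3 sigma4 / (sigma3 delta4))
                * sqrt(rho4 theta24 / (rho3 theta13)).

    Controller parameters only — the process strains' growth parameters,
    ``gamma`` and the actuation gains drop out.  Admissibility of the
    commanded ratio requires ``rho3 rho4 > theta13 theta24`` (the shared
    capacity factor ``phi_c* = sqrt(theta13 theta24/(rho3 rho4))`` must be
    below one, i.e. growth induction strong enough relative to the toxin
    legs); violating it is flagged with the failed inequality.
    """
    if isinstance(params, CocultureRatioParams):
        p = dict(
            rho3=params.rho3, rho4=params.rho4,
            theta13=params.theta13, theta24=params.theta24,
            sigma3=params.sigma[2], sigma4=params.sigma[3],
            delta3=params.delta[2], delta4=params.delta[3],
        )
    else:
        base = CocultureRatioParams()
        p = dict(rho3=base.rho3, rho4=base.rho4,
                 theta13=base.theta13, theta24=base.theta24,
                 sigma3=base.sigma[2], sigma4=base.sigma[3],
                 delta3=base.delta[2], delta4=base.delta[3])
        if params:
            p.update({k: v for k, v in params.items() if k in p})
    p.update({k: v for k, v in overrides.items() if k in p})
    bad = set(overrides) - set(p)
    if bad:
        raise ConfigurationError(f"unknown parameters: {sorted(bad)}")
    if not p["rho3"] * p["rho4"] > p["theta13"] * p["theta24"]:
        raise DomainError(
            "inadmissible reference: requires rho3*rho4 > theta13*theta24 "
            f"(got {p['rho3'] * p['rho4']:.4g} <= {p['theta13'] * p['theta24']:.4g}); "
            "increase rho3 or rho4"
        )
    return (p["delta3"] * p["sigma4"] / (p["sigma3"] * p["delta4"])
            * math.sqrt(p["rho4"] * p["theta24"] / (p["rho3"] * p["theta13"])))


def calibrate_rho4(target_ratio: float, **fixed) -> float:
    """Actuation-side gain ``rho4`` that commands a given ratio ``Gamma``."""
    base = CocultureRatioParams()
    p = dict(rho3=base.rho3, theta13=base.theta13, theta24=base.theta24,
             sigma3=base.sigma[2], sigma4=base.sigma[3],
             delta3=base.delta[2], delta4=base.delta[3])
    p.update({k: v for k, v in fixed.items() if k in p})
    if not target_ratio > 0:
        raise InputError("target ratio must be > 0")
    scale = p["delta3"] * p["sigma4"] / (p["sigma3"] * p["delta4"])
    return (target_ratio / scale) ** 2 * p["rho3"] * p["theta13"] / p["theta24"]


def extinct_populations(model: CircuitModel, state: np.ndarray,
                        capacity: float | None = None) -> list[str]:
    """Names of population states below the extinction reporting threshold."""
    cap = capacity if capacity is not None else model.params.get("N_m", 1.0)
    out = []
    for i, name in enumerate(model.state_names):
        if name.startswith("N") and state[i] < EXTINCTION_FRACTION * cap:
            out.append(name)
    return out
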