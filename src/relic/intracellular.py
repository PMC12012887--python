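"""Embedded intracellular control circuits.

Two application circuits are assembled here as ready-to-simulate
:class:`~relic.model.CircuitModel` templates:

* :func:`layered_gene_expression_circuit` — the layered autocatalytic
  controller closed around a single-gene expression plant
  ``f(x1, r) = b_p1* r - gamma_p1 x1`` with resource-limited actuation
  ``k* z1 r``, sharing one translational resource pool with L external load
  modules whose only footprint is the aggregate zeroth-order load ``Q0``.
* :func:`operon_ratio_circuit` — two genes co-expressed from one
  polycistronic transcript, with the ratiometric controller acting through
  a Z1-activated auxiliary transcript; transcription and translation draw
  from two separate resource pools R1 and R2.

Also provided: the minimal-motif version of the gene-expression circuit
(for demonstrating imperfect adaptation under competition), closed-form
equilibria and the feasibility / stability criteria of the layered loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, InputError
from .model import CircuitModel
from .motifs import (
    LayeredMotifParams,
    MinimalMotifParams,
    RatiometricParams,
    ResponseFunction,
    LINEAR,
    layered_setpoint,
)
from .resources import ResourcePool

__all__ = [
    "GeneExpressionPlantParams",
    "ExternalLoadSpec",
    "OperonCircuitParams",
    "minimal_gene_expression_circuit",
    "layered_gene_expression_circuit",
    "layered_equilibrium",
    "feasibility_conditions",
    "stability_criterion",
    "ratiometric_gene_expression_circuit",
    "operon_ratio_circuit",
    "operon_open_loop_ratio",
]


@dataclass(frozen=True)
class GeneExpressionPlantParams:
    """Single-gene expression plant: resource-limited birth, first-order death."""

    b_p1_star: float
    gamma_p1: float
    k_star: float
    w_x1: float = 0.0

    def __post_init__(self):
        if not self.gamma_p1 > 0:
            raise InputError(f"gamma_p1 must be > 0, got {self.gamma_p1}")
        if self.b_p1_star < 0 or self.k_star < 0 or self.w_x1 < 0:
            raise InputError("plant rates and gains must be >= 0")


@dataclass(frozen=True)
class ExternalLoadSpec:
    """L external genetic modules coupled only through shared resources.

    Each module contributes a constant zeroth-order occupancy; the aggregate
    is the scalar ``Q0`` that rescales the pool's effective capacity.
    Individual module dynamics never enter the controlled circuit.
    """

    L: int = 0
    Q0_per_module: float = 0.0

    def __post_init__(self):
        if self.L < 0 or self.Q0_per_module < 0:
            raise InputError("load count and per-module occupancy must be >= 0")

    @property
    def Q0(self) -> float:
        return self.L * self.Q0_per_module


# ---------------------------------------------------------------------------
# Minimal-motif gene expression (imperfect adaptation under competition)
# ---------------------------------------------------------------------------

_MINIMAL_DEFAULTS = dict(
    alpha1_star=1.0, sense_gain=1.0, k_star=1.0,
    b_p1_star=0.1, gamma_p1=1.0,
    w_z1=5.0, w_bar_lin=1.0, w_bar_quad=0.1,
    R_tot=100.0, Q0=0.0,
)


def minimal_gene_expression_circuit(**overrides: float) -> CircuitModel:
    """Minimal autocatalytic controller closed around the expression plant.

    States ``[x1, z1]``.  With all competition gains zero the loop achieves
    robust perfect adaptation; with nonzero gains the steady output inherits
    process parameters and a step in ``k_star`` leaves a residual error.
    """
    params = dict(_MINIMAL_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params.update(overrides)

    def free_r(y, p):
        x1, z1 = y
        return p["R_tot"] / (1.0 + p["Q0"] + p["w_z1"] * z1
                             + p["w_bar_lin"] * x1 + p["w_bar_quad"] * x1 * x1)

    def rhs(t, y, p):
        x1, z1 = y
        r = free_r(y, p)
        dx1 = p["b_p1_star"] * r + p["k_star"] * z1 * r - p["gamma_p1"] * x1
        dz1 = z1 * (p["alpha1_star"] * r - p["sense_gain"] * x1)
        return np.array([dx1, dz1])

    return CircuitModel(
        name="minimal_gene_expression",
        state_names=["x1", "z1"],
        params=params,
        rhs=rhs,
        derived={"r": free_r},
        output="x1",
    )


# ---------------------------------------------------------------------------
# Layered motif, embedded gene-expression control (with external loads)
# ---------------------------------------------------------------------------

_LAYERED_DEFAULTS = dict(
    alpha1_star=1.0, alpha2_star=0.25, gamma_c2=0.25, sense_gain=1.0,
    k_star=1.0, b_p1_star=0.1, gamma_p1=1.0,
    w1=1.0, w2=1.0, w_x1=0.0,
    R_tot=100.0, Q0=0.0,
)


def layered_gene_expression_circuit(**overrides: float) -> CircuitModel:
    """Layered autocatalytic controller embedded with the expression plant.

    States ``[x1, z1, z2]``; dynamics::

        r    = R_tot / (1 + Q0 + w1 z1 + w2 z2 + w_x1 x1)
        dx1  = b_p1* r + k* z1 r - gamma_p1 x1
        dz1  = z1 (alpha1* r - theta x1)
        dz2  = z2 (alpha2* x1 r - gamma_c2)

    External load modules enter only through ``Q0``; a step in ``Q0`` is
    equivalent to simultaneously rescaling ``w1``, ``w2`` and ``R_tot``.
    With no loads (``Q0 = 0``) this is exactly the layered closed loop.
    """
    params = dict(_LAYERED_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params.update(overrides)

    def free_r(y, p):
        x1, z1, z2 = y
        return p["R_tot"] / (1.0 + p["Q0"] + p["w1"] * z1 + p["w2"] * z2
                             + p["w_x1"] * x1)

    def rhs(t, y, p):
        x1, z1, z2 = y
        r = free_r(y, p)
        dx1 = p["b_p1_star"] * r + p["k_star"] * z1 * r - p["gamma_p1"] * x1
        dz1 = z1 * (p["alpha1_star"] * r - p["sense_gain"] * x1)
        dz2 = z2 * (p["alpha2_star"] * x1 * r - p["gamma_c2"])
        return np.array([dx1, dz1, dz2])

    return CircuitModel(
        name="layered_gene_expression",
        state_names=["x1", "z1", "z2"],
        params=params,
        rhs=rhs,
        derived={"r": free_r},
        output="x1",
    )


def embedded_control_circuit(
    plant: GeneExpressionPlantParams,
    loads: ExternalLoadSpec,
    controller: LayeredMotifParams,
    pool: ResourcePool,
) -> CircuitModel:
    """Typed assembly of the embedded control loop from its building blocks."""
    return layered_gene_expression_circuit(
        alpha1_star=controller.alpha1_star,
        alpha2_star=controller.alpha2_star,
        gamma_c2=controller.gamma_c2,
        sense_gain=controller.sense_gain,
        k_star=controller.k_star,
        w1=controller.w1,
        w2=controller.w2,
        b_p1_star=plant.b_p1_star,
        gamma_p1=plant.gamma_p1,
        w_x1=plant.w_x1,
        R_tot=pool.R_tot,
        Q0=pool.Q0 + loads.Q0,
    )


def _controller_from(p: dict) -> LayeredMotifParams:
    return LayeredMotifParams(
        alpha1_star=p["alpha1_star"], alpha2_star=p["alpha2_star"],
        gamma_c2=p["gamma_c2"], sense_gain=p["sense_gain"], k_star=p["k_star"],
        w1=p["w1"], w2=p["w2"],
    )


def layered_equilibrium(params: dict | None = None, **overrides) -> dict:
    """Closed-form strictly positive equilibrium of the layered closed loop.

    Returns a dict with ``x1, z1, z2, r`` and the feasibility booleans.
    ``z1`` and ``z2`` must come out positive for the desired equilibrium to
    exist; the exact conditions are::

        z1* = (gamma_p1 Sigma - b_p1* r*) / (k* r*)      > 0
        z2* = (R_eff/r* - 1 - w1 z1* - w_x1 Sigma) / w2  > 0

    Requires ``w2 > 0`` (with no Z2 competition the buffer layer cannot set
    the resource level).
    """
    p = dict(_LAYERED_DEFAULTS)
    if params:
        p.update(params)
    p.update(overrides)
    if not p["w2"] > 0:
        raise DomainError("closed-form equilibrium requires w2 > 0")
    sp = layered_setpoint(_controller_from(p))
    sigma, r_star = sp.sigma, sp.r_star
    z1 = (p["gamma_p1"] * sigma - p["b_p1_star"] * r_star) / (p["k_star"] * r_star)
    z2 = (p["R_tot"] / r_star - 1.0 - p["Q0"] - p["w1"] * z1
          - p["w_x1"] * sigma) / p["w2"]
    return {
        "x1": sigma, "z1": z1, "z2": z2, "r": r_star,
        "feasible": bool(z1 > 0 and z2 > 0),
    }


def feasibility_conditions(
    plant: GeneExpressionPlantParams,
    controller: LayeredMotifParams,
    pool: ResourcePool,
) -> tuple[bool, bool]:
    """The two sufficient conditions for a feasible desired equilibrium.

    1. ``gamma_p1 * alpha2* * Sigma**2 > b_p1* * gamma_c2`` — the plant's
       basal production alone must not overshoot the set-point (equivalently
       ``z1* > 0``).
    2. ``R_tot > r* + w1 gamma_p1 Sigma / k*`` — the pool is large enough to
       carry the regulated free-resource level plus the occupancy of the
       main loop (a conservative bound for ``z2* > 0``; as ``k* -> inf`` it
       reduces to ``R_tot > r*``).
    """
    sp = layered_setpoint(controller)
    cond1 = (plant.gamma_p1 * controller.alpha2_star * sp.sigma ** 2
             > plant.b_p1_star * controller.gamma_c2)
    cond2 = (pool.R_tot
             > sp.r_star + controller.w1 * plant.gamma_p1 * sp.sigma / controller.k_star)
    return bool(cond1), bool(cond2)


def stability_criterion(
    plant: GeneExpressionPlantParams,
    controller: LayeredMotifParams,
) -> bool:
    """Sufficient local stability condition ``2 gamma_c2 <= gamma_p1``.

    Given a feasible positive equilibrium, this single inequality on the
    buffer turnover versus the plant turnover guarantees that all Jacobian
    eigenvalues at the desired equilibrium have negative real part.  It is
    sufficient only: when it fails, stability must be checked numerically.
    """
    return bool(2.0 * controller.gamma_c2 <= plant.gamma_p1)


# ---------------------------------------------------------------------------
# Ratiometric gene expression (single pool)
# ---------------------------------------------------------------------------

_RATIO_DEFAULTS = dict(
    alpha1_star=1.0, alpha2_star=0.5, gamma_c2=1.0, sense_gain=0.5,
    k_star=1.0, b_p1_star=0.0, b_p2_star=1.0,
    gamma_x1=1.0, gamma_x2=1.0, w1=1.0, w2=1.0,
    R_tot=100.0, Q0=0.0,
)


def ratiometric_gene_expression_circuit(
    H1: ResponseFunction = LINEAR, H2: ResponseFunction = LINEAR,
    G1: ResponseFunction = LINEAR, G2: ResponseFunction = LINEAR,
    **overrides: float,
) -> CircuitModel:
    """Ratiometric controller around two independently expressed genes.

    States ``[x1, x2, z1, z2]``; X2 is expressed constitutively, X1 is
    actuated by Z1 (resource-limited, ``k* z1 r``).  At any strictly
    positive equilibrium ``x1*/x2*`` sits on the ratio manifold; for linear
    response maps the ratio equals
    ``Gamma = sqrt(alpha1* gamma_c2 g1 g2 / (alpha2* theta h1 h2))``.
    """
    params = dict(_RATIO_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params.update(overrides)
    maps = {"H1": H1, "H2": H2, "G1": G1, "G2": G2}

    def free_r(y, p):
        x1, x2, z1, z2 = y
        return (p["R_tot"] / (1.0 + p["Q0"])
                / (1.0 + p["w1"] * z1 + p["w2"] * z2))

    def rhs(t, y, p):
        x1, x2, z1, z2 = y
        r = free_r(y, p)
        dx1 = p["b_p1_star"] * r + p["k_star"] * z1 * r - p["gamma_x1"] * x1
        dx2 = p["b_p2_star"] * r - p["gamma_x2"] * x2
        dz1 = z1 * (p["alpha1_star"] * maps["G1"](x2) * r
                    - p["sense_gain"] * maps["H1"](x1))
        dz2 = z2 * (p["alpha2_star"] * maps["H2"](x1) * r
                    - p["gamma_c2"] * maps["G2"](x2))
        return np.array([dx1, dx2, dz1, dz2])

    return CircuitModel(
        name="ratiometric_gene_expression",
        state_names=["x1", "x2", "z1", "z2"],
        params=params,
        rhs=rhs,
        derived={"r": free_r,
                 "ratio": lambda y, p: y[0] / y[1] if y[1] > 0 else np.nan},
        output="x1",
        meta={"maps": maps},
    )


# ---------------------------------------------------------------------------
# Operon gene-ratio circuit (two resource pools)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperonCircuitParams:
    """Two genes on one polycistronic transcript plus the ratiometric controller.

    ``eta1_star`` / ``eta2_star`` are the translation rates of X1 and X2
    from the shared transcript M_P (both read the *same* transcript state,
    which is what cancels transcriptional competition from the open-loop
    ratio); ``T_star`` and ``delta_mp`` govern M_P itself.  Actuation is a
    Z1-activated auxiliary transcript M_A translated into extra X1.  Pools:
    R1 (transcription) and R2 (translation).
    """

    eta1_star: float = 1.0
    eta2_star: float = 1.0
    gamma_x1: float = 1.0
    gamma_x2: float = 1.0
    T_star: float = 1.0
    delta_mp: float = 1.0
    eta_a_star: float = 1.0
    delta_ma: float = 1.0
    controller: RatiometricParams = None  # type: ignore[assignment]
    pool_tx: ResourcePool = None  # type: ignore[assignment]
    pool_tl: ResourcePool = None  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("eta1_star", "eta2_star", "gamma_x1", "gamma_x2",
                     "T_star", "delta_mp", "eta_a_star", "delta_ma"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0")
        if self.controller is None:
            object.__setattr__(self, "controller", RatiometricParams(
                alpha1_star=1.0, alpha2_star=0.5, gamma_c2=1.0,
                sense_gain=0.5, k_star=1.0, w1=1.0, w2=1.0,
            ))
        if self.pool_tx is None:
            object.__setattr__(self, "pool_tx", ResourcePool("R1", 10.0))
        if self.pool_tl is None:
            object.__setattr__(self, "pool_tl", ResourcePool("R2", 10.0))
        if self.pool_tx.pool_id == self.pool_tl.pool_id:
            raise ConfigurationError(
                "operon circuit needs two distinct resource pools "
                f"(got {self.pool_tx.pool_id!r} twice)"
            )


_OPERON_DEFAULTS = dict(
    eta1_star=1.0, eta2_star=1.0, gamma_x1=1.0, gamma_x2=1.0,
    T_star=1.0, delta_mp=1.0, eta_a_star=1.0, delta_ma=1.0,
    alpha1_star=1.0, alpha2_star=0.5, gamma_c2=1.0, sense_gain=0.5, k_star=1.0,
    R1_tot=10.0, Q01=0.0, R2_tot=10.0, Q02=0.0,
    w_gene=0.1, w_act=0.2, w_c1_tx=0.5, w_c2_tx=0.5,
    w_mp=0.5, w_ma=0.5, w_c1_tl=0.5, w_c2_tl=0.5,
    mrna_qss=0.0,
)


def operon_ratio_circuit(
    H1: ResponseFunction = LINEAR, H2: ResponseFunction = LINEAR,
    G1: ResponseFunction = LINEAR, G2: ResponseFunction = LINEAR,
    **overrides: float,
) -> CircuitModel:
    """Closed-loop operon gene-ratio circuit with two resource pools.

    States ``[m_p, m_a, x1, x2, z1, z2]``.  The controller genes are
    transcribed from R1 and translated from R2, so their effective
    production laws carry the product ``r1 r2``; dividing the two controller
    equilibrium relations eliminates that product, which is why the steady
    ratio is immune to disturbances in either pool, while the product
    ``r1* r2*`` itself is pinned to ``gamma_c2 G2(x2*)/(alpha2* H2(x1*))``
    — a constant tied to the commanded ratio.

    Set ``mrna_qss=1`` to slave both transcripts to their quasi-steady
    state (the reduction used for fast mRNA turnover).
    """
    params = dict(_OPERON_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    params.update(overrides)
    maps = {"H1": H1, "H2": H2, "G1": G1, "G2": G2}

    def pools(y, p):
        m_p, m_a, x1, x2, z1, z2 = y
        occ_c1 = z1 * maps["G1"](x2)
        occ_c2 = z2 * maps["H2"](x1)
        r1 = p["R1_tot"] / (1.0 + p["Q01"] + p["w_gene"] + p["w_act"] * z1
                            + p["w_c1_tx"] * occ_c1 + p["w_c2_tx"] * occ_c2)
        r2 = p["R2_tot"] / (1.0 + p["Q02"] + p["w_mp"] * m_p + p["w_ma"] * m_a
                            + p["w_c1_tl"] * occ_c1 + p["w_c2_tl"] * occ_c2)
        return r1, r2

    def rhs(t, y, p):
        m_p, m_a, x1, x2, z1, z2 = y
        r1, r2 = pools(y, p)
        if p["mrna_qss"]:
            m_p = p["T_star"] * r1 / p["delta_mp"]
            m_a = p["k_star"] * z1 * r1 / p["delta_ma"]
            dm_p = dm_a = 0.0
        else:
            dm_p = p["T_star"] * r1 - p["delta_mp"] * m_p
            dm_a = p["k_star"] * z1 * r1 - p["delta_ma"] * m_a
        dx1 = (p["eta1_star"] * m_p + p["eta_a_star"] * m_a) * r2 - p["gamma_x1"] * x1
        dx2 = p["eta2_star"] * m_p * r2 - p["gamma_x2"] * x2
        dz1 = z1 * (p["alpha1_star"] * maps["G1"](x2) * r1 * r2
                    - p["sense_gain"] * maps["H1"](x1))
        dz2 = z2 * (p["alpha2_star"] * maps["H2"](x1) * r1 * r2
                    - p["gamma_c2"] * maps["G2"](x2))
        return np.array([dm_p, dm_a, dx1, dx2, dz1, dz2])

    return CircuitModel(
        name="operon_ratio",
        state_names=["m_p", "m_a", "x1", "x2", "z1", "z2"],
        params=params,
        rhs=rhs,
        derived={
            "r1": lambda y, p: pools(y, p)[0],
            "r2": lambda y, p: pools(y, p)[1],
            "ratio": lambda y, p: y[2] / y[3] if y[3] > 0 else np.nan,
        },
        output="x1",
        meta={"maps": maps, "pools": ("R1", "R2")},
    )


def operon_open_loop_ratio(
    eta1_star: float, eta2_star: float, gamma_x1: float, gamma_x2: float
) -> float:
    """Open-loop steady-state ratio ``x1*/x2* = eta1* gamma_x2 / (eta2* gamma_x1)``.

    Both proteins are translated from the same transcript, so transcription
    (and transcriptional competition) cancels from the ratio; only the
    translation-rate and degradation-rate asymmetries remain.
    """
    if not (gamma_x1 > 0 and gamma_x2 > 0):
        raise DomainError("degradation rates must be > 0")
    if not (eta1_star > 0 and eta2_star > 0):
        raise InputError("translation rates must be > 0")
    return eta1_star * gamma_x2 / (eta2_star * gamma_x1)
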