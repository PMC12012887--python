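"""Autocatalytic integral-feedback controller motifs.

Three motifs are implemented, all built on positive autoregulation of the
controller species (which makes zero an absorbing state and confers
robustness to dilution):

* **Minimal motif** — a single species Z1 with resource-limited
  autocatalysis, catalytically inhibited by the regulated output X_n::

      dz1/dt = alpha1* z1 r  -  theta x_n z1

  In the resource-unlimited regime (all competition gains zero, r constant)
  the zero of ``d(ln z1)/dt`` pins ``x_n* = alpha1* r / theta`` and the loop
  performs integral feedback.  Once the autocatalysis competes for a shared
  pool, ``r`` becomes state-dependent and the set-point inherits process
  parameters: perfect adaptation is lost.

* **Layered motif** — a second autocatalytic species Z2 whose only link to
  the main loop is the shared resource pool.  Z2's production is bimolecular
  in (Z2, X_n) and it decays at a constant rate ``gamma_c2 > 0``::

      dz1/dt = alpha1* z1 r            -  theta x_n z1
      dz2/dt = alpha2* x_n z2 r        -  gamma_c2 z2

  The two equilibrium relations ``alpha1* r* = theta x_n*`` and
  ``x_n* r* = gamma_c2 / alpha2*`` jointly pin both the output and the free
  resource to values set by controller parameters alone:

      Sigma = sqrt(alpha1* gamma_c2 / (alpha2* theta)),
      r*    = gamma_c2 / (alpha2* Sigma).

  Z2 acts as an active resource buffer, restoring robust perfect adaptation
  under competition.

* **Ratiometric motif** — the layered motif with both constitutive legs
  replaced by read-outs of a second process species, steering the ratio
  ``x1*/x2*`` instead of a concentration::

      dz1/dt = z1 (alpha1* G1(x2) r  -  theta    H1(x1))
      dz2/dt = z2 (alpha2* H2(x1) r  -  gamma_c2 G2(x2))

  Any strictly positive equilibrium lies on the *ratio manifold*
  ``H1 H2 (x1*) = (alpha1* gamma_c2 / (alpha2* theta)) G1 G2 (x2*)``; with
  linear response maps this is a line through the origin and the ratio
  ``Gamma = sqrt(alpha1* gamma_c2 g1 g2 / (alpha2* theta h1 h2))`` is
  regulated perfectly.

Concentrations and time are in arbitrary units throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, InputError
from .resources import ResourcePool

__all__ = [
    "ResponseFunction",
    "LINEAR",
    "MinimalMotifParams",
    "LayeredMotifParams",
    "RatiometricParams",
    "SetpointReport",
    "minimal_motif_rhs",
    "layered_motif_rhs",
    "layered_setpoint",
    "ratiometric_rhs",
    "ratio_manifold",
    "ratio_setpoint_linear",
    "default_process_load",
]


@dataclass(frozen=True)
class ResponseFunction:
    """A monotone response map, either linear or Hill-saturating.

    ``linear``: ``f(x) = gain * x``.
    ``hill``:   ``f(x) = gain * x**n / (ec50**n + x**n)`` — saturating at
    ``gain`` with half-maximum at ``ec50``; its initial slope (n = 1) is
    ``gain / ec50``.
    """

    kind: str = "linear"
    gain: float = 1.0
    n: float = 1.0
    ec50: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "hill"):
            raise ConfigurationError(f"unknown response kind {self.kind!r}")
        if self.gain <= 0 or self.ec50 <= 0 or self.n <= 0:
            raise ConfigurationError("response parameters must be > 0 (monotone map)")

    def __call__(self, x: float) -> float:
        if self.kind == "linear":
            return self.gain * x
        xn = x ** self.n
        return self.gain * xn / (self.ec50 ** self.n + xn)

    @property
    def is_linear(self) -> bool:
        return self.kind == "linear"

    @property
    def slope0(self) -> float:
        """Initial slope at the origin (requires n == 1 for the Hill form)."""
        if self.kind == "linear":
            return self.gain
        if self.n != 1:
            raise DomainError("initial slope defined only for n = 1 Hill maps")
        return self.gain / self.ec50


LINEAR = ResponseFunction("linear", 1.0)


def _nonfinite_process_error(state, dx):
    from .errors import SimulationError

    return SimulationError(
        f"process RHS returned non-finite derivatives {dx!r}",
        last_state=np.asarray(state),
    )


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise InputError(f"{name} must be > 0, got {value}")


def _require_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise InputError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class MinimalMotifParams:
    """Parameters of the minimal (single-species) autocatalytic controller.

    ``w_z1`` is the competition gain of Z1's own autocatalysis;
    ``w_bar_lin`` and ``w_bar_quad`` aggregate the process-side competition
    (linear and quadratic denominator terms, the quadratic ones arising from
    bimolecular production reactions on the process side).
    """

    alpha1_star: float
    sense_gain: float
    k_star: float
    w_z1: float = 0.0
    w_bar_lin: float = 0.0
    w_bar_quad: float = 0.0

    def __post_init__(self):
        _require_positive(alpha1_star=self.alpha1_star, sense_gain=self.sense_gain,
                          k_star=self.k_star)
        _require_nonneg(w_z1=self.w_z1, w_bar_lin=self.w_bar_lin,
                        w_bar_quad=self.w_bar_quad)


@dataclass(frozen=True)
class LayeredMotifParams:
    """Parameters of the layered (two-species) autocatalytic controller."""

    alpha1_star: float
    alpha2_star: float
    gamma_c2: float
    sense_gain: float
    k_star: float
    w1: float = 0.0
    w2: float = 0.0

    def __post_init__(self):
        _require_positive(alpha1_star=self.alpha1_star, alpha2_star=self.alpha2_star,
                          gamma_c2=self.gamma_c2, sense_gain=self.sense_gain,
                          k_star=self.k_star)
        _require_nonneg(w1=self.w1, w2=self.w2)


@dataclass(frozen=True)
class RatiometricParams:
    """Parameters of the ratiometric variant of the layered controller.

    ``H1, H2`` read the first process species, ``G1, G2`` the second; all
    four must be monotone with ``f(0) = 0`` in the linear case.  Controller
    degradation/dilution is assumed negligible; the only Z2 turnover is the
    X2-modulated term ``gamma_c2 G2(x2) z2``.
    """

    alpha1_star: float
    alpha2_star: float
    gamma_c2: float
    sense_gain: float
    k_star: float
    w1: float = 0.0
    w2: float = 0.0
    H1: ResponseFunction = LINEAR
    H2: ResponseFunction = LINEAR
    G1: ResponseFunction = LINEAR
    G2: ResponseFunction = LINEAR

    def __post_init__(self):
        _require_positive(alpha1_star=self.alpha1_star, alpha2_star=self.alpha2_star,
                          gamma_c2=self.gamma_c2, sense_gain=self.sense_gain,
                          k_star=self.k_star)
        _require_nonneg(w1=self.w1, w2=self.w2)
        for name in ("H1", "H2", "G1", "G2"):
            fn = getattr(self, name)
            if not isinstance(fn, ResponseFunction):
                raise ConfigurationError(f"{name} must be a ResponseFunction")

    @property
    def all_linear(self) -> bool:
        return all(getattr(self, n).is_linear for n in ("H1", "H2", "G1", "G2"))

    @property
    def manifold_constant(self) -> float:
        """C in the manifold relation H1 H2 (x1*) = C * G1 G2 (x2*)."""
        return self.alpha1_star * self.gamma_c2 / (self.alpha2_star * self.sense_gain)


@dataclass(frozen=True)
class SetpointReport:
    """Closed-form set-point of the layered motif."""

    sigma: float
    r_star: float

    def __post_init__(self):
        _require_positive(sigma=self.sigma, r_star=self.r_star)


def default_process_load(x: np.ndarray) -> tuple[float, float]:
    """Aggregate process-side substrate load: (linear sum, pairwise products).

    The quadratic aggregate includes self-pairs, matching bimolecular
    production whose two substrates coincide.
    """
    x = np.asarray(x, float)
    lin = float(np.sum(x))
    quad = 0.5 * (lin * lin + float(np.sum(x * x)))
    return lin, quad


def minimal_motif_rhs(
    state: np.ndarray,
    params: MinimalMotifParams,
    pool: ResourcePool,
    process_rhs: Callable[[np.ndarray, float, float], np.ndarray],
    process_load: Callable[[np.ndarray], tuple[float, float]] = default_process_load,
    output_index: int = -1,
) -> np.ndarray:
    """Closed-loop derivatives of the minimal motif around an arbitrary plant.

    ``state`` is ``[z1, x...]``; the regulated output is ``x[output_index]``.
    The plant callback receives ``(x, r, u)`` with actuation
    ``u = k_star * z1 * r`` (resource-limited actuation).  ``z1 = 0`` is
    absorbing.
    """
    state = np.asarray(state, float)
    z1, x = state[0], state[1:]
    xn = x[output_index]
    lin, quad = process_load(x)
    denom = 1.0 + params.w_z1 * z1 + params.w_bar_lin * lin + params.w_bar_quad * quad
    r = pool.R_eff / denom
    u = params.k_star * z1 * r
    dx = np.asarray(process_rhs(x, r, u), float)
    if not np.all(np.isfinite(dx)):
        raise _nonfinite_process_error(state, dx)
    dz1 = z1 * (params.alpha1_star * r - params.sense_gain * xn)
    return np.concatenate(([dz1], dx))


def layered_motif_rhs(
    state: np.ndarray,
    params: LayeredMotifParams,
    pool: ResourcePool,
    process_rhs: Callable[[np.ndarray, float, float], np.ndarray],
    output_index: int = -1,
    extra_load: Callable[[np.ndarray], float] | None = None,
) -> np.ndarray:
    """Closed-loop derivatives of the layered motif: state = [z1, z2, x...].

    Resource sharing is the only interaction between the two controller
    layers; both ``z1 = 0`` and ``z2 = 0`` are absorbing.  ``extra_load``
    optionally adds further (process-side) occupancy terms to the resource
    denominator.
    """
    state = np.asarray(state, float)
    z1, z2, x = state[0], state[1], state[2:]
    xn = x[output_index]
    denom = 1.0 + params.w1 * z1 + params.w2 * z2
    if extra_load is not None:
        denom += extra_load(x)
    r = pool.R_eff / denom
    u = params.k_star * z1 * r
    dx = np.asarray(process_rhs(x, r, u), float)
    if not np.all(np.isfinite(dx)):
        raise _nonfinite_process_error(state, dx)
    dz1 = z1 * (params.alpha1_star * r - params.sense_gain * xn)
    dz2 = z2 * (params.alpha2_star * xn * r - params.gamma_c2)
    return np.concatenate(([dz1, dz2], dx))


def layered_setpoint(params: LayeredMotifParams) -> SetpointReport:
    """Closed-form output set-point and regulated free-resource level.

    ``Sigma = sqrt(alpha1* gamma_c2 / (alpha2* theta))`` and
    ``r* = gamma_c2 / (alpha2* Sigma)``; both depend on controller
    parameters only, so the loop rejects steps in every process- or
    resource-side parameter (k*, gamma_p1, b_p1*, Q0, R_tot, w1, w2) as long
    as the post-step equilibrium stays feasible and stable.
    """
    sigma = math.sqrt(
        params.alpha1_star * params.gamma_c2
        / (params.alpha2_star * params.sense_gain)
    )
    r_star = params.gamma_c2 / (params.alpha2_star * sigma)
    return SetpointReport(sigma=sigma, r_star=r_star)


def ratiometric_rhs(
    state: np.ndarray,
    params: RatiometricParams,
    pool: ResourcePool,
    process_rhs: Callable[[np.ndarray, float, np.ndarray], np.ndarray],
    u: Callable[[np.ndarray, float], np.ndarray] | None = None,
    x1_index: int = 0,
    x2_index: int = 1,
) -> np.ndarray:
    """Closed-loop derivatives of the ratiometric motif: state = [z1, z2, x...].

    The stabilizing control input is a design choice of the embedding
    circuit; by default Z1 actuates the first process species with the
    resource-limited law ``u1 = k_star * z1 * r``.  The hook ``u(state, r)``
    may override it and must return one actuation term per process state.
    """
    state = np.asarray(state, float)
    z1, z2, x = state[0], state[1], state[2:]
    x1, x2 = x[x1_index], x[x2_index]
    denom = 1.0 + params.w1 * z1 + params.w2 * z2
    r = pool.R_eff / denom
    if u is None:
        act = np.zeros_like(x)
        act[x1_index] = params.k_star * z1 * r
    else:
        act = np.asarray(u(state, r), float)
    dx = np.asarray(process_rhs(x, r, act), float)
    if not np.all(np.isfinite(dx)):
        raise _nonfinite_process_error(state, dx)
    dz1 = z1 * (params.alpha1_star * params.G1(x2) * r
                - params.sense_gain * params.H1(x1))
    dz2 = z2 * (params.alpha2_star * params.H2(x1) * r
                - params.gamma_c2 * params.G2(x2))
    return np.concatenate(([dz1, dz2], dx))


def manifold_residual(params: RatiometricParams, x1: float, x2: float) -> float:
    """Residual of the ratio-manifold relation at a candidate steady state."""
    return (params.H1(x1) * params.H2(x1)
            - params.manifold_constant * params.G1(x2) * params.G2(x2))


def ratio_manifold(params: RatiometricParams, x2_star: float) -> float:
    """Map a steady X2 level to the steady X1 level on the ratio manifold.

    Solves ``H1 H2 (x1) = C G1 G2 (x2*)``.  With linear response maps this
    is the line ``x1 = Gamma x2*``; with saturating maps the target may
    exceed the range of ``H1 H2``, which raises :class:`DomainError`.
    """
    if not x2_star > 0:
        raise InputError(f"x2_star must be > 0, got {x2_star}")
    target = params.manifold_constant * params.G1(x2_star) * params.G2(x2_star)
    if params.H1.is_linear and params.H2.is_linear:
        return math.sqrt(target / (params.H1.gain * params.H2.gain))

    def hbar(x):
        return params.H1(x) * params.H2(x)

    # Hill maps saturate at their gain; a linear factor is unbounded.
    if not (params.H1.is_linear or params.H2.is_linear):
        sup = params.H1.gain * params.H2.gain
        if target >= sup:
            raise DomainError(
                f"ratio-manifold target {target:.4g} is outside the invertible "
                f"range of the saturating sensing maps (sup {sup:.4g})"
            )
    hi = 1.0
    while hbar(hi) < target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - guarded by the sup check above
            raise DomainError("sensing maps could not be inverted on the requested range")
    return float(brentq(lambda x: hbar(x) - target, 0.0, hi, xtol=1e-14, rtol=1e-14))


def ratio_setpoint_linear(params: RatiometricParams) -> float:
    """Regulated ratio Gamma for purely linear response maps.

    ``Gamma = sqrt(alpha1* gamma_c2 g1 g2 / (alpha2* theta h1 h2))`` depends
    on controller parameters only.  At the corresponding equilibrium the
    controller also pins the free resource, ``r* = gamma_c2 g2 /
    (alpha2* h2 Gamma)`` — the parallel resource regulation of the layered
    motif carries over.  Saturating maps are rejected; use
    :func:`ratio_manifold` instead.
    """
    if not params.all_linear:
        raise InputError("ratio_setpoint_linear requires linear H and G maps; "
                         "use ratio_manifold for saturating configurations")
    num = params.alpha1_star * params.gamma_c2 * params.G1.gain * params.G2.gain
    den = params.alpha2_star * params.sense_gain * params.H1.gain * params.H2.gain
    return math.sqrt(num / den)


def ratiometric_resource_setpoint(params: RatiometricParams) -> float:
    """Steady free-resource level of the linear ratiometric loop."""
    gamma = ratio_setpoint_linear(params)
    return (params.gamma_c2 * params.G2.gain) / (params.alpha2_star * params.H2.gain * gamma)
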