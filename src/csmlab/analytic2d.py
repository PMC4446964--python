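"""Closed-form 2D cell surface mechanics for an arbitrary shape class.

A single cell is described by the energy

    E(p, a) = J p + lambda_p (p - P)^2 + lambda_a (a - A)^2,

with adhesion energy J per unit contact length, membrane rest length P,
target area A and the two constraint weights.  Interfacial tension is
gamma = dE/dp = tau + 2 k_p lambda_p l with tau = J - 2 k_p lambda_p L_p,
and pressure Pi = -dE/da.

Restricting the cell to a one-parameter shape family p = k_p l,
a = k_a l^2 (circle: k_p = 2 pi, k_a = pi, l the radius; hexagon: k_p = 6,
k_a = 3 sqrt(3)/2, l the side length) reduces the equilibrium condition
dE/dl = 0 to a depressed cubic whose behaviour is governed by two aggregate
parameters only:

    tau  — the length-independent tension component, and
    eps  — the squared length of the inflection point of dE/dl.

Four regimes result.  Region I: tension at the on-manifold equilibrium is
negative, the regular shape is unstable and the cell instead satisfies both
constraints independently (a* = A, p* = P - J/(2 lambda_p)) with an
unpredictable ruffled shape.  Region II: a single stable regular equilibrium
with positive tension.  Region III: bistable — a stable positive equilibrium
coexists with the stable trivial one l* = 0, separated by an unstable
equilibrium.  Region IV: only l* = 0 is stable and the cell vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "MechParams2D",
    "ShapeClass2D",
    "CIRCLE",
    "HEXAGON",
    "Aggregates2D",
    "Equilibrium2D",
    "FarhadifarCoords",
    "tension_and_pressure",
    "aggregates",
    "equilibria",
    "classify_region",
    "bifurcation_lines",
    "farhadifar_map",
    "energy",
    "energy_gradient",
]

#: relative tolerance for on-boundary region classification
_BOUNDARY_RTOL = 1e-9
#: slack for clamping arccos/arcsin arguments that overshoot [-1, 1]
_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class MechParams2D:
    """The five biophysical parameters of the 2D energy function."""

    J: float
    lambda_p: float
    P: float
    lambda_a: float
    A: float

    def __post_init__(self):
        if self.lambda_a <= 0:
            raise ValueError("lambda_a must be > 0")
        if self.lambda_p < 0:
            raise ValueError("lambda_p must be >= 0")
        if self.A < 0:
            raise ValueError("target area A must be >= 0")


@dataclass(frozen=True)
class ShapeClass2D:
    """A one-parameter shape family p = k_p l, a = k_a l^2."""

    k_p: float
    k_a: float
    name: str = "custom"

    def __post_init__(self):
        if self.k_p <= 0 or self.k_a <= 0:
            raise ValueError("shape scaling constants must be positive")

    def L_p(self, params: MechParams2D) -> float:
        """Rest length expressed on the shape manifold: L_p = P / k_p."""
        return params.P / self.k_p

    def L_a(self, params: MechParams2D) -> float:
        """Target-area length scale: L_a = sqrt(A / k_a)."""
        return math.sqrt(params.A / self.k_a)


CIRCLE = ShapeClass2D(k_p=2 * math.pi, k_a=math.pi, name="circle")
HEXAGON = ShapeClass2D(k_p=6.0, k_a=3 * math.sqrt(3) / 2, name="hexagon")


@dataclass(frozen=True)
class Aggregates2D:
    """Aggregate parameters governing the 2D bifurcation structure.

    tau     : length-independent tension, J - 2 k_p lambda_p L_p.
    epsilon : squared inflection length, L_a^2/3 - k_p^2 lambda_p /
              (6 k_a^2 lambda_a).
    alpha   : dE/dl at l = sqrt(eps) when tau = 0; real (negative) only for
              eps >= 0, NaN otherwise.
    beta    : 4 k_a^2 lambda_a / k_p (curvature aggregate).
    zeta    : -(alpha/k_p)^2 continued to real arithmetic; positive for
              eps < 0, where it parametrises the single stable root.
    """

    tau: float
    epsilon: float
    alpha: float
    beta: float
    zeta: float

    @property
    def tau_fold(self) -> float:
        """Fold-bifurcation tension 2 beta eps^(3/2) (= -alpha/k_p); NaN if eps<0."""
        if self.epsilon < 0:
            return math.nan
        return 2 * self.beta * self.epsilon**1.5 * 1.0


def energy(l: float, params: MechParams2D, shape: ShapeClass2D) -> float:
    """E(l) on the shape manifold."""
    p = shape.k_p * l
    a = shape.k_a * l * l
    return (
        params.J * p
        + params.lambda_p * (p - params.P) ** 2
        + params.lambda_a * (a - params.A) ** 2
    )


def energy_gradient(l, params: MechParams2D, shape: ShapeClass2D):
    """dE/dl = k_p (tau + beta l (l^2 - 3 eps)); accepts scalars or arrays."""
    ag = aggregates(params, shape)
    l = np.asarray(l, dtype=float)
    out = shape.k_p * (ag.tau + ag.beta * l * (l * l - 3 * ag.epsilon))
    return float(out) if out.ndim == 0 else out


def tension_and_pressure(
    l: float, params: MechParams2D, shape: ShapeClass2D
) -> tuple[float, float]:
    """Interfacial tension gamma and pressure Pi at length scale l."""
    if l < 0:
        raise ValueError("length scale l must be >= 0")
    gamma = params.J + 2 * shape.k_p * params.lambda_p * (l - shape.L_p(params))
    Pi = -2 * shape.k_a * params.lambda_a * (l * l - shape.L_a(params) ** 2)
    return gamma, Pi


def aggregates(params: MechParams2D, shape: ShapeClass2D) -> Aggregates2D:
    """Compute (tau, eps, alpha, beta, zeta) for a parameter set and shape."""
    kp, ka = shape.k_p, shape.k_a
    tau = params.J - 2 * kp * params.lambda_p * shape.L_p(params)
    La2 = params.A / ka
    eps = La2 / 3 - kp**2 * params.lambda_p / (6 * ka**2 * params.lambda_a)
    beta = 4 * ka**2 * params.lambda_a / kp
    if eps >= 0:
        alpha = -8 * ka**2 * params.lambda_a * eps**1.5
    else:
        alpha = math.nan  # imaginary; the zeta branch applies
    # zeta = -(alpha/k_p)^2 = -(8 k_a^2 lambda_a / k_p)^2 eps^3, real always
    zeta = -((8 * ka**2 * params.lambda_a / kp) ** 2) * eps**3
    return Aggregates2D(tau=tau, epsilon=eps, alpha=alpha, beta=beta, zeta=zeta)


@dataclass(frozen=True)
class Equilibrium2D:
    """One equilibrium of the 2D energy.

    On-manifold equilibria satisfy p* = k_p l*, a* = k_a l*^2.  The region-I
    off-manifold solution reports a* = A and p* = P - J/(2 lambda_p) with
    l_star = NaN (the shape is unpredictable, only perimeter and area are
    determined).
    """

    l_star: float
    p_star: float
    a_star: float
    stability: str  # "stable" | "unstable"
    branch: str  # "rho0" | "rho1" | "rho2" | "rho3" | "off-manifold"
    tension_sign: int  # sign of gamma(l*); 0 for the trivial root

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def _clamped(fn: Callable[[float], float], x: float, lo=-1.0, hi=1.0) -> float:
    if x < lo:
        if x < lo - _CLAMP_TOL * max(1.0, abs(lo)):
            raise ArithmeticError(f"trig argument {x} exceeds [-1,1] beyond tolerance")
        x = lo
    elif x > hi:
        if x > hi + _CLAMP_TOL * max(1.0, abs(hi)):
            raise ArithmeticError(f"trig argument {x} exceeds [-1,1] beyond tolerance")
        x = hi
    return fn(x)


def _make_eq(
    l: float, params: MechParams2D, shape: ShapeClass2D, ag: Aggregates2D, branch: str
) -> Equilibrium2D:
    gamma, _ = tension_and_pressure(l, params, shape)
    # stability from the sign of d2E/dl2 = 3 k_p beta (l^2 - eps)
    curv = l * l - ag.epsilon
    return Equilibrium2D(
        l_star=l,
        p_star=shape.k_p * l,
        a_star=shape.k_a * l * l,
        stability="stable" if curv > 0 else "unstable",
        branch=branch,
        tension_sign=int(np.sign(gamma)),
    )


def equilibria(params: MechParams2D, shape: ShapeClass2D) -> list[Equilibrium2D]:
    """All equilibria of E(l), with stability, plus the region-I solution.

    The trivial root l* = 0 is always returned; it is stable iff tau > 0
    (the slope of dE/dl at 0+ is k_p tau).  Non-trivial positive roots come
    from the closed forms of the depressed cubic: the cos/cosh pair for the
    stable branch (the cosh form is used when tau k_p / alpha > 1 to avoid
    complex intermediates), the sin form for the unstable branch, and the
    real Cardano form for eps < 0.  In region I the off-manifold solution
    (a* = A, p* = P - J/(2 lambda_p)) is appended.
    """
    ag = aggregates(params, shape)
    tau, eps = ag.tau, ag.epsilon
    out: list[Equilibrium2D] = [
        Equilibrium2D(
            l_star=0.0,
            p_star=0.0,
            a_star=0.0,
            stability="stable" if tau > 0 else "unstable",
            branch="rho0",
            tension_sign=0,
        )
    ]
    if eps > 0:
        sqeps = math.sqrt(eps)
        arg = tau * shape.k_p / ag.alpha  # alpha < 0
        if tau < 0:
            if arg <= 1.0 + _CLAMP_TOL:
                l1 = 2 * sqeps * math.cos(_clamped(math.acos, arg) / 3)
            else:
                l1 = 2 * sqeps * math.cosh(math.acosh(arg) / 3)
            out.append(_make_eq(l1, params, shape, ag, "rho1"))
        elif tau == 0.0:
            out.append(_make_eq(math.sqrt(3 * eps), params, shape, ag, "rho1"))
        elif arg >= -1.0 - _CLAMP_TOL:
            l1 = 2 * sqeps * math.cos(_clamped(math.acos, arg) / 3)
            l2 = 2 * sqeps * math.sin(_clamped(math.asin, -arg) / 3)
            out.append(_make_eq(l1, params, shape, ag, "rho1"))
            out.append(_make_eq(l2, params, shape, ag, "rho2"))
        # tau beyond the fold: no positive roots
    elif tau < 0:
        # eps <= 0: single stable root via the real Cardano form
        zeta = ag.zeta
        if eps == 0:
            l3 = (-tau / ag.beta) ** (1 / 3.0)
        else:
            s = math.sqrt(tau * tau + zeta)
            l3 = (
                math.sqrt(-eps)
                / zeta ** (1 / 6.0)
                * (np.cbrt(-tau + s) - np.cbrt(tau + s))
            )
        out.append(_make_eq(l3, params, shape, ag, "rho3"))

    if classify_region(params, shape) == "I":
        if params.lambda_p == 0:
            p_off = math.nan  # P - J/(2 lambda_p) diverges; region degenerates
        else:
            p_off = params.P - params.J / (2 * params.lambda_p)
        out.append(
            Equilibrium2D(
                l_star=math.nan,
                p_star=p_off,
                a_star=params.A,
                stability="stable",
                branch="off-manifold",
                tension_sign=0,
            )
        )
    return out


def classify_region(params: MechParams2D, shape: ShapeClass2D) -> str:
    """Region I-IV of the (tau, eps) plane; boundaries reported as e.g. "I/II".

    I   : tau < -2 k_p lambda_p L_a   (negative tension at the regular shape)
    II  : -2 k_p lambda_p L_a < tau < 0
    III : 0 < tau < 2 beta eps^(3/2)  (requires eps > 0; bistable)
    IV  : otherwise (tau > fold; vanishing only)
    """
    ag = aggregates(params, shape)
    tau = ag.tau
    tau1 = -2 * shape.k_p * params.lambda_p * shape.L_a(params)
    # tau is a difference of potentially large terms; treat it as zero when
    # it is zero relative to those terms
    tau_scale = abs(params.J) + 2 * shape.k_p * params.lambda_p * shape.L_p(params)

    def near(x, y):
        return math.isclose(x, y, rel_tol=_BOUNDARY_RTOL, abs_tol=1e-300)

    if tau1 != 0 and near(tau, tau1):
        return "I/II"
    if tau == 0.0 or abs(tau) <= _BOUNDARY_RTOL * tau_scale:
        return "II/III"
    if tau < tau1:
        return "I"
    if tau < 0:
        return "II" if tau1 < 0 else "I"  # lambda_p = 0 degenerates boundary 1
    if ag.epsilon > 0:
        fold = ag.tau_fold
        if near(tau, fold):
            return "III/IV"
        if tau < fold:
            return "III"
    return "IV"


@dataclass(frozen=True)
class FarhadifarCoords:
    """Normalised tension and contractility of the vertex-model plane."""

    Lambda_bar: float
    Gamma_bar: float
    region: str


def farhadifar_map(params: MechParams2D, shape: ShapeClass2D) -> FarhadifarCoords:
    """Map to the normalised (Lambda_bar, Gamma_bar) vertex-model coordinates.

    The mapping assumes a zero rest length (L_p = 0, hence tau = J), under
    which Lambda = J, Gamma = lambda_p, K = lambda_a and A0 = k_a L_a^2, so

        Lambda_bar = J / (k_a^(3/2) lambda_a L_a^3),
        Gamma_bar  = lambda_p / (k_a lambda_a L_a^2).
    """
    if params.P != 0:
        raise ValueError(
            "the vertex-model normalisation assumes a zero membrane rest "
            "length (P = 0, so that tau = J); rescale or remap first"
        )
    La = shape.L_a(params)
    ka = shape.k_a
    Lb = params.J / (ka**1.5 * params.lambda_a * La**3)
    Gb = params.lambda_p / (ka * params.lambda_a * La**2)
    return FarhadifarCoords(
        Lambda_bar=Lb, Gamma_bar=Gb, region=classify_region(params, shape)
    )


@dataclass(frozen=True)
class BifurcationLines2D:
    """The three bifurcation lines of the 2D diagram.

    In (tau, eps): tension-sign line tau = -2 k_p lambda_p L_a (a constant
    given lambda_p and L_a), pseudo-transcritical line tau = 0, and the fold
    tau = 2 beta eps^(3/2) (a curve in eps).  In the normalised plane the
    lines are Gamma_bar = -(sqrt(k_a)/(2 k_p)) Lambda_bar, Lambda_bar = 0,
    and Gamma_bar = (4 k_a - 3 (k_a k_p Lambda_bar)^(2/3)) / (2 k_p^2).
    """

    shape: ShapeClass2D
    tau_boundary_1: float | None
    tau_boundary_2: float
    fold_tau_of_eps: Callable[[np.ndarray], np.ndarray]
    gammabar_1: Callable[[np.ndarray], np.ndarray]
    gammabar_3: Callable[[np.ndarray], np.ndarray]


def bifurcation_lines(
    shape: ShapeClass2D,
    *,
    lambda_p: float | None = None,
    L_a: float | None = None,
) -> BifurcationLines2D:
    """Bifurcation lines for a shape class, in (tau, eps) and normalised form."""
    kp, ka = shape.k_p, shape.k_a
    lam_a_factor = 4 * ka**2 / kp  # beta / lambda_a

    tau1 = None
    if lambda_p is not None and L_a is not None:
        tau1 = -2 * kp * lambda_p * L_a

    def fold(eps, lambda_a=1.0):
        eps = np.asarray(eps, dtype=float)
        return 2 * lam_a_factor * lambda_a * np.where(eps > 0, eps, np.nan) ** 1.5

    def g1(lb):
        return -(math.sqrt(ka) / (2 * kp)) * np.asarray(lb, dtype=float)

    def g3(lb):
        lb = np.asarray(lb, dtype=float)
        return (4 * ka - 3 * (ka * kp * lb) ** (2 / 3.0)) / (2 * kp**2)

    return BifurcationLines2D(
        shape=shape,
        tau_boundary_1=tau1,
        tau_boundary_2=0.0,
        fold_tau_of_eps=fold,
        gammabar_1=g1,
        gammabar_3=g3,
    )
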