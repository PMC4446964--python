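"""Closed-form 3D cell surface mechanics for an arbitrary shape class.

The 3D energy is E(s, v) = J s + lambda_s (s - S)^2 + lambda_v (v - V)^2.
On a one-parameter shape family s = k_s l^2, v = k_v l^3 (sphere:
k_s = 4 pi, k_v = 4 pi / 3; rhombic dodecahedron — the space-filling shape
of packed 3D tissue — k_s = 8 sqrt(2), k_v = 16 / (3 sqrt(3))) the
equilibrium condition becomes a quintic,

    dE/dl = 2 k_s (a l^5 + b l^3 - c l^2 + tau l) = 0,

with a = 3 k_v^2 lambda_v / k_s, b = 2 k_s lambda_s,
c = 3 k_v^2 lambda_v L_v^3 / k_s and tau = J - 2 k_s lambda_s L_s^2.
Unlike in 2D, dE/dl vanishes at l = 0 for every parameter choice, so small
cells shrink or grow ever more slowly.  Closed-form quintic roots are
uninformative; positive roots are located numerically by sign bracketing.

The bifurcation structure lives in a reduced (mu, nu) plane built from
phi = b/(6a) and psi = c/(8a):  nu = tau/(12 a phi^2), mu = psi/phi^(3/2)
when lambda_s > 0, and nu' = tau/(12 a), mu' = psi when lambda_s = 0.
Regions I-IV mirror the 2D classification; for lambda_s = 0 the
tension-sign boundary collapses onto nu' = 0 (region II does not exist
separately) and the fold is nu' = mu'^(4/3) / 2^(2/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MechParams3D",
    "ShapeClass3D",
    "SPHERE",
    "RHOMBIC_DODECAHEDRON",
    "Aggregates3D",
    "Equilibrium3D",
    "aggregates3",
    "equilibria3",
    "classify_region3",
    "energy_gradient3",
]

_BOUNDARY_RTOL = 1e-9
_N_BRACKETS = 4096
_ROOT_RTOL = 1e-12


@dataclass(frozen=True)
class MechParams3D:
    """The five biophysical parameters of the 3D energy function."""

    J: float
    lambda_s: float
    S: float
    lambda_v: float
    V: float

    def __post_init__(self):
        if self.lambda_v <= 0:
            raise ValueError("lambda_v must be > 0")
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be >= 0")
        if self.V < 0:
            raise ValueError("target volume V must be >= 0")


@dataclass(frozen=True)
class ShapeClass3D:
    """A one-parameter shape family s = k_s l^2, v = k_v l^3."""

    k_s: float
    k_v: float
    name: str = "custom"

    def __post_init__(self):
        if self.k_s <= 0 or self.k_v <= 0:
            raise ValueError("shape scaling constants must be positive")

    def L_s(self, params: MechParams3D) -> float:
        return math.sqrt(params.S / self.k_s)

    def L_v(self, params: MechParams3D) -> float:
        return (params.V / self.k_v) ** (1 / 3.0)


SPHERE = ShapeClass3D(k_s=4 * math.pi, k_v=4 * math.pi / 3, name="sphere")
RHOMBIC_DODECAHEDRON = ShapeClass3D(
    k_s=8 * math.sqrt(2), k_v=16 / (3 * math.sqrt(3)), name="rhombic-dodecahedron"
)


@dataclass(frozen=True)
class Aggregates3D:
    """Quintic coefficients and reduced coordinates of the 3D analysis."""

    tau: float
    a: float
    b: float
    c: float
    phi: float
    psi: float
    mu: float  # NaN on the lambda_s = 0 branch
    nu: float
    mu_prime: float  # NaN on the lambda_s > 0 branch
    nu_prime: float

    @property
    def reduced(self) -> tuple[float, float]:
        """(mu, nu) or (mu', nu'), whichever branch is active."""
        if math.isnan(self.mu):
            return self.mu_prime, self.nu_prime
        return self.mu, self.nu


def aggregates3(params: MechParams3D, shape: ShapeClass3D) -> Aggregates3D:
    ks, kv = shape.k_s, shape.k_v
    Ls, Lv = shape.L_s(params), shape.L_v(params)
    tau = params.J - 2 * ks * params.lambda_s * Ls**2
    a = 3 * kv**2 * params.lambda_v / ks
    b = 2 * ks * params.lambda_s
    c = 3 * kv**2 * params.lambda_v * Lv**3 / ks
    phi = b / (6 * a)
    psi = c / (8 * a)
    if params.lambda_s == 0:
        return Aggregates3D(
            tau=tau, a=a, b=b, c=c, phi=phi, psi=psi,
            mu=math.nan, nu=math.nan, mu_prime=psi, nu_prime=tau / (12 * a),
        )
    return Aggregates3D(
        tau=tau, a=a, b=b, c=c, phi=phi, psi=psi,
        mu=psi / phi**1.5, nu=tau / (12 * a * phi**2),
        mu_prime=math.nan, nu_prime=math.nan,
    )


def energy_gradient3(l, params: MechParams3D, shape: ShapeClass3D):
    """dE/dl = 2 k_s (a l^5 + b l^3 - c l^2 + tau l)."""
    ag = aggregates3(params, shape)
    l = np.asarray(l, dtype=float)
    out = 2 * shape.k_s * (ag.a * l**5 + ag.b * l**3 - ag.c * l**2 + ag.tau * l)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Equilibrium3D:
    l_star: float
    s_star: float
    v_star: float
    stability: str
    branch: str  # "trivial" | "lower" | "upper" | "single" | "double"

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def _quartic(l, ag):
    # dE/dl / (2 k_s l) — the quartic factor whose positive roots are the
    # non-trivial equilibria
    return ag.a * l**4 + ag.b * l**2 - ag.c * l + ag.tau


def equilibria3(params: MechParams3D, shape: ShapeClass3D) -> list[Equilibrium3D]:
    """l* = 0 plus all positive roots of the quartic factor, with stability.

    tau < 0 gives exactly one positive root (stable); tau > 0 gives zero or
    two (the lower unstable, the upper stable).  Roots are bracketed on a
    dense grid and refined by Brent's method; a fold (double root) is
    reported when the quartic touches zero without a sign change.
    """
    ag = aggregates3(params, shape)
    out = [
        Equilibrium3D(
            l_star=0.0, s_star=0.0, v_star=0.0,
            stability="stable" if ag.tau > 0 else "unstable",
            branch="trivial",
        )
    ]
    # any positive root satisfies a l^4 <= c l + |tau| (the b-term only
    # pushes the quartic up), which bounds it by the L_v, phi and tau scales
    l_max = 10 * max(
        shape.L_v(params),
        math.sqrt(ag.phi),
        (2 * abs(ag.tau) / ag.a) ** 0.25,
        1.0,
    )
    lin = np.linspace(0.0, l_max, _N_BRACKETS + 1)[1:]
    geo = np.geomspace(l_max * 1e-8, l_max, _N_BRACKETS // 4)
    grid = np.unique(np.concatenate([lin, geo]))
    q = _quartic(grid, ag)
    roots: list[float] = []
    sign = np.sign(q)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(
            brentq(lambda x: _quartic(x, ag), grid[i], grid[i + 1], rtol=_ROOT_RTOL)
        )
    # exact zeros on the grid (rare) and folds where the quartic touches zero
    for i in np.flatnonzero(sign == 0):
        roots.append(float(grid[i]))
    roots = sorted(set(roots))
    double = not roots and ag.tau > 0 and _near_fold(ag)
    if double:
        roots = [2 * math.sqrt(ag.phi) * math.sinh(math.asinh(ag.mu) / 3)
                 if ag.phi > 0 else (2 * ag.psi) ** (1 / 3.0)]
    names = _branch_names(len(roots), ag.tau, double)
    for l, name in zip(roots, names):
        d2 = 5 * ag.a * l**4 + 3 * ag.b * l**2 - 2 * ag.c * l + ag.tau
        out.append(
            Equilibrium3D(
                l_star=l,
                s_star=shape.k_s * l * l,
                v_star=shape.k_v * l**3,
                stability="stable" if d2 > 0 else "unstable",
                branch=name,
            )
        )
    return out


def _near_fold(ag: Aggregates3D, rtol: float = 1e-9) -> bool:
    if ag.phi > 0:
        f = math.sinh(math.asinh(ag.mu) / 3)
        return math.isclose(ag.nu, f * (ag.mu - f), rel_tol=rtol)
    return math.isclose(ag.nu_prime, ag.mu_prime ** (4 / 3.0) / 2 ** (2 / 3.0),
                        rel_tol=rtol)


def _branch_names(n: int, tau: float, double: bool) -> list[str]:
    if double:
        return ["double"]
    if n == 1:
        return ["single"]
    if n == 2:
        return ["lower", "upper"]
    return [f"root{i}" for i in range(n)]


def classify_region3(params: MechParams3D, shape: ShapeClass3D) -> str:
    """Region I-IV in the reduced plane; boundaries reported as e.g. "II/III".

    lambda_s > 0:  I iff nu < -9 k_v^2 lambda_v L_v^2 / (2 k_s^2 lambda_s);
    II between that bound and 0; III iff 0 < nu < f(mu)(mu - f(mu)) with
    f(mu) = sinh(arcsinh(mu)/3); IV otherwise.  lambda_s = 0: the I/II
    boundary collapses onto nu' = 0 and the fold is nu' = mu'^(4/3)/2^(2/3);
    region II does not exist separately.
    """
    ag = aggregates3(params, shape)

    def near(x, y):
        return math.isclose(x, y, rel_tol=_BOUNDARY_RTOL, abs_tol=1e-300)

    if params.lambda_s == 0:
        nu, mu = ag.nu_prime, ag.mu_prime
        fold = mu ** (4 / 3.0) / 2 ** (2 / 3.0)
        if nu == 0:
            return "I/III"
        if nu < 0:
            return "I"
        if fold != 0 and near(nu, fold):
            return "III/IV"
        return "III" if nu < fold else "IV"

    nu, mu = ag.nu, ag.mu
    bound1 = -9 * shape.k_v**2 * params.lambda_v * shape.L_v(params) ** 2 / (
        2 * shape.k_s**2 * params.lambda_s
    )
    f = math.sinh(math.asinh(mu) / 3)
    fold = f * (mu - f)
    nu_scale = (abs(params.J) + 2 * shape.k_s * params.lambda_s
                * shape.L_s(params) ** 2) / (12 * ag.a * ag.phi**2)
    if bound1 != 0 and near(nu, bound1):
        return "I/II"
    if nu == 0 or abs(nu) <= _BOUNDARY_RTOL * nu_scale:
        return "II/III"
    if nu < bound1:
        return "I"
    if nu < 0:
        return "II"
    if fold != 0 and near(nu, fold):
        return "III/IV"
    return "III" if nu < fold else "IV"
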