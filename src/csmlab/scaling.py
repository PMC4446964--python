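"""Parameter bridges between the lattice (CPM) and geometric descriptions.

Three independent, exact transformations:

* **CPM <-> geometric** via the perimeter scaling factor xi of the chosen
  neighbourhood: J = xi J_CPM (cell-medium) or (xi/2) J_CPM (cell-cell,
  because the tension of a shared boundary is paid by both cells),
  P = P_CPM / xi, lambda_p = xi^2 lambda_p_CPM; the 3D surface analogues
  are identical in form.  lambda_a, A (lambda_v, V) are untouched.

* **Resolution rescaling** by the lattice refinement factor k = 1/dx:
  J' = J/k, lambda_p' = lambda_p/k^2, lambda_a' = lambda_a/k^4, P' = kP,
  A' = k^2 A in 2D (powers shift by one in 3D).  The transformation
  preserves the force balance for any cell shape.  The temperature T is
  deliberately left untouched: it does not appear in the force-balance
  derivation, and the reference resolution comparisons hold T fixed.

* **Adhesion <-> rest-length remapping**: shifting every cell-cell adhesion
  energy by dJ (and every cell-medium energy by dJ/2) while shifting every
  rest perimeter by dJ / (4 lambda_p) leaves every energy difference — and
  hence the entire stochastic dynamics — exactly unchanged.  This requires
  lambda_p > 0; no compensation through lambda_p itself exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .analytic2d import MechParams2D
from .analytic3d import MechParams3D

__all__ = [
    "ResolutionFactor",
    "AdhesionShift",
    "cpm_to_geometric",
    "geometric_to_cpm",
    "rescale_resolution",
    "remap_adhesion",
    "remap_cpm_params",
    "weighted_mean_shift",
]


@dataclass(frozen=True)
class ResolutionFactor:
    """Lattice refinement factor k = 1/dx."""

    k: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("resolution factor k must be positive")


@dataclass(frozen=True)
class AdhesionShift:
    """A uniform shift of the adhesion matrix.

    The exact one-to-one remapping shifts every cell-cell entry by
    ``dJ_cell_cell`` and every cell-medium entry by half of it.
    """

    dJ_cell_cell: float

    @property
    def dJ_cell_medium(self) -> float:
        return self.dJ_cell_cell / 2.0


def _check_xi(xi: float) -> None:
    if xi <= 0:
        raise ValueError(f"xi must be positive, got {xi}")


def cpm_to_geometric(
    params_cpm: MechParams2D | MechParams3D,
    xi: float,
    dim: int = 2,
    *,
    interface: str = "cell-medium",
):
    """Geometric parameters from CPM-unit parameters.

    ``interface`` selects the adhesion factor: xi for cell-medium contacts,
    xi/2 for cell-cell contacts (shared-boundary convention).
    """
    _check_xi(xi)
    jfac = xi if interface == "cell-medium" else xi / 2.0
    if dim == 2:
        return MechParams2D(
            J=jfac * params_cpm.J,
            lambda_p=xi**2 * params_cpm.lambda_p,
            P=params_cpm.P / xi,
            lambda_a=params_cpm.lambda_a,
            A=params_cpm.A,
        )
    return MechParams3D(
        J=jfac * params_cpm.J,
        lambda_s=xi**2 * params_cpm.lambda_s,
        S=params_cpm.S / xi,
        lambda_v=params_cpm.lambda_v,
        V=params_cpm.V,
    )


def geometric_to_cpm(
    params,
    xi: float,
    dim: int = 2,
    *,
    interface: str = "cell-medium",
):
    """Inverse of :func:`cpm_to_geometric`; the round trip is exact."""
    _check_xi(xi)
    jfac = xi if interface == "cell-medium" else xi / 2.0
    if dim == 2:
        return MechParams2D(
            J=params.J / jfac,
            lambda_p=params.lambda_p / xi**2,
            P=xi * params.P,
            lambda_a=params.lambda_a,
            A=params.A,
        )
    return MechParams3D(
        J=params.J / jfac,
        lambda_s=params.lambda_s / xi**2,
        S=xi * params.S,
        lambda_v=params.lambda_v,
        V=params.V,
    )


def rescale_resolution(params, k: float, dim: int = 2):
    """Rescale a geometric parameter set to lattice refinement k.

    Valid for any cell shape; composes multiplicatively
    (rescale(k1) o rescale(k2) = rescale(k1 k2)).
    """
    if k <= 0:
        raise ValueError(f"resolution factor k must be positive, got {k}")
    if dim == 2:
        return MechParams2D(
            J=params.J / k,
            lambda_p=params.lambda_p / k**2,
            P=k * params.P,
            lambda_a=params.lambda_a / k**4,
            A=k**2 * params.A,
        )
    return MechParams3D(
        J=params.J / k**2,
        lambda_s=params.lambda_s / k**4,
        S=k**2 * params.S,
        lambda_v=params.lambda_v / k**6,
        V=k**3 * params.V,
    )


def remap_adhesion(J: np.ndarray, P_target, lambda_p: float, shift: AdhesionShift):
    """Uniformly shift an adhesion matrix and compensate the rest perimeter.

    Parameters
    ----------
    J : (T+1, T+1) symmetric adhesion matrix, index 0 = medium.
    P_target : per-type (or per-cell) rest perimeters, shifted in place of
        a copy by dJ_cell_cell / (4 lambda_p).
    lambda_p : perimeter constraint weight (> 0; the remapping cannot
        compensate through lambda_p and does not exist without the
        perimeter constraint).

    Returns (J', P_target') leaving the inputs untouched.  With the proxy
    convention used here the shifted system has identical energy
    differences for every possible copy attempt, hence identical dynamics.
    """
    if lambda_p <= 0:
        raise ValueError(
            "adhesion<->rest-length remapping requires lambda_p > 0: no "
            "compensation through the perimeter weight exists, the shift is "
            "absorbed by the rest perimeter only"
        )
    J = np.asarray(J, dtype=float)
    Jp = J.copy()
    Jp[1:, 1:] += shift.dJ_cell_cell
    Jp[0, 1:] += shift.dJ_cell_medium
    Jp[1:, 0] += shift.dJ_cell_medium
    dP = shift.dJ_cell_cell / (4.0 * lambda_p)
    Pp = np.asarray(P_target, dtype=float) + dP
    return Jp, Pp


def remap_cpm_params(params, shift: AdhesionShift):
    """Remapped copy of a :class:`csmlab.cpm.CPMParams`."""
    lam = np.asarray(params.lambda_p, dtype=float)
    if np.any(lam[1:] <= 0):
        raise ValueError("remapping requires lambda_p > 0 for every cell type")
    Jp, _ = remap_adhesion(params.J, np.zeros(1), float(lam[1:].flat[0]), shift)
    Pp = np.asarray(params.P_target, dtype=float).copy()
    Pp[1:] = Pp[1:] + shift.dJ_cell_cell / (4.0 * lam[1:])
    return replace(params, J=Jp, P_target=Pp)


def weighted_mean_shift(dJ: np.ndarray, contact: np.ndarray) -> float:
    """Diagnostic: contact-length-weighted mean adhesion shift of one cell.

    For a *non*-uniform shift matrix there is no static one-to-one mapping;
    the instantaneous compensating rest-length shift is
    dP = mean_w(dJ) / (2 lambda_p), where the mean weighs each partner's
    shift (half of it for cell-cell contacts, matching the shared-boundary
    convention) by the current contact proxy.

    Parameters
    ----------
    dJ : per-partner shift values (cell-cell entries already halved by the
        caller, or pass the raw matrix row and halve here — see tests).
    contact : matching contact proxy lengths.
    """
    dJ = np.asarray(dJ, dtype=float)
    contact = np.asarray(contact, dtype=float)
    total = contact.sum()
    if total == 0:
        return 0.0
    return float((dJ * contact).sum() / total)
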