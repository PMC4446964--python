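"""Canonical study conditions for the desk-scale experiments.

The single-cell reference parameter set (geometric units, resolution k=1)
used throughout the 2D analysis: lambda_p = 25,
P = 2000, lambda_a = 0.0625, A = 31416 (target radius 100), simulated with
a 6th-level neighbourhood (xi = 18) at T = 20000; J selects the region
(0, 80 000, 200 000, 300 000 for regions I-IV).

Desk-scale runs use the exact resolution rescaling to shrink the lattice:
all parameters are transformed with the k-power laws, T is held fixed, and
the Monte Carlo clock accelerates accordingly (coarser lattices relax in
fewer MCS), so the *dynamics* are those of the full-size system.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analytic2d import MechParams2D
from .cpm import CPMParams
from .experiments import run_region_suite
from .neighbourhoods import build_neighbourhood
from .scaling import geometric_to_cpm, rescale_resolution

__all__ = [
    "REFERENCE_2D",
    "REGION_J_2D",
    "single_cell_params",
    "single_cell_cpm_params",
    "sorting_cpm_params",
    "region_suite_small",
    "region_suite_from_config",
]

#: geometric reference parameters of the 2D single-cell runs (J set per region)
REFERENCE_2D = dict(lambda_p=25.0, P=2000.0, lambda_a=0.0625, A=31416.0)
#: adhesion energy per region, geometric units
REGION_J_2D = {"I": 0.0, "II": 80_000.0, "III": 200_000.0, "IV": 300_000.0}
#: simulation temperature of the reference runs
REFERENCE_T = 20_000.0
#: neighbourhood level of the reference runs (xi = 18)
REFERENCE_LEVEL = 6


def single_cell_params(J: float) -> MechParams2D:
    """Geometric 2D parameter set of the single-cell reference runs."""
    return MechParams2D(J=J, **REFERENCE_2D)


def single_cell_cpm_params(
    J: float,
    k: float = 1.0,
    *,
    T: float = REFERENCE_T,
    level: int = REFERENCE_LEVEL,
) -> CPMParams:
    """CPM parameters for a single cell at resolution k.

    The geometric reference set is resolution-rescaled by k, then converted
    to CPM units through xi of the chosen neighbourhood (cell-medium
    interface, as appropriate for an isolated cell).  T is not rescaled.
    """
    neigh = build_neighbourhood(level=level, dim=2)
    xi = neigh.xi()
    geo = rescale_resolution(single_cell_params(J), k, dim=2)
    cpm = geometric_to_cpm(geo, xi, dim=2, interface="cell-medium")
    return CPMParams(
        J=np.array([[0.0, cpm.J], [cpm.J, 0.0]]),
        A_target=np.array([0.0, cpm.A]),
        P_target=np.array([0.0, cpm.P]),
        lambda_a=np.array([0.0, cpm.lambda_a]),
        lambda_p=np.array([0.0, cpm.lambda_p]),
        T=T,
        neighbourhood=neigh,
        k=k,
    )


def sorting_cpm_params(T: float = 600.0) -> CPMParams:
    """The three-type differential-adhesion sorting parameter set (CPM units).

    Types G(reen), Y(ellow), B(lue) in a medium M; Moore neighbourhood;
    J_GG = J_YY = J_BB = 400, J_GM = 600, J_YM = 1200, J_BM = 1800,
    J_GY = J_YB = 800, J_GB = 1400; A = 30, P = 67, lambda_a = 1000,
    lambda_p = 20.
    """
    J = np.array(
        [
            #    M     G     Y     B
            [0.0, 600.0, 1200.0, 1800.0],
            [600.0, 400.0, 800.0, 1400.0],
            [1200.0, 800.0, 400.0, 800.0],
            [1800.0, 1400.0, 800.0, 400.0],
        ]
    )
    n = build_neighbourhood(level=2, dim=2)
    return CPMParams(
        J=J,
        A_target=np.array([0.0, 30.0, 30.0, 30.0]),
        P_target=np.array([0.0, 67.0, 67.0, 67.0]),
        lambda_a=np.array([0.0, 1000.0, 1000.0, 1000.0]),
        lambda_p=np.array([0.0, 20.0, 20.0, 20.0]),
        T=T,
        neighbourhood=n,
    )


def region_suite_small(
    *,
    k: float = 0.25,
    J_values=None,
    initial_radii=(30.0, 50.0),
    seeds=(1, 2, 3),
    lattice: int = 96,
    n_mcs: int = 120,
    T: float = REFERENCE_T,
) -> pd.DataFrame:
    """Scaled-down single-cell region sweep (radii given at full resolution).

    Roughly two orders of magnitude below the full 10 000-run sweep; the
    coarse lattice (k = 0.25) keeps each run to a few seconds while the
    k-power rescaling preserves the reference dynamics exactly.
    """
    if J_values is None:
        J_values = list(REGION_J_2D.values())
    return run_region_suite(
        single_cell_params(0.0),
        J_values=list(J_values),
        initial_radii=list(initial_radii),
        seeds=seeds,
        cpm_factory=lambda J: single_cell_cpm_params(J, k, T=T),
        lattice_dims=(lattice, lattice),
        n_mcs=n_mcs,
    )


def region_suite_from_config(cfg: dict) -> pd.DataFrame:
    """CLI adapter: run the region suite from a plain dict of options."""
    kwargs = {}
    for key in ("k", "J_values", "initial_radii", "seeds", "lattice", "n_mcs", "T"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return region_suite_small(**kwargs)
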