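"""Initial-condition generators and turnkey desk-scale experiments.

Generators are pure functions of their arguments and seed: discs/spheres
for single-cell runs, Voronoi tissues for packing and sorting runs.  The
experiment runners reproduce, at reduced size, the single-cell region
phenomenology (persist vs vanish against the analytic predictions), with
every random draw controlled by explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic2d import CIRCLE, MechParams2D, aggregates, classify_region, equilibria
from .cpm import CPMParams, LatticeState, run_mcs
from .neighbourhoods import Neighbourhood

__all__ = [
    "ExperimentSpec",
    "make_disc",
    "make_tissue",
    "run_region_suite",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Serialisable description of a desk-scale experiment."""

    name: str
    cpm_params: CPMParams
    lattice_dims: tuple[int, ...]
    initial_radius: float | None = None
    n_cells: int | None = None
    init_region: tuple[int, ...] | None = None
    type_fractions: Sequence[float] = (1.0,)
    seeds: Sequence[int] = (0,)
    mcs: int = 100
    record_every: int = 10


def make_disc(
    radius: float,
    lattice_dims: tuple[int, ...],
    cell_type: int = 1,
    neighbourhood: Neighbourhood | None = None,
    boundary: str = "fixed-medium",
    margin: int | None = None,
) -> LatticeState:
    """A single disc (2D) or ball (3D) cell centred on the lattice.

    All sites within Euclidean distance ``radius`` of the centre carry
    cell id 1; radius 0 yields an empty (all-medium) lattice.  The disc
    must fit with a margin of at least the copy-neighbourhood radius.
    """
    if neighbourhood is None:
        raise ValueError("a neighbourhood is required to initialise the ledger")
    dims = tuple(int(d) for d in lattice_dims)
    if margin is None:
        margin = 3
    if radius > 0 and any(radius + margin > d / 2 for d in dims):
        raise ValueError(
            f"disc of radius {radius} does not fit lattice {dims} with "
            f"margin {margin}"
        )
    labels = np.zeros(dims, dtype=np.int32)
    if radius > 0:
        centre = [d // 2 for d in dims]
        grids = np.ogrid[tuple(slice(0, d) for d in dims)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        labels[dist2 <= radius * radius] = 1
    types = {1: cell_type} if radius > 0 else {}
    return LatticeState(labels, types, neighbourhood, boundary=boundary)


def make_tissue(
    lattice_dims: tuple[int, ...],
    n_cells: int,
    init_region: tuple[int, ...],
    type_fractions: Sequence[float],
    seed: int,
    neighbourhood: Neighbourhood | None = None,
    boundary: str = "fixed-medium",
) -> LatticeState:
    """A blob of ``n_cells`` Voronoi cells surrounded by medium.

    Seeds are placed uniformly at random (without collision) inside the
    centred ``init_region`` window; every site of the window is assigned to
    the nearest seed; types are drawn from ``type_fractions``.  Fully
    deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if neighbourhood is None:
        raise ValueError("a neighbourhood is required to initialise the ledger")
    dims = tuple(int(d) for d in lattice_dims)
    region = tuple(int(r) for r in init_region)
    if any(r > d for r, d in zip(region, dims)):
        raise ValueError("init_region exceeds the lattice")
    if n_cells > int(np.prod(region)) // 4:
        raise ValueError("overcrowded: fewer than 4 sites per cell in the region")
    rng = np.random.default_rng(seed)
    lo = [(d - r) // 2 for d, r in zip(dims, region)]

    flat_choices = rng.choice(int(np.prod(region)), size=n_cells, replace=False)
    seeds_rc = np.stack(np.unravel_index(flat_choices, region), axis=1)

    grids = np.stack(
        np.meshgrid(*[np.arange(r) for r in region], indexing="ij"), axis=-1
    ).reshape(-1, len(region))
    d2 = ((grids[:, None, :] - seeds_rc[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1).astype(np.int32) + 1

    labels = np.zeros(dims, dtype=np.int32)
    window = tuple(slice(l, l + r) for l, r in zip(lo, region))
    labels[window] = assign.reshape(region)

    fracs = np.asarray(type_fractions, dtype=float)
    fracs = fracs / fracs.sum()
    types_drawn = rng.choice(len(fracs), size=n_cells, p=fracs) + 1
    cell_types = {cid: int(t) for cid, t in zip(range(1, n_cells + 1), types_drawn)}
    return LatticeState(labels, cell_types, neighbourhood, boundary=boundary)


def _persisted(traj: pd.DataFrame, cell_id: int, n_mcs: int) -> bool:
    """Alive at the end AND over the whole last 10% of the run."""
    tail = traj[(traj.cell_id == cell_id) & (traj.mcs >= 0.9 * n_mcs)]
    if tail.empty:
        return False
    recorded = set(tail.mcs)
    expected = {m for m in set(traj.mcs) if m >= 0.9 * n_mcs}
    return recorded == expected and (tail.n_sites > 0).all()


def run_region_suite(
    params_geo: MechParams2D,
    J_values: Sequence[float],
    initial_radii: Sequence[float],
    seeds: Sequence[int],
    *,
    cpm_factory,
    lattice_dims: tuple[int, int],
    n_mcs: int,
    record_every: int = 10,
    window_frac: float = 0.1,
) -> pd.DataFrame:
    """Sweep (J, r0, seed), run the CPM, and merge analytic predictions.

    ``cpm_factory(J)`` must return the CPMParams for adhesion energy J (in
    geometric units) so that callers control the xi/resolution bookkeeping.
    Returns one row per run with final status (vanished/persisted), the
    mean and SD of geometric area and perimeter over the last
    ``window_frac`` of recorded MCS, and the analytic region/equilibria.
    """
    rows = []
    for J in J_values:
        p = MechParams2D(J=J, lambda_p=params_geo.lambda_p, P=params_geo.P,
                         lambda_a=params_geo.lambda_a, A=params_geo.A)
        region = classify_region(p, CIRCLE)
        eqs = equilibria(p, CIRCLE)
        stable_a = max(
            (e.a_star for e in eqs if e.stable and e.branch.startswith("rho")
             and e.l_star > 0),
            default=np.nan,
        )
        unstable_l = next(
            (e.l_star for e in eqs if e.branch == "rho2"), np.nan
        )
        tau = aggregates(p, CIRCLE).tau
        cpm_params = cpm_factory(J)
        for r0 in initial_radii:
            for seed in seeds:
                # radii are given in reference units; the lattice is k times
                # finer (or coarser)
                state = make_disc(
                    cpm_params.k * r0, lattice_dims,
                    neighbourhood=cpm_params.neighbourhood,
                )
                traj = run_mcs(state, cpm_params, n_mcs, rng_seed=seed,
                               record_every=record_every)
                t = traj.table
                cell = t[t.cell_id == 1]
                alive = _persisted(t, 1, n_mcs)
                tail = cell[cell.mcs >= (1 - window_frac) * n_mcs]
                rows.append({
                    "J": J, "tau": tau, "r0": r0, "seed": seed,
                    "region": region,
                    "status": "persisted" if alive else "vanished",
                    "area_mean": tail.area_geo.mean() if alive else 0.0,
                    "area_sd": tail.area_geo.std(ddof=0) if alive else 0.0,
                    "perim_mean": tail.perim_geo.mean() if alive else 0.0,
                    "perim_sd": tail.perim_geo.std(ddof=0) if alive else 0.0,
                    "analytic_area_stable": stable_a,
                    "analytic_l_unstable": unstable_l,
                })
    return pd.DataFrame(rows)
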