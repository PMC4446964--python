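"""Lattice-based Cellular Potts simulator (2D and 3D).

A configuration is an integer label grid (0 = medium, >= 1 = cell id) with
per-cell bookkeeping of the site count n_sigma and the perimeter proxy
p_CPM (the multiplicity-weighted count of foreign sites within the chosen
neighbourhood of every cell site).  The total energy is

    E = sum over unordered neighbouring-site pairs with distinct labels of
        J[type_i, type_j]
      + sum over cells of lambda_p (p_CPM - P)^2 + lambda_a (n - A)^2,

which realises the per-cell Hamiltonian in which the tension of a cell-cell
boundary is shared by both cells while a cell-medium boundary is paid once.
The SAME neighbourhood is used for the adhesion sum and the perimeter
proxy; mixing neighbourhoods breaks the xi-based bridge to the geometric
description.

Dynamics: one Monte Carlo step (MCS) visits every lattice site once in a
fresh random permutation; each visited site draws one uniformly random
source from the (smaller) copy neighbourhood and, if the labels differ,
attempts to copy the source label with the modified-Metropolis probability

    p = 1                    if dE < -Y,
        exp(-(dE + Y)/T)     otherwise.

The random stream is consumed in a documented order (site permutation,
then source indices, then acceptance uniforms, one block per MCS), so runs
are exactly reproducible from the seed — and identical between the
numba-accelerated kernel and the pure-Python reference path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .neighbourhoods import Neighbourhood, build_neighbourhood

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "CPMParams",
    "LatticeState",
    "Trajectory",
    "hamiltonian",
    "delta_energy",
    "attempt_copy",
    "run_mcs",
    "measure_cell",
    "recount_ledger",
]


@dataclass(frozen=True)
class CPMParams:
    """Simulation parameters in CPM (lattice) units.

    J : (T+1, T+1) symmetric adhesion matrix indexed by type, 0 = medium.
    A_target, P_target : per-type target site count and rest perimeter
        proxy (geometric targets times xi); index 0 (medium) is ignored.
    lambda_a, lambda_p : per-type constraint weights.
    T : simulation temperature (> 0; the zero-temperature limit produces
        grid artefacts and is disallowed).
    Y : yield, the offset in the acceptance rule (default 0).
    neighbourhood : used for BOTH the adhesion term and the perimeter proxy.
    copy_neighbourhood : proposals are drawn from this (typically smaller)
        neighbourhood; defaults to level 2 (Moore) in 2D, level 3 in 3D.
    boundary : "fixed-medium" (out-of-lattice sites read as immutable
        medium) or "periodic".
    k : lattice resolution factor (1/dx), used only for measurement.
    """

    J: np.ndarray
    A_target: np.ndarray
    P_target: np.ndarray
    lambda_a: np.ndarray
    lambda_p: np.ndarray
    T: float
    Y: float = 0.0
    neighbourhood: Neighbourhood = field(default=None)
    copy_neighbourhood: Neighbourhood | None = None
    boundary: str = "fixed-medium"
    k: float = 1.0

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square (types+1, types+1) matrix")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        object.__setattr__(self, "J", J)
        for name in ("A_target", "P_target", "lambda_a", "lambda_p"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.T <= 0:
            raise ValueError("temperature T must be > 0")
        if self.Y < 0:
            raise ValueError("yield Y must be >= 0")
        if self.boundary not in ("fixed-medium", "periodic"):
            raise ValueError("boundary must be 'fixed-medium' or 'periodic'")
        if self.neighbourhood is None:
            raise ValueError("a neighbourhood is required")
        if self.copy_neighbourhood is None:
            default_level = 2 if self.neighbourhood.dim == 2 else 3
            object.__setattr__(
                self,
                "copy_neighbourhood",
                build_neighbourhood(level=default_level, dim=self.neighbourhood.dim),
            )

    @property
    def n_types(self) -> int:
        return self.J.shape[0] - 1

    @property
    def dim(self) -> int:
        return self.neighbourhood.dim


class LatticeState:
    """Label grid plus the per-cell ledger (type, n_sites, perimeter proxy)."""

    def __init__(self, labels: np.ndarray, cell_types: dict[int, int],
                 neighbourhood: Neighbourhood, boundary: str = "fixed-medium"):
        self.labels = np.ascontiguousarray(labels, dtype=np.int32)
        if self.labels.ndim != neighbourhood.dim:
            raise ValueError("label grid dimensionality does not match neighbourhood")
        self.neighbourhood = neighbourhood
        self.boundary = boundary
        self.mcs = 0
        max_id = int(self.labels.max(initial=0))
        for cid in cell_types:
            max_id = max(max_id, cid)
        self.cell_type = np.zeros(max_id + 1, dtype=np.int32)
        for cid, t in cell_types.items():
            self.cell_type[cid] = t
        self.n_sites = np.zeros(max_id + 1, dtype=np.int64)
        self.p_cpm = np.zeros(max_id + 1, dtype=np.int64)
        recount_ledger(self)

    def cells(self) -> dict[int, tuple[int, int, int]]:
        """Living cells: id -> (type, n_sites, p_cpm)."""
        return {
            int(cid): (int(self.cell_type[cid]), int(self.n_sites[cid]),
                       int(self.p_cpm[cid]))
            for cid in range(1, len(self.n_sites))
            if self.n_sites[cid] > 0
        }

    def copy(self) -> "LatticeState":
        new = object.__new__(LatticeState)
        new.labels = self.labels.copy()
        new.neighbourhood = self.neighbourhood
        new.boundary = self.boundary
        new.mcs = self.mcs
        new.cell_type = self.cell_type.copy()
        new.n_sites = self.n_sites.copy()
        new.p_cpm = self.p_cpm.copy()
        return new


def _shifted_labels(labels: np.ndarray, offset, boundary: str) -> np.ndarray:
    """Labels at site + offset; out-of-lattice reads are medium (fixed)."""
    if boundary == "periodic":
        return np.roll(labels, shift=tuple(-int(o) for o in offset),
                       axis=tuple(range(labels.ndim)))
    out = np.zeros_like(labels)
    src = []
    dst = []
    for o, n in zip(offset, labels.shape):
        o = int(o)
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = labels[tuple(src)]
    return out


def recount_ledger(state: LatticeState) -> None:
    """Recompute n_sites and p_CPM from scratch (vectorised over offsets)."""
    labels = state.labels
    max_id = len(state.n_sites) - 1
    state.n_sites[:] = np.bincount(labels.ravel(), minlength=max_id + 1)[: max_id + 1]
    state.n_sites[0] = 0
    p = np.zeros(max_id + 1, dtype=np.int64)
    for off in state.neighbourhood.offsets:
        neigh = _shifted_labels(labels, off, state.boundary)
        diff = (labels != neigh) & (labels > 0)
        p += np.bincount(labels[diff].ravel(), minlength=max_id + 1)[: max_id + 1]
    state.p_cpm[:] = p


def hamiltonian(state: LatticeState, params: CPMParams) -> float:
    """Total energy, recomputed globally from the grid.

    Adhesion counts every unordered neighbouring-site pair with distinct
    labels once with J[type_i, type_j]; the per-cell elastic terms use the
    ledger-free proxy recount.
    """
    labels = state.labels
    if labels.max(initial=0) >= len(state.cell_type):
        raise ValueError("grid contains a label without a cell-table entry")
    if state.boundary == "periodic":
        padded = labels
    else:
        # pad with medium so that real/virtual-medium pairs are seen from
        # both sides, like every other pair, before halving
        pad = int(math.ceil(state.neighbourhood.radius))
        padded = np.pad(labels, pad)
    types = state.cell_type[padded]
    adhesion = 0.0
    for off in state.neighbourhood.offsets:
        neigh = _shifted_labels(padded, off, state.boundary)
        diff = padded != neigh
        t2 = state.cell_type[neigh]
        adhesion += params.J[types[diff], t2[diff]].sum()
    adhesion /= 2.0  # each unordered pair seen from both sides

    # elastic terms from a fresh recount, independent of the running ledger
    check = state.copy()
    recount_ledger(check)
    elastic = 0.0
    for cid in range(1, len(check.n_sites)):
        n = check.n_sites[cid]
        if n == 0:
            continue
        t = check.cell_type[cid]
        elastic += params.lambda_p[t] * (check.p_cpm[cid] - params.P_target[t]) ** 2
        elastic += params.lambda_a[t] * (n - params.A_target[t]) ** 2
    return float(adhesion + elastic)


def _site_label(labels: np.ndarray, idx: tuple[int, ...], boundary: str) -> int:
    for i, n in zip(idx, labels.shape):
        if i < 0 or i >= n:
            if boundary == "periodic":
                idx = tuple(j % n for j, n in zip(idx, labels.shape))
                break
            return 0
    return int(labels[idx])


def delta_energy(
    state: LatticeState, site: tuple[int, ...], new_label: int, params: CPMParams
) -> float:
    """Energy change of relabelling ``site`` to ``new_label``, computed locally.

    One pass over the shared neighbourhood yields the adhesion change and
    the foreign-site counts from which the perimeter-proxy changes of the
    losing and gaining cells follow; the area terms change by one site each.
    """
    labels = state.labels
    old = int(labels[site])
    if new_label == old:
        raise ValueError("new label equals the current label")
    t_old = int(state.cell_type[old]) if old else 0
    t_new = int(state.cell_type[new_label]) if new_label else 0

    n_off = len(state.neighbourhood.offsets)
    cnt_old = 0  # foreign sites around `site` w.r.t. the old label
    cnt_new = 0  # w.r.t. the new label
    d_adh = 0.0
    for off in state.neighbourhood.offsets:
        idx = tuple(int(s + o) for s, o in zip(site, off))
        lab = _site_label(labels, idx, state.boundary)
        t_lab = int(state.cell_type[lab]) if lab else 0
        if lab != old:
            cnt_old += 1
            d_adh -= params.J[t_old, t_lab]
        if lab != new_label:
            cnt_new += 1
            d_adh += params.J[t_new, t_lab]

    dE = d_adh
    if old > 0:
        t = t_old
        p0 = state.p_cpm[old]
        dp = n_off - 2 * cnt_old  # -cnt_old (own) + (n_off - cnt_old) (others)
        dE += params.lambda_p[t] * (
            (p0 + dp - params.P_target[t]) ** 2 - (p0 - params.P_target[t]) ** 2
        )
        n0 = state.n_sites[old]
        dE += params.lambda_a[t] * (
            (n0 - 1 - params.A_target[t]) ** 2 - (n0 - params.A_target[t]) ** 2
        )
    if new_label > 0:
        t = t_new
        p0 = state.p_cpm[new_label]
        dp = 2 * cnt_new - n_off
        dE += params.lambda_p[t] * (
            (p0 + dp - params.P_target[t]) ** 2 - (p0 - params.P_target[t]) ** 2
        )
        n0 = state.n_sites[new_label]
        dE += params.lambda_a[t] * (
            (n0 + 1 - params.A_target[t]) ** 2 - (n0 - params.A_target[t]) ** 2
        )
    return float(dE)


def _apply_flip(state: LatticeState, site, new_label: int) -> None:
    labels = state.labels
    old = int(labels[site])
    n_off = len(state.neighbourhood.offsets)
    cnt_old = 0
    cnt_new = 0
    for off in state.neighbourhood.offsets:
        idx = tuple(int(s + o) for s, o in zip(site, off))
        lab = _site_label(labels, idx, state.boundary)
        if lab != old:
            cnt_old += 1
        if lab != new_label:
            cnt_new += 1
    labels[site] = new_label
    if old > 0:
        state.n_sites[old] -= 1
        state.p_cpm[old] += n_off - 2 * cnt_old
        if state.n_sites[old] == 0:
            state.p_cpm[old] = 0
    if new_label > 0:
        state.n_sites[new_label] += 1
        state.p_cpm[new_label] += 2 * cnt_new - n_off


def attempt_copy(
    state: LatticeState,
    site: tuple[int, ...],
    source_label: int,
    params: CPMParams,
    rng: np.random.Generator,
    *,
    uniform: float | None = None,
) -> bool:
    """One modified-Metropolis copy attempt; updates grid and ledger on accept.

    ``uniform`` allows a pre-drawn acceptance variate (used by run_mcs to
    keep the stream order identical across code paths).
    """
    if params.T <= 0:
        raise ValueError("temperature T must be > 0")
    dE = delta_energy(state, site, source_label, params)
    if dE < -params.Y:
        accept = True
    else:
        u = rng.random() if uniform is None else uniform
        accept = u < math.exp(-(dE + params.Y) / params.T)
    if accept:
        _apply_flip(state, site, source_label)
    return accept


# --------------------------------------------------------------------------
# MCS sweeps: numba kernel and an exactly equivalent pure-Python reference
# --------------------------------------------------------------------------


@njit(cache=True)
def _sweep_kernel(
    labels,  # int32 flat
    shape,  # int64[dim]
    cell_type,  # int32[max_id+1]
    n_sites,  # int64
    p_cpm,  # int64
    J,  # float64 2d
    A_t,
    P_t,
    lam_a,
    lam_p,
    T,
    Y,
    offs,  # int64[n_off, dim]  shared neighbourhood
    copy_offs,  # int64[m, dim]
    periodic,  # bool
    perm,  # int64[N] site visit order
    src_idx,  # int64[N] copy-source indices
    unif,  # float64[N]
):
    dim = shape.shape[0]
    n_off = offs.shape[0]
    N = perm.shape[0]
    coord = np.empty(dim, dtype=np.int64)
    nb = np.empty(dim, dtype=np.int64)
    for step in range(N):
        flat = perm[step]
        rem = flat
        for d in range(dim - 1, -1, -1):
            coord[d] = rem % shape[d]
            rem //= shape[d]
        # copy source
        ok = True
        for d in range(dim):
            nb[d] = coord[d] + copy_offs[src_idx[step], d]
            if nb[d] < 0 or nb[d] >= shape[d]:
                if periodic:
                    nb[d] = nb[d] % shape[d]
                else:
                    ok = False
        if ok:
            f2 = 0
            for d in range(dim):
                f2 = f2 * shape[d] + nb[d]
            new_label = labels[f2]
        else:
            new_label = 0  # immutable medium frame
        old = labels[flat]
        if new_label == old:
            continue
        t_old = cell_type[old] if old > 0 else 0
        t_new = cell_type[new_label] if new_label > 0 else 0
        cnt_old = 0
        cnt_new = 0
        d_adh = 0.0
        for j in range(n_off):
            ok2 = True
            for d in range(dim):
                nb[d] = coord[d] + offs[j, d]
                if nb[d] < 0 or nb[d] >= shape[d]:
                    if periodic:
                        nb[d] = nb[d] % shape[d]
                    else:
                        ok2 = False
            if ok2:
                f2 = 0
                for d in range(dim):
                    f2 = f2 * shape[d] + nb[d]
                lab = labels[f2]
            else:
                lab = 0
            t_lab = cell_type[lab] if lab > 0 else 0
            if lab != old:
                cnt_old += 1
                d_adh -= J[t_old, t_lab]
            if lab != new_label:
                cnt_new += 1
                d_adh += J[t_new, t_lab]
        dE = d_adh
        if old > 0:
            p0 = p_cpm[old]
            dp = n_off - 2 * cnt_old
            dE += lam_p[t_old] * (
                (p0 + dp - P_t[t_old]) ** 2 - (p0 - P_t[t_old]) ** 2
            )
            n0 = n_sites[old]
            dE += lam_a[t_old] * (
                (n0 - 1 - A_t[t_old]) ** 2 - (n0 - A_t[t_old]) ** 2
            )
        if new_label > 0:
            p0 = p_cpm[new_label]
            dp = 2 * cnt_new - n_off
            dE += lam_p[t_new] * (
                (p0 + dp - P_t[t_new]) ** 2 - (p0 - P_t[t_new]) ** 2
            )
            n0 = n_sites[new_label]
            dE += lam_a[t_new] * (
                (n0 + 1 - A_t[t_new]) ** 2 - (n0 - A_t[t_new]) ** 2
            )
        if dE < -Y:
            accept = True
        else:
            accept = unif[step] < math.exp(-(dE + Y) / T)
        if accept:
            labels[flat] = new_label
            if old > 0:
                n_sites[old] -= 1
                p_cpm[old] += n_off - 2 * cnt_old
                if n_sites[old] == 0:
                    p_cpm[old] = 0
            if new_label > 0:
                n_sites[new_label] += 1
                p_cpm[new_label] += 2 * cnt_new - n_off


def _sweep_python(state: LatticeState, params: CPMParams, perm, src_idx, unif):
    shape = state.labels.shape
    copy_offs = params.copy_neighbourhood.offsets
    for step, flat in enumerate(perm):
        site = np.unravel_index(int(flat), shape)
        src = tuple(int(s + o) for s, o in zip(site, copy_offs[src_idx[step]]))
        new_label = _site_label(state.labels, src, state.boundary)
        old = int(state.labels[site])
        if new_label == old:
            continue
        attempt_copy(state, site, new_label, params, rng=None,
                     uniform=float(unif[step]))


@dataclass
class Trajectory:
    """Per-cell time series and optional raster snapshots from a run."""

    table: pd.DataFrame
    snapshots: list[tuple[int, np.ndarray]]
    final_state: LatticeState


def run_mcs(
    state: LatticeState,
    params: CPMParams,
    n_mcs: int,
    rng_seed: int,
    *,
    record_every: int = 1,
    snapshot_every: int = 0,
    use_numba: bool = True,
) -> Trajectory:
    """Run ``n_mcs`` Monte Carlo steps, mutating ``state`` in place.

    Per MCS the random stream yields, in order: a permutation of all sites,
    one copy-source index per site, one acceptance uniform per site.  The
    trajectory table records, at ``record_every`` strides and at the final
    MCS, per living cell: mcs, cell id, type, n_sites, p_cpm and the
    geometric conversions a = n/k^2 (n/k^3 in 3D) and p = p_cpm/xi.
    """
    rng = np.random.default_rng(rng_seed)
    xi = params.neighbourhood.xi()
    dim = state.labels.ndim
    N = state.labels.size
    shape_arr = np.asarray(state.labels.shape, dtype=np.int64)
    offs = np.ascontiguousarray(params.neighbourhood.offsets, dtype=np.int64)
    copy_offs = np.ascontiguousarray(params.copy_neighbourhood.offsets, dtype=np.int64)
    periodic = state.boundary == "periodic"
    flat = state.labels.reshape(-1)

    rows = []
    snaps: list[tuple[int, np.ndarray]] = []

    def record(mcs):
        for cid in range(1, len(state.n_sites)):
            n = int(state.n_sites[cid])
            if n == 0:
                continue
            t = int(state.cell_type[cid])
            p = int(state.p_cpm[cid])
            # geometric units of the reference resolution: lengths shrink by
            # k, areas by k^2 (volumes by k^3), surfaces by k^2
            rows.append(
                (mcs, cid, t, n, p, n / params.k**dim,
                 p / (xi * params.k ** (dim - 1)))
            )

    record(state.mcs)
    if snapshot_every:
        snaps.append((state.mcs, state.labels.copy()))

    for i in range(n_mcs):
        perm = rng.permutation(N).astype(np.int64)
        src_idx = rng.integers(0, len(copy_offs), size=N).astype(np.int64)
        unif = rng.random(N)
        if use_numba and _HAVE_NUMBA:
            _sweep_kernel(
                flat, shape_arr, state.cell_type, state.n_sites, state.p_cpm,
                params.J, params.A_target, params.P_target,
                params.lambda_a, params.lambda_p,
                float(params.T), float(params.Y),
                offs, copy_offs, periodic, perm, src_idx, unif,
            )
        else:
            _sweep_python(state, params, perm, src_idx, unif)
        state.mcs += 1
        if (state.mcs % record_every == 0) or (i == n_mcs - 1):
            record(state.mcs)
        if snapshot_every and (state.mcs % snapshot_every == 0 or i == n_mcs - 1):
            snaps.append((state.mcs, state.labels.copy()))

    table = pd.DataFrame(
        rows,
        columns=["mcs", "cell_id", "type", "n_sites", "p_cpm", "area_geo",
                 "perim_geo"],
    ).drop_duplicates(subset=["mcs", "cell_id"])
    return Trajectory(table=table, snapshots=snaps, final_state=state)


def measure_cell(
    state: LatticeState, cell_id: int, xi: float | None = None, k: float = 1.0
) -> tuple[int, int, float, float]:
    """(n_sites, p_cpm, geometric area, geometric perimeter) for one cell."""
    if cell_id < 1 or cell_id >= len(state.n_sites) or state.n_sites[cell_id] == 0:
        raise KeyError(f"no living cell with id {cell_id}")
    if xi is None:
        xi = state.neighbourhood.xi()
    n = int(state.n_sites[cell_id])
    p = int(state.p_cpm[cell_id])
    dim = state.labels.ndim
    return n, p, n / k**dim, p / (xi * k ** (dim - 1))
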