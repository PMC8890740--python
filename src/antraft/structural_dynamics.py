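"""Per-step update of the structural network and water lattice.

Three operations run in order inside a raft-mode timestep, after the Vicsek
heading update and before the free agents are stepped:

1. :func:`contract_structural` — every structural pair within the
   contraction radius ``R_r`` is assigned the target separation
   ``d_ij * exp(-ddot * dt)`` and positions are relaxed by an overdamped
   Jacobi iteration until the pair residuals fall below the configured
   thresholds.  The anchor never moves; free agents ride their nodes.
2. :func:`pack_water` — water nodes are advected toward the domain centre
   at the same rate and then spread apart by short-range Gaussian pairwise
   repulsion.  The coupling is one-way: structural nodes repel water but
   are never displaced here.
3. :func:`enforce_density` — wherever a density-grid cell exceeds the
   permissible node count, the closest pair in the cell loses one member:
   a deleted water node is reseeded at the domain boundary, a deleted
   structural node unbinds into the freely active layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import relax_pairs, relax_water
from .core import STRUCT, WATER, SimParams, SimState

__all__ = [
    "PairList",
    "UnbindReport",
    "ContractionError",
    "neighbor_pairs",
    "contract_structural",
    "relax_pairs_python",
    "pack_water",
    "enforce_density",
    "seed_boundary_water",
]


class ContractionError(RuntimeError):
    """Raised when the contraction relaxation fails to converge."""


@dataclass
class PairList:
    """Unique node pairs (i < j) within a query radius."""

    i: np.ndarray
    j: np.ndarray
    vec: np.ndarray   # X[i] - X[j]
    dist: np.ndarray

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class UnbindReport:
    """Bookkeeping for one density-enforcement pass."""

    n_unbind: int = 0          # structural -> free conversions
    water_deleted: int = 0
    water_reseeded: int = 0
    n_structural_before: int = 0
    skipped_conversions: int = 0   # deferred: no vacancy available
    unbind_positions: list = field(default_factory=list)


def neighbor_pairs(positions: np.ndarray, radius: float) -> PairList:
    """All unordered pairs with Euclidean distance <= radius (KD-tree)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions = np.asarray(positions, dtype=float)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return PairList(np.empty(0, np.int64), np.empty(0, np.int64),
                        np.empty((0, 2)), np.empty(0))
    i, j = pairs[:, 0], pairs[:, 1]
    vec = positions[i] - positions[j]
    return PairList(i.astype(np.int64), j.astype(np.int64), vec,
                    np.hypot(vec[:, 0], vec[:, 1]))


def relax_pairs_python(X, pi, pj, target, inv_nu, res_max, res_mean,
                       max_iter, anchor):
    """Reference implementation of the relaxation sweep (tests only).

    ``inv_nu`` may be a scalar or a per-node array.
    """
    anchor_pos = X[anchor].copy()
    inv_nu = np.broadcast_to(np.asarray(inv_nu, float), (len(X),))
    for it in range(max_iter + 1):
        res = (X[pi] - X[pj]) - target
        rn = np.hypot(res[:, 0], res[:, 1])
        if rn.max() <= res_max and rn.mean() <= res_mean:
            return it, True
        if it == max_iter:
            return it, False
        disp = np.zeros_like(X)
        np.add.at(disp, pi, -res * inv_nu[pi, None])
        np.add.at(disp, pj, res * inv_nu[pj, None])
        X += disp
        X[anchor] = anchor_pos
    return max_iter, False


def contract_structural(state: SimState, params: SimParams) -> None:
    """One pairwise-contraction step of the structural network.

    Pairs are computed once per step from the positions at step start; the
    target separation of every pair shrinks by ``exp(-ddot * dt)``.  Raises
    :class:`ContractionError` if the residual thresholds are not reached
    within ``relax_max_iter`` sweeps.
    """
    sids = state.nodes.ids_of(STRUCT)
    if len(sids) < 2:
        return
    X = np.ascontiguousarray(state.nodes.pos[sids])
    pl = neighbor_pairs(X, params.R_r_zeta)
    if len(pl) == 0:
        return
    target = pl.vec * params.contraction_factor
    anchor_local = int(np.searchsorted(sids, state.nodes.anchor))
    if params.relax_warm_start and params.contraction_factor != 1.0:
        # uniform scaling about the fixed anchor satisfies every pair
        # target exactly; start the iteration there
        a = X[anchor_local].copy()
        X = np.ascontiguousarray(a + (X - a) * params.contraction_factor)
    # Jacobi stability requires the local damping to exceed roughly the
    # node's pair degree; raise nu per node where the network is locally
    # dense so one crowded spot does not slow the whole relaxation.
    deg = np.bincount(pl.i, minlength=len(sids))
    deg += np.bincount(pl.j, minlength=len(sids))
    nu = np.maximum(params.relax_damping, 1.05 * deg)
    iters, ok = relax_pairs(
        X, pl.i, pl.j,
        np.ascontiguousarray(target[:, 0]), np.ascontiguousarray(target[:, 1]),
        np.ascontiguousarray(1.0 / nu), params.residual_max,
        params.residual_mean, params.relax_max_iter, anchor_local)
    if not ok:
        raise ContractionError(
            f"contraction relaxation did not converge: {iters} sweeps, "
            f"{len(pl)} pairs, {len(sids)} structural nodes "
            f"(nu={params.relax_damping}, cap={params.relax_max_iter})")
    state.nodes.pos[sids] = X


# Repulsion beyond mu + 3 sigma is ~1% of the peak and is truncated; the
# extra 0.5 zeta of query slack covers movement during the relaxation.
_REPULSION_CUTOFF_SIGMAS = 3.0
_PAIR_SLACK = 0.5


def pack_water(state: SimState, params: SimParams) -> None:
    """Advect water toward the origin, then apply Gaussian pairwise
    repulsion (close packing).

    The advection matches the structural contraction rate so the water
    field tracks the shrinking raft; the repulsion (from both water and
    structural neighbours) is applied ``water_max_iter`` times per step
    (default once - the printed strength balances the per-step advection
    at about unit spacing), keeping water evenly spaced against the raft
    edge.  One-way coupling: structural positions are never altered.
    """
    wids = state.nodes.ids_of(WATER)
    if len(wids) == 0:
        return
    state.nodes.pos[wids] *= params.contraction_factor

    sids = state.nodes.ids_of(STRUCT)
    W = np.ascontiguousarray(state.nodes.pos[wids])
    S = np.ascontiguousarray(state.nodes.pos[sids])
    cutoff = (params.water_mu + _REPULSION_CUTOFF_SIGMAS * params.water_sigma
              + _PAIR_SLACK)
    wtree = cKDTree(W)
    ww = wtree.query_pairs(cutoff, output_type="ndarray")
    ws = wtree.query_ball_tree(cKDTree(S), cutoff)
    wsi = np.fromiter((i for i, lst in enumerate(ws) for _ in lst),
                      dtype=np.int64)
    wsj = np.fromiter((j for lst in ws for j in lst), dtype=np.int64)
    amp = params.water_kappa_over_nu / (params.water_sigma
                                        * math.sqrt(2 * math.pi))
    relax_water(W, S,
                np.ascontiguousarray(ww[:, 0], dtype=np.int64),
                np.ascontiguousarray(ww[:, 1], dtype=np.int64),
                wsi, wsj, amp,
                1.0 / (2.0 * params.water_sigma ** 2), params.water_mu,
                params.water_tol, params.water_max_iter)
    state.nodes.pos[wids] = W


def seed_boundary_water(state: SimState, n: int) -> np.ndarray:
    """Seed ``n`` water nodes uniformly on the square boundary ring of
    width 1 zeta just outside the domain proper, returning their ids.

    The ring lies outside the density-enforcement grid, so freshly seeded
    water acts as a reservoir that is advected back into the domain as the
    interior drains, instead of being deleted again immediately.
    """
    hw = state.nodes.domain_half_width
    rng = state.rng
    side = rng.integers(0, 4, size=n)
    along = rng.uniform(-hw, hw, size=n)
    depth = rng.uniform(hw, hw + 1.0, size=n)
    x = np.where(side < 2, along, np.where(side == 2, depth, -depth))
    y = np.where(side < 2, np.where(side == 0, depth, -depth), along)
    ids = state.nodes.add(np.column_stack([x, y]), WATER)
    state.occupant = np.concatenate(
        [state.occupant, np.full(len(ids), -1, dtype=np.int64)])
    return ids


def _nearest_vacant_structural(state: SimState, point: np.ndarray,
                               exclude: int = -1) -> int:
    """Id of the nearest alive, unoccupied structural node, or -1."""
    mask = (state.nodes.alive & (state.nodes.kind == STRUCT)
            & (state.occupant == -1))
    if exclude >= 0:
        mask[exclude] = False
    ids = np.flatnonzero(mask)
    if len(ids) == 0:
        return -1
    d = state.nodes.pos[ids] - point
    return int(ids[np.argmin(d[:, 0] ** 2 + d[:, 1] ** 2)])


def enforce_density(state: SimState, params: SimParams) -> UnbindReport:
    """Delete nodes wherever a grid cell exceeds the permissible count.

    The domain is covered by an axis-aligned grid of ``L_g x L_g`` cells
    anchored at the domain corner (half-open ``[x, x + L_g)``).  In every
    cell holding more than ``N_p`` nodes the closest pair is found and one
    of its two members is deleted uniformly at random (never the anchor),
    repeating until the cell complies.  Deleted water is reseeded on the
    boundary ring; a deleted structural node is converted to a free agent
    placed on the nearest vacant structural node.  If no vacancy exists the
    deletion is deferred to a later step (the raft is fully jammed).
    """
    rep = UnbindReport(n_structural_before=state.nodes.n_structural)
    nodes = state.nodes
    hw = nodes.domain_half_width
    lg = params.L_g
    alive = np.flatnonzero(nodes.alive)
    ncell = max(1, int(math.ceil(2.0 * hw / lg)))
    # nodes outside the domain proper (the boundary reservoir) are exempt
    inside = (np.abs(nodes.pos[alive, 0]) <= hw) \
        & (np.abs(nodes.pos[alive, 1]) <= hw)
    alive = alive[inside]
    ix = np.clip(((nodes.pos[alive, 0] + hw) // lg).astype(np.int64),
                 0, ncell - 1)
    iy = np.clip(((nodes.pos[alive, 1] + hw) // lg).astype(np.int64),
                 0, ncell - 1)
    key = ix * ncell + iy
    order = np.argsort(key, kind="stable")
    key_sorted = key[order]
    ids_sorted = alive[order]
    cell_starts = np.flatnonzero(np.r_[True, np.diff(key_sorted) > 0])
    cell_ends = np.r_[cell_starts[1:], len(key_sorted)]
    rng = state.rng

    for s, e in zip(cell_starts, cell_ends):
        if e - s <= params.N_p:
            continue
        members = list(ids_sorted[s:e])
        while len(members) > params.N_p:
            P = nodes.pos[members]
            d2 = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            a, b = np.unravel_index(np.argmin(d2), d2.shape)
            pick = rng.integers(0, 2)
            victim = members[a] if pick == 0 else members[b]
            if victim == nodes.anchor:
                victim = members[b] if pick == 0 else members[a]
            vpos = nodes.pos[victim].copy()
            if nodes.kind[victim] == WATER:
                nodes.kill(victim)
                rep.water_deleted += 1
            else:
                rider = state.occupant[victim]
                if rider >= 0:
                    # relocate the rider before removing its node
                    dest = _nearest_vacant_structural(state, vpos, exclude=victim)
                    if dest < 0:
                        rep.skipped_conversions += 1
                        break
                    state.occupant[victim] = -1
                    state.occupant[dest] = rider
                    state.agents.node[rider] = dest
                dest = _nearest_vacant_structural(state, vpos, exclude=victim)
                if dest < 0:
                    if rider >= 0:   # roll the rider back, defer entirely
                        prev = state.agents.node[rider]
                        state.occupant[prev] = -1
                        state.occupant[victim] = rider
                        state.agents.node[rider] = victim
                    rep.skipped_conversions += 1
                    break
                nodes.kill(victim)
                theta = rng.uniform(0.0, 2.0 * math.pi)
                aid = state.agents.add(np.array([dest]), np.array([theta]),
                                       nodes.pos[dest][None, :])[0]
                state.occupant[dest] = aid
                rep.n_unbind += 1
                rep.unbind_positions.append((float(vpos[0]), float(vpos[1])))
                state.events.log_unbind(state.step, float(vpos[0]),
                                        float(vpos[1]))
            members.remove(victim)
    if rep.water_deleted:
        # batch reseed at the end of the pass, one node per deletion
        seed_boundary_water(state, rep.water_deleted)
        rep.water_reseeded = rep.water_deleted
    return rep
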