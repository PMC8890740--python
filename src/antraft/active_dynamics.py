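"""Freely active agents: Vicsek alignment, lattice-constrained stepping,
pausing, and the edge-deposition rule.

A free agent's preferred heading is updated by the Vicsek rule (circular
mean of neighbouring free-agent headings plus uniform noise).  Movement is
constrained to the node lattice: each agent ranks its candidate nodes
(up to 18 within ``R_DOF``) by how closely their bearing matches the
preferred heading, discards candidates beyond the turning limit, and takes
the first eligible one.  Occupied structural nodes are skipped; a water
candidate is taken only if the deposition inequality

    A * N_sigma * phi_sigma  >  N_omega * phi_omega

holds, in which case the water node joins the structural network and the
agent leaves the free layer.  An agent with no eligible candidate pauses
for 2-4 timesteps and then reorients at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import step_agents_kernel
from .core import STRUCT, WATER, SimParams, SimState

__all__ = [
    "DofTable",
    "DepositionInputs",
    "circular_mean",
    "relative_angle",
    "angular_difference",
    "vicsek_update",
    "deposition_inputs",
    "deposition_decision",
    "step_free_agents",
]

TWO_PI = 2.0 * math.pi
# 18 DOF = two hexagonal neighbour shells; one extra query slot for the
# agent's own node, which is removed from the table.
N_DOF = 18


def circular_mean(angles: np.ndarray,
                  rng: np.random.Generator | None = None) -> float:
    """Angle of the summed unit vectors, in [0, 2*pi).

    If the unit vectors cancel the mean direction is undefined and a random
    angle is drawn (``rng`` required in that case).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of no angles")
    sx = float(np.cos(angles).sum())
    sy = float(np.sin(angles).sum())
    if math.hypot(sx, sy) < 1e-12:
        if rng is None:
            raise ValueError("undefined circular mean and no rng supplied")
        return float(rng.uniform(0.0, TWO_PI))
    return math.atan2(sy, sx) % TWO_PI


def relative_angle(xi: np.ndarray, xj: np.ndarray) -> float:
    """Bearing of node j as seen from node i, mapped to [0, 2*pi).

    Equals atan2(yj - yi, xj - xi) on the upper branch and 2*pi + atan2 on
    the lower (yj < yi) branch.
    """
    dx = float(xj[0] - xi[0])
    dy = float(xj[1] - xi[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("relative angle of coincident points")
    return math.atan2(dy, dx) % TWO_PI


def angular_difference(theta: float, vartheta: float) -> float:
    """Absolute angular difference on the circle, in [0, pi]."""
    d = abs(vartheta - theta)
    return d if d < math.pi else TWO_PI - d


@dataclass
class DofTable:
    """Movement candidates of one agent, sorted ascending by ``dtheta``
    (ties: smaller distance, then smaller node id)."""

    node_ids: np.ndarray
    bearing: np.ndarray      # vartheta_ij in [0, 2*pi)
    dtheta: np.ndarray       # |theta_i - vartheta_ij| folded to [0, pi]
    dist: np.ndarray
    kind: np.ndarray
    occupied: np.ndarray


@dataclass
class DepositionInputs:
    """Local measurements entering the edge-deposition inequality."""

    n_sigma: int        # free agents within R, including self
    phi_sigma: float    # order vector of their headings projected on u_i
    n_omega: int        # water nodes within R
    phi_omega: float    # mean water direction projected on u_i

    @property
    def lhs(self) -> float:
        return self.n_sigma * self.phi_sigma

    @property
    def rhs(self) -> float:
        return self.n_omega * self.phi_omega


def deposition_decision(A: float, inputs: DepositionInputs) -> bool:
    """True iff ``A * N_sigma * phi_sigma > N_omega * phi_omega``."""
    if A <= 0:
        raise ValueError("activity A must be positive")
    return A * inputs.lhs > inputs.rhs


def _agent_tree(state: SimState, ids: np.ndarray,
                boxsize=None) -> tuple[cKDTree, np.ndarray]:
    pos = state.nodes.pos[state.agents.node[ids]]
    if boxsize is not None:
        pos = np.mod(pos, boxsize)
    return cKDTree(pos, boxsize=boxsize), pos


def deposition_inputs(state: SimState, agent_id: int,
                      params: SimParams) -> DepositionInputs:
    """Measure the deposition inputs for one agent (reference path).

    The sigma sum runs over free agents within ``R`` including the agent
    itself (paused agents included); the omega sum over alive water nodes
    within ``R``.  ``u_i`` is the agent's current preferred heading.
    """
    ids = state.agents.active_ids
    th_i = state.agents.theta[agent_id]
    u = np.array([math.cos(th_i), math.sin(th_i)])
    xi = state.nodes.pos[state.agents.node[agent_id]]

    apos = state.nodes.pos[state.agents.node[ids]]
    d = np.hypot(apos[:, 0] - xi[0], apos[:, 1] - xi[1])
    # in-contact walkers transmit their push; paused neighbours do not
    near = ids[(d <= params.R_zeta)
               & ((state.agents.pause[ids] == 0) | (ids == agent_id))]
    if agent_id not in near:
        near = np.append(near, agent_id)
    c = np.cos(state.agents.theta[near]).sum()
    s = np.sin(state.agents.theta[near]).sum()
    n_sigma = len(near)
    phi_sigma = float((c * u[0] + s * u[1]) / n_sigma)

    wids = state.nodes.ids_of(WATER)
    n_omega = 0
    phi_omega = 0.0
    if len(wids):
        wpos = state.nodes.pos[wids]
        dw = np.hypot(wpos[:, 0] - xi[0], wpos[:, 1] - xi[1])
        sel = (dw <= params.edge_detect_radius) & (dw > 0)
        n_omega = int(sel.sum())
        if n_omega:
            rhat = (wpos[sel] - xi) / dw[sel][:, None]
            if params.edge_inverse_r:
                rhat = rhat * (params.R_zeta / dw[sel])[:, None]
            m = rhat.mean(axis=0)
            phi_omega = float(m @ u)
    return DepositionInputs(n_sigma, phi_sigma, n_omega, phi_omega)


def vicsek_update(state: SimState, params: SimParams,
                  boxsize=None) -> None:
    """Synchronous heading update of all moving free agents.

    Each non-paused agent's heading becomes the circular mean of the
    headings of all free agents (including itself and paused neighbours)
    within ``R``, plus noise uniform on [-pi*eta, pi*eta].  Structural
    nodes exert no influence.  Paused agents keep their heading frozen.

    Draw order: noise for every active agent, then tie-break angles for
    every active agent (used only where the mean is undefined).
    """
    ids = state.agents.active_ids
    n = len(ids)
    if n == 0:
        return
    noise = state.rng.uniform(-math.pi * params.eta, math.pi * params.eta,
                              size=n)
    tie = state.rng.uniform(0.0, TWO_PI, size=n)
    theta = state.agents.theta[ids]
    sc = np.cos(theta).copy()
    ss = np.sin(theta).copy()
    tree, _ = _agent_tree(state, ids, boxsize)
    pairs = tree.query_pairs(params.R_zeta, output_type="ndarray")
    if len(pairs):
        np.add.at(sc, pairs[:, 0], np.cos(theta[pairs[:, 1]]))
        np.add.at(ss, pairs[:, 0], np.sin(theta[pairs[:, 1]]))
        np.add.at(sc, pairs[:, 1], np.cos(theta[pairs[:, 0]]))
        np.add.at(ss, pairs[:, 1], np.sin(theta[pairs[:, 0]]))
    norm = np.hypot(sc, ss)
    mean = np.where(norm < 1e-12, tie, np.arctan2(ss, sc))
    new_theta = np.mod(mean + noise, TWO_PI)
    moving = state.agents.pause[ids] == 0
    state.agents.theta[ids[moving]] = new_theta[moving]


def _candidate_tables(state: SimState, ids: np.ndarray, params: SimParams,
                      boxsize=None):
    """Up-to-18 nearest alive nodes within R_DOF for each agent, with
    bearings and distances; the agent's own node is excluded."""
    alive = np.flatnonzero(state.nodes.alive)
    pos = state.nodes.pos[alive]
    if boxsize is not None:
        pos = np.mod(pos, boxsize)
    tree = cKDTree(pos, boxsize=boxsize)
    own = state.agents.node[ids]
    apos = state.nodes.pos[own]
    if boxsize is not None:
        apos = np.mod(apos, boxsize)
    dist, li = tree.query(apos, k=N_DOF + 1,
                          distance_upper_bound=params.R_DOF)
    missing = li >= len(alive)
    gids = np.where(missing, -1, alive[np.where(missing, 0, li)])
    # drop the agent's own node from its table
    self_mask = gids == own[:, None]
    gids[self_mask] = -1
    dist[self_mask | missing] = np.inf

    dvec = np.where(gids[:, :, None] >= 0,
                    state.nodes.pos[gids] - state.nodes.pos[own][:, None, :],
                    0.0)
    if boxsize is not None:
        box = np.asarray(boxsize, dtype=float)
        dvec -= box * np.round(dvec / box)
    ang = np.mod(np.arctan2(dvec[:, :, 1], dvec[:, :, 0]), TWO_PI)
    dist = np.where(np.isinf(dist), -1.0, dist)
    # keep only up to N_DOF valid candidates per row (own node removed)
    return gids.astype(np.int64), ang, dist


def dof_table(state: SimState, agent_id: int, params: SimParams,
              boxsize=None) -> DofTable:
    """Sorted movement-DOF table of one agent (reference path)."""
    ids = np.array([agent_id])
    gids, ang, dist = _candidate_tables(state, ids, params, boxsize)
    valid = (gids[0] >= 0) & (dist[0] > 0)
    g, a, d = gids[0][valid], ang[0][valid], dist[0][valid]
    th = state.agents.theta[agent_id]
    dth = np.array([angular_difference(th, ai) for ai in a])
    order = np.lexsort((g, d, dth))
    g, a, d, dth = g[order], a[order], d[order], dth[order]
    return DofTable(g, a, dth, d, state.nodes.kind[g].copy(),
                    state.occupant[g] >= 0)


def _sigma_csr(state: SimState, ids: np.ndarray, params: SimParams,
               boxsize=None):
    """CSR adjacency (excluding self) of free agents within R."""
    n = len(ids)
    tree, _ = _agent_tree(state, ids, boxsize)
    pairs = tree.query_pairs(params.R_zeta, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    a = np.concatenate([pairs[:, 0], pairs[:, 1]])
    b = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(a, kind="stable")
    idx = np.ascontiguousarray(b[order])
    counts = np.bincount(a, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, idx


def step_free_agents(state: SimState, params: SimParams,
                     boxsize=None, engine: str = "numba") -> int:
    """Step every free agent once; returns the number of bind events.

    Pipeline: decrement pause timers (expiring agents reorient at random
    and may move this step); then agents are visited in a fresh random
    permutation and walk their candidate tables.  Candidate geometry and
    the sigma adjacency are frozen at sub-step start; node kinds and
    occupancy are live.  Each bind converts the water node to structural,
    removes the agent from the free layer, and one replacement water node
    is seeded at the domain boundary so the water population is conserved
    (skipped in periodic free-flow domains, which have no water).

    Draw order: reorientation angles for expiring agents, the permutation,
    one pause-duration uniform per agent, then boundary reseeds.
    """
    ids = state.agents.active_ids
    if len(ids) == 0:
        return 0
    ag = state.agents
    # pause bookkeeping (vectorized; order-independent)
    paused = ids[ag.pause[ids] > 0]
    expiring = paused[ag.pause[paused] == 1]
    ag.pause[paused] -= 1
    if len(expiring):
        ag.theta[expiring] = state.rng.uniform(0.0, TWO_PI,
                                               size=len(expiring))
    ag.prev_pos[ids] = state.nodes.pos[ag.node[ids]]

    perm = state.rng.permutation(len(ids))
    u_pause = state.rng.uniform(0.0, 1.0, size=len(ids))

    gids, ang, dist = _candidate_tables(state, ids, params, boxsize)
    indptr, sidx = _sigma_csr(state, ids, params, boxsize)

    theta = ag.theta[ids].copy()
    pause = ag.pause[ids].copy()
    anode = ag.node[ids].copy()
    free_flag = np.ones(len(ids), dtype=np.bool_)
    # occupancy in local agent indices for the kernel
    occ_local = np.full(len(state.nodes), -1, dtype=np.int64)
    occ_local[anode] = np.arange(len(ids))
    bind_agent = np.full(len(ids), -1, dtype=np.int64)
    bind_node = np.full(len(ids), -1, dtype=np.int64)
    lo, hi = params.pause_range

    if engine == "numba":
        n_binds = step_agents_kernel(
            perm, theta, pause, anode, free_flag,
            gids, ang, dist,
            state.nodes.kind, occ_local,
            params.A, params.edge_detect_radius,
            params.R_zeta if params.edge_inverse_r else 0.0,
            params.deposit_reach_zeta, params.turn_limit,
            u_pause, lo, hi - lo,
            indptr, sidx, bind_agent, bind_node)
    elif engine == "python":
        n_binds = _step_agents_python(
            perm, theta, pause, anode, free_flag,
            gids, ang, dist,
            state.nodes.kind, occ_local,
            params.A, params.edge_detect_radius,
            params.R_zeta if params.edge_inverse_r else 0.0,
            params.deposit_reach_zeta, params.turn_limit,
            u_pause, lo, hi - lo,
            indptr, sidx, bind_agent, bind_node)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    ag.pause[ids] = pause
    ag.node[ids] = anode
    state.occupant.fill(-1)
    still = np.flatnonzero(free_flag)
    state.occupant[anode[still]] = ids[still]
    for k in range(n_binds):
        a_local = bind_agent[k]
        node = bind_node[k]
        ag.active[ids[a_local]] = False
        p = state.nodes.pos[node]
        state.events.log_bind(state.step, float(p[0]), float(p[1]))
    if n_binds and boxsize is None:
        from .structural_dynamics import seed_boundary_water
        seed_boundary_water(state, n_binds)
    return int(n_binds)


def _step_agents_python(order, theta, pause, anode, free_flag,
                        cand_idx, cand_ang, cand_dist,
                        kind, occ, A, r_omega, w_ref, reach, turn_limit,
                        u_pause, pause_lo, pause_span,
                        sig_indptr, sig_idx, bind_agent, bind_node):
    """Pure-Python mirror of the numba stepping kernel (tests)."""
    n_binds = 0
    for a in order:
        if not free_flag[a] or pause[a] > 0:
            continue
        th = theta[a]
        u = np.array([math.cos(th), math.sin(th)])
        valid = (cand_idx[a] >= 0) & (cand_dist[a] > 0)
        cs = np.flatnonzero(valid)
        dth = np.array([angular_difference(th, cand_ang[a, c]) for c in cs])
        order_c = np.lexsort((cand_idx[a, cs], cand_dist[a, cs], dth))
        moved = False
        dep_known = False
        dep_ok = False
        for rank, (c, d) in enumerate(zip(cs[order_c], dth[order_c])):
            if d > turn_limit:
                break
            node = cand_idx[a, c]
            if kind[node] == STRUCT:
                if occ[node] == -1:
                    occ[anode[a]] = -1
                    occ[node] = a
                    anode[a] = node
                    moved = True
                    break
            else:
                # head-on encounters with in-contact water only
                if rank > 0 or cand_dist[a, c] > reach:
                    continue
                if not dep_known:
                    sx, sy = u[0], u[1]
                    for s in sig_idx[sig_indptr[a]:sig_indptr[a + 1]]:
                        if free_flag[s] and pause[s] == 0:
                            sx += math.cos(theta[s])
                            sy += math.sin(theta[s])
                    lhs = A * (sx * u[0] + sy * u[1])
                    wsel = (valid & (cand_dist[a] <= r_omega)
                            & (kind[cand_idx[a]] == WATER))
                    w = (w_ref / cand_dist[a][wsel] if w_ref > 0
                         else np.ones(int(wsel.sum())))
                    rhs = ((w * np.cos(cand_ang[a][wsel])).sum() * u[0]
                           + (w * np.sin(cand_ang[a][wsel])).sum() * u[1])
                    dep_ok = lhs > rhs
                    dep_known = True
                if dep_ok:
                    kind[node] = STRUCT
                    occ[anode[a]] = -1
                    free_flag[a] = False
                    anode[a] = node
                    bind_agent[n_binds] = a
                    bind_node[n_binds] = node
                    n_binds += 1
                    moved = True
                    break
        if not moved:
            pause[a] = pause_lo + int(u_pause[a] * (pause_span + 1))
    return n_binds
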