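"""Numba kernels for the per-step hot loops.

Pure-Python reference implementations of the same logic live in
``structural_dynamics`` / ``active_dynamics``; equivalence is enforced by
tests.  Kernels mutate their array arguments in place.
"""

import math

import numpy as np
from numba import njit

__all__ = ["relax_pairs", "step_agents_kernel"]


@njit(cache=True)
def relax_pairs(X, pi, pj, tx, ty, inv_nu, res_max, res_mean, max_iter,
                anchor):
    """Overdamped Jacobi relaxation of pairwise separation targets.

    X : (n,2) positions, updated in place.  pi, pj: pair index arrays.
    tx, ty: target separation vectors X[i]-X[j].  inv_nu: per-node
    damping reciprocals.  The anchor node is restored after every sweep.
    Returns (iterations, converged).
    """
    n = X.shape[0]
    m = pi.shape[0]
    if m == 0:
        return 0, True
    ax = X[anchor, 0]
    ay = X[anchor, 1]
    disp = np.zeros((n, 2))
    res_max2 = res_max * res_max
    it = 0
    for it in range(max_iter + 1):
        for q in range(n):
            disp[q, 0] = 0.0
            disp[q, 1] = 0.0
        rmax2 = 0.0
        for p in range(m):
            i = pi[p]
            j = pj[p]
            rx = X[i, 0] - X[j, 0] - tx[p]
            ry = X[i, 1] - X[j, 1] - ty[p]
            rn2 = rx * rx + ry * ry
            if rn2 > rmax2:
                rmax2 = rn2
            disp[i, 0] -= rx * inv_nu[i]
            disp[i, 1] -= ry * inv_nu[i]
            disp[j, 0] += rx * inv_nu[j]
            disp[j, 1] += ry * inv_nu[j]
        if rmax2 <= res_max2:
            # max criterion met: now check the mean residual too
            rsum = 0.0
            for p in range(m):
                rx = X[pi[p], 0] - X[pj[p], 0] - tx[p]
                ry = X[pi[p], 1] - X[pj[p], 1] - ty[p]
                rsum += math.sqrt(rx * rx + ry * ry)
            if rsum / m <= res_mean:
                return it, True
        if it == max_iter:
            return it, False
        for q in range(n):
            X[q, 0] += disp[q, 0]
            X[q, 1] += disp[q, 1]
        X[anchor, 0] = ax
        X[anchor, 1] = ay
    return it, False


@njit(cache=True)
def relax_water(W, S, wwi, wwj, wsi, wsj, amp, inv2s2, mu, tol, max_iter):
    """Iterate Gaussian pairwise repulsion on water nodes to equilibrium.

    W: (m,2) water positions (updated in place); S: fixed structural
    positions.  ww*: water-water pairs; ws*: (water, structural) pairs.
    Stops when the largest per-iteration displacement drops below tol.
    Returns the number of iterations run.
    """
    m = W.shape[0]
    disp = np.zeros((m, 2))
    it = 0
    for it in range(max_iter):
        for q in range(m):
            disp[q, 0] = 0.0
            disp[q, 1] = 0.0
        for p in range(wwi.shape[0]):
            i = wwi[p]
            j = wwj[p]
            dx = W[i, 0] - W[j, 0]
            dy = W[i, 1] - W[j, 1]
            d = math.sqrt(dx * dx + dy * dy)
            if d < 1e-9:
                continue
            f = amp * math.exp(-(d - mu) * (d - mu) * inv2s2) / d
            disp[i, 0] += f * dx
            disp[i, 1] += f * dy
            disp[j, 0] -= f * dx
            disp[j, 1] -= f * dy
        for p in range(wsi.shape[0]):
            i = wsi[p]
            j = wsj[p]
            dx = W[i, 0] - S[j, 0]
            dy = W[i, 1] - S[j, 1]
            d = math.sqrt(dx * dx + dy * dy)
            if d < 1e-9:
                continue
            f = amp * math.exp(-(d - mu) * (d - mu) * inv2s2) / d
            disp[i, 0] += f * dx
            disp[i, 1] += f * dy
        dmax = 0.0
        for q in range(m):
            W[q, 0] += disp[q, 0]
            W[q, 1] += disp[q, 1]
            dn = math.sqrt(disp[q, 0] ** 2 + disp[q, 1] ** 2)
            if dn > dmax:
                dmax = dn
        if dmax <= tol:
            return it + 1
    return it + 1


@njit(cache=True)
def step_agents_kernel(order, theta, pause, anode, free_flag,
                       cand_idx, cand_ang, cand_dist,
                       kind, occ, A, r_omega, w_ref, reach, turn_limit,
                       u_pause, pause_lo, pause_span,
                       sig_indptr, sig_idx,
                       bind_agent, bind_node):
    """Sequential lattice walk of all free agents for one timestep.

    Agents are visited in ``order`` (a permutation of local agent indices).
    Candidate tables (global node id / bearing / distance, -1 padded) are
    precomputed from the positions at the start of the sub-step; node kinds
    and occupancy are live, so earlier movers block or free sites for later
    agents.  A successful deposition flips the water node to structural and
    removes the agent from the free layer.  Returns the number of binds.
    """
    n_binds = 0
    kmax = cand_idx.shape[1]
    dth = np.empty(kmax)
    sort_ix = np.empty(kmax, dtype=np.int64)
    two_pi = 2.0 * math.pi
    for oo in range(order.shape[0]):
        a = order[oo]
        if not free_flag[a] or pause[a] > 0:
            continue
        th = theta[a]
        ux = math.cos(th)
        uy = math.sin(th)
        # angular difference to each candidate bearing, two-branch form
        nc = 0
        for c in range(kmax):
            if cand_idx[a, c] < 0 or cand_dist[a, c] <= 0.0:
                continue
            d = abs(cand_ang[a, c] - th)
            if d >= math.pi:
                d = two_pi - d
            dth[nc] = d
            sort_ix[nc] = c
            nc += 1
        # insertion sort by (dtheta, distance, node id)
        for u in range(1, nc):
            cu = sort_ix[u]
            du = dth[u]
            v = u - 1
            while v >= 0:
                cv = sort_ix[v]
                dv = dth[v]
                if (dv > du
                        or (dv == du and cand_dist[a, cv] > cand_dist[a, cu])
                        or (dv == du and cand_dist[a, cv] == cand_dist[a, cu]
                            and cand_idx[a, cv] > cand_idx[a, cu])):
                    sort_ix[v + 1] = cv
                    dth[v + 1] = dv
                    v -= 1
                else:
                    break
            sort_ix[v + 1] = cu
            dth[v + 1] = du

        moved = False
        dep_known = False
        dep_ok = False
        for u in range(nc):
            if dth[u] > turn_limit:
                break
            c = sort_ix[u]
            node = cand_idx[a, c]
            if kind[node] == 0:  # structural
                if occ[node] == -1:
                    occ[anode[a]] = -1
                    occ[node] = a
                    anode[a] = node
                    moved = True
                    break
            else:
                # Edge encounters are head-on only: the deposition rule is
                # evaluated just when the water node is the agent's
                # top-ranked candidate (a ~+-15 degree perception cone);
                # water met later in the walk is simply skipped.  Only
                # water in contact with the agent's node is enterable.
                if u > 0 or cand_dist[a, c] > reach:
                    continue
                if not dep_known:
                    # self-propulsion is transmitted by in-contact free
                    # agents that are actively walking; paused agents
                    # (stationary explorers) exert no push
                    sx = ux
                    sy = uy
                    for s in range(sig_indptr[a], sig_indptr[a + 1]):
                        b = sig_idx[s]
                        if free_flag[b] and pause[b] == 0:
                            sx += math.cos(theta[b])
                            sy += math.sin(theta[b])
                    lhs = A * (sx * ux + sy * uy)
                    wx = 0.0
                    wy = 0.0
                    for c2 in range(kmax):
                        nd = cand_idx[a, c2]
                        dd = cand_dist[a, c2]
                        if nd >= 0 and 0.0 < dd <= r_omega and kind[nd] == 1:
                            w = w_ref / dd if w_ref > 0.0 else 1.0
                            wx += w * math.cos(cand_ang[a, c2])
                            wy += w * math.sin(cand_ang[a, c2])
                    rhs = wx * ux + wy * uy
                    dep_ok = lhs > rhs
                    dep_known = True
                if dep_ok:
                    kind[node] = 0
                    occ[anode[a]] = -1
                    free_flag[a] = False
                    anode[a] = node
                    bind_agent[n_binds] = a
                    bind_node[n_binds] = node
                    n_binds += 1
                    moved = True
                    break
        if not moved:
            pause[a] = pause_lo + np.int64(u_pause[a] * (pause_span + 1))
    return n_binds
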