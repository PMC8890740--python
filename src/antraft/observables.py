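"""Measurements: strain rate, treadmilling rates, shape, order,
persistence length, and protrusion morphometrics.

Conventions: inputs are :class:`~antraft.simulator.Snapshot` objects or raw
arrays in zeta; reported lengths follow the field's conventions (body
lengths ``ell`` for protrusion widths, growth rates and tip radii; %/min
for rates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .core import STRUCT, WATER, UnitSystem

__all__ = [
    "StrainFit",
    "ShapeMetrics",
    "ProtrusionRecord",
    "strain_rate",
    "turnover_rates",
    "perimeter_agents",
    "surface_excess",
    "packing_fraction",
    "order_parameter",
    "persistence_length",
    "rasterize_structural",
    "detect_protrusions",
    "match_protrusions",
    "growth_rate",
    "pratt_fit",
    "boundary_contour",
    "tip_radius",
    "convex_edge_radii",
]

# perimeter agents have water within one body length (1 ell ~ 1.6 zeta)
PERIMETER_WATER_RADIUS_ZETA = 1.6


# --------------------------------------------------------------------------
# treadmilling / contraction
# --------------------------------------------------------------------------

@dataclass
class StrainFit:
    """Least-squares fit of inward radial speed against radius."""

    slope_pct_per_min: float
    intercept: float
    r_squared: float
    window: tuple[float, float]
    n_nodes: int


def strain_rate(snapshots, window: tuple[float, float]) -> StrainFit:
    """Global contractile strain rate from recorded snapshots.

    For every structural node alive throughout the window the inward radial
    speed toward the anchor is computed from its first-to-last displacement;
    the least-squares slope of speed against time-averaged radius is the
    strain rate (in %/min).  Nodes are matched across snapshots by
    persistent label.
    """
    snaps = [s for s in snapshots if window[0] <= s.t_min <= window[1]]
    if len(snaps) < 2:
        raise ValueError("need at least two snapshots spanning the window")
    w = snaps[-1].t_min - snaps[0].t_min
    if w < 13.0:
        warnings.warn(f"strain window of {w:.1f} min is shorter than the "
                      "13 min measurement convention", stacklevel=2)

    common: set | None = None
    for s in snaps:
        labels = set(s.node_label[s.node_alive & (s.node_kind == STRUCT)]
                     .tolist())
        common = labels if common is None else (common & labels)
    common_arr = np.fromiter(common, dtype=np.int64)
    if len(common_arr) == 0:
        raise ValueError("no structural nodes persist through the window")

    radii = np.empty((len(snaps), len(common_arr)))
    times = np.array([s.t_min for s in snaps])
    for k, s in enumerate(snaps):
        lut = {lab: i for i, lab in enumerate(s.node_label)}
        idx = np.array([lut[lab] for lab in common_arr])
        rel = s.node_pos[idx] - s.node_pos[s.anchor]
        radii[k] = np.hypot(rel[:, 0], rel[:, 1])
    speed = (radii[0] - radii[-1]) / w
    rbar = np.trapezoid(radii, times, axis=0) / w
    slope, intercept = np.polyfit(rbar, speed, 1)
    pred = slope * rbar + intercept
    ss_res = float(((speed - pred) ** 2).sum())
    ss_tot = float(((speed - speed.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StrainFit(slope_pct_per_min=100.0 * slope, intercept=intercept,
                     r_squared=r2, window=(snaps[0].t_min, snaps[-1].t_min),
                     n_nodes=len(common_arr))


def turnover_rates(metrics, bin_minutes: float = 1.0):
    """Edge-binding rate alpha and bulk unbinding rate delta, %/min.

    ``metrics`` is the per-step frame produced by the simulator (columns
    ``t_min``, ``binds``, ``unbinds``, ``n_structural``).  Events in each
    time bin are divided by the bin-mean structural population and the bin
    width; exact bookkeeping of the event log.
    """
    import pandas as pd

    if len(metrics) == 0:
        raise ValueError("empty metrics")
    if (metrics["n_structural"] <= 0).any():
        raise ValueError("structural count must stay positive")
    b = (metrics["t_min"] / bin_minutes).astype(int)
    g = metrics.groupby(b)
    out = pd.DataFrame({
        "t_mid": g["t_min"].mean(),
        "alpha": 100.0 * g["binds"].sum() / (g["n_structural"].mean()
                                             * bin_minutes),
        "delta": 100.0 * g["unbinds"].sum() / (g["n_structural"].mean()
                                               * bin_minutes),
    })
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# shape
# --------------------------------------------------------------------------

@dataclass
class ShapeMetrics:
    perimeter_count: int
    area_count: int
    surface_excess: float
    phi: float


def _fields(state):
    """(pos, kind, alive, anchor) from a SimState or Snapshot."""
    if hasattr(state, "nodes"):
        n = state.nodes
        return n.pos, n.kind, n.alive, n.anchor
    return state.node_pos, state.node_kind, state.node_alive, state.anchor


def perimeter_agents(state) -> np.ndarray:
    """Ids of structural nodes with at least one water node within 1.6
    zeta (one body length)."""
    pos, kind, alive, _ = _fields(state)
    sids = np.flatnonzero(alive & (kind == STRUCT))
    wids = np.flatnonzero(alive & (kind == WATER))
    if len(wids) == 0 or len(sids) == 0:
        return np.empty(0, dtype=np.int64)
    tree = cKDTree(pos[wids])
    d, _ = tree.query(pos[sids], k=1,
                      distance_upper_bound=PERIMETER_WATER_RADIUS_ZETA)
    return sids[np.isfinite(d)]


def surface_excess(state) -> float:
    """``S = C / (2 sqrt(pi A))`` from agent counts.

    C is the number of perimeter structural agents and A the total
    structural count; with the density held at ~1 node per zeta^2 both act
    as length/area measures.  S is 1 for a circle and grows with shape
    eccentricity.
    """
    pos, kind, alive, _ = _fields(state)
    a_r = int(np.count_nonzero(alive & (kind == STRUCT)))
    if a_r < 3:
        raise ValueError("raft too small for a shape measurement")
    c = len(perimeter_agents(state))
    return c / (2.0 * math.sqrt(math.pi * a_r))


def packing_fraction(state) -> float:
    """Active free agents per structural agent."""
    if hasattr(state, "nodes"):
        return state.agents.n_active / state.nodes.n_structural
    n_r = int(np.count_nonzero(state.node_alive & (state.node_kind == STRUCT)))
    return int(state.agent_active.sum()) / n_r


# --------------------------------------------------------------------------
# motion statistics
# --------------------------------------------------------------------------

def order_parameter(velocities: np.ndarray) -> float:
    """Norm of the mean velocity over the mean speed, in [0, 1]."""
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or len(v) == 0:
        raise ValueError("velocities must be a non-empty (N, 2) array")
    speeds = np.hypot(v[:, 0], v[:, 1])
    mean_speed = speeds.mean()
    if mean_speed == 0:
        raise ValueError("all speeds are zero")
    mv = v.mean(axis=0)
    return float(math.hypot(mv[0], mv[1]) / mean_speed)


def persistence_length(trajectories, max_lag_zeta: float = 10.0,
                       min_total_path_zeta: float = 160.0,
                       bin_width: float = 0.5,
                       units: UnitSystem | None = None) -> float:
    """Trajectory persistence length from the tangent correlation.

    Fits ``<cos(dtheta(s))> = exp(-s / l_p)`` over path-length lags
    ``s <= max_lag_zeta`` by least squares in log space (intercept forced
    through 1 at s=0).  Trajectories are (n, 2) arrays of unwrapped
    positions in zeta; zero-length steps (paused agents) are skipped.
    Returns ``l_p`` in body lengths; ``inf`` for straight trajectories
    (the fit only bounds l_p from below at the largest lag).
    """
    units = units or UnitSystem()
    nbins = int(math.ceil(max_lag_zeta / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    total_path = 0.0
    for traj in trajectories:
        traj = np.asarray(traj, dtype=float)
        steps = np.diff(traj, axis=0)
        lens = np.hypot(steps[:, 0], steps[:, 1])
        keep = lens > 1e-12
        steps, lens = steps[keep], lens[keep]
        if len(steps) < 2:
            continue
        total_path += lens.sum()
        ang = np.arctan2(steps[:, 1], steps[:, 0])
        s = np.concatenate([[0.0], np.cumsum(lens)[:-1]])
        # all pairs within the lag window
        for m in range(len(steps) - 1):
            smax = s[m] + max_lag_zeta
            n = np.searchsorted(s, smax, side="right")
            lag = s[m + 1:n] - s[m]
            if len(lag) == 0:
                continue
            b = np.minimum((lag / bin_width).astype(int), nbins - 1)
            np.add.at(sums, b, np.cos(ang[m + 1:n] - ang[m]))
            np.add.at(counts, b, 1)
    if total_path < min_total_path_zeta:
        raise ValueError(
            f"total path length {total_path:.0f} zeta below the minimum "
            f"{min_total_path_zeta:.0f}")
    have = counts > 0
    lags = (np.arange(nbins) + 0.5) * bin_width
    corr = np.full(nbins, np.nan)
    corr[have] = sums[have] / counts[have]
    pos_mask = have & (corr > 0)
    if pos_mask.sum() < 2:
        return float(units.zeta_to_ell(max_lag_zeta))  # lower bound
    x = lags[pos_mask]
    y = np.log(corr[pos_mask])
    slope = float((x * y).sum() / (x * x).sum())   # intercept fixed at 0
    if slope >= 0:
        return math.inf
    return float(units.zeta_to_ell(-1.0 / slope))


def agent_trajectories(track: dict, box=None) -> dict[int, np.ndarray]:
    """Rebuild per-agent position series from per-step tracking records.

    ``track`` maps step -> (agent ids, positions).  With a periodic
    ``box`` the positions are unwrapped by minimal image.  Returns agent
    id -> (n, 2) array (consecutive steps where the agent was active).
    """
    series: dict[int, list[np.ndarray]] = {}
    last: dict[int, np.ndarray] = {}
    for step in sorted(track):
        ids, pos = track[step]
        for a, p in zip(ids, pos):
            a = int(a)
            if a in last and box is not None:
                d = p - last[a]
                d -= np.asarray(box) * np.round(d / np.asarray(box))
                series[a].append(series[a][-1] + d)
            elif a in last:
                series[a].append(p)
            else:
                series[a] = [p]
            last[a] = p
    return {a: np.asarray(v) for a, v in series.items() if len(v) >= 2}


# --------------------------------------------------------------------------
# protrusion morphometrics
# --------------------------------------------------------------------------

@dataclass
class ProtrusionRecord:
    """One segmented protrusion branch."""

    skeleton: np.ndarray          # (n, 2) polyline base -> tip, zeta
    base: np.ndarray              # (2,) zeta
    tip: np.ndarray               # (2,) zeta
    width_ell: float              # mean local width, body lengths
    length_zeta: float            # arc length of the skeleton
    cells: set = field(default_factory=set)   # footprint cells (iy, ix)
    origin: np.ndarray = None     # raster origin, zeta
    member_nodes: np.ndarray = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the branch's raster
        cells."""
        pts = np.atleast_2d(points)
        cells = np.floor(pts - self.origin).astype(int)
        return np.array([(c[1], c[0]) in self.cells for c in cells])


def rasterize_structural(state, pad: int = 3):
    """Binary occupancy image of structural nodes at 1 zeta resolution.

    Returns (image, origin) with image[iy, ix] covering
    ``origin + [ix, iy] .. origin + [ix+1, iy+1]``.
    """
    pos, kind, alive, _ = _fields(state)
    p = pos[alive & (kind == STRUCT)]
    if len(p) == 0:
        raise ValueError("no structural nodes")
    origin = np.floor(p.min(axis=0)).astype(int) - pad
    span = np.ceil(p.max(axis=0)).astype(int) + pad - origin + 1
    img = np.zeros((int(span[1]), int(span[0])), dtype=bool)
    ij = np.floor(p - origin).astype(int)
    img[ij[:, 1], ij[:, 0]] = True
    return img, origin.astype(float)


_NBR8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_path(pixels: set):
    """Longest 8-connected path through a pixel set (double BFS)."""

    def bfs(start):
        from collections import deque
        dist = {start: 0.0}
        prev = {start: None}
        q = deque([start])
        far, fard = start, 0.0
        while q:
            u = q.popleft()
            for dy, dx in _NBR8:
                v = (u[0] + dy, u[1] + dx)
                if v in pixels and v not in dist:
                    dist[v] = dist[u] + math.hypot(dy, dx)
                    prev[v] = u
                    q.append(v)
                    if dist[v] > fard:
                        far, fard = v, dist[v]
        return far, fard, prev

    p1, _, _ = bfs(next(iter(pixels)))
    p2, length, prev = bfs(p1)
    path = []
    cur = p2
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path[::-1], length     # p1 .. p2


def detect_protrusions(state, units: UnitSystem | None = None,
                       max_width_ell: float = 10.0) -> list[ProtrusionRecord]:
    """Segment elongated structural branches narrower than the width
    threshold (half the free-ant persistence length, 10 ell).

    Pipeline: rasterize structural occupancy at 1 zeta, close with a
    radius-1 disk, take the medial-axis skeleton with its distance
    transform; skeleton pixels whose local width (twice the distance
    transform) is below the threshold form candidate branches; a branch is
    kept if its arc length is at least its mean width (aspect ratio >= 1).
    """
    units = units or UnitSystem()
    wmax_zeta = units.ell_to_zeta(max_width_ell)
    img, origin = rasterize_structural(state)
    img = morphology.closing(img, morphology.disk(1))
    skel, dist = morphology.medial_axis(img, return_distance=True)
    width = 2.0 * dist
    narrow = skel & (width < wmax_zeta)
    if not narrow.any():
        return []
    # bulk = what survives opening at the width threshold; a genuine
    # branch lives mostly outside it (this rejects medial-axis spurs that
    # radiate inside a compact body)
    bulk = morphology.opening(img, morphology.disk(
        max(1, int(round(wmax_zeta / 2.0)))))
    dist_out = ndi.distance_transform_edt(~bulk)
    lab, n = ndi.label(narrow, structure=np.ones((3, 3)))
    pos, kind, alive, _ = _fields(state)
    spos = pos[alive & (kind == STRUCT)]
    centroid = spos.mean(axis=0)
    wide = skel & ~narrow
    records = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lab == k)
        pix = set(zip(ys.tolist(), xs.tolist()))
        w_mean = float(width[ys, xs].mean())
        path, length = _longest_path(pix)
        if length < max(w_mean, 2.0):
            continue
        if bulk[ys, xs].mean() > 0.5:
            continue
        # the branch must stand off from the bulk at one end; this
        # rejects the shallow wedges skeletonization leaves at the
        # junctions of wide lobes
        tip_standoff = max(dist_out[path[0]], dist_out[path[-1]])
        if tip_standoff < 0.75 * w_mean:
            continue
        # orient the path: base = end attached to (or nearest) the bulk
        def touches_wide(p):
            return any(wide[p[0] + dy, p[1] + dx] for dy, dx in _NBR8
                       if 0 <= p[0] + dy < wide.shape[0]
                       and 0 <= p[1] + dx < wide.shape[1])

        e0, e1 = path[0], path[-1]
        t0 = touches_wide(e0)
        t1 = touches_wide(e1)
        if t1 and not t0:
            path = path[::-1]
        elif t0 == t1:
            # fall back: base is the end closer to the raft centroid
            w0 = origin + np.array([e0[1] + 0.5, e0[0] + 0.5])
            w1 = origin + np.array([e1[1] + 0.5, e1[0] + 0.5])
            if (np.linalg.norm(w1 - centroid)
                    < np.linalg.norm(w0 - centroid)):
                path = path[::-1]
        poly = origin + np.array([[c + 0.5, r + 0.5] for r, c in path])
        # footprint: occupied raster cells within the local half-width of
        # the branch centreline
        yy, xx = np.nonzero(img)
        occ_cells = np.column_stack([yy, xx])
        d2 = ((occ_cells[:, None, 0] - ys[None, :]) ** 2
              + (occ_cells[:, None, 1] - xs[None, :]) ** 2)
        near = d2.min(axis=1) <= (w_mean / 2.0 + 1.0) ** 2
        foot = set(map(tuple, occ_cells[near]))
        cell = np.floor(spos - origin).astype(int)
        inmask = np.array([(cy, cx) in foot for cx, cy in cell])
        records.append(ProtrusionRecord(
            skeleton=poly, base=poly[0], tip=poly[-1],
            width_ell=units.zeta_to_ell(w_mean), length_zeta=float(length),
            cells=foot, origin=origin,
            member_nodes=np.flatnonzero(inmask)))
    return records


def match_protrusions(prev: list[ProtrusionRecord],
                      curr: list[ProtrusionRecord],
                      max_base_shift: float = 5.0):
    """Greedy pairing of protrusions across frames by base proximity."""
    pairs = []
    used = set()
    for i, p in enumerate(prev):
        best, bestd = -1, max_base_shift
        for j, c in enumerate(curr):
            if j in used:
                continue
            d = float(np.linalg.norm(p.base - c.base))
            if d < bestd:
                best, bestd = j, d
        if best >= 0:
            used.add(best)
            pairs.append((i, best))
    return pairs


def growth_rate(sequence, smooth_minutes: float = 1.0) -> float:
    """Tip growth rate of one tracked protrusion, in ell/min.

    ``sequence`` is a time-ordered list of ``(t_min, ProtrusionRecord)``
    for the same protrusion.  Per interval the tip displacement is
    projected on the skeleton direction at the tip; the series is smoothed
    with a moving window of ``smooth_minutes`` and averaged.  Negative
    values indicate recession.
    """
    units = UnitSystem()
    if len(sequence) < 2:
        raise ValueError("need the protrusion in at least two frames")
    ts = np.array([t for t, _ in sequence])
    vs = []
    for (t0, p0), (t1, p1) in zip(sequence, sequence[1:]):
        tangent = p1.skeleton[-1] - p1.skeleton[max(0, len(p1.skeleton) - 4)]
        nrm = np.linalg.norm(tangent)
        if nrm == 0 or t1 <= t0:
            continue
        tangent = tangent / nrm
        v = float((p1.tip - p0.tip) @ tangent) / (t1 - t0)
        vs.append((0.5 * (t0 + t1), units.zeta_to_ell(v)))
    if not vs:
        raise ValueError("degenerate protrusion track")
    tmid = np.array([t for t, _ in vs])
    vv = np.array([v for _, v in vs])
    if len(vv) > 1 and smooth_minutes > 0:
        sm = np.array([vv[np.abs(tmid - t) <= smooth_minutes / 2].mean()
                       for t in tmid])
    else:
        sm = vv
    return float(sm.mean())


# --------------------------------------------------------------------------
# circle fitting and tip radii
# --------------------------------------------------------------------------

def pratt_fit(points: np.ndarray):
    """Algebraic Pratt circle fit; exact on noiseless circular data.

    Returns ``(center, radius)``; raises ``ValueError`` for fewer than
    three points or (near-)collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    z = x * x + y * y
    M = np.column_stack([z, x, y, np.ones_like(x)])
    P = M.T @ M
    B = np.array([[0.0, 0.0, 0.0, -2.0],
                  [0.0, 1.0, 0.0, 0.0],
                  [0.0, 0.0, 1.0, 0.0],
                  [-2.0, 0.0, 0.0, 0.0]])
    vals, vecs = scipy.linalg.eig(P, B)
    vals = np.real_if_close(vals)
    good = np.isfinite(vals) & (np.abs(vals.imag) < 1e-9) & (vals.real > -1e-9)
    if not good.any():
        raise ValueError("degenerate configuration for circle fit")
    k = np.flatnonzero(good)[np.argmin(vals.real[good])]
    a, b, c, d = np.real(vecs[:, k])
    if abs(a) < 1e-12 * max(abs(b), abs(c), 1.0):
        raise ValueError("points are collinear (infinite radius)")
    cx, cy = -b / (2 * a), -c / (2 * a)
    r2 = (b * b + c * c - 4 * a * d) / (4 * a * a)
    if r2 <= 0:
        raise ValueError("degenerate circle")
    return np.array([cx, cy]), float(math.sqrt(r2))


def boundary_contour(state) -> np.ndarray:
    """Ordered (counter-clockwise) boundary polyline of the raft, zeta."""
    img, origin = rasterize_structural(state)
    img = morphology.closing(img, morphology.disk(1))
    contours = measure.find_contours(img.astype(float), 0.5)
    if not contours:
        raise ValueError("no raft boundary found")
    c = max(contours, key=len)           # rows, cols
    pts = origin + np.column_stack([c[:, 1], c[:, 0]])
    area = 0.5 * np.sum(pts[:-1, 0] * pts[1:, 1] - pts[1:, 0] * pts[:-1, 1])
    if area < 0:
        pts = pts[::-1]
    return pts


def _smooth_closed(pts: np.ndarray, window_zeta: float) -> np.ndarray:
    """Circular moving average of closed-contour coordinates."""
    if len(pts) < 8:
        return pts
    step = float(np.hypot(*np.diff(pts, axis=0).T).mean())
    m = max(1, int(round(window_zeta / max(step, 1e-9))))
    if m <= 1:
        return pts
    kernel = np.ones(m) / m
    pad = np.concatenate([pts[-m:], pts, pts[:m]])
    sm = np.column_stack([np.convolve(pad[:, 0], kernel, mode="same"),
                          np.convolve(pad[:, 1], kernel, mode="same")])
    return sm[m:-m]


def _vertex_curvature(pts: np.ndarray, window_zeta: float) -> np.ndarray:
    """Signed curvature at each vertex of a closed CCW contour, with an
    arc-length moving average of the given window."""
    seg = np.roll(pts, -1, axis=0) - pts
    ds = np.hypot(seg[:, 0], seg[:, 1])
    ds = np.maximum(ds, 1e-9)
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    dang = ang - np.roll(ang, 1)
    dang = (dang + math.pi) % (2.0 * math.pi) - math.pi
    kappa = dang / (0.5 * (ds + np.roll(ds, 1)))
    npts = max(1, int(round(window_zeta / max(ds.mean(), 1e-9))))
    if npts > 1:
        kernel = np.ones(npts) / npts
        kappa = np.convolve(np.concatenate([kappa[-npts:], kappa,
                                            kappa[:npts]]),
                            kernel, mode="same")[npts:-npts]
    return kappa


# Segmentation into convex/concave regions needs heavier smoothing than
# the radius fit: raster stair-step noise at the 1-zeta scale would flip
# the curvature sign on gently curved boundaries.
_SEG_SMOOTH_ELL = 5.0


def _smoothed_curvature(pts: np.ndarray, window_zeta: float):
    """(kappa_seg, s, fit_points): segmentation curvature on a heavily
    smoothed geometry, aligned with lightly smoothed fit points and their
    arc-length coordinates."""
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    keep = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T) > 1e-12
    pts = pts[keep]
    if len(pts) < 3:
        return np.zeros(len(pts)), np.zeros(len(pts)), pts
    p_fit = _smooth_closed(pts, window_zeta)
    p_seg = _smooth_closed(p_fit,
                           _SEG_SMOOTH_ELL * UnitSystem().ell_in_zeta)
    kappa = _vertex_curvature(p_seg, window_zeta)
    ds = np.hypot(*(np.roll(p_fit, -1, axis=0) - p_fit).T)
    s = np.concatenate([[0.0], np.cumsum(ds)[:-1]])
    return kappa, s, p_fit


def tip_radius(boundary: np.ndarray, tip: np.ndarray,
               units: UnitSystem | None = None) -> float:
    """Local radius of curvature at a protrusion tip, in body lengths.

    The signed curvature along the boundary is smoothed with a 1 ell
    moving average; the convex segment around the tip is cropped at the
    nearest flanking inflection points and Pratt-fitted.  One or two
    remaining points map to 0.5 ell and 1 ell respectively (single-agent
    and two-agent tips).
    """
    units = units or UnitSystem()
    win = units.ell_to_zeta(1.0)
    kappa, _, cpts = _smoothed_curvature(boundary, win)
    n = len(cpts)
    if n < 3:
        raise ValueError("boundary too short")
    d = np.hypot(cpts[:, 0] - tip[0], cpts[:, 1] - tip[1])
    i0 = int(np.argmin(d))
    if d[i0] > 5.0:
        raise ValueError("tip does not lie on the boundary")
    sign0 = kappa[i0] >= 0
    lo = i0
    for k in range(1, n):
        j = (i0 - k) % n
        if (kappa[j] >= 0) != sign0:
            break
        lo = j
    hi = i0
    for k in range(1, n):
        j = (i0 + k) % n
        if (kappa[j] >= 0) != sign0:
            break
        hi = j
    if lo <= hi:
        segment = cpts[lo:hi + 1]
    else:
        segment = np.concatenate([cpts[lo:], cpts[:hi + 1]])
    if len(segment) == 1:
        return 0.5
    if len(segment) == 2:
        return 1.0
    try:
        _, r = pratt_fit(segment)
    except ValueError:
        return 1.0
    return float(units.zeta_to_ell(r))


def convex_edge_radii(state, units: UnitSystem | None = None,
                      min_arc_ell: float = 2.0) -> list[float]:
    """Radii of all maximal convex boundary segments (used when a raft has
    no protrusions: the mean convex edge radius).

    Segments shorter than ``min_arc_ell`` and fits larger than the raft's
    own bounding radius (near-flat stretches with ill-conditioned fits)
    are discarded.
    """
    units = units or UnitSystem()
    pts = boundary_contour(state)
    bound = float(np.max(np.hypot(*(pts - pts.mean(axis=0)).T)))
    kappa, mids, cpts = _smoothed_curvature(pts, units.ell_to_zeta(1.0))
    convex = kappa > 0
    # merge segments across the contour seam
    lab, n = ndi.label(convex)
    if n > 1 and convex[0] and convex[-1]:
        lab[lab == lab[-1]] = lab[0]
    radii = []
    for k in np.unique(lab[lab > 0]):
        sel = lab == k
        if sel.sum() < 3:
            continue
        arc = mids[sel].max() - mids[sel].min()
        if arc < units.ell_to_zeta(min_arc_ell):
            continue
        try:
            _, r = pratt_fit(cpts[sel])
        except ValueError:
            continue
        if r > 1.5 * bound:
            continue
        radii.append(float(units.zeta_to_ell(r)))
    return radii
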