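"""Unit system, model parameters, state containers and raft initialization.

The simulator works in *internal units*: lengths in ``zeta`` (the occupancy
length of one structural ant, 1.81 mm) and times in timesteps of 0.6 s.
User-facing parameters follow the conventions of the source system: body
lengths ``ell`` (2.93 mm) for behavioural radii, percent-per-minute for
rates.  :class:`UnitSystem` performs all conversions.

Two node kinds exist on the lattice: *structural* agents (the contracting
raft network) and *water* nodes (vacant sites a free agent may deposit
into).  Freely active agents live on top of structural nodes and are stored
separately in :class:`FreeAgentPop`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "STRUCT",
    "WATER",
    "UnitSystem",
    "SimParams",
    "NodeField",
    "FreeAgentPop",
    "EventLog",
    "SimState",
    "init_lattice",
    "init_raft",
    "init_state",
]

STRUCT = 0
WATER = 1


@dataclass(frozen=True)
class UnitSystem:
    """Conversions between internal units (zeta, timestep) and field units.

    Parameters
    ----------
    zeta_mm:
        Occupancy length of one structural ant in mm; the internal length
        unit.  ``zeta = rho_r**-0.5`` for a planar structural density
        ``rho_r`` of 0.304 ants / mm^2.
    ell_mm:
        Mean ant body length in mm; behavioural radii and reported results
        use this unit.
    dt_s:
        Seconds per timestep; the internal time unit.
    """

    zeta_mm: float = 1.81
    ell_mm: float = 2.93
    dt_s: float = 0.6

    @property
    def ell_in_zeta(self) -> float:
        """Length of one body length expressed in zeta (~1.619)."""
        return self.ell_mm / self.zeta_mm

    @property
    def dt_min(self) -> float:
        """Timestep in minutes (0.01 min for the 0.6 s default)."""
        return self.dt_s / 60.0

    def ell_to_zeta(self, x: float) -> float:
        return x * self.ell_in_zeta

    def zeta_to_ell(self, x: float) -> float:
        return x / self.ell_in_zeta

    def rate_per_step(self, pct_per_min: float) -> float:
        """Convert a rate in %/min to a dimensionless fraction per timestep."""
        return pct_per_min / 100.0 * self.dt_min


@dataclass
class SimParams:
    """All model constants, stored in user-facing units and validated.

    ``A`` (the activity, the ratio of self-propulsion to effective water
    repulsion) is the single free parameter of the deposition rule and has
    no default.  Everything else defaults to the calibrated values.

    Lengths suffixed ``_ell`` conventions: ``R_r``, ``R`` and ``init_radius``
    are body lengths; ``R_DOF``, ``water_sigma``, ``jitter``,
    ``domain_half_width`` and the residual tolerances are zeta.  Rates
    (``ddot``) are %/min.
    """

    A: float
    ddot: float = 1.9              # pairwise contraction rate, %/min
    R_r: float = 1.5               # contraction neighbour radius, ell
    relax_damping: float = 16.0    # over-damping scalar nu (>= 1)
    # Seed the contraction relaxation with the uniform-scaling
    # configuration about the anchor - the exact solution of the pairwise
    # targets - so the Jacobi sweeps only polish residuals (usually 0
    # sweeps).  Cold-started relaxation stops ~2.5% short of the targets
    # and is orders of magnitude slower; the emergent strain rate differs
    # by under 2% between the two.
    relax_warm_start: bool = True
    relax_max_iter: int = 12000    # iteration cap before a diagnostic error
    residual_max: float = 5e-5     # max pair residual, zeta
    residual_mean: float = 1e-5    # mean pair residual, zeta
    water_sigma: float = 0.5       # Gaussian repulsion std, zeta
    water_mu: float = 0.0          # Gaussian repulsion mean, zeta
    water_kappa_over_nu: float = 0.02  # repulsion scale / damping
    water_tol: float = 1e-3        # water relaxation residual, zeta
    water_max_iter: int = 1        # repulsion applications per step
    rho_d: float = 1.0             # density threshold, nodes / zeta^2
    L_g: float = 2.0               # density grid cell edge, zeta
    N_p: int = 4                   # permissible nodes per grid cell
    R: float = 0.9                 # Vicsek / detection radius, ell
    eta: float = 0.2               # Vicsek noise in [0, 1]
    R_DOF: float = 2.5             # movement-DOF radius, zeta
    # Edge deposition geometry.  An agent may deposit only into water in
    # contact with its node (deposit_reach covers the nearest-neighbour
    # spacing plus jitter); farther water can still be the preferred DOF
    # but is not enterable.  The repulsion sum runs over water within
    # edge_detect_zeta (defaults to the contact radius R when None);
    # edge_inverse_r weights each contribution by R/r (the discrete
    # energy-gradient force) instead of unit weights.
    deposit_reach_zeta: float = 1.35
    edge_detect_zeta: float | None = 2.5
    edge_inverse_r: bool = True
    turn_limit: float = math.pi / 2.0  # max |heading - step| angle, rad
    pause_range: tuple[int, int] = (2, 4)  # pause duration, timesteps
    init_radius: float = 10.0      # initial raft radius, ell
    packing_fraction: float = 1.0  # initial free agents per structural agent
    jitter: float = 1.0 / 6.0      # lattice offset half-range, zeta
    domain_half_width: float | None = None  # zeta; default 2.5 x raft radius
    seed: int | None = None
    units: UnitSystem = field(default_factory=UnitSystem)

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"activity A must be > 0, got {self.A}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if not 0.0 <= self.packing_fraction <= 1.0:
            raise ValueError(
                f"packing_fraction must lie in [0, 1], got {self.packing_fraction}"
            )
        if self.relax_damping < 1.0:
            raise ValueError("relax_damping (nu) must be >= 1")
        if self.jitter < 0 or self.init_radius <= 0 or self.ddot < 0:
            raise ValueError("jitter must be >= 0, init_radius > 0, ddot >= 0")
        if self.N_p != int(round(self.rho_d * self.L_g**2)):
            raise ValueError(
                f"N_p must equal rho_d * L_g^2 = {self.rho_d * self.L_g ** 2:g}, "
                f"got {self.N_p}"
            )
        if not 0 < self.pause_range[0] <= self.pause_range[1]:
            raise ValueError(f"bad pause_range {self.pause_range}")
        hw = self.domain_half_width_zeta
        if self.init_radius_zeta >= hw:
            raise ValueError(
                f"raft radius {self.init_radius_zeta:.2f} zeta does not fit in "
                f"domain half-width {hw:.2f} zeta"
            )

    # -- derived internal-unit values ------------------------------------
    @property
    def R_r_zeta(self) -> float:
        return self.units.ell_to_zeta(self.R_r)

    @property
    def R_zeta(self) -> float:
        return self.units.ell_to_zeta(self.R)

    @property
    def init_radius_zeta(self) -> float:
        return self.units.ell_to_zeta(self.init_radius)

    @property
    def domain_half_width_zeta(self) -> float:
        if self.domain_half_width is not None:
            return self.domain_half_width
        return 2.5 * self.init_radius_zeta

    @property
    def edge_detect_radius(self) -> float:
        return (self.R_zeta if self.edge_detect_zeta is None
                else self.edge_detect_zeta)

    @property
    def ddot_per_step(self) -> float:
        """Pairwise contraction rate as a fraction per timestep."""
        return self.units.rate_per_step(self.ddot)

    @property
    def contraction_factor(self) -> float:
        """Per-step separation decay factor exp(-ddot * dt)."""
        return math.exp(-self.ddot_per_step)

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}


class NodeField:
    """Positions and kinds of every lattice node.

    Node ids are stable: deleted nodes keep their slot with ``alive=False``
    and new nodes are appended, so trajectories can be tracked by id across
    snapshots.  The anchor node is structural, never moves and is never
    deleted.
    """

    def __init__(self, pos: np.ndarray, kind: np.ndarray,
                 domain_half_width: float, anchor: int = -1) -> None:
        self.pos = np.ascontiguousarray(pos, dtype=np.float64)
        self.kind = np.ascontiguousarray(kind, dtype=np.int8)
        self.alive = np.ones(len(self.pos), dtype=bool)
        self.domain_half_width = float(domain_half_width)
        self.anchor = int(anchor)
        # persistent labels survive compaction; ids are transient slots
        self.label = np.arange(len(self.pos), dtype=np.int64)
        self.next_label = len(self.pos)
        if self.pos.ndim != 2 or self.pos.shape[1] != 2:
            raise ValueError("pos must be (N, 2)")
        if len(self.kind) != len(self.pos):
            raise ValueError("kind and pos lengths differ")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_structural(self) -> int:
        return int(np.count_nonzero(self.alive & (self.kind == STRUCT)))

    @property
    def n_water(self) -> int:
        return int(np.count_nonzero(self.alive & (self.kind == WATER)))

    def ids_of(self, kind: int) -> np.ndarray:
        return np.flatnonzero(self.alive & (self.kind == kind))

    def add(self, pos: np.ndarray, kind: int) -> np.ndarray:
        """Append nodes, returning their new ids."""
        pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
        n0 = len(self.pos)
        self.pos = np.concatenate([self.pos, pos])
        self.kind = np.concatenate(
            [self.kind, np.full(len(pos), kind, dtype=np.int8)])
        self.alive = np.concatenate(
            [self.alive, np.ones(len(pos), dtype=bool)])
        self.label = np.concatenate(
            [self.label,
             np.arange(self.next_label, self.next_label + len(pos))])
        self.next_label += len(pos)
        return np.arange(n0, len(self.pos))

    def kill(self, idx: int) -> None:
        if idx == self.anchor:
            raise ValueError("the anchor node cannot be deleted")
        self.alive[idx] = False

    def copy(self) -> "NodeField":
        nf = NodeField(self.pos.copy(), self.kind.copy(),
                       self.domain_half_width, self.anchor)
        nf.alive = self.alive.copy()
        nf.label = self.label.copy()
        nf.next_label = self.next_label
        return nf


class FreeAgentPop:
    """Freely active agents walking on the structural lattice.

    Each active agent occupies exactly one alive structural node (volume
    exclusion) and carries a heading ``theta`` in [0, 2*pi), a pause timer
    in timesteps, and its previous position (for velocity observables).
    Agents that bind into the network are deactivated, never removed, so
    agent ids are stable too.
    """

    def __init__(self) -> None:
        self.node = np.empty(0, dtype=np.int64)
        self.theta = np.empty(0, dtype=np.float64)
        self.pause = np.empty(0, dtype=np.int64)
        self.prev_pos = np.empty((0, 2), dtype=np.float64)
        self.active = np.empty(0, dtype=bool)

    def __len__(self) -> int:
        return len(self.node)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.active))

    @property
    def active_ids(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def add(self, node_ids: np.ndarray, thetas: np.ndarray,
            positions: np.ndarray) -> np.ndarray:
        node_ids = np.atleast_1d(np.asarray(node_ids, dtype=np.int64))
        n = len(node_ids)
        self.node = np.concatenate([self.node, node_ids])
        self.theta = np.concatenate(
            [self.theta, np.atleast_1d(np.asarray(thetas, dtype=np.float64))])
        self.pause = np.concatenate([self.pause, np.zeros(n, dtype=np.int64)])
        self.prev_pos = np.concatenate(
            [self.prev_pos, np.atleast_2d(np.asarray(positions, float))])
        self.active = np.concatenate([self.active, np.ones(n, dtype=bool)])
        return np.arange(len(self.node) - n, len(self.node))

    def copy(self) -> "FreeAgentPop":
        p = FreeAgentPop()
        p.node = self.node.copy()
        p.theta = self.theta.copy()
        p.pause = self.pause.copy()
        p.prev_pos = self.prev_pos.copy()
        p.active = self.active.copy()
        return p


class EventLog:
    """Time-stamped bind (edge deposition) and unbind (density) events."""

    def __init__(self) -> None:
        self.binds: list[tuple[int, float, float]] = []      # (step, x, y)
        self.unbinds: list[tuple[int, float, float]] = []    # (step, x, y)
        self.reports: list[dict] = []                        # per-step metrics

    def log_bind(self, step: int, x: float, y: float) -> None:
        self.binds.append((step, x, y))

    def log_unbind(self, step: int, x: float, y: float) -> None:
        self.unbinds.append((step, x, y))

    def copy(self) -> "EventLog":
        log = EventLog()
        log.binds = list(self.binds)
        log.unbinds = list(self.unbinds)
        log.reports = [dict(r) for r in self.reports]
        return log


@dataclass
class SimState:
    """Full mutable simulation state.

    ``occupant`` maps node id -> agent id (or -1); it is maintained by every
    update operation and re-checkable with :meth:`validate`.
    """

    nodes: NodeField
    agents: FreeAgentPop
    rng: np.random.Generator
    events: EventLog = field(default_factory=EventLog)
    step: int = 0
    occupant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.occupant is None:
            self.rebuild_occupancy()

    def rebuild_occupancy(self) -> None:
        occ = np.full(len(self.nodes), -1, dtype=np.int64)
        ids = self.agents.active_ids
        occ[self.agents.node[ids]] = ids
        self.occupant = occ

    @property
    def total_agents(self) -> int:
        """Ants in the system: structural nodes plus active free agents."""
        return self.nodes.n_structural + self.agents.n_active

    def agent_positions(self, ids: np.ndarray | None = None) -> np.ndarray:
        if ids is None:
            ids = self.agents.active_ids
        return self.nodes.pos[self.agents.node[ids]]

    def validate(self) -> None:
        """Raise AssertionError if a state invariant is broken."""
        ag = self.agents
        ids = ag.active_ids
        occ_nodes = ag.node[ids]
        assert np.all(self.nodes.alive[occ_nodes]), "agent on dead node"
        assert np.all(self.nodes.kind[occ_nodes] == STRUCT), \
            "agent on a non-structural node"
        assert len(np.unique(occ_nodes)) == len(occ_nodes), \
            "two agents share one node"
        assert self.nodes.alive[self.nodes.anchor], "anchor deleted"
        assert self.nodes.kind[self.nodes.anchor] == STRUCT, \
            "anchor not structural"
        occ = np.full(len(self.nodes), -1, dtype=np.int64)
        occ[occ_nodes] = ids
        assert np.array_equal(occ, self.occupant), "occupancy map stale"
        assert np.all(np.isfinite(self.nodes.pos[self.nodes.alive]))

    def compact(self) -> None:
        """Drop dead node slots, preserving labels and relative order.

        Physically a no-op: ids are renumbered but every ordering the
        dynamics depends on is preserved, so trajectories are unchanged.
        """
        keep = np.flatnonzero(self.nodes.alive)
        remap = np.full(len(self.nodes), -1, dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        nf = self.nodes
        nf.pos = np.ascontiguousarray(nf.pos[keep])
        nf.kind = np.ascontiguousarray(nf.kind[keep])
        nf.label = np.ascontiguousarray(nf.label[keep])
        nf.alive = np.ones(len(keep), dtype=bool)
        nf.anchor = int(remap[nf.anchor])
        ag = self.agents
        ids = ag.active_ids
        ag.node[ids] = remap[ag.node[ids]]
        ag.node[~ag.active] = -1
        self.rebuild_occupancy()

    def copy(self) -> "SimState":
        st = SimState(self.nodes.copy(), self.agents.copy(),
                      np.random.default_rng(), self.events.copy(), self.step,
                      self.occupant.copy())
        st.rng = np.random.Generator(type(self.rng.bit_generator)())
        st.rng.bit_generator.state = self.rng.bit_generator.state
        return st


def hex_lattice(half_width: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Close-packed hexagonal lattice with unit spacing filling the square
    ``[-half_width, half_width]^2``, each coordinate independently offset by
    ``Uniform[-jitter, +jitter]``.

    The node at the origin belongs to the ideal (unjittered) lattice, so the
    raft centre always has a nearby anchor candidate.
    """
    if half_width <= 0:
        raise ValueError("domain half-width must be positive")
    dy = math.sqrt(3.0) / 2.0
    krange = np.arange(-math.floor(half_width / dy), math.floor(half_width / dy) + 1)
    rows = []
    m = math.floor(half_width + 0.5)
    base_x = np.arange(-m, m + 1, dtype=float)
    for k in krange:
        x = base_x + (0.5 if (k % 2) else 0.0)
        x = x[np.abs(x) <= half_width]
        rows.append(np.column_stack([x, np.full(len(x), k * dy)]))
    pos = np.concatenate(rows)
    if jitter > 0:
        pos = pos + rng.uniform(-jitter, jitter, size=pos.shape)
    return pos


def init_lattice(domain_half_width: float, jitter: float,
                 seed: int | np.random.Generator) -> NodeField:
    """Create the node lattice; every node starts out as water.

    Classification into structural / water happens in :func:`init_raft`.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    pos = hex_lattice(domain_half_width, jitter, rng)
    kind = np.full(len(pos), WATER, dtype=np.int8)
    return NodeField(pos, kind, domain_half_width)


def init_raft(nodes: NodeField, radius_ell: float, phi0: float,
              rng: np.random.Generator,
              units: UnitSystem | None = None) -> SimState:
    """Classify a circular raft and seed the freely active layer.

    Nodes inside the circle of the given radius (body lengths) around the
    origin become structural; the node nearest the origin is the fixed
    anchor.  ``round(phi0 * N_structural)`` distinct structural nodes each
    receive one free agent with heading ``Uniform[0, 2*pi)``.

    Draw order from ``rng``: (1) node choice for agents, (2) headings.
    """
    units = units or UnitSystem()
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError("phi0 must lie in [0, 1]")
    radius_zeta = units.ell_to_zeta(radius_ell)
    if radius_zeta >= nodes.domain_half_width:
        raise ValueError("raft does not fit in the domain")
    r = np.hypot(nodes.pos[:, 0], nodes.pos[:, 1])
    inside = r <= radius_zeta
    nodes.kind[:] = WATER
    nodes.kind[inside] = STRUCT
    nodes.anchor = int(np.argmin(r))
    nodes.kind[nodes.anchor] = STRUCT

    agents = FreeAgentPop()
    struct_ids = nodes.ids_of(STRUCT)
    n_free = int(round(phi0 * len(struct_ids)))
    if n_free > 0:
        chosen = rng.choice(struct_ids, size=n_free, replace=False)
        thetas = rng.uniform(0.0, 2.0 * math.pi, size=n_free)
        agents.add(chosen, thetas, nodes.pos[chosen])
    return SimState(nodes=nodes, agents=agents, rng=rng)


def init_state(params: SimParams, seed: int | None = None) -> SimState:
    """Convenience initializer: lattice + circular raft from parameters."""
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    nodes = init_lattice(params.domain_half_width_zeta, params.jitter, rng)
    return init_raft(nodes, params.init_radius, params.packing_fraction,
                     rng, params.units)
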