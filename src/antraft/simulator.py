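"""Per-step pipeline orchestration, recording, and the periodic free-flow
mode used to calibrate the Vicsek parameters.

Raft mode executes, per timestep:

    vicsek_update -> contract_structural -> pack_water -> enforce_density
    -> step_free_agents -> recorders

Free-flow mode runs only the surface traffic (vicsek_update ->
step_free_agents) on a static, fully structural, periodic hexagonal
lattice; there is no water, so agents never deposit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import active_dynamics, structural_dynamics
from .core import (STRUCT, WATER, FreeAgentPop, NodeField, SimParams,
                   SimState, hex_lattice)

__all__ = [
    "RunConfig",
    "Snapshot",
    "RunResult",
    "run",
    "init_freeflow",
    "save_checkpoint",
    "load_checkpoint",
    "SNAPSHOT_COLUMNS",
]


@dataclass
class RunConfig:
    """What to simulate and what to record.

    ``schedule`` is a binary-step activity programme: a list of
    ``(t_start_min, A)`` pairs with strictly increasing start times; the
    run begins with ``params.A`` until the first switch.  ``track_from``
    enables per-step recording of agent positions (for velocity-based
    observables) from that step on.
    """

    n_steps: int
    record_every: int = 0
    mode: str = "raft"
    schedule: list[tuple[float, float]] = field(default_factory=list)
    box: tuple[float, float] | None = None   # free-flow periodic box, zeta
    track_from: int | None = None
    log_every: int = 0
    engine: str = "numba"

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mode not in ("raft", "freeflow"):
            raise ValueError(f"unknown mode {self.mode!r}")
        times = [t for t, _ in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if self.mode == "freeflow":
            if self.schedule:
                raise ValueError("activity schedules apply to raft mode only")
            if self.box is None:
                raise ValueError("freeflow mode needs a periodic box")


@dataclass
class Snapshot:
    """Copy of the public state at one recorded step."""

    step: int
    t_min: float
    node_pos: np.ndarray
    node_kind: np.ndarray
    node_alive: np.ndarray
    node_label: np.ndarray
    anchor: int
    agent_node: np.ndarray
    agent_theta: np.ndarray
    agent_pause: np.ndarray
    agent_active: np.ndarray


@dataclass
class RunResult:
    snapshots: list[Snapshot]
    metrics: pd.DataFrame
    track: dict[int, tuple[np.ndarray, np.ndarray]]
    # track: step -> (active agent ids, their positions)


def _take_snapshot(state: SimState, dt_min: float) -> Snapshot:
    return Snapshot(
        step=state.step,
        t_min=state.step * dt_min,
        node_pos=state.nodes.pos.copy(),
        node_kind=state.nodes.kind.copy(),
        node_alive=state.nodes.alive.copy(),
        node_label=state.nodes.label.copy(),
        anchor=state.nodes.anchor,
        agent_node=state.agents.node.copy(),
        agent_theta=state.agents.theta.copy(),
        agent_pause=state.agents.pause.copy(),
        agent_active=state.agents.active.copy(),
    )


def run(state: SimState, params: SimParams, cfg: RunConfig,
        logger=None) -> RunResult:
    """Advance the state by ``cfg.n_steps`` timesteps.

    Identical (state, params, config) and RNG state produce identical
    outputs.  Convergence failures of the contraction relaxation
    propagate.
    """
    dt_min = params.units.dt_min
    snapshots: list[Snapshot] = []
    metrics_rows: list[dict] = []
    track: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    schedule = sorted(cfg.schedule)
    sched_i = 0
    current = params
    if cfg.record_every:
        snapshots.append(_take_snapshot(state, dt_min))

    for _ in range(cfg.n_steps):
        t_min = state.step * dt_min
        while sched_i < len(schedule) and t_min >= schedule[sched_i][0]:
            current = current.with_(A=schedule[sched_i][1])
            sched_i += 1

        if cfg.mode == "raft":
            active_dynamics.vicsek_update(state, current)
            structural_dynamics.contract_structural(state, current)
            structural_dynamics.pack_water(state, current)
            rep = structural_dynamics.enforce_density(state, current)
            binds = active_dynamics.step_free_agents(
                state, current, engine=cfg.engine)
        else:
            active_dynamics.vicsek_update(state, current, boxsize=cfg.box)
            binds = active_dynamics.step_free_agents(
                state, current, boxsize=cfg.box, engine=cfg.engine)
            rep = structural_dynamics.UnbindReport(
                n_structural_before=state.nodes.n_structural)

        state.step += 1
        row = {
            "step": state.step,
            "t_min": state.step * dt_min,
            "n_structural": state.nodes.n_structural,
            "n_free": state.agents.n_active,
            "n_water": state.nodes.n_water,
            "binds": binds,
            "unbinds": rep.n_unbind,
            "water_deleted": rep.water_deleted,
            "skipped_conversions": rep.skipped_conversions,
            "n_structural_before": rep.n_structural_before,
        }
        metrics_rows.append(row)
        state.events.reports.append(row)

        if cfg.track_from is not None and state.step >= cfg.track_from:
            ids = state.agents.active_ids
            track[state.step] = (ids.copy(), state.agent_positions(ids))
        if cfg.record_every and state.step % cfg.record_every == 0:
            snapshots.append(_take_snapshot(state, dt_min))
        if state.step % 200 == 0 and \
                np.count_nonzero(~state.nodes.alive) > 0.2 * len(state.nodes):
            state.compact()
        if logger is not None and cfg.log_every and \
                state.step % cfg.log_every == 0:
            logger.info(
                "step %d: N_r=%d N_f=%d binds=%d unbinds=%d",
                state.step, row["n_structural"], row["n_free"],
                row["binds"], row["unbinds"])

    return RunResult(snapshots, pd.DataFrame(metrics_rows), track)


def init_freeflow(params: SimParams, box_zeta: float,
                  seed: int | np.random.Generator):
    """Static periodic hexagonal lattice with agents at the configured
    packing fraction; returns ``(state, (Lx, Ly))``.

    The box is built from whole lattice cells nearest to the requested
    edge length so the hexagonal tiling closes periodically.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dy = math.sqrt(3.0) / 2.0
    nx = max(4, int(round(box_zeta)))
    ny = max(4, int(round(box_zeta / dy)))
    if ny % 2:
        ny += 1          # even row count keeps the tiling periodic
    Lx, Ly = float(nx), ny * dy
    xs = []
    for k in range(ny):
        x = np.arange(nx, dtype=float) + (0.5 if k % 2 else 0.0)
        xs.append(np.column_stack([x, np.full(nx, k * dy)]))
    pos = np.concatenate(xs)
    if params.jitter > 0:
        pos = pos + rng.uniform(-params.jitter, params.jitter, pos.shape)
    pos[:, 0] %= Lx
    pos[:, 1] %= Ly
    nodes = NodeField(pos, np.full(len(pos), STRUCT, dtype=np.int8),
                      domain_half_width=max(Lx, Ly))
    nodes.anchor = int(np.argmin(pos[:, 0] ** 2 + pos[:, 1] ** 2))
    agents = FreeAgentPop()
    n_free = int(round(params.packing_fraction * len(pos)))
    chosen = rng.choice(len(pos), size=n_free, replace=False)
    agents.add(chosen, rng.uniform(0.0, 2 * math.pi, n_free), pos[chosen])
    return SimState(nodes=nodes, agents=agents, rng=rng), (Lx, Ly)


SNAPSHOT_COLUMNS = ["node_id", "x_zeta", "y_zeta", "kind", "is_anchor",
                    "free_agent_id", "theta_rad", "pause_steps"]


def save_checkpoint(state: SimState, path: str | Path) -> None:
    """Write the state to ``path`` (CSV) plus ``path.meta.json``.

    The CSV holds one row per alive node with any free agent riding it;
    the sidecar holds the step counter, domain geometry and the exact RNG
    state, so a resumed run continues bit-identically.
    """
    path = Path(path)
    nodes = state.nodes
    ids = np.flatnonzero(nodes.alive)
    occ = state.occupant[ids]
    theta = np.full(len(ids), np.nan)
    pause = np.full(len(ids), -1, dtype=np.int64)
    has = occ >= 0
    theta[has] = state.agents.theta[occ[has]]
    pause[has] = state.agents.pause[occ[has]]
    df = pd.DataFrame({
        "node_id": ids,
        "x_zeta": nodes.pos[ids, 0],
        "y_zeta": nodes.pos[ids, 1],
        "kind": np.where(nodes.kind[ids] == STRUCT, "structural", "water"),
        "is_anchor": (ids == nodes.anchor).astype(int),
        "free_agent_id": occ,
        "theta_rad": theta,
        "pause_steps": pause,
    })
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "schema": 1,
        "step": state.step,
        "domain_half_width": nodes.domain_half_width,
        "rng": state.rng.bit_generator.state,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def load_checkpoint(path: str | Path) -> SimState:
    """Inverse of :func:`save_checkpoint` (node ids are compacted)."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != SNAPSHOT_COLUMNS:
        raise ValueError(f"snapshot schema mismatch: {list(df.columns)}")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    if "rng" not in meta:
        raise ValueError("checkpoint sidecar is missing the RNG state")
    kinds = df["kind"].to_numpy()
    bad = ~np.isin(kinds, ["structural", "water"])
    if bad.any():
        raise ValueError(f"invalid node kind value(s): {set(kinds[bad])}")
    if int((df["is_anchor"] == 1).sum()) != 1:
        raise ValueError("checkpoint must contain exactly one anchor")
    pos = df[["x_zeta", "y_zeta"]].to_numpy()
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite node coordinates")
    kind = np.where(kinds == "structural", STRUCT, WATER).astype(np.int8)
    nodes = NodeField(pos, kind, meta["domain_half_width"])
    nodes.anchor = int(np.flatnonzero(df["is_anchor"].to_numpy() == 1)[0])
    if kind[nodes.anchor] != STRUCT:
        raise ValueError("anchor node is not structural")
    agents = FreeAgentPop()
    rows = np.flatnonzero(df["free_agent_id"].to_numpy() >= 0)
    order = np.argsort(df["free_agent_id"].to_numpy()[rows])
    rows = rows[order]
    if len(rows):
        agents.add(rows, df["theta_rad"].to_numpy()[rows], pos[rows])
        agents.pause[:] = df["pause_steps"].to_numpy()[rows]
    bitgen = np.random.PCG64()
    bitgen.state = meta["rng"]
    state = SimState(nodes=nodes, agents=agents,
                     rng=np.random.Generator(bitgen))
    state.step = int(meta["step"])
    state.validate()
    return state
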