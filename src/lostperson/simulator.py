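"""Discrete-time agent dynamics with velocity smoothing.

The agent starts at the initial planning point (IPP) x(1); its second
position x(2) is drawn uniformly from the accessible 8-neighborhood, fixing
the initial velocity v(1) = x(2) - x(1).  Each subsequent update draws a
strategy from the behavioral profile, proposes a provisional cell
x_hat(t+1) on the body-frame grid, and smooths the move with one time step
of memory:

    x(t+1) = (2 - alpha) x(t) + (alpha - 1) x(t-1) + alpha v(t),
    v(t)   = x_hat(t+1) - x(t).

Positions stay continuous between steps; the map is queried at the
componentwise-rounded cell.  If the rounded smoothed cell is inaccessible or
off the map, the agent stays put for that step regardless of strategy (no
momentum is accumulated, so it cannot tunnel through water next step).

Time is calibrated so one step covers one cell side at the maximum walking
speed: 1.575 m/s on 6.67 m cells gives T = 850 steps per hour, and runs of
K = 100 hours let the agent traverse the whole 20 km map.  The smoothing
default alpha = 0.55 sits just off the even weighting 0.5 to avoid
cancellation between the memory terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import behavior as bh
from .terrain import DEFAULT_CELL_SIZE, GridMap

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Paper-calibration constants.
MAX_WALKING_SPEED_MS = 1.575
AVERAGE_WALKING_SPEED_MPH = 3.5


def mph_to_ms(mph: float) -> float:
    """Convert miles per hour to meters per second (3.5 mph ~ 1.56 m/s)."""
    return mph * 1609.344 / 3600.0


def steps_per_hour(
    max_speed_ms: float = MAX_WALKING_SPEED_MS,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> int:
    """Whole time steps per hour so one step spans one cell at max speed.

    1.575 m/s on 20 km / 3000 = 6.67 m cells gives 850 steps per hour.
    """
    if max_speed_ms <= 0 or cell_size <= 0:
        raise ValueError("speed and cell size must be positive")
    return int(max_speed_ms * 3600.0 / cell_size)


@dataclass
class SimConfig:
    """Simulation parameters.

    alpha : smoothing factor in (0, 1]; 1 disables memory entirely.
    hours : simulated duration K (hours); fractional values are allowed for
        scaled-down studies, the step count K*T is rounded to an integer.
    steps_per_hour : T, steps per simulated hour.
    replicates : Monte Carlo replicate count per (incident, profile).
    seed : master seed; replicate r runs on the child stream spawned with
        key (r,), so replicate sets are reproducible and order-stable.
    """

    alpha: float = 0.55
    hours: float = 100.0
    steps_per_hour: int = 850
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.hours <= 0:
            raise ValueError("hours must be positive")
        if self.steps_per_hour < 1 or self.replicates < 1:
            raise ValueError("steps_per_hour and replicates must be >= 1")

    @property
    def n_steps(self) -> int:
        """Total position updates per trajectory (K*T)."""
        return int(round(self.hours * self.steps_per_hour))


@dataclass
class AgentState:
    """Mutable state of one simulated agent.

    ``x``/``y`` is the continuous position, ``px``/``py`` the continuous
    previous position, ``cell`` the rounded grid cell, ``heading`` the body
    frame orientation.  ``position_history`` stores the rounded cell per
    step and ``behavior_history`` the strategy id that produced it (``None``
    for the two initialization entries); ``backtrack_cursor`` indexes the
    position the next consecutive BT step will replay from.
    """

    x: float
    y: float
    px: float
    py: float
    cell: tuple[int, int]
    heading: int
    position_history: list = field(default_factory=list)
    behavior_history: list = field(default_factory=list)
    backtrack_cursor: int = 0


@dataclass
class Trajectory:
    """One simulated agent path.

    ``cells`` is the (n_steps + 1, 2) integer array of rounded (x, y) cells
    including the start; ``behaviors`` the strategy id per entry (-1 for the
    two initialization entries); ``stay_put_steps`` counts moves rejected by
    inaccessibility or the map edge.
    """

    cells: np.ndarray
    behaviors: np.ndarray
    replicate: int = 0
    seed: Optional[int] = None
    stay_put_steps: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(len(self.cells)),
                "x": self.cells[:, 0],
                "y": self.cells[:, 1],
                "behavior": [
                    bh.STRATEGIES[b] if b >= 0 else "" for b in self.behaviors
                ],
            }
        )

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def save_trajectories(trajectories: Sequence[Trajectory], path: str) -> None:
    """Persist replicate trajectories as one compact array file."""
    np.savez_compressed(
        path,
        cells=np.stack([t.cells for t in trajectories]),
        behaviors=np.stack([t.behaviors for t in trajectories]),
        stay_put=np.asarray([t.stay_put_steps for t in trajectories]),
    )


def load_trajectories(path: str) -> list[Trajectory]:
    with np.load(path) as data:
        return [
            Trajectory(cells=c, behaviors=b, replicate=r, stay_put_steps=int(s))
            for r, (c, b, s) in enumerate(
                zip(data["cells"], data["behaviors"], data["stay_put"])
            )
        ]


def _as_generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def init_agent(
    ipp: tuple[int, int], grid: GridMap, rng: np.random.Generator
) -> AgentState:
    """Place the agent at the IPP and draw x(2) from accessible neighbors."""
    ix, iy = int(ipp[0]), int(ipp[1])
    if not grid.in_bounds(ix, iy):
        raise ValueError(f"IPP (x={ix}, y={iy}) outside map")
    if grid.inaccessible[iy, ix]:
        raise ValueError(f"IPP (x={ix}, y={iy}) is inaccessible")
    neighbors = [
        (ix + dx, iy + dy)
        for dx, dy in bh.NEIGHBORHOOD9
        if (dx, dy) != (0, 0) and grid.accessible(ix + dx, iy + dy)
    ]
    if not neighbors:
        raise ValueError(f"IPP (x={ix}, y={iy}) has no accessible neighbors")
    x2 = neighbors[int(rng.random() * len(neighbors))]
    heading = bh.body_frame_heading((x2[0] - ix, x2[1] - iy), previous=0)
    return AgentState(
        x=float(x2[0]),
        y=float(x2[1]),
        px=float(ix),
        py=float(iy),
        cell=x2,
        heading=heading,
        position_history=[(ix, iy), x2],
        behavior_history=[None, None],
        backtrack_cursor=0,
    )


def smooth_update(
    x_t: tuple[float, float],
    x_tm1: tuple[float, float],
    x_hat: tuple[float, float],
    alpha: float,
) -> tuple[float, float]:
    """One evaluation of the smoothing update (componentwise)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    a2, a1 = 2.0 - alpha, alpha - 1.0
    return (
        a2 * x_t[0] + a1 * x_tm1[0] + alpha * (x_hat[0] - x_t[0]),
        a2 * x_t[1] + a1 * x_tm1[1] + alpha * (x_hat[1] - x_t[1]),
    )


def step(
    state: AgentState,
    pmf: bh.BehaviorPMF,
    grid: GridMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> AgentState:
    """Advance the agent by one time step (mutates and returns ``state``).

    Reference implementation of the update; :func:`simulate` runs the same
    logic in an inlined loop and is tested to be draw-for-draw identical.
    """
    strategy = bh.sample_strategy(pmf, rng)
    x_hat = bh.propose_step(strategy, state, grid, rng)
    nx, ny = smooth_update((state.x, state.y), (state.px, state.py), x_hat, config.alpha)
    cx = int(math.floor(nx + 0.5))
    cy = int(math.floor(ny + 0.5))
    if not grid.in_bounds(cx, cy) or grid.inaccessible[cy, cx]:
        # blocked: stay put this step, keep momentum state unchanged
        state.position_history.append(state.cell)
        state.behavior_history.append(strategy)
        return state
    state.heading = bh.body_frame_heading((nx - state.x, ny - state.y), state.heading)
    state.px, state.py = state.x, state.y
    state.x, state.y = nx, ny
    state.cell = (cx, cy)
    state.position_history.append(state.cell)
    state.behavior_history.append(strategy)
    return state


def simulate(
    ipp: tuple[int, int],
    pmf: bh.BehaviorPMF,
    grid: GridMap,
    config: SimConfig,
    seed: Optional[SeedLike] = None,
    replicate: int = 0,
) -> Trajectory:
    """Simulate one trajectory of ``config.n_steps`` position updates.

    The returned cell sequence has length n_steps + 1 (the IPP plus one cell
    per update; the draw of x(2) counts as the first update).  The same seed
    always reproduces the bit-identical integer cell sequence.
    """
    rng = _as_generator(config.seed if seed is None else seed)
    n_updates = config.n_steps - 1  # x(2) was the first update

    state = init_agent(ipp, grid, rng)
    # -- inlined hot loop: identical draw sequence to step() ---------------
    alpha = config.alpha
    a2, a1 = 2.0 - alpha, alpha - 1.0
    elev = grid.elevation
    feat = grid.linear_features
    inacc = grid.inaccessible
    rows, cols = grid.rows, grid.cols
    cum = pmf.cumulative()
    c0, c1, c2, c3, c4, _ = cum
    vectors = bh.HEADING_VECTORS
    neigh9 = bh.NEIGHBORHOOD9
    atan2 = math.atan2
    floor = math.floor
    quarter = math.pi / 4.0
    random = rng.random

    x, y = state.x, state.y
    px, py = state.px, state.py
    cellx, celly = state.cell
    heading = state.heading
    positions = state.position_history
    behaviors = state.behavior_history
    cursor = state.backtrack_cursor
    stay_put = 0

    for _ in range(n_updates):
        u = random()
        if u < c0:
            strategy = 0  # RW
            k = int(random() * 9)
            dx, dy = neigh9[k]
            hx, hy = cellx + dx, celly + dy
        elif u < c1:
            strategy = 1  # RT
            n_c = 0
            cand0x = cand0y = cand1x = cand1y = cand2x = cand2y = 0
            for hk in (heading - 1, heading, heading + 1):
                dx, dy = vectors[hk % 8]
                nxi, nyi = cellx + dx, celly + dy
                if 0 <= nxi < cols and 0 <= nyi < rows and feat[nyi, nxi]:
                    if n_c == 0:
                        cand0x, cand0y = nxi, nyi
                    elif n_c == 1:
                        cand1x, cand1y = nxi, nyi
                    else:
                        cand2x, cand2y = nxi, nyi
                    n_c += 1
            if n_c:
                k = int(random() * n_c)
                if k == 0:
                    hx, hy = cand0x, cand0y
                elif k == 1:
                    hx, hy = cand1x, cand1y
                else:
                    hx, hy = cand2x, cand2y
            else:
                k = int(random() * 9)
                dx, dy = neigh9[k]
                hx, hy = cellx + dx, celly + dy
        elif u < c2:
            strategy = 2  # DT
            dx, dy = vectors[heading]
            hx, hy = cellx + dx, celly + dy
        elif u < c3:
            strategy = 3  # SP
            hx, hy = cellx, celly
        elif u < c4:
            strategy = 4  # VE
            best = -math.inf
            tied = []
            for dx, dy in neigh9:
                nxi, nyi = cellx + dx, celly + dy
                if 0 <= nxi < cols and 0 <= nyi < rows:
                    e = elev[nyi, nxi]
                    if e > best:
                        best = e
                        tied = [(nxi, nyi)]
                    elif e == best:
                        tied.append((nxi, nyi))
            if len(tied) == 1:
                hx, hy = tied[0]
            else:
                hx, hy = tied[int(random() * len(tied))]
        else:
            strategy = 5  # BT
            if behaviors[-1] != 5:
                idx = len(positions) - 2
            else:
                idx = cursor - 1
                while idx > 0 and behaviors[idx] == 5:
                    idx -= 1
                if idx < 0:
                    idx = 0
            cursor = idx
            hx, hy = positions[idx]

        nx = a2 * x + a1 * px + alpha * (hx - x)
        ny = a2 * y + a1 * py + alpha * (hy - y)
        cx = int(floor(nx + 0.5))
        cy = int(floor(ny + 0.5))
        if 0 <= cx < cols and 0 <= cy < rows and not inacc[cy, cx]:
            vx = nx - x
            vy = ny - y
            if vx != 0 or vy != 0:
                heading = int(round(atan2(vy, vx) / quarter)) % 8
            px, py = x, y
            x, y = nx, ny
            cellx, celly = cx, cy
        else:
            stay_put += 1
        positions.append((cellx, celly))
        behaviors.append(strategy)
    # ----------------------------------------------------------------------

    cells = np.asarray(positions, dtype=np.int32)
    beh = np.asarray(
        [-1 if b is None else b for b in behaviors], dtype=np.int8
    )
    return Trajectory(
        cells=cells,
        behaviors=beh,
        replicate=replicate,
        seed=seed if isinstance(seed, int) else None,
        stay_put_steps=stay_put,
    )


def simulate_replicates(
    ipp: tuple[int, int],
    pmf: bh.BehaviorPMF,
    grid: GridMap,
    config: SimConfig,
    seed: Optional[Union[int, np.random.SeedSequence]] = None,
) -> list[Trajectory]:
    """Simulate ``config.replicates`` independent trajectories.

    Replicate r runs on the child stream of the master seed spawned with
    key (r,): a counter-based scheme, so the replicate set is reproducible
    and order-stable under a fixed master seed.
    """
    master = config.seed if seed is None else seed
    if isinstance(master, np.random.SeedSequence):
        children = [
            np.random.SeedSequence(
                entropy=master.entropy, spawn_key=tuple(master.spawn_key) + (r,)
            )
            for r in range(config.replicates)
        ]
    else:
        children = [
            np.random.SeedSequence(entropy=master, spawn_key=(r,))
            for r in range(config.replicates)
        ]
    return [
        simulate(ipp, pmf, grid, config, seed=child, replicate=r)
        for r, child in enumerate(children)
    ]


def child_seed(master: Union[int, np.random.SeedSequence], *key: int) -> np.random.SeedSequence:
    """Deterministic child seed of a master seed under an integer key path."""
    if isinstance(master, np.random.SeedSequence):
        return np.random.SeedSequence(
            entropy=master.entropy, spawn_key=tuple(master.spawn_key) + key
        )
    return np.random.SeedSequence(entropy=master, spawn_key=key)
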