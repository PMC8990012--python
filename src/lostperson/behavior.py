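"""Lost-person reorientation strategies and behavioral profiles.

A lost person type (LPT) is a probability mass function over six
reorientation strategies, in the fixed order

* ``RW`` random walking -- move to any of the 9 cells of the local 3x3
  neighborhood (8 neighbors + self) with equal probability;
* ``RT`` route traveling -- follow a linear feature, persisting in the
  direction of motion; fall back to a random walk if no feature is ahead;
* ``DT`` direction traveling -- hold the current compass bearing;
* ``SP`` staying put -- remain in place;
* ``VE`` view enhancing -- climb toward the locally highest cell;
* ``BT`` backtracking -- retrace the route already traveled.

At each time step an independent strategy is drawn from the profile and a
provisional next cell is proposed on a body-frame 3x3 grid aligned with the
agent's velocity heading (one of 8 compass sectors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import AgentState
    from .terrain import GridMap

#: Strategy order used everywhere a profile is a plain 6-vector.
STRATEGIES = ("RW", "RT", "DT", "SP", "VE", "BT")
RW, RT, DT, SP, VE, BT = range(6)

#: Eight compass headings, counterclockwise from east; y increases north.
HEADING_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
HEADING_VECTORS = (
    (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1),
)

#: The 9 cells of the 3x3 neighborhood (including self), fixed order.
NEIGHBORHOOD9 = (
    (-1, -1), (0, -1), (1, -1),
    (-1, 0), (0, 0), (1, 0),
    (-1, 1), (0, 1), (1, 1),
)

_PMF_TOL = 1e-9


@dataclass(frozen=True)
class BehaviorPMF:
    """A validated probability mass function over the six strategies."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = self.probabilities
        if len(p) != len(STRATEGIES):
            raise ValueError(
                f"expected {len(STRATEGIES)} probabilities, got {len(p)}"
            )
        for name, v in zip(STRATEGIES, p):
            if v < 0:
                raise ValueError(f"negative probability {v} for {name}")
        total = sum(p)
        if abs(total - 1.0) > _PMF_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def __getitem__(self, i: int) -> float:
        return self.probabilities[i]

    def __iter__(self):
        return iter(self.probabilities)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)

    def cumulative(self) -> tuple[float, ...]:
        """Cumulative probabilities for inverse-CDF strategy sampling."""
        out, acc = [], 0.0
        for v in self.probabilities:
            acc += v
            out.append(acc)
        out[-1] = 1.0  # guard against round-off at the top
        return tuple(out)

    def to_json(self) -> str:
        import json

        return json.dumps(list(self.probabilities))


def make_pmf(values: Sequence[float]) -> BehaviorPMF:
    """Validate a 6-vector of strategy probabilities into a profile."""
    return BehaviorPMF(tuple(float(v) for v in values))


def enumerate_lpts(n_strategies: int = 6, step: float = 1.0 / 6.0) -> list[BehaviorPMF]:
    """All lattice profiles with entries that are multiples of ``step``.

    Incrementing each strategy's probability from zero to one in increments
    of ``step`` and keeping the vectors that sum to one enumerates the
    compositions of ``1/step`` into ``n_strategies`` nonnegative parts:
    C(1/step + n - 1, n - 1) profiles in deterministic lexicographic order.
    For six strategies at step 1/6 this is the 462-element LPT set.
    """
    if n_strategies < 1:
        raise ValueError("n_strategies must be >= 1")
    m = 1.0 / step
    levels = int(round(m))
    if abs(m - levels) > 1e-9 or levels < 1:
        raise ValueError(f"1/step must be a positive integer, got {m}")

    wrap = make_pmf if n_strategies == len(STRATEGIES) else _RawPMF
    out: list = []

    def compose(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            vec = tuple((c / levels) for c in prefix + [remaining])
            out.append(wrap(vec))
            return
        for c in range(remaining + 1):
            compose(prefix + [c], remaining - c, slots - 1)

    compose([], levels, n_strategies)
    return out


class _RawPMF(tuple):
    """A lattice PMF with arbitrary arity (used for oracle-sized lattices)."""

    @property
    def probabilities(self):
        return tuple(self)

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


def sample_strategy(pmf: BehaviorPMF, rng: np.random.Generator) -> int:
    """Draw one strategy id i.i.d. from the profile."""
    u = rng.random()
    for i, c in enumerate(pmf.cumulative()):
        if u < c:
            return i
    return len(pmf.probabilities) - 1


def body_frame_heading(
    velocity: tuple[float, float], previous: int
) -> int:
    """Snap a velocity to the nearest of the 8 compass sectors.

    A zero velocity retains the previous heading so that forward-looking
    strategies keep a defined direction after a stall.
    """
    vx, vy = velocity
    if vx == 0 and vy == 0:
        return previous
    k = int(round(math.atan2(vy, vx) / (math.pi / 4.0)))
    return k % 8


def propose_step(
    strategy: int,
    state: "AgentState",
    grid: "GridMap",
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Provisional next cell for one strategy, in global cell coordinates.

    Candidates are expressed on the body-frame 3x3 grid oriented by the
    current heading and mapped back to global cells.  Inaccessibility of the
    *result* is the simulator's concern, not handled here; only candidate
    eligibility (forward features for RT, in-bounds elevations for VE) looks
    at the map.

    For BT the backtrack cursor on ``state`` is advanced as a side effect:
    the first BT step proposes the previous position x(t-1); each consecutive
    BT step walks the cursor one stored position further back, skipping
    positions that were themselves produced by BT and clamping at the start
    of the trajectory.
    """
    cx, cy = state.cell
    h = state.heading
    if strategy == SP:
        return (cx, cy)
    if strategy == DT:
        dx, dy = HEADING_VECTORS[h]
        return (cx + dx, cy + dy)
    if strategy == RW:
        k = int(rng.random() * 9)
        dx, dy = NEIGHBORHOOD9[k]
        return (cx + dx, cy + dy)
    if strategy == RT:
        cands = []
        for hk in (h - 1, h, h + 1):  # front-right, front, front-left
            dx, dy = HEADING_VECTORS[hk % 8]
            nx, ny = cx + dx, cy + dy
            if 0 <= nx < grid.cols and 0 <= ny < grid.rows and grid.linear_features[ny, nx]:
                cands.append((nx, ny))
        if cands:
            return cands[int(rng.random() * len(cands))]
        k = int(rng.random() * 9)  # no feature ahead: random walk
        dx, dy = NEIGHBORHOOD9[k]
        return (cx + dx, cy + dy)
    if strategy == VE:
        best = -math.inf
        tied: list[tuple[int, int]] = []
        for dx, dy in NEIGHBORHOOD9:
            nx, ny = cx + dx, cy + dy
            if not (0 <= nx < grid.cols and 0 <= ny < grid.rows):
                continue
            e = grid.elevation[ny, nx]
            if e > best:
                best = e
                tied = [(nx, ny)]
            elif e == best:
                tied.append((nx, ny))
        if len(tied) == 1:
            return tied[0]
        return tied[int(rng.random() * len(tied))]
    if strategy == BT:
        positions = state.position_history
        behaviors = state.behavior_history
        if behaviors[-1] != BT:
            idx = len(positions) - 2  # x(t-1)
        else:
            idx = state.backtrack_cursor - 1
            while idx > 0 and behaviors[idx] == BT:
                idx -= 1
            if idx < 0:
                idx = 0
        state.backtrack_cursor = idx
        return positions[idx]
    raise ValueError(f"unknown strategy id {strategy}")
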