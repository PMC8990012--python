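"""Fitting behavioral profiles to incident endpoints with the energy statistic.

For one incident, each candidate profile is simulated for n Monte Carlo
replicates; the closest point of each replicate to the actual find location
forms a sample X = {x_1, ..., x_n}, compared to the single find point Y = {y}
with the energy statistic

    E(X, Y) = 2A - B - C,
    A = (1/nm) sum_ij ||x_i - y_j||,   B = (1/n^2) sum_ij ||x_i - x_j||,
    C = (1/m^2) sum_ij ||y_i - y_j||,

which for a single find point (m = 1) reduces to E = 2A - B with C = 0.
Lower energy means the cloud of closest points concentrates at the find.
The profile with minimum energy is the incident's best fit p_i; incidents
are combined into an average profile with weights w_i = (d_i / E_i)^L,
where d_i is the IPP-to-find distance and L = 1/2 emphasizes better fits:

    p_avg = (w_1 p_1 + ... + w_N p_N) / |w_1 p_1 + ... + w_N p_N|,

normalized by the component sum so the average is again a valid profile.
All distances are in meters (cells x cell_size) so d/E is dimensionless
regardless of grid resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import behavior as bh
from .simulator import SimConfig, Trajectory, child_seed, simulate
from .terrain import GridMap

if TYPE_CHECKING:  # pragma: no cover
    from .incidents import Incident

#: Weight exponent L emphasizing better-fitting profiles.
DEFAULT_WEIGHT_EXPONENT = 0.5
#: Cap applied to the weight of a perfect (zero-energy) fit.
DEFAULT_MAX_WEIGHT = 1e9


@dataclass(frozen=True)
class ClosestPoint:
    """Closest approach of one replicate trajectory to the find location."""

    cell: tuple[int, int]
    time_index: int
    distance_m: float


@dataclass
class FitResult:
    """Best-fitting profile for one incident.

    ``energies`` is the full table of energy statistics, one per candidate
    profile in enumeration order; it is retained for the cross-validation
    percentile comparison.
    """

    incident_id: str
    pmf: bh.BehaviorPMF
    energy_m: float
    distance_m: float
    weight: float
    energies: np.ndarray
    mean_closest_time_h: float = float("nan")


def closest_point(
    trajectory: Trajectory, find: tuple[int, int], cell_size: float
) -> ClosestPoint:
    """Trajectory point minimizing Euclidean distance to the find location.

    Ties are broken by the earliest time index (``argmin`` convention).
    """
    cells = trajectory.cells
    if len(cells) == 0:
        raise ValueError("empty trajectory")
    dx = cells[:, 0].astype(np.float64) - find[0]
    dy = cells[:, 1].astype(np.float64) - find[1]
    d2 = dx * dx + dy * dy
    idx = int(np.argmin(d2))
    return ClosestPoint(
        cell=(int(cells[idx, 0]), int(cells[idx, 1])),
        time_index=idx,
        distance_m=float(np.sqrt(d2[idx])) * cell_size,
    )


def energy_statistic(
    points: Sequence[tuple[float, float]] | np.ndarray,
    find: tuple[float, float],
    cell_size: float = 1.0,
) -> float:
    """Energy statistic between closest points X and the single find point Y.

    ``points`` are closest-point cells of the n replicates; the result is in
    meters.  B is normalized by n^2, so zero self-distances are included;
    C vanishes because the find has a single realization.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty closest-point sample")
    pts = pts.reshape(len(pts), -1) * cell_size
    y = np.asarray(find, dtype=float) * cell_size
    n = len(pts)
    a = float(np.mean(np.linalg.norm(pts - y, axis=1)))
    b = 2.0 * float(pdist(pts).sum()) / (n * n) if n > 1 else 0.0
    return 2.0 * a - b


def incident_weight(
    distance_m: float,
    energy_m: float,
    exponent: float = DEFAULT_WEIGHT_EXPONENT,
    max_weight: float = DEFAULT_MAX_WEIGHT,
) -> float:
    """Incident weight w = (d / E)^L.

    A zero-energy (perfect) fit is capped at ``max_weight`` with a warning
    rather than propagating an infinity.
    """
    if distance_m <= 0:
        raise ValueError("IPP-to-find distance must be positive")
    if energy_m < 0:
        raise ValueError("energy must be nonnegative")
    if energy_m == 0:
        warnings.warn(
            "zero energy statistic (perfect fit); weight capped", stacklevel=2
        )
        return max_weight
    return min((distance_m / energy_m) ** exponent, max_weight)


def best_lpt_for_incident(
    incident: "Incident",
    lpts: Sequence[bh.BehaviorPMF],
    grid: GridMap,
    config: SimConfig,
    seed: Optional[int | np.random.SeedSequence] = None,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> FitResult:
    """Fit one incident: simulate every candidate profile and pick argmin.

    Profile j runs its replicates on child streams of the master seed keyed
    by (j, r).  Energy ties are broken by the lexicographically smallest
    profile for reproducibility.  Replicates are simulated one at a time and
    reduced to their closest points immediately, so memory stays flat at
    paper scale.
    """
    if not lpts:
        raise ValueError("empty candidate profile list")
    master = config.seed if seed is None else seed
    find = incident.find
    energies = np.empty(len(lpts), dtype=float)
    mean_times = np.empty(len(lpts), dtype=float)
    for j, pmf in enumerate(lpts):
        cps = np.empty((config.replicates, 2), dtype=float)
        t_sum = 0.0
        for r in range(config.replicates):
            traj = simulate(
                incident.ipp, pmf, grid, config,
                seed=child_seed(master, j, r), replicate=r,
            )
            cp = closest_point(traj, find, grid.cell_size)
            cps[r] = cp.cell
            t_sum += cp.time_index
        energies[j] = energy_statistic(cps, find, grid.cell_size)
        mean_times[j] = t_sum / config.replicates / config.steps_per_hour
    e_min = energies.min()
    candidates = [j for j in np.nonzero(energies == e_min)[0]]
    best = min(candidates, key=lambda j: tuple(lpts[j].probabilities))
    d = incident.distance_to_find_m(grid.cell_size)
    return FitResult(
        incident_id=incident.id,
        pmf=lpts[best],
        energy_m=float(e_min),
        distance_m=d,
        weight=incident_weight(d, float(e_min), weight_exponent),
        energies=energies,
        mean_closest_time_h=float(mean_times[best]),
    )


def weighted_profile(
    pmfs: Sequence[bh.BehaviorPMF], weights: Sequence[float]
) -> bh.BehaviorPMF:
    """Weighted component-wise average of profiles, normalized to sum to 1."""
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        raise ValueError("no profiles to average")
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and nonnegative")
    acc = np.zeros(len(bh.STRATEGIES))
    for pmf, wi in zip(pmfs, w):
        acc += wi * pmf.as_array()
    total = acc.sum()  # 1-norm of the weighted sum (entries are nonnegative)
    if total == 0:
        raise ValueError("all weights are zero; average profile undefined")
    return bh.make_pmf(acc / total)


def average_profile(fits: Sequence[FitResult]) -> bh.BehaviorPMF:
    """Weighted average behavioral profile over per-incident best fits."""
    return weighted_profile([f.pmf for f in fits], [f.weight for f in fits])


def fits_to_dataframe(fits: Sequence[FitResult]):
    """Tabulate fit results (one row per incident, sorted by weight)."""
    import pandas as pd

    rows = []
    for f in sorted(fits, key=lambda f: f.weight, reverse=True):
        row = {"incident": f.incident_id}
        row.update(
            {f"p_{s.lower()}": v for s, v in zip(bh.STRATEGIES, f.pmf)}
        )
        row.update(
            {
                "energy_m": f.energy_m,
                "distance_m": f.distance_m,
                "weight": f.weight,
                "mean_closest_time_h": f.mean_closest_time_h,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
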