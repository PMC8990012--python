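"""Model validation: leave-one-out cross-validation and speed diagnostics.

LOOCV holds out one incident at a time, averages the remaining best-fit
profiles into a trained profile, simulates the held-out incident with that
single profile, and ranks the resulting energy statistic within the
incident's original table of candidate-profile energies.  The percentile is
oriented so that *high* is good: it is the share of candidate profiles the
trained profile beats (has lower energy than).

The effective-speed diagnostic regresses the mean time of closest approach
(hours) on the IPP-to-find distance (km), restricted to short incidents
where the relation is approximately linear; inverting the slope gives the
model's net displacement rate in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy import stats

from . import behavior as bh
from .fitting import FitResult, closest_point, energy_statistic, weighted_profile
from .simulator import SimConfig, child_seed, simulate
from .terrain import GridMap


@dataclass
class LoocvRecord:
    """One cross-validation fold."""

    incident_id: str
    trained_pmf: bh.BehaviorPMF
    energy_m: float
    percentile: float


@dataclass
class SpeedFit:
    """Linear fit of closest-approach time (h) versus distance (km)."""

    slope_h_per_km: float
    intercept_h: float
    r_squared: float
    effective_speed_ms: float
    cutoff_km: float
    n_points: int

    @property
    def speed_defined(self) -> bool:
        return np.isfinite(self.effective_speed_ms)


def percentile_rank(energy: float, reference: Sequence[float]) -> float:
    """Share (in percent) of reference energies that ``energy`` beats.

    100 means lower energy than every candidate profile; 0 means worse than
    all of them.  Antitone in ``energy``.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference energy table")
    return 100.0 * float(np.count_nonzero(ref >= energy)) / ref.size


def loocv(
    incidents: Sequence,
    fits: Sequence[FitResult],
    grid: Union[GridMap, Callable[[object], GridMap]],
    config: SimConfig,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> list[LoocvRecord]:
    """Leave-one-out cross-validation of the averaged profile.

    ``grid`` is either one shared map or a callable mapping an incident to
    its map.  Fold i trains on all fits but i, simulates
    ``config.replicates`` trajectories of the held-out incident under the
    trained profile (child seed keyed by (1, i)), and ranks the resulting
    energy within the incident's stored candidate-energy table.
    """
    if len(incidents) != len(fits):
        raise ValueError("incidents and fits must align")
    if len(incidents) < 2:
        raise ValueError("LOOCV needs at least two incidents")
    for f in fits:
        if f.energies is None or len(f.energies) == 0:
            raise ValueError(f"incident {f.incident_id}: missing energy table")
    master = config.seed if seed is None else seed
    grid_for = grid if callable(grid) else (lambda _inc: grid)
    records = []
    for i, (inc, fit) in enumerate(zip(incidents, fits)):
        rest = [f for j, f in enumerate(fits) if j != i]
        trained = weighted_profile([f.pmf for f in rest], [f.weight for f in rest])
        g = grid_for(inc)
        cps = np.empty((config.replicates, 2), dtype=float)
        for r in range(config.replicates):
            traj = simulate(
                inc.ipp, trained, g, config,
                seed=child_seed(master, 1, i, r), replicate=r,
            )
            cps[r] = closest_point(traj, inc.find, g.cell_size).cell
        e = energy_statistic(cps, inc.find, g.cell_size)
        records.append(
            LoocvRecord(
                incident_id=inc.id,
                trained_pmf=trained,
                energy_m=float(e),
                percentile=percentile_rank(e, fit.energies),
            )
        )
    return records


def loocv_summary(records: Sequence[LoocvRecord]) -> dict[str, float]:
    """Headline fractions: shares of folds above the 95th/50th percentile."""
    pct = np.asarray([r.percentile for r in records], dtype=float)
    return {
        "frac_above_95th": float(np.mean(pct > 95.0)),
        "frac_above_50th": float(np.mean(pct > 50.0)),
    }


def loocv_to_dataframe(records: Sequence[LoocvRecord]):
    import pandas as pd

    rows = []
    for r in records:
        row = {"incident": r.incident_id}
        row.update(
            {f"p_{s.lower()}": v for s, v in zip(bh.STRATEGIES, r.trained_pmf)}
        )
        row.update({"energy_m": r.energy_m, "percentile": r.percentile})
        rows.append(row)
    return pd.DataFrame(rows)


def effective_speed_fit(
    mean_times_h: Sequence[float],
    distances_km: Sequence[float],
    cutoff_km: float = 4.0,
) -> SpeedFit:
    """OLS fit of closest-approach time on distance below a distance cutoff.

    The effective speed is 1000 / (3600 * slope) m/s when the slope is
    positive; a non-positive slope leaves the speed undefined (NaN).
    """
    t = np.asarray(mean_times_h, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if t.shape != d.shape:
        raise ValueError("times and distances must align")
    mask = d < cutoff_km
    if mask.sum() < 2:
        raise ValueError(
            f"need at least 2 incidents with distance < {cutoff_km} km, "
            f"have {int(mask.sum())}"
        )
    res = stats.linregress(d[mask], t[mask])
    slope = float(res.slope)
    speed = 1000.0 / (slope * 3600.0) if slope > 0 else float("nan")
    return SpeedFit(
        slope_h_per_km=slope,
        intercept_h=float(res.intercept),
        r_squared=float(res.rvalue**2),
        effective_speed_ms=speed,
        cutoff_km=cutoff_km,
        n_points=int(mask.sum()),
    )
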