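"""Search-incident records, exclusion criteria, file I/O, synthetic incidents.

An incident pairs an initial planning point (IPP) with the find location
where the lost person was actually located.  For paper-style maps the IPP
sits at the central cell of its own 20 km x 20 km map.  Incidents are
screened by exclusion criteria before fitting: the find must be more than a
minimum distance from the IPP (1 km by default), inside the map, accessible,
and clear of the map boundary (100 cells by default).

The synthetic-incident generator produces endpoints of trajectories
simulated from a known ground-truth profile, emulating the structure of real
incident endpoints (an IPP, a find point, no timing information) for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import math

import numpy as np
import pandas as pd

from . import behavior as bh
from .simulator import SimConfig, child_seed, simulate
from .terrain import GridMap


@dataclass
class Incident:
    """One search incident: IPP and find location in cell coordinates."""

    id: str
    ipp: tuple[int, int]
    find: tuple[int, int]
    category: str = "hiker"
    map_id: Optional[str] = None

    def distance_to_find_m(self, cell_size: float) -> float:
        """Straight-line IPP-to-find distance in meters."""
        return math.hypot(
            self.find[0] - self.ipp[0], self.find[1] - self.ipp[1]
        ) * cell_size


@dataclass
class SyntheticIncidentTruth:
    """Ground truth behind one synthetic incident (for recovery tests)."""

    pmf: bh.BehaviorPMF
    seed: int
    find_time_index: int
    attempt: int = 0


@dataclass
class ExclusionConfig:
    """Incident screening thresholds (paper-scale defaults)."""

    min_distance_m: float = 1000.0
    boundary_margin_cells: int = 100

    def scaled(self, factor: float) -> "ExclusionConfig":
        """Thresholds scaled by a map-size ratio (for scaled-down maps)."""
        return ExclusionConfig(
            min_distance_m=self.min_distance_m * factor,
            boundary_margin_cells=int(round(self.boundary_margin_cells * factor)),
        )


def apply_exclusion_criteria(
    incident: Incident,
    grid: GridMap,
    config: ExclusionConfig = ExclusionConfig(),
) -> tuple[bool, Optional[str]]:
    """Screen one incident; returns (keep, reason-if-rejected).

    Rejection reasons are checked in order: find too close to the IPP
    (straight-line distance), find outside the map, find in an inaccessible
    cell, find within the boundary margin (Chebyshev distance to the nearest
    map edge).
    """
    fx, fy = incident.find
    d = incident.distance_to_find_m(grid.cell_size)
    if d < config.min_distance_m:
        return False, (
            f"find within {config.min_distance_m:.0f} m of IPP ({d:.0f} m)"
        )
    if not grid.in_bounds(fx, fy):
        return False, f"find (x={fx}, y={fy}) outside map limits"
    if grid.inaccessible[fy, fx]:
        return False, f"find (x={fx}, y={fy}) in an inaccessible area"
    edge = min(fx, fy, grid.cols - 1 - fx, grid.rows - 1 - fy)
    if edge < config.boundary_margin_cells:
        return False, (
            f"find within {config.boundary_margin_cells} cells of the map "
            f"boundary ({edge} cells)"
        )
    return True, None


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CELL_COLS = ("id", "ipp_x", "ipp_y", "find_x", "find_y")
_GEO_COLS = ("id", "ipp_lon", "ipp_lat", "find_lon", "find_lat")


def read_incidents(
    path: str,
    grid: Optional[GridMap] = None,
) -> list[Incident]:
    """Read incidents from CSV.

    Two dialects: cell coordinates (columns id, ipp_x, ipp_y, find_x,
    find_y) or world coordinates (id, ipp_lon, ipp_lat, find_lon, find_lat)
    converted through the map's geo-transform (``grid`` required).
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if set(_CELL_COLS) <= cols:
        names, geo = _CELL_COLS, False
    elif set(_GEO_COLS) <= cols:
        if grid is None or grid.transform is None:
            raise ValueError(
                "lon/lat incident file requires a GridMap with a geo-transform"
            )
        names, geo = _GEO_COLS, True
    else:
        raise ValueError(
            f"missing columns: need {_CELL_COLS} or {_GEO_COLS}, "
            f"found {sorted(cols)}"
        )
    out: list[Incident] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            vals = [float(row[c]) for c in names[1:]]
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric coordinate in {dict(row)}")
            continue
        if geo:
            ipp = grid.world_to_cell(vals[0], vals[1])
            find = grid.world_to_cell(vals[2], vals[3])
        else:
            ipp = (int(round(vals[0])), int(round(vals[1])))
            find = (int(round(vals[2])), int(round(vals[3])))
        cat = str(row["category"]) if "category" in cols else "hiker"
        out.append(Incident(id=str(row["id"]), ipp=ipp, find=find, category=cat))
    if errors:
        raise ValueError("malformed incident rows:\n" + "\n".join(errors))
    return out


def write_incidents(incidents: Sequence[Incident], path: str) -> None:
    """Write incidents as cell-coordinate CSV (round-trips with read)."""
    pd.DataFrame(
        {
            "id": [i.id for i in incidents],
            "ipp_x": [i.ipp[0] for i in incidents],
            "ipp_y": [i.ipp[1] for i in incidents],
            "find_x": [i.find[0] for i in incidents],
            "find_y": [i.find[1] for i in incidents],
            "category": [i.category for i in incidents],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic incidents
# ---------------------------------------------------------------------------

def generate_synthetic_incident(
    grid: GridMap,
    truth_pmf: bh.BehaviorPMF,
    mobile_hours: float,
    config: SimConfig,
    seed: Union[int, np.random.SeedSequence],
    exclusion: ExclusionConfig = ExclusionConfig(),
    incident_id: str = "synthetic",
    max_retries: int = 50,
) -> tuple[Incident, SyntheticIncidentTruth]:
    """Generate one incident whose find lies on a truth-profile trajectory.

    One trajectory of ``mobile_hours`` is simulated from the map center; the
    find is its cell at a time drawn uniformly over the mobile window
    (incident data carries no timing, so any time in the window is equally
    plausible).  The draw is retried with fresh child seeds until the
    incident passes the exclusion criteria; a truth profile that cannot
    produce admissible finds (e.g. pure staying-put never clears the
    minimum distance) exhausts the retry budget with an explanatory error.
    """
    if mobile_hours > config.hours:
        raise ValueError("mobile_hours cannot exceed the simulated duration")
    sim_cfg = SimConfig(
        alpha=config.alpha,
        hours=mobile_hours,
        steps_per_hour=config.steps_per_hour,
        replicates=1,
        seed=config.seed,
    )
    ipp = grid.center
    reasons: list[str] = []
    for attempt in range(max_retries):
        ss = child_seed(seed, attempt)
        traj = simulate(ipp, truth_pmf, grid, sim_cfg, seed=ss)
        t_rng = np.random.default_rng(child_seed(seed, attempt, 999))
        t_idx = int(t_rng.integers(1, len(traj.cells)))
        find = (int(traj.cells[t_idx, 0]), int(traj.cells[t_idx, 1]))
        inc = Incident(id=incident_id, ipp=ipp, find=find)
        keep, reason = apply_exclusion_criteria(inc, grid, exclusion)
        if keep:
            truth = SyntheticIncidentTruth(
                pmf=truth_pmf,
                seed=seed if isinstance(seed, int) else -1,
                find_time_index=t_idx,
                attempt=attempt,
            )
            return inc, truth
        reasons.append(reason)
    raise RuntimeError(
        f"could not generate an admissible incident in {max_retries} tries; "
        f"the truth profile conflicts with the exclusion criteria "
        f"(last reason: {reasons[-1]})"
    )


def generate_synthetic_incidents(
    grid: GridMap,
    truth_pmf: bh.BehaviorPMF,
    n: int,
    mobile_hours: float,
    config: SimConfig,
    seed: Union[int, np.random.SeedSequence],
    exclusion: ExclusionConfig = ExclusionConfig(),
) -> tuple[list[Incident], list[SyntheticIncidentTruth]]:
    """Generate ``n`` admissible synthetic incidents with indexed ids."""
    incidents, truths = [], []
    for i in range(n):
        inc, truth = generate_synthetic_incident(
            grid,
            truth_pmf,
            mobile_hours,
            config,
            seed=child_seed(seed, i),
            exclusion=exclusion,
            incident_id=f"syn-{i:03d}",
        )
        incidents.append(inc)
        truths.append(truth)
    return incidents, truths
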