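"""Water residency times, exit-region classification and residency aggregation.

The residency statistic: a water has left the chromophore pocket at the
earliest time t* from which its oxygen's distance to the chromophore
beta-methylene bridge atom stays above a cutoff (default 2 nm) at every
sampled frame for at least a persistence window (default 0.1 ns), inclusive
of the window's start frame.  A water that never satisfies the criterion is
censored at the trajectory duration and reported with a "greater-than"
convention.  Exits are classified by the nearest interstrand gate centroid
at the first frame of the persistent excursion; this geometric rule is the
package's operational definition of an exit point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import SeriesStat
from .model import AtomSelection, RegionSet, SelectionError, Trajectory

__all__ = [
    "ResidencyCriteria",
    "ResidencyRecord",
    "ResidencySummary",
    "WaterSummaryRow",
    "default_bridge_selection",
    "distance_trace",
    "residency_time",
    "classify_exit",
    "aggregate_residency",
]

log = logging.getLogger(__name__)


def default_bridge_selection() -> AtomSelection:
    """The chromophore methylene-bridge carbon (standard component name CB2)."""
    return AtomSelection(name="CB2", res_name="CRO")


@dataclass(frozen=True)
class ResidencyCriteria:
    cutoff_nm: float = 2.0
    persistence_ns: float = 0.1
    reference_atom: AtomSelection | None = None  # defaults to the bridge carbon

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        if self.persistence_ns < 0:
            raise ValueError("persistence must be non-negative")

    def reference(self) -> AtomSelection:
        return self.reference_atom or default_bridge_selection()


@dataclass(frozen=True)
class ResidencyRecord:
    water_id: str
    residency_ns: float
    censored: bool
    exit_region: str | None = None
    exit_frame: int | None = None  # first frame of the persistent excursion
    decision_margin_nm: float | None = None  # runner-up minus nearest gate distance


@dataclass(frozen=True)
class WaterSummaryRow:
    water_id: str
    n: int  # non-censored records
    mean_ns: float | None
    sd_ns: float | None  # sample (n-1) sd; None when n < 2
    n_censored: int

    @property
    def available(self) -> bool:
        return self.n >= 1


@dataclass(frozen=True)
class ResidencySummary:
    rows: tuple[WaterSummaryRow, ...]

    def row(self, water_id: str) -> WaterSummaryRow:
        for r in self.rows:
            if r.water_id == water_id:
                return r
        raise KeyError(water_id)


def distance_trace(
    traj: Trajectory,
    water_res_id: int,
    criteria: ResidencyCriteria = ResidencyCriteria(),
    water_chain: str | None = None,
    label: str = "",
) -> SeriesStat:
    """Per-frame distance (nm) from a water's oxygen to the reference atom."""
    water_o = AtomSelection(res_id=water_res_id, chain=water_chain, element="O")
    idx = water_o.resolve(traj.topology)
    if idx.size == 0:
        raise SelectionError(f"water residue {water_res_id} has no oxygen atom")
    if idx.size > 1:
        raise SelectionError(f"water residue {water_res_id} is ambiguous")
    ref = criteria.reference().resolve_single(traj.topology)
    d = np.linalg.norm(traj.coords[:, int(idx[0])] - traj.coords[:, ref], axis=-1)
    return SeriesStat(times=traj.times.copy(), values=d, label=label)


def residency_time(
    trace: SeriesStat,
    criteria: ResidencyCriteria = ResidencyCriteria(),
    water_id: str = "",
    spacing_rtol: float = 1e-6,
) -> ResidencyRecord:
    """Earliest t* with the trace above cutoff at every frame in [t*, t*+persistence].

    The window is inclusive of its start frame and must be fully sampled
    within the trace; if no such window exists the record is censored at the
    trace duration.
    """
    t = trace.times
    if len(t) < 2:
        raise ValueError("residency requires a multi-frame trace")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=spacing_rtol, atol=1e-9):
        raise ValueError("non-uniform frame spacing beyond tolerance")
    step = float(dt[0])
    window = int(round(criteria.persistence_ns / step)) + 1
    if window < 2:
        raise ValueError("persistence must span at least one frame interval")
    above = trace.values > criteria.cutoff_nm
    n = len(above)
    duration = float(t[-1] - t[0])
    if n >= window:
        run = np.convolve(above.astype(int), np.ones(window, dtype=int), mode="valid")
        hits = np.nonzero(run == window)[0]
        if hits.size:
            i = int(hits[0])
            return ResidencyRecord(
                water_id=water_id,
                residency_ns=float(t[i] - t[0]),
                censored=False,
                exit_frame=i,
            )
    return ResidencyRecord(
        water_id=water_id, residency_ns=duration, censored=True
    )


def _gate_centroids(
    traj: Trajectory, frame_index: int, regions: RegionSet
) -> dict[str, np.ndarray]:
    centroids: dict[str, np.ndarray] = {}
    for label, (s1, s2) in regions.regions.items():
        idx = np.concatenate(
            [s1.selection().resolve(traj.topology), s2.selection().resolve(traj.topology)]
        )
        if idx.size == 0:
            raise SelectionError(f"region {label!r} residues not present in topology")
        centroids[label] = traj.coords[frame_index, idx].mean(axis=0)
    return centroids


def classify_exit(
    traj: Trajectory,
    water_res_id: int,
    record: ResidencyRecord,
    regions: RegionSet,
    water_chain: str | None = None,
) -> ResidencyRecord:
    """Assign the exit gate: the region whose Calpha gate centroid is nearest
    the water oxygen at the first frame of the persistent excursion.

    Ties break toward the earlier region label (logged); the runner-up margin
    is recorded for audit.
    """
    if record.censored:
        raise ValueError("cannot classify the exit of a censored record")
    if record.exit_frame is None:
        raise ValueError("record carries no exit frame")
    water_o = AtomSelection(res_id=water_res_id, chain=water_chain, element="O")
    wi = int(water_o.resolve_nonempty(traj.topology)[0])
    pos = traj.coords[record.exit_frame, wi]
    centroids = _gate_centroids(traj, record.exit_frame, regions)
    labels = list(centroids)
    dists = np.array([np.linalg.norm(pos - centroids[lb]) for lb in labels])
    order = np.argsort(dists, kind="stable")  # stable: ties -> earlier label
    best = int(order[0])
    margin = float(dists[order[1]] - dists[best]) if len(labels) > 1 else np.inf
    if len(labels) > 1 and margin < 1e-9:
        log.info(
            "water %s: exit gate tie between %s and %s; keeping %s",
            record.water_id, labels[best], labels[int(order[1])], labels[best],
        )
    log.debug(
        "water %s exits via %s (distance %.3f nm, margin %.3f nm)",
        record.water_id, labels[best], dists[best], margin,
    )
    return replace(
        record, exit_region=labels[best], decision_margin_nm=margin
    )


def aggregate_residency(records: list[ResidencyRecord]) -> ResidencySummary:
    """Per-water mean and sample sd of residency across runs.

    Censored records are excluded from the statistics and counted separately;
    a water with only censored records is flagged unavailable (n = 0).
    """
    by_water: dict[str, list[ResidencyRecord]] = {}
    for r in records:
        by_water.setdefault(r.water_id, []).append(r)
    rows = []
    for water_id, recs in by_water.items():
        vals = np.array([r.residency_ns for r in recs if not r.censored])
        n_cens = sum(r.censored for r in recs)
        if vals.size == 0:
            rows.append(WaterSummaryRow(water_id, 0, None, None, n_cens))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else None
        rows.append(WaterSummaryRow(water_id, int(vals.size), mean, sd, n_cens))
    return ResidencySummary(rows=tuple(rows))


def format_residency(record: ResidencyRecord, duration_ns: float | None = None) -> str:
    """Text rendering; censored residencies use the '> duration' convention."""
    if record.censored:
        d = duration_ns if duration_ns is not None else record.residency_ns
        return f">{d:g}"
    return f"{record.residency_ns:g}"
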