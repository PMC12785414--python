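"""Two-state segmentation of chromophore RMSD series and carbonyl flip analysis.

The chromophore of red fluorescent proteins can hop between conformers that
differ mainly in the orientation of the acylimine carbonyl (the backbone
C=O contributed by the residue preceding the chromophore); in the high-RMSD
conformer that oxygen is rotated ~180 deg out of the conjugated plane.
States are defined operationally by deterministic two-means clustering of
the RMSD series, and flips by a persistent departure of the carbonyl
dihedral from its reference-frame value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SeriesStat
from .model import AtomSelection, Trajectory

__all__ = [
    "StateSegmentation",
    "FlipSeries",
    "segment_states",
    "dihedral_series",
    "flip_angle",
    "default_flip_quadruple",
]

_LEVEL_TOL = 1e-12


@dataclass(frozen=True)
class StateSegmentation:
    labels: np.ndarray  # per-frame, values in {"low", "high"} (or all "low")
    occupancy: dict[str, float]
    switch_count: int
    levels: dict[str, float]  # per-state mean RMSD (nm)


def segment_states(series: SeriesStat, n_states: int = 2) -> StateSegmentation:
    """Deterministic 1-D two-means segmentation of an RMSD series.

    Centers are initialised at the series minimum and maximum and refined by
    Lloyd iteration; labels are assigned by level ("low"/"high").  A constant
    series collapses to a single occupied state with zero switches.  Only
    two states are supported — the analysis operationalises "at least two
    distinct conformations", not a general mixture model.
    """
    if n_states != 2:
        raise ValueError("only two-state segmentation is supported")
    v = series.values
    if len(v) < 10:
        raise ValueError("segmentation requires at least 10 frames")
    if np.ptp(v) < _LEVEL_TOL:
        labels = np.array(["low"] * len(v))
        return StateSegmentation(
            labels=labels,
            occupancy={"low": 1.0, "high": 0.0},
            switch_count=0,
            levels={"low": float(v.mean())},
        )
    lo, hi = float(v.min()), float(v.max())
    for _ in range(200):
        assign = np.abs(v - lo) <= np.abs(v - hi)  # True -> low cluster
        new_lo = float(v[assign].mean()) if assign.any() else lo
        new_hi = float(v[~assign].mean()) if (~assign).any() else hi
        if abs(new_lo - lo) < _LEVEL_TOL and abs(new_hi - hi) < _LEVEL_TOL:
            break
        lo, hi = new_lo, new_hi
    labels = np.where(assign, "low", "high")
    switches = int(np.sum(labels[1:] != labels[:-1]))
    occ_low = float(np.mean(assign))
    return StateSegmentation(
        labels=labels,
        occupancy={"low": occ_low, "high": 1.0 - occ_low},
        switch_count=switches,
        levels={"low": lo, "high": hi},
    )


def default_flip_quadruple() -> tuple[AtomSelection, ...]:
    """Dihedral atoms for the acylimine carbonyl flip: N-CA-C-O of residue 65.

    Rotation of the carbonyl oxygen about the CA-C axis (the flip seen in the
    high-RMSD chromophore conformer) changes this dihedral directly.  The
    quadruple is a named default; override for other topologies.
    """
    return tuple(AtomSelection(name=n, res_id=65) for n in ("N", "CA", "C", "O"))


def dihedral_series(coords: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees, (-180, 180]) of four atoms over all frames."""
    p = coords[:, quad, :]  # (T, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    bad = (norm1 < 1e-12) | (norm2 < 1e-12)
    if bad.any():
        raise ValueError(f"collinear dihedral geometry at frame {int(np.nonzero(bad)[0][0])}")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 to keep the (-180, 180] contract
    ang[ang <= -180.0 + 1e-12] = 180.0
    return ang


def _wrap(delta: np.ndarray) -> np.ndarray:
    return (delta + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class FlipSeries:
    times: np.ndarray
    angles_deg: np.ndarray  # (-180, 180]
    reference_deg: float
    events: tuple[int, ...]  # onset frame indices, strictly increasing
    threshold_deg: float
    persistence_frames: int


def flip_angle(
    traj: Trajectory,
    dihedral_atoms: tuple[AtomSelection, ...] | None = None,
    threshold_deg: float = 120.0,
    persistence_ns: float = 0.05,
) -> FlipSeries:
    """Carbonyl flip dihedral per frame plus persistent flip events.

    An event starts at a frame where the angle departs from the frame-0
    reference by at least ``threshold_deg`` and stays departed for at least
    ``persistence_ns`` (default 0.05 ns — below the water-residency
    persistence scale, above the frame interval, suppressing single-frame
    noise).
    """
    sels = dihedral_atoms or default_flip_quadruple()
    if len(sels) != 4:
        raise ValueError("a dihedral needs exactly four atom selections")
    quad = np.array([s.resolve_single(traj.topology) for s in sels])
    angles = dihedral_series(traj.coords, quad)
    ref = float(angles[0])
    departed = np.abs(_wrap(angles - ref)) >= threshold_deg
    if traj.n_frames > 1:
        persist = max(1, int(round(persistence_ns / traj.frame_interval_ns)))
    else:
        persist = 1
    events: list[int] = []
    i = 0
    n = len(departed)
    while i < n:
        if departed[i] and (i == 0 or not departed[i - 1]):
            j = i
            while j < n and departed[j]:
                j += 1
            if j - i >= persist:
                events.append(i)
            i = j
        else:
            i += 1
    return FlipSeries(
        times=traj.times.copy(),
        angles_deg=angles,
        reference_deg=ref,
        events=tuple(events),
        threshold_deg=float(threshold_deg),
        persistence_frames=persist,
    )
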