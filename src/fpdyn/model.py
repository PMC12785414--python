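"""Domain types for structures, trajectories, atom selections and barrel regions.

Internal units are nm (coordinates) and ns (times) throughout the package;
angstroms appear only at PDB boundaries and in crystal-comparison reporting.
Residue numbering follows the author (mCherry-derived) convention, e.g. the
chromophore tripeptide is 66-68 and the acylimine carbonyl belongs to F65.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "RegionSegment",
    "RegionSet",
    "SelectionError",
    "TopologyError",
]


class TopologyError(ValueError):
    """Raised when a topology or trajectory violates a structural invariant."""


class SelectionError(ValueError):
    """Raised when an atom selection cannot be resolved as required."""


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.

    ``res_id`` is the author residue number; ``serial`` must be unique within
    a topology.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str


@dataclass(frozen=True)
class Frame:
    """A single coordinate snapshot: per-atom 3-vectors in nm at ``time_ns``."""

    time_ns: float
    coords: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise TopologyError(f"frame coordinates must be (n, 3), got {c.shape}")
        if not np.isfinite(c).all():
            raise TopologyError("frame contains non-finite coordinates")
        if self.time_ns < 0:
            raise TopologyError("frame time must be non-negative")
        object.__setattr__(self, "coords", c)


def _check_serials(topology: Sequence[Atom]) -> None:
    serials = [a.serial for a in topology]
    if len(set(serials)) != len(serials):
        seen: set[int] = set()
        for s in serials:
            if s in seen:
                raise TopologyError(f"duplicate atom serial {s} in topology")
            seen.add(s)


class Trajectory:
    """An ordered atom list plus one or more coordinate frames.

    Frames are stored internally as a dense ``(n_frames, n_atoms, 3)`` array
    in nm with a matching ``times`` vector in ns.  Frame times must be
    strictly increasing and (for multi-frame trajectories) uniformly spaced
    within ``spacing_rtol``.
    """

    def __init__(
        self,
        topology: Sequence[Atom],
        coords: np.ndarray,
        times: np.ndarray,
        spacing_rtol: float = 1e-6,
    ) -> None:
        topology = list(topology)
        _check_serials(topology)
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TopologyError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[0] == 0:
            raise TopologyError("trajectory must contain at least one frame")
        if coords.shape[1] != len(topology):
            raise TopologyError(
                f"coordinate count {coords.shape[1]} != topology atom count {len(topology)}"
            )
        if times.shape != (coords.shape[0],):
            raise TopologyError("times must have one entry per frame")
        if not np.isfinite(coords).all():
            raise TopologyError("trajectory contains non-finite coordinates")
        if len(times) > 1:
            dt = np.diff(times)
            if not (dt > 0).all():
                raise TopologyError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=spacing_rtol, atol=1e-9):
                raise TopologyError("frame spacing is not uniform within tolerance")
        self.topology = topology
        self.coords = coords
        self.times = times

    # -- basic properties -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ns(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def frame_interval_ns(self) -> float:
        if self.n_frames < 2:
            raise TopologyError("frame interval undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time_ns=float(self.times[i]), coords=self.coords[i])

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, topology: Sequence[Atom], frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise TopologyError("trajectory must contain at least one frame")
        coords = np.stack([f.coords for f in frames])
        times = np.array([f.time_ns for f in frames])
        return cls(topology, coords, times)


IdSpec = int | tuple[int, int] | Iterable[int] | None
StrSpec = str | Iterable[str] | None


def _norm_str(spec: StrSpec) -> frozenset[str] | None:
    if spec is None:
        return None
    if isinstance(spec, str):
        return frozenset({spec})
    return frozenset(spec)


@dataclass(frozen=True)
class AtomSelection:
    """Declarative predicate over (name, res_name, res_id, chain, element).

    ``res_id`` accepts a single id, an inclusive ``(lo, hi)`` interval, or an
    explicit id collection.  Resolution against a topology is deterministic
    and preserves topology order.  An optional ``predicate`` refines the match.
    """

    name: StrSpec = None
    res_name: StrSpec = None
    res_id: IdSpec = None
    chain: StrSpec = None
    element: StrSpec = None
    predicate: Callable[[Atom], bool] | None = None

    def matches(self, atom: Atom) -> bool:
        for spec, value in (
            (_norm_str(self.name), atom.name),
            (_norm_str(self.res_name), atom.res_name),
            (_norm_str(self.chain), atom.chain),
            (_norm_str(self.element), atom.element),
        ):
            if spec is not None and value not in spec:
                return False
        rid = self.res_id
        if rid is not None:
            if isinstance(rid, int):
                if atom.res_id != rid:
                    return False
            elif isinstance(rid, tuple) and len(rid) == 2:
                lo, hi = rid
                if not (lo <= atom.res_id <= hi):
                    return False
            else:
                if atom.res_id not in set(rid):  # type: ignore[arg-type]
                    return False
        if self.predicate is not None and not self.predicate(atom):
            return False
        return True

    def resolve(self, topology: Sequence[Atom]) -> np.ndarray:
        """Indices of matching atoms, in topology order (possibly empty)."""
        return np.array(
            [i for i, a in enumerate(topology) if self.matches(a)], dtype=int
        )

    def resolve_nonempty(self, topology: Sequence[Atom]) -> np.ndarray:
        idx = self.resolve(topology)
        if idx.size == 0:
            raise SelectionError(f"selection {self} matched no atoms")
        return idx

    def resolve_single(self, topology: Sequence[Atom]) -> int:
        idx = self.resolve(topology)
        if idx.size != 1:
            raise SelectionError(
                f"selection {self} must resolve to exactly one atom, got {idx.size}"
            )
        return int(idx[0])


@dataclass(frozen=True)
class RegionSegment:
    """A chain plus an inclusive author residue-number interval."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise TopologyError(
                f"region segment has reversed bounds {self.start}..{self.end}"
            )

    def selection(self, name: str = "CA") -> AtomSelection:
        return AtomSelection(name=name, chain=self.chain, res_id=(self.start, self.end))


@dataclass
class RegionSet:
    """Named interstrand gates, each defined by a pair of residue-range segments.

    Label order is significant: ties in exit-gate assignment break toward the
    earlier label.
    """

    regions: dict[str, tuple[RegionSegment, RegionSegment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regions:
            raise TopologyError("region set must contain at least one region")

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, label: str) -> tuple[RegionSegment, RegionSegment]:
        return self.regions[label]
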