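"""Geometric hydrogen-bond detection and partitioned per-frame counting.

A bond event is a (donor, hydrogen, acceptor) triple satisfying both a
donor-acceptor distance cutoff and a hydrogen-donor-acceptor angle cutoff
(defaults 0.35 nm / 30 deg, the widely used MD-analysis defaults).  Donor and
acceptor typing follows a small element rule table (N and O accept; N and O
donate when carrying a bonded hydrogen), overridable per call.  Topologies
must declare hydrogens explicitly — heavy-atom-only input is rejected rather
than silently inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Atom, AtomSelection, SelectionError, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondCountSeries",
    "build_hydrogen_map",
    "find_hbonds",
    "count_partitioned",
]

DONOR_ELEMENTS = frozenset({"N", "O"})
ACCEPTOR_ELEMENTS = frozenset({"N", "O"})

_MAX_XH_BOND_NM = 0.15


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.35  # nm
    max_hda_angle: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_hda_angle <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


def build_hydrogen_map(
    topology: list[Atom], coords: np.ndarray
) -> dict[int, list[int]]:
    """Assign each hydrogen to its covalent heavy atom by proximity.

    Each H is attached to the nearest non-hydrogen atom of the same residue
    within 0.15 nm in the given (single-frame) geometry.  Returns a map from
    heavy-atom index to its hydrogen indices.
    """
    coords = np.asarray(coords, dtype=float)
    hmap: dict[int, list[int]] = {}
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(topology):
        by_res.setdefault((a.chain, a.res_id), []).append(i)
    for i, a in enumerate(topology):
        if a.element != "H":
            continue
        heavies = [j for j in by_res[(a.chain, a.res_id)]
                   if topology[j].element != "H"]
        if not heavies:
            raise SelectionError(
                f"hydrogen {a.name} (serial {a.serial}) has no heavy atom in its residue"
            )
        d = np.linalg.norm(coords[heavies] - coords[i], axis=-1)
        j = heavies[int(np.argmin(d))]
        if d.min() > _MAX_XH_BOND_NM:
            raise SelectionError(
                f"hydrogen {a.name} (serial {a.serial}) is {d.min():.3f} nm from the "
                "nearest heavy atom; topology does not look covalently sensible"
            )
        hmap.setdefault(j, []).append(i)
    return hmap


def _donor_pairs(
    topology: list[Atom],
    donor_idx: np.ndarray,
    hmap: dict[int, list[int]],
    require_h: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand donor atoms into (donor, hydrogen) index pairs."""
    d_list: list[int] = []
    h_list: list[int] = []
    for d in donor_idx:
        hs = hmap.get(int(d), [])
        if not hs:
            if require_h:
                a = topology[int(d)]
                raise SelectionError(
                    f"donor atom {a.name} (serial {a.serial}) has no bonded hydrogen"
                )
            continue
        for h in hs:
            d_list.append(int(d))
            h_list.append(h)
    return np.asarray(d_list, dtype=int), np.asarray(h_list, dtype=int)


def _events_all_frames(
    coords: np.ndarray,  # (T, N, 3)
    d_idx: np.ndarray,
    h_idx: np.ndarray,
    a_idx: np.ndarray,
    criteria: HBondCriteria,
    chunk: int = 2000,
) -> list[np.ndarray]:
    """Per-frame arrays of event triples (donor, hydrogen, acceptor)."""
    T = coords.shape[0]
    cos_min = np.cos(np.deg2rad(criteria.max_hda_angle))
    out: list[np.ndarray] = []
    if d_idx.size == 0 or a_idx.size == 0:
        return [np.empty((0, 3), dtype=int) for _ in range(T)]
    for t0 in range(0, T, chunk):
        c = coords[t0:t0 + chunk]
        dpos = c[:, d_idx]  # (t, P, 3)
        hpos = c[:, h_idx]
        apos = c[:, a_idx]  # (t, A, 3)
        da = apos[:, None, :, :] - dpos[:, :, None, :]  # (t, P, A, 3)
        dist = np.linalg.norm(da, axis=-1)
        dh = hpos - dpos  # (t, P, 3)
        dh_norm = np.linalg.norm(dh, axis=-1)
        cosang = np.einsum("tpax,tpx->tpa", da, dh) / (
            dist * dh_norm[:, :, None] + 1e-300
        )
        ok = (dist <= criteria.max_da_distance) & (cosang >= cos_min)
        # a donor is never its own acceptor
        ok &= d_idx[None, :, None] != a_idx[None, None, :]
        for ti in range(c.shape[0]):
            p, a = np.nonzero(ok[ti])
            out.append(np.column_stack([d_idx[p], h_idx[p], a_idx[a]]))
    return out


def find_hbonds(
    frame_coords: np.ndarray,
    topology: list[Atom],
    donors: AtomSelection,
    acceptors: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogen_map: dict[int, list[int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen-bond events in one frame between explicit donor/acceptor sets.

    Every selected donor must have at least one declared hydrogen; the
    returned triples are topology indices ``(donor, hydrogen, acceptor)``.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    donor_idx = donors.resolve_nonempty(topology)
    acceptor_idx = acceptors.resolve_nonempty(topology)
    hmap = hydrogen_map or build_hydrogen_map(topology, frame_coords)
    d_idx, h_idx = _donor_pairs(topology, donor_idx, hmap, require_h=True)
    events = _events_all_frames(
        frame_coords[None], d_idx, h_idx, acceptor_idx, criteria
    )[0]
    return [tuple(row) for row in events]


@dataclass(frozen=True)
class HBondCountSeries:
    """Per-frame bond counts split by partner class, with summary statistics."""

    times: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.counts.values()), axis=0)

    def mean_sd(self, cls: str) -> tuple[float, float]:
        c = self.counts[cls]
        return float(c.mean()), float(c.std(ddof=1)) if len(c) > 1 else 0.0

    def median(self, cls: str) -> float:
        return float(np.median(self.counts[cls]))

    def frequency_table(self, cls: str) -> dict[int, int]:
        vals, freq = np.unique(self.counts[cls], return_counts=True)
        return {int(v): int(f) for v, f in zip(vals, freq)}


def _typed_donors_acceptors(
    topology: list[Atom],
    idx: np.ndarray,
    hmap: dict[int, list[int]],
    donor_elements: frozenset[str],
    acceptor_elements: frozenset[str],
) -> tuple[np.ndarray, np.ndarray]:
    donors = np.array(
        [i for i in idx if topology[i].element in donor_elements and hmap.get(int(i))],
        dtype=int,
    )
    acceptors = np.array(
        [i for i in idx if topology[i].element in acceptor_elements], dtype=int
    )
    return donors, acceptors


def count_partitioned(
    traj: Trajectory,
    group: AtomSelection,
    partners: dict[str, AtomSelection],
    criteria: HBondCriteria = HBondCriteria(),
    donor_elements: frozenset[str] = DONOR_ELEMENTS,
    acceptor_elements: frozenset[str] = ACCEPTOR_ELEMENTS,
) -> HBondCountSeries:
    """Count bonds per frame between a group and disjoint partner classes.

    Direction-agnostic: an event counts toward a class when one end (donor or
    acceptor) lies in the group and the other end in that class.  The typical
    partition is {protein, water} against the chromophore.
    """
    topo = traj.topology
    group_idx = group.resolve_nonempty(topo)
    partner_idx = {cls: sel.resolve_nonempty(topo) for cls, sel in partners.items()}
    claimed: set[int] = set()
    for cls, idx in partner_idx.items():
        overlap = claimed & set(idx.tolist())
        if overlap:
            raise SelectionError(f"partner class {cls!r} overlaps another class")
        claimed |= set(idx.tolist())
    g_overlap = claimed & set(group_idx.tolist())
    if g_overlap:
        raise SelectionError("partner classes must not overlap the group selection")

    hmap = build_hydrogen_map(topo, traj.coords[0])
    g_don, g_acc = _typed_donors_acceptors(
        topo, group_idx, hmap, donor_elements, acceptor_elements
    )
    counts: dict[str, np.ndarray] = {}
    for cls, idx in partner_idx.items():
        p_don, p_acc = _typed_donors_acceptors(
            topo, idx, hmap, donor_elements, acceptor_elements
        )
        per_frame = np.zeros(traj.n_frames, dtype=int)
        # group donates to class
        d_idx, h_idx = _donor_pairs(topo, g_don, hmap, require_h=False)
        for ti, ev in enumerate(
            _events_all_frames(traj.coords, d_idx, h_idx, p_acc, criteria)
        ):
            per_frame[ti] += len(ev)
        # class donates to group
        d_idx, h_idx = _donor_pairs(topo, p_don, hmap, require_h=False)
        for ti, ev in enumerate(
            _events_all_frames(traj.coords, d_idx, h_idx, g_acc, criteria)
        ):
            per_frame[ti] += len(ev)
        counts[cls] = per_frame
    return HBondCountSeries(times=traj.times.copy(), counts=counts)
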