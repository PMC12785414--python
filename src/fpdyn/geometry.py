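"""Superposition, RMSD/RMSF statistics, pair distances and distance histograms.

All statistics are geometric (no mass weighting): per-residue Calpha and
chromophore heavy-atom analyses as used for barrel fluorescent proteins.
Trajectory statistics are reported in nm; crystal-to-crystal comparisons can
be read out in angstrom via :attr:`SuperpositionResult.rmsd_angstrom`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import AtomSelection, Frame, SelectionError, Trajectory

__all__ = [
    "SuperpositionResult",
    "SeriesStat",
    "FluctuationProfile",
    "Histogram",
    "kabsch",
    "superpose_frames",
    "rmsd_series",
    "rmsf",
    "delta_rmsf",
    "pair_distance_series",
    "histogram",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), nm
    rmsd: float  # nm, over the fitted selection

    @property
    def rmsd_angstrom(self) -> float:
        return self.rmsd * 10.0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SeriesStat:
    """A per-frame scalar series (times in ns, values in nm)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if not np.isfinite(v).all():
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-atom or per-residue RMSF values keyed by identifier strings."""

    keys: tuple[str, ...]
    values: np.ndarray  # nm; deltas of two profiles may be negative

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(self.keys) != len(v):
            raise ValueError("one value per key required")
        object.__setattr__(self, "keys", tuple(self.keys))
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.keys, map(float, self.values)))


def _check_pointset(x: np.ndarray, name: str) -> None:
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    if x.shape[0] < 3:
        raise ValueError(f"{name} must contain at least 3 points")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError(f"{name} is degenerate (collinear or coincident points)")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired point sets (nm).

    Returns the proper rotation and translation mapping ``mobile`` onto
    ``reference`` together with the post-fit RMSD over the pairing.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    _check_pointset(mobile, "mobile")
    _check_pointset(reference, "reference")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - ref_mean, mobile - mob_mean)
    rmat = rot.as_matrix()
    translation = ref_mean - rmat @ mob_mean
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


def match_by_identity(
    topo_a, topo_b, selection: AtomSelection
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms of two topologies by (chain, res_id, atom name).

    Used for crystal-to-crystal comparisons of closely related structures;
    only atoms present in both (within the selection) are paired, in the
    first topology's order.  No sequence alignment is attempted.
    """
    def keyed(topo):
        out = {}
        for i in selection.resolve(topo):
            a = topo[i]
            out[(a.chain, a.res_id, a.name)] = i
        return out

    ka, kb = keyed(topo_a), keyed(topo_b)
    common = [k for k in ka if k in kb]
    if not common:
        raise SelectionError("no atoms in common under the selection")
    return (np.array([ka[k] for k in common], dtype=int),
            np.array([kb[k] for k in common], dtype=int))


def superpose_frames(
    traj: Trajectory,
    reference: Frame,
    fit_sel: AtomSelection,
) -> np.ndarray:
    """All frames rigidly fitted to ``reference`` on ``fit_sel``.

    Returns a new ``(n_frames, n_atoms, 3)`` array; the fit is computed on
    the selection but applied to every atom of each frame.
    """
    fit_idx = fit_sel.resolve_nonempty(traj.topology)
    ref_fit = reference.coords[fit_idx]
    out = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        sup = kabsch(traj.coords[i, fit_idx], ref_fit)
        out[i] = sup.apply(traj.coords[i])
    return out


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection,
    label: str = "rmsd",
) -> SeriesStat:
    """Per-frame RMSD over ``measure_sel`` after superposing on ``fit_sel``.

    The canonical use fits on protein Calpha atoms and measures over the
    chromophore heavy atoms (including the acylimine carbonyl).
    """
    measure_idx = measure_sel.resolve_nonempty(traj.topology)
    fitted = superpose_frames(traj, reference, fit_sel)
    ref_measure = reference.coords[measure_idx]
    values = np.array([_rmsd(fitted[i, measure_idx], ref_measure)
                       for i in range(traj.n_frames)])
    return SeriesStat(times=traj.times.copy(), values=values, label=label)


def _atom_key(traj: Trajectory, i: int) -> str:
    a = traj.topology[i]
    return f"{a.chain}:{a.res_id}:{a.name}"


def _residue_key(traj: Trajectory, i: int) -> str:
    a = traj.topology[i]
    return f"{a.chain}:{a.res_id}"


def rmsf(
    traj: Trajectory,
    measure_sel: AtomSelection,
    fit_sel: AtomSelection,
    per_residue: bool = False,
) -> FluctuationProfile:
    """Root-mean-square fluctuation about the time-averaged structure.

    Two-pass alignment: frames are fitted to frame 0 on ``fit_sel``, the mean
    structure is formed, and frames are re-fitted to that mean before the
    fluctuation is computed — the standard stable reference choice.  With
    ``per_residue`` the profile is keyed by residue (intended for Calpha
    selections); otherwise one value per selected atom.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    measure_idx = measure_sel.resolve_nonempty(traj.topology)
    pass1 = superpose_frames(traj, traj.frame(0), fit_sel)
    mean_frame = Frame(time_ns=0.0, coords=pass1.mean(axis=0))
    aligned = superpose_frames(
        Trajectory(traj.topology, pass1, traj.times), mean_frame, fit_sel
    )
    mean_pos = aligned.mean(axis=0)
    sq = np.sum((aligned[:, measure_idx] - mean_pos[measure_idx]) ** 2, axis=-1)
    values = np.sqrt(sq.mean(axis=0))
    key_fn = _residue_key if per_residue else _atom_key
    keys = tuple(key_fn(traj, i) for i in measure_idx)
    if len(set(keys)) != len(keys):
        raise SelectionError(
            "per-atom keys are not unique; use per_residue only with one atom "
            "per residue (e.g. a Calpha selection)"
        )
    return FluctuationProfile(keys=keys, values=values)


def delta_rmsf(a: FluctuationProfile, b: FluctuationProfile) -> FluctuationProfile:
    """Elementwise ``a - b``; positive values mean ``a`` is more mobile."""
    if set(a.keys) != set(b.keys):
        missing = sorted(set(a.keys) ^ set(b.keys))
        raise ValueError(f"profile key mismatch: {missing}")
    b_map = b.as_dict()
    values = np.array([av - b_map[k] for k, av in zip(a.keys, a.values)])
    return FluctuationProfile(keys=a.keys, values=values)


def pair_distance_series(
    traj: Trajectory,
    a: AtomSelection,
    b: AtomSelection,
    label: str = "",
) -> SeriesStat:
    """Per-frame Euclidean distance (nm) between two single-atom selections."""
    ia = a.resolve_single(traj.topology)
    ib = b.resolve_single(traj.topology)
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=-1)
    return SeriesStat(times=traj.times.copy(), values=d, label=label)


@dataclass(frozen=True)
class Histogram:
    """Left-closed right-open bins anchored at 0; mode ties break low."""

    bin_width: float
    centers: np.ndarray
    counts: np.ndarray
    mode_center: float


def histogram(series: SeriesStat, bin_width: float) -> Histogram:
    """Bin a series with bins ``[k*w, (k+1)*w)`` anchored at zero.

    The mode is the center of the most populated bin; ties break toward the
    lower bin for determinism.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(series) == 0:
        raise ValueError("cannot histogram an empty series")
    idx = np.floor(series.values / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
    mode_center = float(centers[int(np.argmax(counts))])  # argmax -> first/lowest
    return Histogram(bin_width=float(bin_width), centers=centers,
                     counts=counts, mode_center=mode_center)
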