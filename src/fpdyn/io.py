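"""Readers and writers: PDB structures/trajectories, region configs, TSV tables.

PDB handling is delegated to gemmi; this module layers the package's
validation contracts (duplicate serials, consistent atom ordering across
models) and the angstrom-to-nm unit conversion on top.  Multi-model PDB is
the canonical portable trajectory dialect: one MODEL block per frame, frame
times assigned from a caller-supplied interval.
"""

from __future__ import annotations

import configparser
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .model import Atom, RegionSegment, RegionSet, TopologyError, Trajectory

__all__ = [
    "ParseError",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "load_regions",
    "write_regions",
    "default_regions",
    "write_series_tsv",
    "write_profile_tsv",
    "write_histogram_tsv",
]

_A_PER_NM = 10.0


class ParseError(ValueError):
    """Raised when an input file cannot be parsed under the declared dialect."""


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports offending line
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinate models found")
    return st


def _model_atoms(model: gemmi.Model) -> tuple[list[Atom], np.ndarray]:
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            for a in res:
                atoms.append(
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name,
                        res_name=res.name,
                        res_id=res.seqid.num,
                        chain=chain.name,
                    )
                )
                xyz.append((a.pos.x, a.pos.y, a.pos.z))
    return atoms, np.asarray(xyz, dtype=float) / _A_PER_NM


def read_structure(path: str | Path, dialect: str = "pdb") -> Trajectory:
    """Read a single-model PDB file as a one-frame trajectory at time 0.

    Coordinates are converted angstrom -> nm; atom metadata (names, author
    residue numbers, chains) is preserved without renumbering.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported structure dialect {dialect!r}")
    st = _read_gemmi(path)
    if len(st) != 1:
        raise ParseError(
            f"{path}: expected a single-model structure, found {len(st)} models"
        )
    atoms, xyz = _model_atoms(st[0])
    if not atoms:
        raise ParseError(f"{path}: structure contains no atoms")
    return Trajectory(atoms, xyz[None, :, :], np.array([0.0]))


def read_trajectory(
    path: str | Path,
    frame_interval_ns: float = 0.01,
    start_time_ns: float = 0.0,
) -> Trajectory:
    """Read a multi-model PDB trajectory (one frame per MODEL block).

    All models must contain the same atoms in the same order; a mismatch is
    an error naming the offending model index.  Frame times are assigned as
    ``start + i * frame_interval_ns``.
    """
    if frame_interval_ns <= 0:
        raise ValueError("frame interval must be positive")
    st = _read_gemmi(path)
    atoms0, xyz0 = _model_atoms(st[0])
    if not atoms0:
        raise ParseError(f"{path}: model 1 contains no atoms")
    coords = [xyz0]
    for i in range(1, len(st)):
        atoms_i, xyz_i = _model_atoms(st[i])
        if atoms_i != atoms0:
            raise ParseError(
                f"{path}: model {i + 1} atom list does not match model 1 "
                f"({len(atoms_i)} vs {len(atoms0)} atoms or differing order)"
            )
        coords.append(xyz_i)
    times = start_time_ns + frame_interval_ns * np.arange(len(coords))
    return Trajectory(atoms0, np.stack(coords), times)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as fixed-column multi-model PDB (nm -> angstrom)."""
    st = gemmi.Structure()
    st.name = "fpdyn"
    for fi in range(traj.n_frames):
        model = gemmi.Model(fi + 1)
        chain: gemmi.Chain | None = None
        res: gemmi.Residue | None = None
        prev_key: tuple[str, int, str] | None = None
        for ai, atom in enumerate(traj.topology):
            if chain is None or chain.name != atom.chain:
                chain = gemmi.Chain(atom.chain)
                model.add_chain(chain)
                chain = model[-1]
                prev_key = None
            key = (atom.chain, atom.res_id, atom.res_name)
            if key != prev_key:
                res = gemmi.Residue()
                res.name = atom.res_name
                res.seqid = gemmi.SeqId(atom.res_id, " ")
                chain.add_residue(res)
                res = chain[-1]
                prev_key = key
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.serial = atom.serial
            x, y, z = traj.coords[fi, ai] * _A_PER_NM
            ga.pos = gemmi.Position(x, y, z)
            assert res is not None
            res.add_atom(ga)
        st.add_model(model)
    Path(path).write_text(st.make_pdb_string())


# -- region configuration -------------------------------------------------


def _parse_segment(text: str, label: str, key: str) -> RegionSegment:
    parts = text.split()
    if len(parts) != 3:
        raise ParseError(
            f"region {label!r} {key}: expected 'CHAIN START END', got {text!r}"
        )
    chain, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"region {label!r} {key}: non-integer bounds in {text!r}") from exc
    try:
        return RegionSegment(chain=chain, start=start, end=end)
    except TopologyError as exc:
        raise ParseError(f"region {label!r} {key}: {exc}") from exc


def load_regions(path: str | Path) -> RegionSet:
    """Load named interstrand gates from a key/value region config.

    Format: one section per region label, with ``segment1``/``segment2``
    entries of the form ``CHAIN START END`` (inclusive author numbering)::

        [Reg 1]
        segment1 = A 139 145
        segment2 = A 193 201
    """
    parser = configparser.ConfigParser()
    parser.optionxform = str  # type: ignore[assignment]
    try:
        with open(path) as fh:
            parser.read_file(fh)
    except configparser.DuplicateSectionError as exc:
        raise ParseError(f"{path}: duplicate region label: {exc}") from exc
    except configparser.Error as exc:
        raise ParseError(f"{path}: {exc}") from exc
    regions: dict[str, tuple[RegionSegment, RegionSegment]] = {}
    for label in parser.sections():
        section = parser[label]
        for key in ("segment1", "segment2"):
            if key not in section:
                raise ParseError(f"region {label!r} is missing {key}")
        regions[label] = (
            _parse_segment(section["segment1"], label, "segment1"),
            _parse_segment(section["segment2"], label, "segment2"),
        )
    if not regions:
        raise ParseError(f"{path}: no regions defined")
    return RegionSet(regions)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    lines = []
    for label, (s1, s2) in regions.regions.items():
        lines.append(f"[{label}]")
        lines.append(f"segment1 = {s1.chain} {s1.start} {s1.end}")
        lines.append(f"segment2 = {s2.chain} {s2.start} {s2.end}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def default_regions() -> RegionSet:
    """The shipped default gate taxonomy (Reg 1-4 over the barrel strands)."""
    from importlib import resources

    with resources.as_file(
        resources.files("fpdyn").joinpath("data/default_regions.cfg")
    ) as p:
        return load_regions(p)


# -- TSV output -----------------------------------------------------------


def write_series_tsv(path: str | Path, times: np.ndarray, values: np.ndarray,
                     value_name: str = "value_nm") -> None:
    with open(path, "w") as fh:
        fh.write(f"time_ns\t{value_name}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6g}\t{v:.6g}\n")


def write_profile_tsv(path: str | Path, keys: Sequence[str], values: np.ndarray,
                      value_name: str = "rmsf_nm") -> None:
    with open(path, "w") as fh:
        fh.write(f"key\t{value_name}\n")
        for k, v in zip(keys, values):
            fh.write(f"{k}\t{v:.6g}\n")


def write_histogram_tsv(path: str | Path, centers: np.ndarray, counts: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("bin_center_nm\tcount\n")
        for c, n in zip(centers, counts):
            fh.write(f"{c:.6g}\t{int(n)}\n")
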