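"""Multi-model PDB trajectory reading and annotated writing.

The reader handles the fixed-width PDB dialect used for MD trajectories: one
MODEL/ENDMDL block per frame (a file without MODEL records is a single-frame
trajectory), coordinates in columns 31-54, selection of C-alpha atoms by
default.  The writer emits one MODEL per frame with mobility annotations:
occupancy 1.00 for atoms in the frame's low-mobility set (0.00 otherwise) and
the per-atom deviation in Angstrom in the b-factor column.

Only the selected atoms (by default the C-alpha trace) are carried through
alignment and written back; the annotation convention matches what structure
viewers expect for coloring by mobility class.
"""

from __future__ import annotations

import logging
from typing import Callable, NamedTuple

import numpy as np

from lovofit.geometry import CorrespondenceError, FrameCoordinates
from lovofit.trajectory import MobilityReport, Trajectory, per_atom_deviation_series

__all__ = [
    "AtomId",
    "PdbFormatError",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "write_annotated_trajectory",
]

logger = logging.getLogger(__name__)

_BFACTOR_MAX = 999.99  # widest value %6.2f can hold


class PdbFormatError(ValueError):
    """A PDB line or model block violates the fixed-width format contract."""


class AtomId(NamedTuple):
    """Identity of one atom: enough to match atoms across models and write them back."""

    chain: str
    resnum: int
    icode: str
    name: str
    resname: str


class _AtomRecord(NamedTuple):
    atom_id: AtomId
    xyz: tuple
    is_hetatm: bool
    altloc: str
    element: str


def _parse_atom_line(line: str, lineno: int) -> _AtomRecord:
    # Fixed-width PDB columns (1-based): name 13-16, altloc 17, resname 18-20,
    # chain 22, resnum 23-26, icode 27, x/y/z 31-54, element 77-78.
    if len(line) < 54:
        raise PdbFormatError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbFormatError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    return _AtomRecord(
        atom_id=AtomId(chain, resnum, icode, name, resname),
        xyz=(x, y, z),
        is_hetatm=line.startswith("HETATM"),
        altloc=altloc,
        element=element,
    )


def _calpha_selector(rec: _AtomRecord) -> bool:
    # Atom name CA on a standard residue; exclude calcium ions, which also
    # carry the name CA (element CA, or a residue literally called CA).
    return (
        rec.atom_id.name == "CA"
        and not rec.is_hetatm
        and rec.element != "CA"
        and rec.atom_id.resname != "CA"
    )


def make_selector(
    names: set | None = None, chains: set | None = None
) -> Callable[[_AtomRecord], bool]:
    """Selector matching atom names and/or chain identifiers (ATOM records only)."""

    def _select(rec: _AtomRecord) -> bool:
        if rec.is_hetatm:
            return False
        if names is not None and rec.atom_id.name not in names:
            return False
        if chains is not None and rec.atom_id.chain not in chains:
            return False
        return True

    return _select


def read_pdb_trajectory(path, selection="calpha") -> Trajectory:
    """Read a multi-MODEL PDB file into a :class:`Trajectory`.

    ``selection`` is ``"calpha"`` (default: atoms named CA, excluding calcium
    ions and HETATM records) or a predicate taking the parsed record.  Only
    alternate locations ' ' and 'A' are kept.  The atom roster is fixed by the
    first model; every later model must contain exactly the same atoms in the
    same order.
    """
    if selection == "calpha":
        selector = _calpha_selector
    elif callable(selection):
        selector = selection
    else:
        raise ValueError(f"unknown selection: {selection!r}")

    models: list[list[_AtomRecord]] = []
    current: list[_AtomRecord] | None = None
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model_record = True
                if current:
                    models.append(current)
                current = []
            elif record == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif record in ("ATOM  ", "HETATM"):
                rec = _parse_atom_line(line, lineno)
                if rec.altloc not in (" ", "A"):
                    continue
                if selector(rec):
                    if current is None:
                        if saw_model_record:
                            raise PdbFormatError(
                                f"line {lineno}: ATOM record outside MODEL/ENDMDL block"
                            )
                        current = []
                    current.append(rec)
    if current:
        models.append(current)
    if not models:
        raise PdbFormatError(f"{path}: no atoms matched the selection")

    roster = tuple(rec.atom_id for rec in models[0])
    if len(set(roster)) != len(roster):
        raise PdbFormatError(f"{path}: duplicate atom identity in first model")
    frames = []
    for m, recs in enumerate(models, start=1):
        ids = tuple(rec.atom_id for rec in recs)
        if ids != roster:
            detail = _roster_mismatch_detail(roster, ids)
            raise CorrespondenceError(f"model {m} does not match the first model: {detail}")
        coords = np.array([rec.xyz for rec in recs])
        frames.append(FrameCoordinates(coords, roster))
    return Trajectory(frames, frame_labels=tuple(range(len(frames))))


def _roster_mismatch_detail(roster: tuple, ids: tuple) -> str:
    if len(ids) != len(roster):
        return f"expected {len(roster)} atoms, found {len(ids)}"
    for k, (a, b) in enumerate(zip(roster, ids)):
        if a != b:
            return f"atom {k} is {b} but the first model has {a}"
    return "unknown mismatch"


def _format_atom_line(
    serial: int, atom_id: AtomId, xyz: np.ndarray, occupancy: float, bfactor: float
) -> str:
    name = atom_id.name
    # standard alignment: 1-2 character names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    icode = atom_id.icode or " "
    return (
        f"ATOM  {serial:5d} {name_field:<4s} {atom_id.resname:<3s} "
        f"{atom_id.chain:1s}{atom_id.resnum:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {name[:1]:>2s}\n"
    )


def write_pdb_trajectory(
    traj_coords: np.ndarray,
    atom_ids,
    path,
    occupancy: np.ndarray | None = None,
    bfactor: np.ndarray | None = None,
) -> None:
    """Write coordinates ``(n_frames, n_atoms, 3)`` as a multi-MODEL PDB file.

    ``occupancy`` and ``bfactor`` are optional per-frame per-atom arrays of
    the same leading shape; they default to 1.00 and 0.00.  B-factors wider
    than the %6.2f field are clamped to 999.99 with a logged warning.
    """
    traj_coords = np.asarray(traj_coords)
    n_frames, n_atoms = traj_coords.shape[:2]
    occ = np.ones((n_frames, n_atoms)) if occupancy is None else np.asarray(occupancy)
    bf = np.zeros((n_frames, n_atoms)) if bfactor is None else np.asarray(bfactor)
    if np.any(bf > _BFACTOR_MAX):
        logger.warning(
            "clamping %d b-factor values above %.2f to the PDB field width",
            int(np.sum(bf > _BFACTOR_MAX)),
            _BFACTOR_MAX,
        )
        bf = np.minimum(bf, _BFACTOR_MAX)
    ids = list(atom_ids)
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, atom_id in enumerate(ids):
                serial = (a + 1) % 100000
                fh.write(
                    _format_atom_line(serial, atom_id, traj_coords[f, a], occ[f, a], bf[f, a])
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_annotated_trajectory(traj: Trajectory, report: MobilityReport, path) -> None:
    """Write the aligned trajectory with mobility annotations.

    One MODEL per frame, coordinates after alignment; occupancy is 1.00 for
    atoms in that frame's low-mobility set and 0.00 otherwise; the b-factor
    column carries the per-atom deviation (A) of that frame.  A round-trip
    read reproduces coordinates to the PDB format precision (5e-4 A).
    """
    if report.n_frames != traj.n_frames or report.atom_ids != traj.atom_ids:
        raise CorrespondenceError("report does not correspond to the trajectory")
    ids = traj.atom_ids
    if not all(isinstance(a, AtomId) for a in ids):
        # synthetic / programmatic rosters: wrap as alanine CA trace
        ids = tuple(
            AtomId(chain="A", resnum=i + 1, icode="", name="CA", resname="ALA")
            for i in range(traj.n_atoms)
        )
    occupancy = report.low_membership.astype(float)
    bfactor = per_atom_deviation_series(report)
    write_pdb_trajectory(report.aligned, ids, path, occupancy=occupancy, bfactor=bfactor)
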