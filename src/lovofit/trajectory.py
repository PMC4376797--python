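"""Frame-by-frame LOVO alignment of a trajectory and derived mobility measures.

Each frame is aligned independently to the reference (multistart LOVO), so the
low-mobility subset may differ from frame to frame.  The report aggregates the
per-frame RMSD split (low / high / total), per-atom RMSF, and the fraction of
frames in which each atom belonged to the low-mobility set ("low fraction",
whose thresholding at 0.5 defines the consensus core).

Frames are processed sequentially but are statistically independent: each
frame ``i`` draws its random starting subsets from a generator seeded with
``rng_seed XOR i`` (masked to 31 bits), so results do not depend on
processing order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lovofit.geometry import CorrespondenceError, FrameCoordinates
from lovofit.lovo import (
    FrameAlignment,
    LovoOptions,
    lovo_align_frame_multistart,
    n_low_from_phi,
)

__all__ = [
    "Trajectory",
    "MobilityReport",
    "align_trajectory",
    "phi_scan",
    "compute_rmsf",
    "per_atom_deviation_series",
    "default_phi_grid",
    "write_frame_table",
    "write_phi_scan_table",
    "write_atom_table",
]

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames sharing one atom roster."""

    frames: tuple
    frame_labels: tuple

    def __init__(
        self,
        frames: Sequence[FrameCoordinates],
        frame_labels: Sequence | None = None,
    ) -> None:
        frames = tuple(frames)
        if len(frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        roster = frames[0].atom_ids
        for k, f in enumerate(frames[1:], start=1):
            if f.atom_ids != roster:
                raise CorrespondenceError(
                    f"frame {k} does not share the atom roster of frame 0"
                )
        if frame_labels is None:
            frame_labels = tuple(range(len(frames)))
        else:
            frame_labels = tuple(frame_labels)
            if len(frame_labels) != len(frames):
                raise ValueError("frame_labels length must match number of frames")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_labels", frame_labels)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def atom_ids(self) -> tuple:
        return self.frames[0].atom_ids

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class MobilityReport:
    """Aggregated result of aligning a whole trajectory at one ``phi``.

    Attributes
    ----------
    frame_table
        One row per frame: ``frame, rmsd_L, rmsd_H, rmsd_T, iters, converged``.
    rmsf
        Per-atom RMSF (A) about the reference coordinates, computed on the
        aligned trajectory.
    low_fraction
        Per-atom fraction of frames in which the atom was in the low set.
    aligned
        Transformed coordinates, shape ``(n_frames, n_atoms, 3)``.
    msd_series
        Per-frame per-atom squared deviations after alignment,
        shape ``(n_frames, n_atoms)``.
    low_membership
        Boolean matrix ``(n_frames, n_atoms)``: frame-wise low-set membership.
    """

    phi: float
    n_low: int
    atom_ids: tuple
    reference_coords: np.ndarray
    frame_table: pd.DataFrame
    alignments: list = field(repr=False)
    aligned: np.ndarray = field(repr=False)
    msd_series: np.ndarray = field(repr=False)
    low_membership: np.ndarray = field(repr=False)
    rmsf: np.ndarray = field(repr=False)
    low_fraction: np.ndarray = field(repr=False)
    warnings: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.aligned.shape[1]

    def consensus_core(self, threshold: float = 0.5) -> np.ndarray:
        """Atoms in the low set in at least ``threshold`` of the frames."""
        return np.flatnonzero(self.low_fraction >= threshold)


def _frame_options(options: LovoOptions, frame_index: int) -> LovoOptions:
    seed = (int(options.rng_seed) ^ int(frame_index)) & 0x7FFFFFFF
    return LovoOptions(
        phi=options.phi,
        n_starts=options.n_starts,
        max_iterations=options.max_iterations,
        convergence_tol=options.convergence_tol,
        rng_seed=seed,
    )


def align_trajectory(
    traj: Trajectory,
    reference: FrameCoordinates | None,
    phi: float,
    options: LovoOptions = LovoOptions(),
) -> MobilityReport:
    """LOVO-align every frame to the reference and aggregate mobility measures.

    ``reference=None`` uses the first frame.  Each frame is aligned
    independently with :func:`lovo_align_frame_multistart`; the low-mobility
    subset is re-identified per frame.
    """
    if reference is None:
        reference = traj.frames[0]
    if reference.atom_ids != traj.atom_ids:
        raise CorrespondenceError("reference does not share the trajectory roster")
    n = traj.n_atoms
    n_low = n_low_from_phi(phi, n)

    alignments: list[FrameAlignment] = []
    aligned = np.empty((traj.n_frames, n, 3))
    msd_series = np.empty((traj.n_frames, n))
    low_membership = np.zeros((traj.n_frames, n), dtype=bool)
    rows = []
    warn_list: list[str] = []
    for i, frame in enumerate(traj.frames):
        fa = lovo_align_frame_multistart(
            frame, reference, phi, _frame_options(options, i)
        )
        alignments.append(fa)
        aligned[i] = fa.transform.apply(frame.coords)
        msd_series[i] = fa.msd_all
        low_membership[i, fa.low_set] = True
        if not fa.converged:
            warn_list.append(
                f"frame {traj.frame_labels[i]} did not converge within "
                f"{options.max_iterations} iterations"
            )
        rows.append(
            {
                "frame": traj.frame_labels[i],
                "rmsd_L": fa.rmsd_L,
                "rmsd_H": fa.rmsd_H,
                "rmsd_T": fa.rmsd_T,
                "iters": fa.n_iterations,
                "converged": fa.converged,
            }
        )
    frame_table = pd.DataFrame(rows)
    low_fraction = low_membership.mean(axis=0)
    rmsf = np.sqrt(msd_series.mean(axis=0))
    return MobilityReport(
        phi=phi,
        n_low=n_low,
        atom_ids=traj.atom_ids,
        reference_coords=np.array(reference.coords),
        frame_table=frame_table,
        alignments=alignments,
        aligned=aligned,
        msd_series=msd_series,
        low_membership=low_membership,
        rmsf=rmsf,
        low_fraction=low_fraction,
        warnings=warn_list,
    )


def compute_rmsf(report: MobilityReport, reference_mode: str = "reference") -> np.ndarray:
    """Per-atom RMSF (A) of the aligned trajectory.

    ``reference_mode="reference"`` measures fluctuations about the reference
    coordinates, ``RMSF_i = sqrt(mean_t ||x_i(t) - x_i^ref||^2)``;
    ``"average"`` measures them about the trajectory-average position of each
    atom, the textbook definition for equilibrated simulations.
    """
    if reference_mode == "reference":
        return np.sqrt(report.msd_series.mean(axis=0))
    if reference_mode == "average":
        if report.n_frames == 1:
            msg = "RMSF about the average of a single-frame trajectory is identically zero"
            warnings.warn(msg)
            report.warnings.append(msg)
        mean_pos = report.aligned.mean(axis=0)
        diff = report.aligned - mean_pos
        return np.sqrt(np.einsum("tij,tij->ti", diff, diff).mean(axis=0))
    raise ValueError(f"unknown reference_mode: {reference_mode!r}")


def per_atom_deviation_series(report: MobilityReport) -> np.ndarray:
    """Per-frame per-atom deviation ``sqrt(MSD_i(t))`` in A, shape ``(n_frames, n_atoms)``.

    This is the quantity written into the b-factor column of annotated PDB
    output, one value per atom per model.
    """
    return np.sqrt(report.msd_series)


def default_phi_grid(start: float = 0.01, stop: float = 0.99, step: float = 0.01) -> np.ndarray:
    """Regular phi grid, inclusive of ``stop`` up to float round-off."""
    n_steps = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n_steps + 1), 10)


def phi_scan(
    traj: Trajectory,
    reference: FrameCoordinates | None,
    phi_grid: Iterable[float] | None = None,
    options: LovoOptions = LovoOptions(),
    mode: str = "all",
) -> pd.DataFrame:
    """Align the trajectory over a grid of phi values and summarize per phi.

    Returns a table with columns ``phi, n_L, mean_rmsd_L, max_rmsd_L,
    mean_rmsd_H, mean_rmsd_T``, rows ordered by increasing phi.  Grid values
    whose rounded atom count falls below 3 are skipped (they cannot define a
    rigid fit).

    ``mode="all"`` (default) summarizes over every frame; ``mode="first_last"``
    aligns only the last frame to the first (the two-conformation variant of
    the scan), in which case mean and max coincide.
    """
    if phi_grid is None:
        phi_grid = default_phi_grid()
    grid = [float(p) for p in phi_grid]
    if any(not (0.0 < p <= 1.0) for p in grid):
        raise ValueError("phi grid values must be in (0, 1]")
    if sorted(grid) != grid:
        raise ValueError("phi grid must be sorted ascending")

    if mode == "first_last":
        if reference is None:
            reference = traj.frames[0]
        traj = Trajectory([traj.frames[-1]], [traj.frame_labels[-1]])
    elif mode != "all":
        raise ValueError(f"unknown mode: {mode!r}")

    rows = []
    for p in grid:
        try:
            n_low = n_low_from_phi(p, traj.n_atoms)
        except ValueError:
            continue  # phi too small for a rigid fit on this roster
        report = align_trajectory(traj, reference, p, options)
        ft = report.frame_table
        rows.append(
            {
                "phi": p,
                "n_L": n_low,
                "mean_rmsd_L": float(ft["rmsd_L"].mean()),
                "max_rmsd_L": float(ft["rmsd_L"].max()),
                "mean_rmsd_H": float(ft["rmsd_H"].mean()),
                "mean_rmsd_T": float(ft["rmsd_T"].mean()),
            }
        )
    return pd.DataFrame(rows)


def write_frame_table(report: MobilityReport, path) -> None:
    """TSV: ``frame  rmsd_L  rmsd_H  rmsd_T  iters  converged``."""
    report.frame_table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_phi_scan_table(scan: pd.DataFrame, path) -> None:
    """TSV: ``phi  n_L  mean_rmsd_L  max_rmsd_L  mean_rmsd_H  mean_rmsd_T``."""
    scan.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_atom_table(
    report: MobilityReport, path, rmsf: np.ndarray | None = None
) -> None:
    """TSV: ``atom_id  rmsf  low_fraction`` (one row per atom)."""
    table = pd.DataFrame(
        {
            "atom_id": [_format_atom_id(a) for a in report.atom_ids],
            "rmsf": rmsf if rmsf is not None else report.rmsf,
            "low_fraction": report.low_fraction,
        }
    )
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _format_atom_id(atom_id) -> str:
    if hasattr(atom_id, "chain"):  # AtomId from pdbio
        icode = atom_id.icode.strip() if atom_id.icode else ""
        return f"{atom_id.chain}:{atom_id.resname}{atom_id.resnum}{icode}:{atom_id.name}"
    return str(atom_id)
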