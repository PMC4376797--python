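"""Rigid-body superposition primitives.

This module provides the exact (global) solution of the rigid-body
superposition problem via Kearsley's quaternion method, together with the
per-atom squared-displacement (MSD) and RMSD measures built on it.

Conventions
-----------
* All coordinates are in Angstrom; squared deviations in Angstrom^2.
* A :class:`RigidTransform` acts on a coordinate as ``x -> R @ x + t`` with
  ``R`` a proper rotation (det = +1).
* Squared deviations are the primary internal quantity; square roots are
  taken only when an RMSD is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CorrespondenceError",
    "DegenerateFitError",
    "FrameCoordinates",
    "RigidTransform",
    "SuperpositionResult",
    "compute_msd_per_atom",
    "compute_rmsd",
    "kearsley_superpose",
    "apply_transform",
]

_ORTHOGONALITY_TOL = 1e-8
_COLLINEARITY_TOL = 1e-12  # A^2, on principal variances of the fit subset


class CorrespondenceError(ValueError):
    """Two frames do not share the same atom roster (count or identity)."""


class DegenerateFitError(ValueError):
    """The fit subset cannot define a unique rigid-body superposition."""


@dataclass(frozen=True)
class FrameCoordinates:
    """Ordered C-alpha coordinates of one trajectory frame.

    Parameters
    ----------
    coords
        ``(N, 3)`` array of positions in Angstrom.
    atom_ids
        Tuple of ``N`` unique, hashable atom identifiers.  Index ``i`` in one
        frame corresponds to index ``i`` in any other frame of the same
        trajectory.
    """

    coords: np.ndarray
    atom_ids: tuple

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"coords must be (N, 3) with N >= 1, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        atom_ids = tuple(self.atom_ids)
        if len(atom_ids) != coords.shape[0]:
            raise ValueError("atom_ids length does not match number of coordinates")
        if len(set(atom_ids)) != len(atom_ids):
            raise ValueError("atom_ids must be unique")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_ids", atom_ids)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "FrameCoordinates":
        """Same roster, new coordinates."""
        return FrameCoordinates(coords, self.atom_ids)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.ascontiguousarray(self.rotation, dtype=float)
        tra = np.ascontiguousarray(self.translation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if tra.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=_ORTHOGONALITY_TOL):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(rot) - 1.0) > _ORTHOGONALITY_TOL:
            raise ValueError("rotation must be proper (det = +1)")
        rot.setflags(write=False)
        tra.setflags(write=False)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an ``(N, 3)`` coordinate array."""
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    """Outcome of a rigid-body fit on a subset, evaluated on all atoms.

    ``rmsd_fit`` is the RMSD over the fitted subset; ``msd_all`` holds the
    squared deviation of every atom of the frame after the transform has been
    applied to the whole structure.
    """

    transform: RigidTransform
    rmsd_fit: float
    msd_all: np.ndarray
    subset: np.ndarray = field(repr=False)


def _check_roster(frame: FrameCoordinates, reference: FrameCoordinates) -> None:
    if frame.n_atoms != reference.n_atoms:
        raise CorrespondenceError(
            f"frame has {frame.n_atoms} atoms but reference has {reference.n_atoms}"
        )
    if frame.atom_ids != reference.atom_ids:
        raise CorrespondenceError("frames do not share the same atom roster/order")


def _normalize_subset(subset, n_atoms: int) -> np.ndarray:
    idx = np.unique(np.asarray(list(subset), dtype=np.intp))
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise IndexError("subset index out of range")
    return idx


def compute_msd_per_atom(
    frame: FrameCoordinates, reference: FrameCoordinates
) -> np.ndarray:
    """Per-atom squared displacement ``MSD_i = ||x_i - x_i^ref||^2`` (A^2)."""
    _check_roster(frame, reference)
    diff = frame.coords - reference.coords
    return np.einsum("ij,ij->i", diff, diff)


def compute_rmsd(
    frame: FrameCoordinates,
    reference: FrameCoordinates,
    subset: Iterable[int] | None = None,
) -> float:
    """RMSD over ``subset`` (default: all atoms) in the current orientation.

    ``RMSD = sqrt(mean_i MSD_i)`` over the chosen atoms; no superposition is
    performed here.
    """
    msd = compute_msd_per_atom(frame, reference)
    if subset is None:
        return float(np.sqrt(msd.mean()))
    idx = _normalize_subset(subset, frame.n_atoms)
    return float(np.sqrt(msd[idx].mean()))


def _kearsley_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation minimizing the RMSD of ``mobile`` onto ``reference``.

    Kearsley's method: the optimal rotation is encoded by the eigenvector of
    the smallest eigenvalue of a 4x4 symmetric matrix built from sums and
    differences of the centered coordinate pairs.  The quaternion sign
    ambiguity (q and -q) is irrelevant.  Always returns a proper rotation,
    also for mirror-symmetric inputs.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    d = (mobile - cm) - (reference - cr)  # differences
    s = (mobile - cm) + (reference - cr)  # sums
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    sx, sy, sz = s[:, 0], s[:, 1], s[:, 2]

    K = np.empty((4, 4))
    K[0, 0] = np.dot(dx, dx) + np.dot(dy, dy) + np.dot(dz, dz)
    K[0, 1] = np.dot(sy, dz) - np.dot(dy, sz)
    K[0, 2] = np.dot(dx, sz) - np.dot(sx, dz)
    K[0, 3] = np.dot(sx, dy) - np.dot(dx, sy)
    K[1, 1] = np.dot(sy, sy) + np.dot(sz, sz) + np.dot(dx, dx)
    K[1, 2] = np.dot(dx, dy) - np.dot(sx, sy)
    K[1, 3] = np.dot(dx, dz) - np.dot(sx, sz)
    K[2, 2] = np.dot(sx, sx) + np.dot(sz, sz) + np.dot(dy, dy)
    K[2, 3] = np.dot(dy, dz) - np.dot(sy, sz)
    K[3, 3] = np.dot(sx, sx) + np.dot(sy, sy) + np.dot(dz, dz)
    K[1, 0] = K[0, 1]
    K[2, 0] = K[0, 2]
    K[3, 0] = K[0, 3]
    K[2, 1] = K[1, 2]
    K[3, 1] = K[1, 3]
    K[3, 2] = K[2, 3]

    _, vecs = np.linalg.eigh(K)
    q0, q1, q2, q3 = vecs[:, 0]  # eigenvector of the smallest eigenvalue

    # rotation acting on the centered mobile coordinates (x -> rot @ x)
    rot = np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2.0 * (q1 * q2 - q0 * q3),
                2.0 * (q1 * q3 + q0 * q2),
            ],
            [
                2.0 * (q1 * q2 + q0 * q3),
                q0 * q0 + q2 * q2 - q1 * q1 - q3 * q3,
                2.0 * (q2 * q3 - q0 * q1),
            ],
            [
                2.0 * (q1 * q3 - q0 * q2),
                2.0 * (q2 * q3 + q0 * q1),
                q0 * q0 + q3 * q3 - q1 * q1 - q2 * q2,
            ],
        ]
    )
    translation = cr - rot @ cm
    return rot, translation


def _check_subset_nondegenerate(ref_subset: np.ndarray) -> None:
    centered = ref_subset - ref_subset.mean(axis=0)
    # principal variances of the reference subset
    cov = centered.T @ centered / ref_subset.shape[0]
    variances = np.sort(np.linalg.eigvalsh(cov))
    if variances[0] < _COLLINEARITY_TOL and variances[1] < _COLLINEARITY_TOL:
        condition = "coincident" if variances[2] < _COLLINEARITY_TOL else "collinear"
        raise DegenerateFitError(
            f"fit subset is degenerate ({condition}): the two smallest principal "
            f"variances are below {_COLLINEARITY_TOL} A^2"
        )


def kearsley_superpose(
    mobile: FrameCoordinates,
    reference: FrameCoordinates,
    subset: Iterable[int] | None = None,
) -> SuperpositionResult:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    The transform minimizes the RMSD over ``subset`` (default: all atoms);
    this is the global minimum of the rigid-body problem.  The returned
    ``msd_all`` is evaluated for *every* atom after applying the transform to
    the whole frame, so callers can re-rank atoms by mobility.

    Raises
    ------
    DegenerateFitError
        If the subset has fewer than 3 atoms or its reference coordinates are
        collinear/coincident.
    """
    _check_roster(mobile, reference)
    if subset is None:
        idx = np.arange(mobile.n_atoms, dtype=np.intp)
    else:
        idx = _normalize_subset(subset, mobile.n_atoms)
    if idx.size < 3:
        raise DegenerateFitError(
            f"fit subset has {idx.size} atoms; at least 3 are required"
        )
    _check_subset_nondegenerate(reference.coords[idx])

    rot, tra = _kearsley_fit(mobile.coords[idx], reference.coords[idx])
    transform = RigidTransform(rot, tra)
    moved = transform.apply(mobile.coords)
    diff = moved - reference.coords
    msd_all = np.einsum("ij,ij->i", diff, diff)
    # recompute the fit RMSD explicitly rather than trusting the eigenvalue
    rmsd_fit = float(np.sqrt(msd_all[idx].mean()))
    return SuperpositionResult(transform=transform, rmsd_fit=rmsd_fit, msd_all=msd_all, subset=idx)


def apply_transform(t: RigidTransform, frame: FrameCoordinates) -> FrameCoordinates:
    """Apply ``x -> R x + t`` to every atom; the roster is preserved."""
    return frame.with_coords(t.apply(frame.coords))
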