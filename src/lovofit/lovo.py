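"""Iterative low-order-value optimization (LOVO) alignment of a single frame.

Given a fraction ``phi`` of atoms to fit, the algorithm alternates between
(a) rigid-body superposition on the current candidate subset and (b)
re-selection of the ``N_L = phi * N`` atoms with the smallest squared
displacements after moving the whole structure.  The objective -- the sum of
the ``N_L`` smallest per-atom squared deviations, ``MSD_L`` -- is
non-increasing across iterations, and the iteration terminates in finitely
many steps because the candidate subsets form a finite set and superposition
on a fixed subset is globally optimal.

The local minimizer found depends on the starting subset; a seeded multistart
(:func:`lovo_align_frame_multistart`) globalizes the search, which matters
for structures with several internally rigid domains of similar size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from lovofit.geometry import (
    DegenerateFitError,
    FrameCoordinates,
    RigidTransform,
    _check_roster,
    _check_subset_nondegenerate,
    _kearsley_fit,
)

__all__ = [
    "LovoOptions",
    "FrameAlignment",
    "n_low_from_phi",
    "select_lowest",
    "lovo_align_frame",
    "lovo_align_frame_multistart",
]


@dataclass(frozen=True)
class LovoOptions:
    """Knobs of the LOVO iteration and its multistart globalization.

    Parameters
    ----------
    phi
        Default fraction of atoms fitted, in ``(0, 1]``; functions that take
        an explicit ``phi`` argument ignore this field.
    n_starts
        Number of starting subsets for the multistart search: one
        deterministic start (the lowest-deviation atoms after a
        whole-structure superposition) plus ``n_starts - 1`` uniformly random
        subsets.
    max_iterations
        Hard cap on LOVO iterations per start.
    convergence_tol
        Threshold in A^2 on the change of ``MSD_L`` between iterations; the
        iteration stops when the change falls below it *and* the selected
        subset is unchanged.
    rng_seed
        Seed of the single generator that draws all random starting subsets.
    """

    phi: float | None = None
    n_starts: int = 100
    max_iterations: int = 200
    convergence_tol: float = 1e-9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phi is not None and not (0.0 < self.phi <= 1.0):
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")


@dataclass(frozen=True)
class FrameAlignment:
    """Converged LOVO result for one frame.

    ``msd_L`` is the *sum* of the ``n_low`` smallest squared deviations (the
    LOVO objective); ``rmsd_L = sqrt(msd_L / n_low)``.  ``rmsd_H`` covers the
    complement and ``rmsd_T`` all atoms, all three evaluated under the same
    final transform, so the total sum of squares decomposes exactly:
    ``N * rmsd_T**2 == N_L * rmsd_L**2 + (N - N_L) * rmsd_H**2``.
    """

    transform: RigidTransform
    low_set: np.ndarray
    msd_all: np.ndarray
    msd_L: float
    rmsd_L: float
    rmsd_H: float
    rmsd_T: float
    n_iterations: int
    converged: bool
    msd_L_history: np.ndarray
    phi: float

    @property
    def n_low(self) -> int:
        return int(self.low_set.size)

    @property
    def realized_phi(self) -> float:
        """Actual fraction fitted, ``n_low / N`` (phi is rounded to an atom count)."""
        return self.n_low / self.msd_all.size


def n_low_from_phi(phi: float, n_atoms: int) -> int:
    """Number of fitted atoms: ``round(phi * N)``, half away from zero, floor 3."""
    if not (0.0 < phi <= 1.0):
        raise ValueError(f"phi must be in (0, 1], got {phi}")
    n_low = int(np.floor(phi * n_atoms + 0.5))
    n_low = max(3, n_low)
    if n_low > n_atoms:
        raise ValueError(
            f"phi={phi} requires fitting {n_low} atoms but the frame has {n_atoms}"
        )
    return n_low


def select_lowest(msd: np.ndarray, n_low: int) -> np.ndarray:
    """Indices of the ``n_low`` smallest deviations, ties broken by atom index.

    Returned sorted by atom index, so equal index sets compare equal.
    """
    msd = np.asarray(msd)
    if not 1 <= n_low <= msd.size:
        raise ValueError(f"n_low={n_low} out of range [1, {msd.size}]")
    order = np.argsort(msd, kind="stable")
    return np.sort(order[:n_low])


def _lovo_iterate(
    coords: np.ndarray,
    ref: np.ndarray,
    initial_set: np.ndarray,
    options: LovoOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], int, bool]:
    """Raw-array LOVO loop; returns (rotation, translation, msd, history, iters, converged)."""
    n_low = initial_set.size
    current_set = initial_set
    rot_cum = np.eye(3)
    tra_cum = np.zeros(3)
    current = coords
    history: list[float] = []
    msd_L_prev = np.inf
    converged = False
    it = 0
    for it in range(1, options.max_iterations + 1):
        _check_subset_nondegenerate(ref[current_set])
        rot, tra = _kearsley_fit(current[current_set], ref[current_set])
        current = current @ rot.T + tra
        rot_cum = rot @ rot_cum
        tra_cum = rot @ tra_cum + tra
        diff = current - ref
        msd = np.einsum("ij,ij->i", diff, diff)
        new_set = select_lowest(msd, n_low)
        msd_L = float(msd[new_set].sum())
        history.append(msd_L)
        if np.array_equal(new_set, current_set) and (
            abs(msd_L_prev - msd_L) < options.convergence_tol
        ):
            current_set = new_set
            converged = True
            break
        current_set = new_set
        msd_L_prev = msd_L
    diff = current - ref
    msd = np.einsum("ij,ij->i", diff, diff)
    return rot_cum, tra_cum, msd, history, it, converged


def _finalize(
    frame: FrameCoordinates,
    rot: np.ndarray,
    tra: np.ndarray,
    msd: np.ndarray,
    history: list[float],
    n_iter: int,
    converged: bool,
    n_low: int,
    phi: float,
) -> FrameAlignment:
    low_set = select_lowest(msd, n_low)
    n = msd.size
    msd_L = float(msd[low_set].sum())
    rmsd_L = float(np.sqrt(msd_L / n_low))
    if n_low < n:
        high_mask = np.ones(n, dtype=bool)
        high_mask[low_set] = False
        rmsd_H = float(np.sqrt(msd[high_mask].mean()))
    else:
        rmsd_H = 0.0
    rmsd_T = float(np.sqrt(msd.mean()))
    return FrameAlignment(
        transform=RigidTransform(rot, tra),
        low_set=low_set,
        msd_all=msd,
        msd_L=msd_L,
        rmsd_L=rmsd_L,
        rmsd_H=rmsd_H,
        rmsd_T=rmsd_T,
        n_iterations=n_iter,
        converged=converged,
        msd_L_history=np.asarray(history),
        phi=phi,
    )


def lovo_align_frame(
    frame: FrameCoordinates,
    reference: FrameCoordinates,
    phi: float,
    initial_set: Iterable[int],
    options: LovoOptions = LovoOptions(),
) -> FrameAlignment:
    """Run the LOVO iteration from one starting subset.

    Iterates superposition on the current subset, whole-structure motion,
    re-ranking of per-atom squared deviations, and re-selection of the bottom
    ``N_L``, until ``MSD_L`` stops changing (within ``convergence_tol``) with
    a stable subset, or ``max_iterations`` is reached.  Non-convergence is
    reported through the ``converged`` flag, not raised.
    """
    _check_roster(frame, reference)
    n_low = n_low_from_phi(phi, frame.n_atoms)
    initial = np.sort(np.asarray(list(initial_set), dtype=np.intp))
    if initial.size != n_low:
        raise ValueError(
            f"initial_set has {initial.size} atoms but phi={phi} requires {n_low}"
        )
    rot, tra, msd, history, n_iter, converged = _lovo_iterate(
        frame.coords, reference.coords, initial, options
    )
    return _finalize(frame, rot, tra, msd, history, n_iter, converged, n_low, phi)


def _deterministic_start(
    coords: np.ndarray, ref: np.ndarray, n_low: int
) -> np.ndarray:
    """Bottom-``n_low`` atoms after a standard whole-structure superposition."""
    rot, tra = _kearsley_fit(coords, ref)
    moved = coords @ rot.T + tra
    diff = moved - ref
    msd = np.einsum("ij,ij->i", diff, diff)
    return select_lowest(msd, n_low)


def lovo_align_frame_multistart(
    frame: FrameCoordinates,
    reference: FrameCoordinates,
    phi: float,
    options: LovoOptions = LovoOptions(),
) -> FrameAlignment:
    """Globalized LOVO alignment: best of ``n_starts`` starting subsets.

    The first start is deterministic (lowest-deviation atoms after a standard
    whole-structure superposition); the remaining ``n_starts - 1`` are
    uniform random ``N_L``-subsets drawn in order from
    ``numpy.random.default_rng(options.rng_seed)``.  The result with the
    smallest ``MSD_L`` wins; ties keep the earlier start.  Deterministic
    given ``rng_seed``.
    """
    _check_roster(frame, reference)
    n = frame.n_atoms
    n_low = n_low_from_phi(phi, n)
    coords, ref = frame.coords, reference.coords

    starts = [_deterministic_start(coords, ref, n_low)]
    rng = np.random.default_rng(options.rng_seed)
    for _ in range(options.n_starts - 1):
        starts.append(np.sort(rng.choice(n, size=n_low, replace=False)))

    best = None
    best_msd_L = np.inf
    for initial in starts:
        rot, tra, msd, history, n_iter, converged = _lovo_iterate(
            coords, ref, initial.astype(np.intp), options
        )
        msd_L = float(np.sort(msd)[:n_low].sum())
        if best is None or msd_L < best_msd_L:
            best_msd_L = msd_L
            best = (rot, tra, msd, history, n_iter, converged)
    assert best is not None
    rot, tra, msd, history, n_iter, converged = best
    return _finalize(frame, rot, tra, msd, history, n_iter, converged, n_low, phi)
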