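# Methods

## Problem and model

Whole-structure rigid-body superposition minimizes the RMSD over all atoms,
so a small, highly mobile substructure (a loop, a fraying terminus, a
denaturing domain) drags the fit and inflates the apparent mobility of every
atom. lovofit instead treats the choice of which atoms to fit as part of the
optimization: for a fraction φ ∈ (0, 1], the objective is the smallest
achievable sum of the N_L = φ·N lowest per-atom squared deviations
(MSD_L), minimized jointly over rigid motions and over N_L-subsets. This is
a low-order-value optimization (LOVO) problem: the objective is the minimum
of a finite family of smooth functions (one per subset), and alternating the
two exact steps — optimal rigid fit for a fixed subset, optimal subset for a
fixed orientation — descends monotonically and terminates at a local
minimizer.

Both alternating steps are exact, which is what gives the descent guarantee:

* **Fit step.** Kearsley's quaternion method. For centered coordinate pairs,
  the 4×4 symmetric matrix built from per-pair sums and differences has the
  optimal rotation as the eigenvector of its smallest eigenvalue; the
  smallest eigenvalue equals the residual sum of squares. We diagonalize with
  a standard symmetric eigensolver (`numpy.linalg.eigh`) and recompute the
  residual explicitly after applying the transform rather than trusting the
  eigenvalue, which is more robust to round-off and also yields the per-atom
  deviations of the *non-fitted* atoms needed by the selection step. The
  quaternion parametrization cannot produce a reflection, so the rotation is
  proper even for mirror-symmetric inputs. The quaternion sign ambiguity
  (q and −q encode the same rotation) is irrelevant.
* **Selection step.** A stable argsort of the per-atom squared deviations;
  ties are broken by atom index so results are identical across platforms and
  sorting algorithms.

## Iteration, convergence, globalization

One frame is aligned by iterating fit → whole-structure move → re-sort →
re-select until (a) the change in MSD_L is below `convergence_tol`
(default 1e-9 Å², an absolute tolerance on a sum of squares) **and** (b) the
selected subset is unchanged between consecutive iterations. Set stability
makes termination finite (the subsets form a finite set and MSD_L strictly
decreases until a fixed point); the numeric tolerance guards against float
churn near the fixed point. Non-convergence within `max_iterations`
(default 200) is reported via a flag, not raised — a trajectory analysis must
tolerate a rare pathological frame. In practice convergence takes 2–20
iterations.

The iteration only finds a local minimizer: structures with several
internally rigid regions have several basins. The multistart wrapper runs
`n_starts` (default 100) starting subsets — one deterministic start (the
bottom-N_L atoms after a standard whole-structure superposition, which is
also the natural single-start choice) plus `n_starts − 1` uniform random
N_L-subsets from `numpy.random.default_rng(rng_seed)` — and keeps the result
with the smallest MSD_L, ties going to the earlier start. The deterministic
start is counted inside `n_starts`. On 10-atom instances at φ = 0.5 the
multistart matches the exhaustive optimum over all 252 subsets in ≳95% of
random instances (asserted in the test suite); misses are genuine secondary
basins, and the reported value is still a valid upper bound on the optimum.

Local minima are not a corner case: when a sizable substructure moves
*coherently* (e.g. a 30% segment displaced as a block), a compromise
alignment that splits the difference between core and segment is a true LOVO
fixed point, and random mixed subsets tend to fall into it. The consensus
aggregation below absorbs occasional per-frame misses.

## Bookkeeping and reported quantities

* N_L = round(φ·N), rounding half away from zero, floored at 3 (a rigid fit
  needs 3 non-collinear atoms); the realized fraction N_L/N is exposed since
  φ·N is rarely integral.
* MSD_L is stored as the *sum* of the N_L smallest squared deviations (exact
  monotonicity); RMSD_L = √(MSD_L/N_L) is taken only at reporting
  boundaries. RMSD_H covers the complement and RMSD_T all atoms, under the
  same final transform, so N·RMSD_T² = N_L·RMSD_L² + (N−N_L)·RMSD_H² holds
  exactly (asserted to 1e-8 relative everywhere).
* The final transform is the composition of all per-iteration motions, so
  applying it once to the raw frame reproduces the converged coordinates.
* Per-frame subsets are re-identified independently on every frame; the
  per-atom `low_fraction` (fraction of frames in the low set) aggregates
  them, and the consensus core is defined as `low_fraction ≥ 0.5`. The 0.5
  threshold is a committed design choice: it is the majority rule, and on the
  synthetic generator it recovers ground truth even when a minority of frames
  converge to compromise alignments.
* RMSF has two conventions, both exposed: about the reference coordinates
  (default — matches per-frame deviation series and the b-factor output) and
  about the trajectory-average position (the equilibrium-fluctuation
  definition; degenerate for a single frame, where it is flagged).
* The φ-scan covers 0.01–0.99 in 0.01 steps by default and reports both the
  mean and the max of RMSD_L over frames, plus a first-vs-last two-frame
  mode; the three usages differ in the literature, so all are exposed rather
  than committing to one. Grid points whose rounded N_L < 3 are skipped.

## Reference and seeds

The default reference is the first frame; an external PDB reference is
accepted. Frames are processed sequentially but independently: frame i uses
seed `rng_seed XOR i` (masked to 31 bits), so per-frame results are
reproducible regardless of processing order, and whole runs are
deterministic given the seed.

## PDB dialect

Fixed-width parsing (coordinates in columns 31–54); HETATM excluded from
selection; altloc ' ' and 'A' kept; insertion codes are part of the atom
identity; the Cα selection excludes calcium ions (element or residue CA).
The roster is fixed by the first model and every later model must match it
exactly, with errors naming the offending model and atom. The writer emits
one MODEL per frame over the selected roster with occupancy = per-frame
low-set membership and b-factor = per-atom deviation (Å), clamped at 999.99
(field width) with a logged warning; coordinates are written %8.3f, so a
round trip is exact to 5e-4 Å. Binary formats (DCD/XTC) are out of scope;
the reader interface is format-agnostic enough to add them later.

## Synthetic generator

`lovofit.synthetic` emulates the two canonical scenarios: a stable core with
a mobile loop (constant displacement schedule) and progressive divergence
(linear ramp). The reference is a self-avoiding random chain with 3.8 Å
consecutive spacing and ≥3.2 Å non-neighbor separation — realistic Cα
geometry, not realistic dynamics. Core atoms get isotropic Gaussian noise
(σ per coordinate, default 0.1 Å, the scale of equilibrium fluctuations);
the mobile segment (contiguous, at the chain end by default or interior as a
hinge) is displaced as a block along a fresh random direction each frame
(default 5 Å, a clearly-resolvable loop excursion); an optional global rigid
motion (uniform random rotation, translation uniform in ±10 Å) checks that
alignment removes frame-of-reference changes. Draw order (chain directions;
then per frame: core noise, segment direction, global motion) is fixed, so
trajectories are bit-reproducible by seed.

What passing tests on this generator do *not* show: real proteins have
correlated (not isotropic/independent) fluctuations, mobile regions that
deform internally rather than translate as blocks, and gradual mobility
boundaries. The generator is a ground-truth harness for the optimizer and
bookkeeping, not a physics model.

## Problem sizes used in checks

The acceptance script and test suite run the oracle comparison at N = 10,
φ = 0.5 (252 subsets enumerable exactly), the rotation-sampling check at
N ≤ 20 with 10⁴ rotations, and the recovery study at N = 200 atoms ×
20 frames with the full 99-point φ-scan at 100 multistarts — sizes at which
every check recomputes from scratch in minutes on one CPU while exercising
the same code paths as production-size trajectories.

## Known limitations

* Unweighted fits only (no mass or B-factor weighting), on a single
  user-selected atom roster; no cross-protein correspondence search.
* The multistart gives no certificate of global optimality; MSD_L is an
  upper bound on the true LOVO optimum.
* φ values implying N_L < 3 are rejected (alignment needs a plane).
* The PDB writer carries only the selected (Cα) atoms, not full residues.
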