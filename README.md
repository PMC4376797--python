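# lovofit

Robust rigid-body alignment of molecular-dynamics trajectories by
low-order-value optimization (LOVO): for every frame, the fraction φ of
Cα atoms with the smallest displacements relative to a reference structure is
identified automatically and the frame is superposed on that subset. The
result is a mobility analysis that is not distorted by a few highly mobile
atoms — the standard failure mode of whole-structure RMSD/RMSF, where one
flexible loop inflates the apparent mobility of every atom.

## Who this is for

Anyone analyzing protein MD trajectories who needs to answer: *is the
structure as a whole diverging, or is a small substructure responsible for
the large RMSD?* The package separates the two cases, quantifies each subset
by its own RMSD, and maps which atoms belong to the rigid core.

## The method

Let {xᵢ(t)} be the N Cα coordinates at frame t and {xᵢʳᵉᶠ} a reference
(by default the first frame). With per-atom squared displacements

    MSDᵢ(t) = ‖xᵢ(t) − xᵢʳᵉᶠ‖²,    RMSD(t) = √( (1/N) Σᵢ MSDᵢ(t) )

the alignment of one frame at fraction φ iterates, from a starting subset of
N_L = round(φ·N) atoms:

1. rigid-body superposition (Kearsley's quaternion method — the eigenvector
   of the smallest eigenvalue of a 4×4 matrix built from centered coordinate
   sums/differences gives the globally optimal rotation) on the current subset;
2. the whole structure is moved by that transform;
3. the per-atom MSDᵢ are re-sorted and the N_L smallest re-selected;
4. stop when MSD_L — the sum of the N_L smallest MSDᵢ — stops changing and
   the subset is stable.

MSD_L never increases across iterations, so the loop terminates at a local
minimizer; a seeded multistart (default 100 starting subsets: one
deterministic start from the whole-structure fit plus random subsets)
globalizes the search. After convergence three RMSDs are reported under the
same transform — RMSD_L (fitted, least-mobile subset), RMSD_H (the rest) and
RMSD_T (all atoms) — which satisfy the exact decomposition
N·RMSD_T² = N_L·RMSD_L² + (N−N_L)·RMSD_H². Scanning φ from 0.01 to 0.99
maps how large a substructure can be superposed to a given precision, which
localizes the rigid core without prior knowledge of it.

## Worked example

Generate a synthetic 100-atom Cα trace (70 rigid core atoms with 0.1 Å
coordinate noise, a 30-atom mobile segment displaced 5 Å per frame, 10
frames), then align at φ = 0.7:

```
lovofit synth --n-core 70 --n-mobile 30 --n-frames 10 \
        --sigma 0.1 --offset 5.0 --seed 7 --out-prefix demo
lovofit align --phi 0.7 --trajectory demo_traj.pdb --seed 7 --out-prefix fit
```

`fit_frames.tsv` (start):

```
frame	rmsd_L	rmsd_H	rmsd_T	iters	converged
0	0.000000	0.000000	0.000000	2	True
1	0.235985	6.097392	3.345510	5	True
2	0.244253	8.565501	4.695967	4	True
```

The core stays at the noise level (RMSD_L ≈ 0.24 Å ≈ σ√3) while the mobile
segment sits at 6–8 Å (RMSD_H); a whole-structure RMSD of 3–5 Å (RMSD_T)
would have suggested, misleadingly, that the entire structure is mobile.
Frame 0 is the reference itself, hence all zeros. `fit_atoms.tsv` gives the
per-atom picture — core atoms have RMSF ≈ 0.2 Å and were in the fitted set
in every frame (`low_fraction` 1.0), mobile atoms ≈ 6 Å and never fitted:

```
atom_id	rmsf	low_fraction
A:ALA1:CA	0.233520	1.000000
...
A:ALA100:CA	6.059571	0.000000
```

A φ-scan shows the scan statistic jumping as soon as φ exceeds the true core
fraction (0.70), localizing the core size within one grid step:

```
lovofit scan --trajectory demo_traj.pdb --phi-min 0.60 --phi-max 0.80 \
        --phi-step 0.05 --seed 7 --n-starts 20 --out-prefix sc
```

```
phi	n_L	mean_rmsd_L	max_rmsd_L	mean_rmsd_H	mean_rmsd_T
0.600000	60	0.184474	0.212604	4.768837	3.020498
0.650000	65	0.197324	0.225490	5.092521	3.018377
0.700000	70	0.214183	0.246883	5.494085	3.016351
0.750000	75	1.241855	1.896906	4.389744	2.444500
0.800000	80	1.520498	2.185761	3.944617	2.228261
```

`lovofit align` also writes an annotated multi-MODEL PDB in which occupancy
marks each frame's least-mobile subset (1.00/0.00) and the b-factor column
carries the per-atom deviation in Å — load it in a structure viewer and color
by occupancy or b-factor to see the core.

The same analyses are available as a library
(`lovofit.align_trajectory`, `lovofit.phi_scan`, `lovofit.compute_rmsf`, …).

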