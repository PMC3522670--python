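# emassemble

Simultaneous rigid-body assembly of multiple coarse-grained protein
subunits into a low-resolution cryo-EM density map.

Cryo-EM maps of large molecular machines often resolve the overall
envelope but not the arrangement of the individual subunits.  Given the
subunit structures and the map, `emassemble` searches for the arrangement
that explains the density: it is built for structural biologists and
methods developers who want a fully scriptable, testable implementation of
multi-component density fitting with symmetry restraints.

## The method

Every coarse-grained bead and every map voxel is an isotropic Gaussian
whose standard deviation is tied to the map resolution R
(sigma = (R/2)/sqrt(3) per axis).  Three ideas carry the method:

1. **Gaussian-overlap fitting energy.**  The overlap of two Gaussians is
   itself a Gaussian of their distance,
   `O(D) = A1 A2 (pi/(s1+s2))^{3/2} exp(-(s1 s2/(s1+s2)) D^2)`,
   so a bead's overlap with the whole map can be precomputed per voxel and
   interpolated.  Each bead is calibrated against the component's own
   simulated map; the fitting energy is a harmonic penalty on the overlap
   *deficiency* (hard below the bead's own maximum, softer below F times
   it, where F >= 1 absorbs spillover from adjacent subunits).  The term
   is smooth and long-range: it pulls subunits into the density without
   dictating their arrangement.
2. **Voxel atom density.**  The same trilinear weights that interpolate
   the overlap deposit each bead's weight into its eight neighbouring
   voxels; a quadratic penalty on densities above a per-voxel cap keeps
   subunits from interpenetrating.
3. **Gradient vector matching (GVM).**  Candidate assemblies are ranked by
   comparing 3D Prewitt gradient vectors ("contour normals") of the map
   against those of the model's atom-density grid — per Cartesian
   component, with a significance threshold on the map gradient and a
   tolerance before the quadratic mismatch penalty starts.

Cyclic (C_X) symmetry enters purely as distance-equality restraints on
backbone-bead pairs (no symmetry axis needed); the search runs as a staged
protocol — random or topology-informed starts, symmetry pre-assembly,
coarse-map assembly by rigid-body minimization, GVM re-ranking on the fine
map, staged refinement with a short-range intermolecular potential, and
combinatorial recombination of ring blocks between top-ranked partial
solutions.  See `docs/methods.md` for the full model description.

## Worked example

`examples/` holds one short script per capability.  Ranking labelled
decoys of a synthetic seven-membered ring by GVM
(`python examples/03_gvm_ranking.py`) prints:

```
reference ranked #2 of 101
top-5 true RMSDs: [0.09 0.   0.44 0.25 0.31] A
Spearman rho(GVM energy, true RMSD) = 0.964 (positive: lower energy = closer to truth)
```

The generating reference and a 0.09 A decoy (numerically the same
structure) occupy the first two ranks, the sub-Angstrom decoys cluster at
the top, and the rank correlation between GVM energy and true RMSD shows
the score orders models by quality — the property that lets the protocol
pick needles out of large candidate pools.  A small end-to-end assembly
run is in `examples/05_toy_protocol.py`; the full desk-scale benchmark is
one command: `emassemble toy-benchmark --seed 1`.

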