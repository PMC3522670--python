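"""Synthetic ring assemblies with known ground truth.

The fixture generator builds small homo-oligomeric ring assemblies of
anisotropic Gaussian bead blobs, plus simulated density maps, so every
stage of the assembly pipeline can be exercised without downloading any
structure.  Subunits are rigid, non-spherical (distinguishable principal
axes, a chiral marker bead pattern) so that orientation recovery is
testable; rings have mathematically exact C_X positional symmetry.

All fixtures are reproducible from (spec, seed); tests commit specs, never
binary fixtures.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .densmap import DensityGrid, simulate_map
from .gvm import GvmConfig, calibrate_model_scale, model_gradient, prewitt_gradient
from .emfit import accumulate_voxel_density
from .densmap import rescale_to_sum
from .structures import Assembly, CoarseModel, RigidPose, rmsd

__all__ = [
    "RingSpec",
    "ToySpec",
    "make_toy_assembly",
    "make_decoy_pool",
    "make_benchmark_case",
    "cyclic_min_rmsd",
]


@dataclasses.dataclass
class RingSpec:
    """One C_X ring: subunit count, placement radius, axial offset and the
    size scale of its subunit (a scaled copy of the common blob — rings of
    different scale are structurally distinguishable, like a small cap ring
    on a larger body)."""

    count: int = 7
    radius: float = 34.0       # Angstrom, ring radius in the xy plane
    z: float = 0.0             # Angstrom, axial position of the ring plane
    phase: float = 0.0         # radians, rotation of the whole ring about z
    scale: float = 1.0         # subunit size scale for this ring

    def __post_init__(self) -> None:
        if self.count < 2:
            raise ValueError("a ring needs at least 2 subunits")
        if self.scale <= 0:
            raise ValueError("subunit scale must be positive")


@dataclasses.dataclass
class ToySpec:
    """Study conditions for the desk-scale benchmark assembly.

    The default is a three-ring stack of 7-fold rings (21 identical
    subunits), echoing the topology of a chaperonin-like double-ring plus
    cap.  Subunits are 32-bead three-lobe Gaussian blobs of residue-like
    bead weight (~110) whose orientation is identifiable from the density
    envelope at the fine-map scale; the rings are sparse (neighbour gaps
    exceed the fine-map kernel width), which keeps each subunit's
    orientation landscape close to its isolated one — the regime in which
    local minimization can lock orientations at all (see docs/methods.md).
    """

    rings: Sequence[RingSpec] = dataclasses.field(
        default_factory=lambda: (
            RingSpec(count=7, radius=38.0, z=-30.0, scale=0.72),
            RingSpec(count=7, radius=44.0, z=0.0),
            RingSpec(count=7, radius=44.0, z=30.0),
        )
    )
    beads_per_subunit: int = 32
    blob_sigmas: tuple = (8.5, 5.5, 2.7)    # Angstrom, anisotropic cloud
    bead_weight: float = 110.0              # mass-like units per bead
    seed: int = 0

    def __post_init__(self) -> None:
        self.rings = tuple(self.rings)
        if self.beads_per_subunit < 3:
            raise ValueError("need at least 3 beads per subunit")
        if len(set(np.round(self.blob_sigmas, 6))) < 2:
            raise ValueError("blob must be non-spherical (orientation identifiability)")


def _make_subunit(spec: ToySpec, scale: float = 1.0) -> CoarseModel:
    """Asymmetric three-lobe bead blob whose orientation is identifiable
    from its density envelope alone: lobes of graded mass sit at the corners
    of a scalene triangle, with the lightest lobe lifted out of plane, so no
    180-degree flip or mirror reproduces the low-resolution density."""
    rng = np.random.default_rng([spec.seed, 7919])
    n = spec.beads_per_subunit
    sx, sy, sz = spec.blob_sigmas
    fracs = (0.5, 0.3, 0.2)
    centers = np.array([[0.9 * sx, 0.0, 0.0],
                        [-0.9 * sx, 0.5 * sy, 0.0],
                        [-0.1 * sx, -0.8 * sy, 0.9 * sz]])
    spreads = np.array([[0.55 * sx, 0.8 * sy, 0.8 * sz],
                        [0.4 * sx, 0.55 * sy, 0.55 * sz],
                        [0.3 * sx, 0.4 * sy, 0.5 * sz]])
    counts = [max(2, int(round(f * n))) for f in fracs]
    counts[0] += n - sum(counts)
    pos = np.vstack([rng.normal(size=(c, 3)) * spreads[k] + centers[k]
                     for k, c in enumerate(counts)])
    pos = scale * (pos - pos.mean(axis=0))
    weights = np.full(n, spec.bead_weight) * rng.uniform(0.9, 1.1, size=n)
    return CoarseModel(
        bead_positions=pos,
        bead_weights=weights,
        bead_kinds=np.array(["BB"] * n),
        residue_index=np.arange(1, n + 1),
        name=f"toy-subunit-x{scale:g}" if scale != 1.0 else "toy-subunit",
    )


DEFAULT_SEATING = Rotation.from_euler("zy", [12.0, 8.0], degrees=True).as_matrix()


def ring_poses(ring: RingSpec, seating: Optional[np.ndarray] = None) -> list:
    """Exact C_X poses: subunit k rotated by 2*pi*k/X about z, seated on the
    ring circle.  ``seating`` is a fixed rotation applied to every subunit
    before the ring rotation; the default points the subunit's long axis
    radially with a small azimuthal/axial tilt (tight, chiral packing)."""
    if seating is None:
        seating = DEFAULT_SEATING
    poses = []
    for k in range(ring.count):
        ang = ring.phase + 2.0 * np.pi * k / ring.count
        Rz = Rotation.from_euler("z", ang).as_matrix()
        t = Rz @ np.array([ring.radius, 0.0, 0.0]) + np.array([0.0, 0.0, ring.z])
        poses.append(RigidPose(Rz @ seating, t))
    return poses


def make_toy_assembly(spec: ToySpec):
    """Reference assembly with exact per-ring C_X symmetry.

    Returns ``(assembly, subunit_model)``; all components share one
    CoarseModel (homo-oligomer).  Deterministic per spec.seed.
    """
    by_scale = {}
    poses, components = [], []
    for ring in spec.rings:
        if ring.scale not in by_scale:
            by_scale[ring.scale] = _make_subunit(spec, ring.scale)
        poses.extend(ring_poses(ring))
        components.extend([by_scale[ring.scale]] * ring.count)
    subunit = by_scale.get(1.0, next(iter(by_scale.values())))
    return Assembly(components, poses), subunit


def ring_slices(spec: ToySpec) -> list:
    """Component index ranges of each ring within the toy assembly."""
    out, start = [], 0
    for ring in spec.rings:
        out.append(range(start, start + ring.count))
        start += ring.count
    return out


def perturb_assembly(assembly: Assembly, translation_mag: float,
                     rotation_mag_rad: float, rng) -> Assembly:
    """Random rigid perturbation of every component (magnitudes are scales
    of a normal draw)."""
    new = assembly.copy()
    for c in range(new.n_components):
        dt = rng.normal(scale=translation_mag / np.sqrt(3.0), size=3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.normal(scale=rotation_mag_rad)
        dR = Rotation.from_rotvec(ang * axis).as_matrix()
        pose = new.poses[c]
        com = pose.apply(new.components[c].bead_positions).mean(axis=0)
        R_new = dR @ pose.rotation
        t_new = dR @ (pose.translation - com) + com + dt
        new.poses[c] = RigidPose(R_new, t_new)
    return new


def make_decoy_pool(reference: Assembly, n: int, rmsd_range: tuple, seed: int):
    """Decoys by random rigid perturbation, labelled with exact unfitted RMSD.

    Perturbation magnitudes span ``rmsd_range`` (Angstrom); at least 5% of
    decoys target the lowest decile of the range.  Returns a StructurePool
    whose scores carry the 'true_rmsd' label.
    """
    from .protocol import StructurePool

    if n < 1:
        raise ValueError("need at least one decoy")
    lo, hi = rmsd_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid rmsd range")
    ref_coords = reference.coordinates()
    pool = StructurePool()
    rgs = reference.components[0].radius_of_gyration()
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        if hi == 0.0:
            decoy = reference.copy()
        else:
            # reserve every 20th decoy for the lowest decile of the range
            span = hi - lo
            if i % 20 == 0:
                target = lo + span * rng.uniform(0.0, 0.1)
            else:
                target = lo + span * rng.uniform(0.0, 1.0)
            # split the displacement between translation and rotation
            decoy = perturb_assembly(reference, 0.8 * target,
                                     0.6 * target / max(rgs, 1e-6), rng)
        label = rmsd(decoy.coordinates(), ref_coords)
        pool.add(decoy, scores={"true_rmsd": label},
                 provenance={"stage": "decoy", "seed": seed, "index": i})
    return pool


def cyclic_min_rmsd(model: Assembly, reference: Assembly,
                    rings: Sequence[range]) -> float:
    """Unfitted RMSD minimised over per-ring cyclic relabelings.

    Components within a homo-oligomeric C_X ring are interchangeable: the
    map cannot distinguish an assembly from the same assembly with its ring
    labels cyclically shifted.  All shift combinations (one per ring) are
    enumerated and the smallest RMSD returned.
    """
    mcoords = [model.poses[c].apply(model.components[c].bead_positions)
               for c in range(model.n_components)]
    rcoords = [reference.poses[c].apply(reference.components[c].bead_positions)
               for c in range(reference.n_components)]
    from itertools import product

    shift_axes = [range(len(r)) for r in rings]
    best = np.inf
    for shifts in product(*shift_axes):
        sq = 0.0
        npts = 0
        for ring, shift in zip(rings, shifts):
            members = list(ring)
            X = len(members)
            for pos_idx, comp in enumerate(members):
                mc = mcoords[members[(pos_idx + shift) % X]]
                rc = rcoords[comp]
                d = mc - rc
                sq += float((d * d).sum())
                npts += len(mc)
        best = min(best, np.sqrt(sq / npts))
    return float(best)


@dataclasses.dataclass
class BenchmarkCase:
    """Everything a protocol run needs: reference, maps, and calibrations."""

    spec: ToySpec
    reference: Assembly
    subunit: CoarseModel
    maps: dict                 # resolution (A) -> DensityGrid
    coarse_resolution: float
    fine_resolution: float
    gvm_model_scale: float
    F_by_res: dict = dataclasses.field(default_factory=dict)
    # ^ per-resolution intermolecular spillover factor of this system
    cap_atoms: dict = dataclasses.field(default_factory=dict)
    # ^ per-resolution reference voxel atom density (average-bead units)

    @property
    def coarse_map(self) -> DensityGrid:
        return self.maps[self.coarse_resolution]

    @property
    def fine_map(self) -> DensityGrid:
        return self.maps[self.fine_resolution]


def _toy_ff_params(subunit: CoarseModel):
    """Soft packing potential matched to the toy material: pair minimum at
    the subunit's internal bead-packing scale, shallow well so refinement
    tightens interfaces without overpowering the map terms."""
    from .forcefield import PairPotentialParams
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(subunit.bead_positions))
    np.fill_diagonal(d, np.inf)
    rmin = float(np.median(d.min(axis=1)))
    return PairPotentialParams(default_radius=rmin, default_depth=0.02)


def make_protocol_config(case: BenchmarkCase, plan=None, seed: int = 0,
                         F: Optional[float] = None, recombination: bool = True):
    """Wire a benchmark case into a ready-to-run ProtocolConfig.

    Builds per-ring C_X symmetry restraints over backbone beads, ring
    topology priors (true ring z, radius prior mean 30 +/- 15 A mirroring a
    loose initial guess), the calibrated GVM configuration and a per-ring
    recombination scheme.
    """
    from .protocol import ProtocolConfig, RecombinationScheme, StagePlan
    from .restraints import build_cx_restraints

    spec = case.spec
    components = list(case.reference.components)
    rsets, offset = [], 0
    for ring in spec.rings:
        model = components[offset]
        rsets.append(build_cx_restraints(list(model.backbone_indices), ring.count,
                                         monomer_offset=offset))
        offset += ring.count
    ring_specs = [(r.z, 40.0, 15.0, r.count) for r in spec.rings]
    blocks = [list(r) for r in ring_slices(spec)]
    scheme = None
    if recombination and len(blocks) > 1:
        # end-block swaps: the child takes one outer ring from parent 2 and
        # the remaining adjacent rings from parent 1 (two patterns for a
        # three-ring stack)
        patterns = [[0], [len(blocks) - 1]] if len(blocks) > 2 else [[0], [1]]
        scheme = RecombinationScheme(blocks=blocks, patterns=patterns)
    from .gvm import GvmConfig

    return ProtocolConfig(
        components=components,
        coarse_map=case.coarse_map,
        fine_map=case.fine_map,
        coarse_resolution=case.coarse_resolution,
        fine_resolution=case.fine_resolution,
        restraints=rsets,
        plan=plan if plan is not None else StagePlan(),
        F=F if F is not None else case.F_by_res[case.coarse_resolution],
        F_fine=case.F_by_res[case.fine_resolution],
        cap_atoms_assembly=1.25 * case.cap_atoms[case.coarse_resolution],
        cap_atoms_refine=1.10 * case.cap_atoms[case.coarse_resolution],
        cap_atoms_fine=1.10 * case.cap_atoms[case.fine_resolution],
        gvm=GvmConfig(model_scale=case.gvm_model_scale),
        ring_specs=ring_specs,
        seed=seed,
        recombination=scheme,
        recombination_placement="after_refinement",
        recombination_rounds=2,
        recombination_top=40,
        sym_weight_assembly=3e5,
        sym_weight_refine=3e5,
        final_polish_top=10,
        ff_params=_toy_ff_params(case.subunit),
    )


def make_benchmark_case(spec: ToySpec, resolutions: tuple = (40.0, 20.0)) -> BenchmarkCase:
    """Simulate maps at the given resolutions (voxel = resolution/4) from the
    toy reference and calibrate the GVM model-gradient scale on it.

    The coarsest resolution drives the assembly stage, the finest the
    scoring stage (mirroring a coarse 40 A / fine 20 A pair).  Two
    calibrations are read off the reference structure, as one would for any
    new system: the GVM model-gradient scale (least-squares ratio between
    the fine map's gradients and the reference's atom-density gradients)
    and the intermolecular spillover factor F (the overlap each bead
    attains in the full assembly's map relative to its own-map maximum;
    the 5th percentile of that ratio keeps the reference itself feasible).
    """
    from .emfit import (build_assembly_table, calibrate_max_overlap,
                        interpolate_overlap, precompute_overlap_grid)
    from .densmap import GaussianParams

    reference, subunit = make_toy_assembly(spec)
    maps = {}
    for res in resolutions:
        maps[res] = simulate_map(reference, res, voxel_size=res / 4.0)
    coarse = max(resolutions)
    fine = min(resolutions)
    fine_map = maps[fine]
    # spillover factors: bead overlap in the assembly map vs own-map maximum,
    # per working resolution (spillover shrinks as resolution improves)
    F_by_res = {}
    for res, grid in maps.items():
        tables, seen = [], {}
        for comp in reference.components:
            if id(comp) not in seen:
                seen[id(comp)], _ = calibrate_max_overlap(
                    comp, res, voxel_size=grid.voxel_size)
            tables.append(seen[id(comp)])
        ogrid = precompute_overlap_grid(grid, GaussianParams.from_resolution(res))
        O_full, _, _, _ = interpolate_overlap(ogrid, reference.coordinates())
        maxO = build_assembly_table(tables, F=1.0).concatenated()
        F_by_res[res] = max(1.0, float(np.quantile(O_full / maxO, 0.05)))
    # reference voxel atom densities calibrate the clash caps per map
    mean_w = float(reference.weights().mean())
    cap_atoms = {}
    for res, grid in maps.items():
        vd = accumulate_voxel_density(reference.coordinates(),
                                      reference.weights(), grid)
        cap_atoms[res] = float(vd.grid.values.max() / mean_w)
    scaled = rescale_to_sum(fine_map, reference.total_weight)
    v_exp = prewitt_gradient(scaled)
    vgrid = accumulate_voxel_density(reference.coordinates(), reference.weights(),
                                     fine_map)
    v_model = model_gradient(vgrid, scale=1.0)
    scale = calibrate_model_scale(v_exp, v_model)
    return BenchmarkCase(
        spec=spec,
        reference=reference,
        subunit=subunit,
        maps=maps,
        coarse_resolution=coarse,
        fine_resolution=fine,
        gvm_model_scale=scale,
        F_by_res=F_by_res,
        cap_atoms=cap_atoms,
    )
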