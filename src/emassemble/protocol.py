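"""Stage orchestration: starts, pre-assembly, assembly, scoring, refinement
and recombination of partial solutions.

The protocol mirrors a five-stage schedule: (1) starting structures are
generated at random or from ring topology priors; (2) a pre-assembly stage
imposes symmetry (all map and atomic terms off); (3) the assembly stage
minimizes the Gaussian-overlap fitting energy against a coarse map together
with clash, symmetry and gravity terms; (4) the scoring stage truncates by
assembly energy and re-ranks by gradient-vector-matching (GVM) against the
fine map; (5) staged refinement turns on the intermolecular force field
(weight 0.01 -> 1, with the map term transiently upweighted by 50 to keep
the assembly together) and re-ranks by GVM.  Partial solutions can be
recombined by swapping component blocks (e.g. rings) between every ordered
pair of top-ranked parents.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .densmap import DensityGrid
from .emfit import (EmFitWeights, MaxOverlapTable, OverlapGrid,
                    build_assembly_table, calibrate_max_overlap,
                    density_clash_energy, em_fit_energy, precompute_overlap_grid)
from .densmap import GaussianParams
from .forcefield import PairPotentialParams, intermolecular_energy
from .gvm import GvmConfig, rank_by_gvm
from .minimize import EnergyStack, minimize, orientation_only_minimize
from .restraints import gravity_terms, location_energy, symmetry_energy
from .structures import Assembly, CoarseModel, RigidPose

__all__ = [
    "StructurePool",
    "StagePlan",
    "RecombinationScheme",
    "random_starts",
    "ring_topology_starts",
    "pre_assembly_stage",
    "assembly_stage",
    "scoring_stage",
    "refinement_stage",
    "recombine",
    "run_protocol",
    "gap_selection",
]


class StructurePool:
    """Ranked collection of assemblies with per-term scores and provenance."""

    def __init__(self):
        self.assemblies: list[Assembly] = []
        self.scores: list[dict] = []
        self.provenance: list[dict] = []

    def __len__(self) -> int:
        return len(self.assemblies)

    def add(self, assembly: Assembly, scores: Optional[dict] = None,
            provenance: Optional[dict] = None) -> None:
        self.assemblies.append(assembly)
        self.scores.append(dict(scores) if scores else {})
        self.provenance.append(dict(provenance) if provenance else {})

    def sort_by(self, key: str) -> None:
        """Stable ascending sort by a score key (ties keep prior order)."""
        order = sorted(range(len(self)), key=lambda i: self.scores[i][key])
        self.assemblies = [self.assemblies[i] for i in order]
        self.scores = [self.scores[i] for i in order]
        self.provenance = [self.provenance[i] for i in order]

    def truncate(self, n: int) -> "StructurePool":
        out = StructurePool()
        out.assemblies = self.assemblies[:n]
        out.scores = self.scores[:n]
        out.provenance = self.provenance[:n]
        return out

    def score_array(self, key: str) -> np.ndarray:
        return np.array([s[key] for s in self.scores], dtype=float)


@dataclasses.dataclass
class StagePlan:
    """Per-stage pool sizes and minimizer settings.

    The reference-scale schedule is 10^6 starts -> 5*10^5 after pre-assembly
    -> 10^5 scored -> 10^3 refined; the desk preset scales this down to
    2000/1000/200/20 so a full run stays interactive on one CPU.
    """

    n_starts: int = 2000
    n_preassembly: int = 1000
    n_scoring: int = 200
    n_refine: int = 20
    preassembly_max_iter: int = 40
    assembly_max_iter: int = 100
    refine_max_iter: int = 80
    orient_max_iter: int = 1500    # refinement sub-stage (a): seating search
    polish_max_iter: int = 300     # final full-stack polish of the leaders
    tol: float = 1e-12

    @classmethod
    def paper_scale(cls) -> "StagePlan":
        return cls(n_starts=1_000_000, n_preassembly=500_000, n_scoring=100_000,
                   n_refine=1000)

    def __post_init__(self) -> None:
        counts = [self.n_starts, self.n_preassembly, self.n_scoring, self.n_refine]
        if any(c < 1 for c in counts):
            raise ValueError("pool sizes must be positive")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("selection counts must be non-increasing across stages")


@dataclasses.dataclass
class RecombinationScheme:
    """Partition of components into blocks plus the swap patterns.

    ``blocks`` is a list of component-index lists (e.g. one per ring);
    ``patterns`` lists which block indices a child takes from the second
    parent (each a proper nonempty subset of blocks).
    """

    blocks: list
    patterns: list

    def __post_init__(self) -> None:
        all_comps = [c for b in self.blocks for c in b]
        if len(set(all_comps)) != len(all_comps):
            raise ValueError("blocks must not overlap")
        nb = len(self.blocks)
        for pat in self.patterns:
            s = set(pat)
            if not s or s == set(range(nb)) or not s.issubset(range(nb)):
                raise ValueError("patterns must be proper nonempty subsets of blocks")


# ---------------------------------------------------------------------------
# Starting structures

def _uniform_rotation(rng) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def random_starts(components: Sequence[CoarseModel], n: int, box, seed: int) -> StructurePool:
    """n assemblies with positions uniform in ``box`` ((lo, hi) per axis) and
    orientations uniform over rotations; per-structure streams derive from
    (seed, index) so pools are reproducible and order-independent."""
    if n < 1:
        raise ValueError("need n >= 1")
    lo, hi = np.asarray(box[0], dtype=float), np.asarray(box[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("empty bounding box")
    pool = StructurePool()
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        poses = []
        for _ in components:
            t = rng.uniform(lo, hi)
            poses.append(RigidPose(_uniform_rotation(rng), t))
        pool.add(Assembly(list(components), poses),
                 provenance={"stage": "random_starts", "seed": seed, "index": i})
    return pool


def ring_topology_starts(
    components: Sequence[CoarseModel],
    ring_specs: Sequence[tuple],
    n: int,
    seed: int,
    z_jitter: float = 5.0,
) -> StructurePool:
    """Starts exploiting ring topology priors.

    ``ring_specs`` is a list of (z, radius_mean, radius_halfwidth, count)
    per ring; components are consumed in order.  Per structure and ring:
    a shared axial displacement U(-z_jitter, z_jitter) is added to z, the
    radius is drawn U(mean-halfwidth, mean+halfwidth), the first component
    is placed at a random phase on that circle and the remaining count-1
    evenly spaced in the xy plane; every orientation is random.  Positions
    have exact X-fold symmetry about the z axis by construction.
    """
    total = sum(int(s[3]) for s in ring_specs)
    if total != len(components):
        raise ValueError("ring specs do not cover the component list")
    if any(int(s[3]) < 1 for s in ring_specs):
        raise ValueError("ring count must be >= 1")
    pool = StructurePool()
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        poses = []
        for (z, r_mean, r_half, count) in ring_specs:
            count = int(count)
            dz = rng.uniform(-z_jitter, z_jitter)       # shared within the ring
            radius = rng.uniform(r_mean - r_half, r_mean + r_half)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            for k in range(count):
                ang = phase + 2.0 * np.pi * k / count
                t = np.array([radius * np.cos(ang), radius * np.sin(ang), z + dz])
                poses.append(RigidPose(_uniform_rotation(rng), t))
        pool.add(Assembly(list(components), poses),
                 provenance={"stage": "ring_topology_starts", "seed": seed, "index": i})
    return pool


# ---------------------------------------------------------------------------
# Energy-term adaptors (callable contracts for EnergyStack)

def symmetry_term(restraints):
    def fn(assembly, coords):
        return symmetry_energy(assembly, restraints, coords=coords)
    return ("symmetry", 1.0, fn)


def gravity_term(attract_k=None, repulse_k=None):
    kwargs = {}
    if attract_k is not None:
        kwargs["attract_k"] = attract_k
    if repulse_k is not None:
        kwargs["repulse_k"] = repulse_k

    def fn(assembly, coords):
        return gravity_terms(assembly, coords=coords, **kwargs)
    return ("gravity", 1.0, fn)


def location_term(restraints):
    def fn(assembly, coords):
        return location_energy(assembly, restraints, coords=coords)
    return ("location", 1.0, fn)


def em_term(ogrid: OverlapGrid, table: MaxOverlapTable,
            weights: Optional[EmFitWeights] = None, weight: float = 1.0):
    def fn(assembly, coords):
        return em_fit_energy(assembly, ogrid, table, weights=weights, coords=coords)
    return ("em_fit", weight, fn)


def clash_term(geometry: DensityGrid, cap_mass: float, k_clash: float = 1.0,
               weight: float = 1.0):
    def fn(assembly, coords):
        e, f, _ = density_clash_energy(coords, assembly.weights(), geometry,
                                       cap_mass, k_clash)
        return e, f
    return ("clash", weight, fn)


def forcefield_term(params: Optional[PairPotentialParams] = None, weight: float = 1.0):
    def fn(assembly, coords):
        return intermolecular_energy(assembly, params, weight=1.0, coords=coords)
    return ("forcefield", weight, fn)


# ---------------------------------------------------------------------------
# Stages

def pre_assembly_stage(
    pool: StructurePool,
    restraints,
    plan: StagePlan,
    orientation_only: bool = False,
    use_gravity: bool = True,
) -> StructurePool:
    """Impose symmetry on starting structures.

    All map and atomic terms are off; the symmetry energy (plus gravity
    unless disabled) is minimized per structure, orientation-only when the
    positions are already symmetric.  The pool is sorted by symmetry energy
    and truncated to the plan's pre-assembly count.
    """
    terms = [symmetry_term(restraints)]
    if use_gravity and not orientation_only:
        terms.append(gravity_term())
    stack = EnergyStack(terms=terms)
    out = StructurePool()
    minimizer = orientation_only_minimize if orientation_only else minimize
    for asm, prov in zip(pool.assemblies, pool.provenance):
        res = minimizer(asm, stack, max_iter=plan.preassembly_max_iter, tol=plan.tol)
        e_sym = res.breakdown.get("symmetry", res.energy)
        out.add(res.assembly, scores={"symmetry": e_sym, "preassembly_total": res.energy},
                provenance={**prov, "stage": "pre_assembly"})
    out.sort_by("symmetry")
    return out.truncate(plan.n_preassembly)


@dataclasses.dataclass
class EmSetup:
    """Coarse-map fitting machinery shared across assembly/refinement."""

    ogrid: OverlapGrid
    table: MaxOverlapTable
    geometry: DensityGrid
    cap_mass: float
    em_weights: EmFitWeights = dataclasses.field(default_factory=EmFitWeights)
    k_clash: float = 1.0


def prepare_em_setup(
    components: Sequence[CoarseModel],
    density: DensityGrid,
    resolution: float,
    F: float,
    cap_atoms: float,
    apply_deconvolution: bool = False,
    em_weights: Optional[EmFitWeights] = None,
    k_clash: float = 1.0,
) -> EmSetup:
    """Precompute the overlap grid for a map and calibrate every component.

    ``cap_atoms`` is the voxel atom-density cap in average-pseudo-atom
    counts (as quoted for a given voxel size); it is converted to the mass
    units beads carry by multiplying with the mean bead weight.
    """
    atom = GaussianParams.from_resolution(resolution)
    ogrid = precompute_overlap_grid(density, atom)
    tables = []
    seen = {}
    for comp in components:
        key = id(comp)
        if key not in seen:     # identical shared models calibrate once
            seen[key], _ = calibrate_max_overlap(
                comp, resolution, voxel_size=density.voxel_size,
                apply_deconvolution=apply_deconvolution)
        tables.append(seen[key])
    table = build_assembly_table(tables, F=F)
    mean_w = float(np.mean(np.concatenate([c.bead_weights for c in components])))
    return EmSetup(ogrid=ogrid, table=table, geometry=density,
                   cap_mass=cap_atoms * mean_w,
                   em_weights=em_weights or EmFitWeights(), k_clash=k_clash)


def assembly_stage(
    pool: StructurePool,
    setup: EmSetup,
    restraints,
    plan: StagePlan,
    use_gravity: bool = True,
    location_restraints=None,
    sym_weight: float = 1.0,
    orientation_frozen: bool = False,
) -> StructurePool:
    """Fit all components simultaneously into the coarse map.

    Minimizes EM fit + clash + symmetry (+ gravity, + optional location
    restraints) per structure; sorts ascending by final total energy.
    Structures whose energy turns non-finite are dropped and counted in the
    returned pool's ``n_dropped`` attribute.
    """
    terms = [
        em_term(setup.ogrid, setup.table, setup.em_weights),
        clash_term(setup.geometry, setup.cap_mass, setup.k_clash),
        ("symmetry", sym_weight, symmetry_term(restraints)[2]),
    ]
    if use_gravity:
        terms.append(gravity_term())
    if location_restraints:
        terms.append(location_term(location_restraints))
    stack = EnergyStack(terms=terms, frozen_rotations=orientation_frozen)
    out = StructurePool()
    dropped = 0
    for asm, prov in zip(pool.assemblies, pool.provenance):
        try:
            res = minimize(asm, stack, max_iter=plan.assembly_max_iter, tol=plan.tol)
        except FloatingPointError:
            dropped += 1
            continue
        out.add(res.assembly,
                scores={"assembly_total": res.energy, **res.breakdown},
                provenance={**prov, "stage": "assembly"})
    out.sort_by("assembly_total")
    out.n_dropped = dropped
    return out


def scoring_stage(
    pool: StructurePool,
    fine_map: DensityGrid,
    gvm_cfg: GvmConfig,
    plan: StagePlan,
) -> StructurePool:
    """Truncate to the scoring count by assembly energy, then re-rank by GVM
    against the fine map."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    if "assembly_total" in pool.scores[0]:
        pool.sort_by("assembly_total")
    out = pool.truncate(plan.n_scoring)
    rank_by_gvm(out, fine_map, gvm_cfg)
    for prov in out.provenance:
        prov["stage"] = "scoring"
    return out


#: Refinement sub-stage schedule: (force-field weight, EM-term weight).
REFINEMENT_SCHEDULE = ((0.0, 1.0), (0.01, 1.0), (1.0, 50.0), (1.0, 1.0))


def refinement_stage(
    pool: StructurePool,
    coarse_setup: EmSetup,
    fine_setup: EmSetup,
    restraints,
    fine_map: DensityGrid,
    gvm_cfg: GvmConfig,
    plan: StagePlan,
    ff_params: Optional[PairPotentialParams] = None,
    schedule=REFINEMENT_SCHEDULE,
    sym_weight: float = 1.0,
) -> StructurePool:
    """Four-sub-stage refinement of the top structures.

    (a) the fine map's fitting term joins the coarse one; (b) intermolecular
    forces at weight 0.01; (c) full forces with the map terms upweighted by
    50 to prevent disintegration; (d) everything at weight 1.  Structures
    are re-ranked by GVM at the end.

    ``sym_weight`` scales the symmetry restraint term in sub-stage (a)
    only: a stiff weight makes each symmetric ring rotate quasi-rigidly, so
    the fine map searches the ring's common seating (3 collective degrees
    of freedom) rather than 3X independent ones; the later sub-stages
    release the coupling (weight 1) so individual subunits can settle.
    Sub-stage (a) gets a longer iteration budget (plan.orient_max_iter)
    because it performs that seating search.
    """
    pool = pool.truncate(plan.n_refine)
    out = StructurePool()
    for asm, prov in zip(pool.assemblies, pool.provenance):
        current = asm
        for k, (ff_w, em_w) in enumerate(schedule):
            w_sym = sym_weight if k == 0 else 1.0
            terms = [
                em_term(coarse_setup.ogrid, coarse_setup.table,
                        coarse_setup.em_weights, weight=em_w),
                em_term(fine_setup.ogrid, fine_setup.table,
                        fine_setup.em_weights, weight=em_w),
                clash_term(fine_setup.geometry, fine_setup.cap_mass,
                           fine_setup.k_clash),
                ("symmetry", w_sym, symmetry_term(restraints)[2]),
            ]
            if ff_w > 0:
                terms.append(forcefield_term(ff_params, weight=ff_w))
            iters = plan.orient_max_iter if k == 0 else plan.refine_max_iter
            res = minimize(current, EnergyStack(terms=terms),
                           max_iter=iters, tol=plan.tol)
            current = res.assembly
        out.add(current, scores={"refined_total": res.energy},
                provenance={**prov, "stage": "refinement"})
    rank_by_gvm(out, fine_map, gvm_cfg)
    return out


def gap_selection(pool: StructurePool, key: str = "gvm", max_count: Optional[int] = None,
                  fallback: int = 32) -> StructurePool:
    """Cut at the largest relative gap in the sorted score within max_count.

    Generalises picking a cluster of clearly-separated top solutions (a
    large energy gap after the first few dozen structures); falls back to a
    fixed count when no meaningful gap exists.
    """
    vals = pool.score_array(key)
    n = len(vals) if max_count is None else min(max_count, len(vals))
    if n <= 1:
        return pool.truncate(n)
    v = vals[:n]
    denom = np.maximum(np.abs(v[:-1]), 1e-12)
    rel_gap = (v[1:] - v[:-1]) / denom
    cut = int(np.argmax(rel_gap)) + 1
    if rel_gap.max() < 1.0:        # no order-of-magnitude-ish gap
        cut = min(fallback, n)
    return pool.truncate(cut)


# ---------------------------------------------------------------------------
# Recombination

def recombine(pool: StructurePool, scheme: RecombinationScheme,
              top: Optional[int] = None) -> StructurePool:
    """Children from every ordered pair of distinct parents and every swap
    pattern: the pattern's blocks take parent 2's poses, the rest parent 1's.
    Children are pooled with the parents; bit-identical duplicate children
    are removed.  With P parents and m patterns, P*(P-1)*m children are
    generated before deduplication.
    """
    parents = pool if top is None else pool.truncate(top)
    P = len(parents)
    if P < 2:
        raise ValueError("need at least two parents to recombine")
    out = StructurePool()
    for i in range(P):
        out.add(parents.assemblies[i].copy(), scores=dict(parents.scores[i]),
                provenance={**parents.provenance[i], "stage": "recombine_parent"})
    seen = set()
    for i in range(P):
        for asm in (parents.assemblies[i],):
            key = _pose_key(asm)
            seen.add(key)
    for i in range(P):
        a1 = parents.assemblies[i]
        for j in range(P):
            if i == j:
                continue
            a2 = parents.assemblies[j]
            for pat in scheme.patterns:
                child = a1.copy()
                for b in pat:
                    for comp in scheme.blocks[b]:
                        child.poses[comp] = a2.poses[comp].copy()
                key = _pose_key(child)
                if key in seen:
                    continue
                seen.add(key)
                out.add(child, provenance={"stage": "recombined",
                                           "parents": (i, j), "pattern": tuple(pat)})
    return out


def _pose_key(assembly: Assembly) -> bytes:
    arr = np.concatenate([np.concatenate([p.rotation.ravel(), p.translation])
                          for p in assembly.poses])
    return arr.tobytes()


# ---------------------------------------------------------------------------
# Full protocol

@dataclasses.dataclass
class ProtocolConfig:
    """Everything one end-to-end run needs (toy or real)."""

    components: Sequence[CoarseModel]
    coarse_map: DensityGrid
    fine_map: DensityGrid
    coarse_resolution: float
    fine_resolution: float
    restraints: list                               # symmetry restraint sets
    plan: StagePlan = dataclasses.field(default_factory=StagePlan)
    F: float = 5.1
    F_fine: Optional[float] = None                 # spillover factor for the fine map
    cap_atoms_assembly: float = 18.0
    cap_atoms_refine: float = 16.0
    cap_atoms_fine: float = 4.0
    gvm: GvmConfig = dataclasses.field(default_factory=GvmConfig)
    ring_specs: Optional[Sequence[tuple]] = None   # enables topology starts
    seed: int = 0
    orientation_only_preassembly: Optional[bool] = None
    recombination: Optional[RecombinationScheme] = None
    recombination_rounds: int = 1
    recombination_top: int = 100
    recombination_placement: str = "after_scoring"   # or "after_refinement"
    sym_weight_assembly: float = 1.0
    sym_weight_refine: float = 1.0
    assembly_orientation_frozen: bool = False
    final_polish_top: int = 0                        # 0 disables the polish pass
    ff_params: Optional[PairPotentialParams] = None
    location_restraints: Optional[list] = None
    apply_deconvolution: bool = False


def run_protocol(config: ProtocolConfig, reference: Optional[Assembly] = None):
    """Execute the staged protocol; returns (final_pool, report).

    The report records per-stage counts and energy quantiles, plus RMSD
    tables when a reference assembly is supplied.  Re-running with the same
    config and seed reproduces the report.
    """
    from .structures import assembly_rmsd

    report = {"stages": []}

    def stage_stats(name, pool, key):
        vals = pool.score_array(key) if len(pool) else np.array([])
        entry = {"stage": name, "count": len(pool)}
        if len(vals):
            entry["energy_quantiles"] = {
                q: float(np.quantile(vals, q)) for q in (0.0, 0.25, 0.5, 0.75, 1.0)
            }
        report["stages"].append(entry)

    # 1. starting structures
    if config.ring_specs is not None:
        pool = ring_topology_starts(config.components, config.ring_specs,
                                    config.plan.n_starts, config.seed)
        positions_symmetric = True
    else:
        all_pos = np.vstack([c.bead_positions for c in config.components])
        span = np.ptp(all_pos, axis=0).max() * 2 + 40.0
        box = (-span / 2 * np.ones(3), span / 2 * np.ones(3))
        pool = random_starts(config.components, config.plan.n_starts, box, config.seed)
        positions_symmetric = False
    report["stages"].append({"stage": "starts", "count": len(pool)})

    # 2. pre-assembly (symmetry imposition)
    orientation_only = (config.orientation_only_preassembly
                        if config.orientation_only_preassembly is not None
                        else positions_symmetric)
    pool = pre_assembly_stage(pool, config.restraints, config.plan,
                              orientation_only=orientation_only)
    stage_stats("pre_assembly", pool, "symmetry")

    # 3. assembly against the coarse map
    coarse_setup = prepare_em_setup(
        config.components, config.coarse_map, config.coarse_resolution,
        F=config.F, cap_atoms=config.cap_atoms_assembly,
        apply_deconvolution=config.apply_deconvolution)
    pool = assembly_stage(pool, coarse_setup, config.restraints, config.plan,
                          location_restraints=config.location_restraints,
                          sym_weight=config.sym_weight_assembly,
                          orientation_frozen=config.assembly_orientation_frozen)
    stage_stats("assembly", pool, "assembly_total")

    # 4. scoring: truncate by assembly energy, re-rank by GVM on the fine map
    pool = scoring_stage(pool, config.fine_map, config.gvm, config.plan)
    stage_stats("scoring", pool, "gvm")

    def recombination_rounds(pool):
        for _ in range(config.recombination_rounds):
            pool = recombine(pool, config.recombination,
                             top=min(config.recombination_top, len(pool)))
            rank_by_gvm(pool, config.fine_map, config.gvm)
            report["stages"].append({"stage": "recombination", "count": len(pool)})
            pool = pool.truncate(config.plan.n_scoring)
        return pool

    if (config.recombination is not None
            and config.recombination_placement == "after_scoring"):
        pool = recombination_rounds(pool)

    # 5. staged refinement with the fine map and the force field
    refine_cap_setup = prepare_em_setup(
        config.components, config.coarse_map, config.coarse_resolution,
        F=config.F, cap_atoms=config.cap_atoms_refine,
        apply_deconvolution=config.apply_deconvolution)
    fine_setup = prepare_em_setup(
        config.components, config.fine_map, config.fine_resolution,
        F=config.F_fine if config.F_fine is not None else config.F,
        cap_atoms=config.cap_atoms_fine,
        apply_deconvolution=config.apply_deconvolution)
    pool = refinement_stage(pool, refine_cap_setup, fine_setup, config.restraints,
                            config.fine_map, config.gvm, config.plan,
                            ff_params=config.ff_params,
                            sym_weight=config.sym_weight_refine)
    stage_stats("refinement", pool, "gvm")

    if (config.recombination is not None
            and config.recombination_placement == "after_refinement"):
        pool = recombination_rounds(pool)

    if config.final_polish_top > 0:
        # short full-stack re-minimization of the leaders (fixes the seams
        # recombination introduces), then a final GVM re-rank
        terms = [
            em_term(refine_cap_setup.ogrid, refine_cap_setup.table,
                    refine_cap_setup.em_weights),
            em_term(fine_setup.ogrid, fine_setup.table, fine_setup.em_weights),
            clash_term(fine_setup.geometry, fine_setup.cap_mass,
                       fine_setup.k_clash),
            symmetry_term(config.restraints),
            forcefield_term(config.ff_params, weight=1.0),
        ]
        stack = EnergyStack(terms=terms)
        top = pool.truncate(config.final_polish_top)
        polished = StructurePool()
        for asm, prov in zip(top.assemblies, top.provenance):
            res = minimize(asm, stack, max_iter=config.plan.polish_max_iter,
                           tol=config.plan.tol)
            polished.add(res.assembly, scores={"polished_total": res.energy},
                         provenance={**prov, "stage": "final_polish"})
        rank_by_gvm(polished, config.fine_map, config.gvm)
        pool = polished
        stage_stats("final_polish", pool, "gvm")

    if reference is not None:
        report["rmsd_top10"] = [
            float(assembly_rmsd(a, reference)) for a in pool.assemblies[:10]
        ]
    report["final_count"] = len(pool)
    return pool, report
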