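"""Symmetry distance-equality restraints, location restraints and gravity terms.

Cyclic (C_X) symmetry is enforced purely through harmonic distance-equality
restraints, with no explicit symmetry axis.  Backbone beads of each monomer
are arranged into pairs (A = C_i, B = C_{p-i}); for each pair, equality set
S_k holds the X cyclically shifted distances d(A_n, B_{n+k}) with monomer
indices taken modulo X.  Within a set, each distance is harmonically
restrained toward the set mean: deviation D = d - mean, force F = -c*D
along the pair axis, energy 0.5*c*D^2 per entry (the exactly consistent
integrated form).  D4 restraints use the three two-member equalities of the
dihedral tetramer.  Location restraints pin component centers of mass;
gravity terms are a pre-assembly device keeping centers of mass at
reasonable distances.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .structures import Assembly

__all__ = [
    "SymmetryRestraintSet",
    "LocationRestraint",
    "build_cx_restraints",
    "build_d4_restraints",
    "symmetry_energy",
    "location_energy",
    "gravity_terms",
]

DEFAULT_SYMMETRY_FORCE_CONSTANT = 0.005   # kcal/mol/A
DEFAULT_LOCATION_FORCE_CONSTANT = 0.5     # kcal/mol/A
DEFAULT_GRAVITY_ATTRACT = 0.001           # kcal/mol/A^2
DEFAULT_GRAVITY_REPULSE = 1.0             # kcal/mol/A^2


@dataclasses.dataclass
class SymmetryRestraintSet:
    """Distance-equality sets for a symmetric homo-oligomer.

    ``equality_sets`` is an integer array (n_sets, set_size, 4) of entries
    (monomer_a, bead_a, monomer_b, bead_b); bead indices are into each
    monomer's own bead array.  For C_X, set_size == X.
    """

    order: int                       # symmetry order X
    equality_sets: np.ndarray        # (n_sets, set_size, 4) int
    force_constant: float = DEFAULT_SYMMETRY_FORCE_CONSTANT
    label: str = "CX"

    def __post_init__(self) -> None:
        self.equality_sets = np.asarray(self.equality_sets, dtype=int)
        if self.equality_sets.ndim != 3 or self.equality_sets.shape[2] != 4:
            raise ValueError("equality_sets must be (n_sets, set_size, 4)")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")

    @property
    def n_sets(self) -> int:
        return self.equality_sets.shape[0]

    @property
    def set_size(self) -> int:
        return self.equality_sets.shape[1]

    def to_text(self) -> str:
        lines = [f"# symmetry {self.label} order {self.order} c {self.force_constant}"]
        for s in self.equality_sets:
            lines.append(" ".join(f"{a},{b},{c},{d}" for a, b, c, d in s))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SymmetryRestraintSet":
        lines = [l for l in text.splitlines() if l.strip()]
        header = lines[0].split()
        label, order, c = header[2], int(header[4]), float(header[6])
        sets = []
        for line in lines[1:]:
            sets.append([tuple(int(x) for x in entry.split(","))
                         for entry in line.split()])
        return cls(order=order, equality_sets=np.array(sets, dtype=int),
                   force_constant=c, label=label)


@dataclasses.dataclass
class LocationRestraint:
    """Harmonic restraint of one component's center of mass to a target."""

    component: int
    target: np.ndarray                # (3,) Angstrom
    force_constant: float = DEFAULT_LOCATION_FORCE_CONSTANT

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


def build_cx_restraints(
    backbone_beads: Sequence[int],
    order: int,
    monomer_offset: int = 0,
    force_constant: float = DEFAULT_SYMMETRY_FORCE_CONSTANT,
) -> SymmetryRestraintSet:
    """Build C_X distance-equality restraints over identical monomers.

    ``backbone_beads`` lists the bead indices (within one monomer) to pair;
    pairing follows A = C_i, B = C_{p-i} over 1-based i <= p-i.  For each
    pair, equality sets S_k are built for k = 1 .. floor(X/2) (the inclusive
    upper bound, so C2 still gets S_1; for X = 7 this yields the three sets
    S_1, S_2, S_3), each containing the X cyclically shifted distances.
    ``monomer_offset`` shifts monomer indices when an assembly contains
    several rings.
    """
    if order < 2:
        raise ValueError("symmetry order must be >= 2")
    beads = list(backbone_beads)
    p = len(beads)
    if p < 1:
        raise ValueError("need at least one backbone bead")
    if p < 2:
        raise ValueError("pairing A = C_i, B = C_{p-i} needs at least two backbone beads")
    ks = range(1, order // 2 + 1)
    sets = []
    for i in range(1, p // 2 + 1):       # 1-based pairing: A = C_i, B = C_{p-i}, i <= p-i
        j = p - i
        a_bead, b_bead = beads[i - 1], beads[j - 1]
        for k in ks:
            entries = []
            for n in range(order):
                entries.append((monomer_offset + n, a_bead,
                                monomer_offset + (n + k) % order, b_bead))
            sets.append(entries)
    return SymmetryRestraintSet(order=order, equality_sets=np.array(sets, dtype=int),
                                force_constant=force_constant, label=f"C{order}")


def build_d4_restraints(
    backbone_beads: Sequence[int],
    monomer_offset: int = 0,
    force_constant: float = DEFAULT_SYMMETRY_FORCE_CONSTANT,
) -> SymmetryRestraintSet:
    """D4 restraints for a tetramer: per bead pair, the three 2-member
    equalities d(A1,B2)=d(A3,B4); d(A1,B3)=d(A2,B4); d(A1,B4)=d(A2,B3)."""
    beads = list(backbone_beads)
    p = len(beads)
    patterns = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    if p < 2:
        raise ValueError("pairing A = C_i, B = C_{p-i} needs at least two backbone beads")
    sets = []
    for i in range(1, p // 2 + 1):
        j = p - i
        a_bead, b_bead = beads[i - 1], beads[j - 1]
        for pat in patterns:
            entries = [(monomer_offset + m1, a_bead, monomer_offset + m2, b_bead)
                       for m1, m2 in pat]
            sets.append(entries)
    return SymmetryRestraintSet(order=4, equality_sets=np.array(sets, dtype=int),
                                force_constant=force_constant, label="D4")


def _entry_coordinates(assembly: Assembly, coords: Optional[np.ndarray],
                       slices) -> np.ndarray:
    if coords is None:
        coords = assembly.coordinates()
    return coords


def symmetry_energy(
    assembly: Assembly,
    restraints,
    coords: Optional[np.ndarray] = None,
):
    """Energy and per-bead forces of one or several symmetry restraint sets.

    Per equality set the mean distance is computed; each entry's deviation
    D = d - mean contributes 0.5*c*D^2 and a restoring force of magnitude
    c*|D| along the pair axis on both beads (equal and opposite, so total
    linear momentum is conserved).  Accepts a single SymmetryRestraintSet or
    a sequence of them.  Returns (energy, forces) with forces shaped like
    the stacked assembly coordinates.
    """
    if isinstance(restraints, SymmetryRestraintSet):
        restraints = [restraints]
    slices = assembly.component_slices()
    if coords is None:
        coords = assembly.coordinates()
    starts = np.array([s.start for s in slices])
    forces = np.zeros_like(coords)
    energy = 0.0
    for rset in restraints:
        if rset.equality_sets.max(initial=-1) >= 0:
            max_mon = int(rset.equality_sets[..., [0, 2]].max())
            if max_mon >= assembly.n_components:
                raise ValueError("restraint references a missing monomer")
        es = rset.equality_sets
        flat_a = starts[es[..., 0]] + es[..., 1]     # (n_sets, size)
        flat_b = starts[es[..., 2]] + es[..., 3]
        xa = coords[flat_a]
        xb = coords[flat_b]
        delta = xa - xb                              # (n_sets, size, 3)
        d = np.linalg.norm(delta, axis=-1)
        mean = d.mean(axis=1, keepdims=True)
        D = d - mean
        c = rset.force_constant
        energy += 0.5 * c * float((D**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(d[..., None] > 0, delta / np.where(d[..., None] == 0, 1.0,
                                                            d[..., None]), 0.0)
        # dE/dd_e = c*D_e (the mean's dependence cancels); force -c*D along u
        f_pair = (-c * D)[..., None] * u
        np.add.at(forces, flat_a.ravel(), f_pair.reshape(-1, 3))
        np.add.at(forces, flat_b.ravel(), -f_pair.reshape(-1, 3))
    return energy, forces


def _component_com(assembly: Assembly, coords, slices, idx):
    m = assembly.components[idx]
    w = m.bead_weights
    c = coords[slices[idx]]
    return (c * w[:, None]).sum(axis=0) / w.sum(), w


def location_energy(
    assembly: Assembly,
    restraints: Sequence[LocationRestraint],
    coords: Optional[np.ndarray] = None,
):
    """Harmonic center-of-mass location restraints.

    Per restraint: displacement d = COM - target, E = 0.5*k*|d|^2, and the
    restoring force -k*d is distributed over the component's beads in
    proportion to their weights (the exact COM-chain-rule gradient).
    """
    slices = assembly.component_slices()
    if coords is None:
        coords = assembly.coordinates()
    forces = np.zeros_like(coords)
    energy = 0.0
    for r in restraints:
        if not 0 <= r.component < assembly.n_components:
            raise IndexError(f"component {r.component} out of range")
        com, w = _component_com(assembly, coords, slices, r.component)
        d = com - r.target
        energy += 0.5 * r.force_constant * float(d @ d)
        f_total = -r.force_constant * d
        forces[slices[r.component]] += f_total[None, :] * (w / w.sum())[:, None]
    return energy, forces


def gravity_terms(
    assembly: Assembly,
    attract_k: float = DEFAULT_GRAVITY_ATTRACT,
    repulse_radius: Optional[float] = None,
    repulse_k: float = DEFAULT_GRAVITY_REPULSE,
    coords: Optional[np.ndarray] = None,
):
    """Pairwise center-of-mass "gravity": weak long-range harmonic attraction
    plus strong short-range harmonic repulsion inside ``repulse_radius``.

    E_pair = 0.5*attract_k*r^2 + 0.5*repulse_k*(r - r0)^2 for r < r0, with
    r0 defaulting to 0.8 times the sum of the two components' radii of
    gyration.  A purely pre-assembly device keeping components at reasonable
    distances; forces are equal and opposite.
    """
    n = assembly.n_components
    if n < 2:
        return 0.0, np.zeros((sum(m.n_beads for m in assembly.components), 3))
    if coords is None:
        coords = assembly.coordinates()
    counts = [m.n_beads for m in assembly.components]
    bead_comp = np.repeat(np.arange(n), counts)
    w = np.concatenate([m.bead_weights for m in assembly.components])
    wsum = np.bincount(bead_comp, weights=w, minlength=n)
    coms = np.empty((n, 3))
    for d in range(3):
        coms[:, d] = np.bincount(bead_comp, w * coords[:, d], minlength=n)
    coms /= wsum[:, None]
    # rigid bodies: radii of gyration are pose-invariant model properties,
    # so the default repulsion radius is a constant (exact gradients)
    rgs = np.array([m.radius_of_gyration() for m in assembly.components])
    ii, jj = np.triu_indices(n, k=1)
    dvec = coms[ii] - coms[jj]
    r = np.linalg.norm(dvec, axis=1)
    r0 = (np.full_like(r, repulse_radius) if repulse_radius is not None
          else 0.8 * (rgs[ii] + rgs[jj]))
    e = 0.5 * attract_k * r**2
    f_mag = -attract_k * r                      # radial dE/dr, sign flipped
    close = r < r0
    e[close] += 0.5 * repulse_k * (r[close] - r0[close]) ** 2
    f_mag[close] += -repulse_k * (r[close] - r0[close])
    energy = float(e.sum())
    with np.errstate(invalid="ignore"):
        u = np.where(r[:, None] > 0, dvec / np.where(r[:, None] == 0, 1.0, r[:, None]), 0.0)
    f_pair = f_mag[:, None] * u                 # force on component i (on j: -f)
    comp_force = np.zeros((n, 3))
    np.add.at(comp_force, ii, f_pair)
    np.add.at(comp_force, jj, -f_pair)
    forces = comp_force[bead_comp] * (w / wsum[bead_comp])[:, None]
    return energy, forces
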