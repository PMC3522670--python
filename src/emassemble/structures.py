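"""Coordinate I/O, coarse-graining, rigid transforms and RMSD metrics.

Subunits are represented as coarse-grained bead models (one backbone bead
at the C-alpha position plus one sidechain bead at the sidechain heavy-atom
centroid by default).  Poses are proper rigid transforms; an assembly is a
list of (model, pose) pairs.  All RMSD flavours used to evaluate assemblies
live here: plain unfitted RMSD, least-squares superposition, and the
pairwise "ligand RMSD" that measures relative component placement.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomicStructure",
    "CoarseModel",
    "RigidPose",
    "Assembly",
    "read_pdb",
    "write_pdb",
    "coarse_grain",
    "apply_pose",
    "superpose",
    "rmsd",
    "ligand_rmsd",
]

_ORTHO_TOL = 1e-8

# Backbone heavy atoms folded into the backbone bead.
_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclasses.dataclass
class AtomicStructure:
    """Flat arrays of atoms parsed from a PDB file (1-based residue numbering)."""

    names: np.ndarray          # atom names, str
    elements: np.ndarray       # element symbols, str
    chains: np.ndarray         # chain identifiers, str
    res_names: np.ndarray      # residue names, str
    res_seq: np.ndarray        # residue sequence numbers, int (as in the file)
    coords: np.ndarray         # (n, 3) float, Angstrom

    def __len__(self) -> int:
        return len(self.names)

    def transformed(self, pose: "RigidPose") -> "AtomicStructure":
        return dataclasses.replace(self, coords=pose.apply(self.coords))


@dataclasses.dataclass
class CoarseModel:
    """A subunit as weighted beads in its own reference frame.

    ``bead_kinds`` distinguishes backbone ('BB') from sidechain ('SC') beads;
    symmetry restraints pair backbone beads only.  Weights are summed atomic
    masses of the atoms each bead represents.
    """

    bead_positions: np.ndarray   # (n, 3) float, Angstrom
    bead_weights: np.ndarray     # (n,) float, > 0
    bead_kinds: np.ndarray       # (n,) str, 'BB' | 'SC'
    residue_index: np.ndarray    # (n,) int
    name: str = "model"

    def __post_init__(self) -> None:
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        self.bead_weights = np.asarray(self.bead_weights, dtype=float)
        self.bead_kinds = np.asarray(self.bead_kinds)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.bead_positions.ndim != 2 or self.bead_positions.shape[1] != 3:
            raise ValueError("bead_positions must be (n, 3)")
        n = len(self.bead_positions)
        if n < 1:
            raise ValueError("a coarse model needs at least one bead")
        if not np.all(np.isfinite(self.bead_positions)):
            raise ValueError("non-finite bead position")
        if len(self.bead_weights) != n or np.any(self.bead_weights <= 0):
            raise ValueError("bead weights must be positive and match bead count")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def total_weight(self) -> float:
        return float(self.bead_weights.sum())

    @property
    def backbone_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bead_kinds == "BB")

    def center_of_mass(self) -> np.ndarray:
        w = self.bead_weights
        return (self.bead_positions * w[:, None]).sum(axis=0) / w.sum()

    def radius_of_gyration(self) -> float:
        cached = getattr(self, "_rg_cache", None)
        if cached is None:
            d = self.bead_positions - self.center_of_mass()
            w = self.bead_weights
            cached = float(np.sqrt((w * (d * d).sum(axis=1)).sum() / w.sum()))
            object.__setattr__(self, "_rg_cache", cached)
        return cached

    def to_table(self) -> str:
        """Whitespace-delimited text table: x y z weight kind residue."""
        lines = ["# x y z weight kind residue"]
        for p, w, k, r in zip(
            self.bead_positions, self.bead_weights, self.bead_kinds, self.residue_index
        ):
            lines.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {w:.4f} {k} {r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, name: str = "model") -> "CoarseModel":
        pos, wts, kinds, res = [], [], [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            x, y, z, w, k, r = line.split()
            pos.append([float(x), float(y), float(z)])
            wts.append(float(w))
            kinds.append(k)
            res.append(int(r))
        return cls(np.array(pos), np.array(wts), np.array(kinds), np.array(res), name)


class RigidPose:
    """A proper rigid transform x' = R.x + t (rotation then translation)."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation: np.ndarray = None, translation: np.ndarray = None):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL * 10):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def _unchecked(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidPose":
        """Internal fast path for matrices already known to be proper rotations."""
        obj = object.__new__(cls)
        obj.rotation = rotation
        obj.translation = translation
        return obj

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return the pose equivalent to applying ``other`` first, then self."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def copy(self) -> "RigidPose":
        return RigidPose._unchecked(self.rotation.copy(), self.translation.copy())

    def __repr__(self) -> str:
        return f"RigidPose(t={np.round(self.translation, 3)})"


class Assembly:
    """Subunits plus their poses, with an optional per-term energy record."""

    def __init__(
        self,
        components: Sequence[CoarseModel],
        poses: Optional[Sequence[RigidPose]] = None,
        energies: Optional[dict] = None,
    ):
        if len(components) < 1:
            raise ValueError("an assembly needs at least one component")
        self.components = list(components)
        if poses is None:
            poses = [RigidPose.identity() for _ in components]
        if len(poses) != len(components):
            raise ValueError("one pose per component required")
        self.poses = list(poses)
        self.energies = dict(energies) if energies else {}

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_slices(self) -> list[slice]:
        out, start = [], 0
        for m in self.components:
            out.append(slice(start, start + m.n_beads))
            start += m.n_beads
        return out

    def coordinates(self) -> np.ndarray:
        """Stacked placed bead coordinates, component order preserved."""
        return np.vstack(
            [pose.apply(m.bead_positions) for m, pose in zip(self.components, self.poses)]
        )

    def weights(self) -> np.ndarray:
        return np.concatenate([m.bead_weights for m in self.components])

    @property
    def total_weight(self) -> float:
        return float(sum(m.total_weight for m in self.components))

    def copy(self) -> "Assembly":
        return Assembly(self.components, [p.copy() for p in self.poses], dict(self.energies))


# ---------------------------------------------------------------------------
# PDB I/O

def read_pdb(path, chain_filter: Optional[str] = None) -> AtomicStructure:
    """Read ATOM/HETATM records from a PDB file.

    ``chain_filter`` may be a single chain id or an iterable of ids; atoms of
    other chains are dropped.  Raises on a missing file, on malformed
    coordinate fields (naming the offending line), and when no atoms survive
    the filter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if chain_filter is not None and isinstance(chain_filter, str):
        chain_filter = {chain_filter}
    elif chain_filter is not None:
        chain_filter = set(chain_filter)

    names, elements, chains, res_names, res_seq, coords = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            chain = line[21].strip()
            if chain_filter is not None and chain not in chain_filter:
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed coordinate field on line {lineno}"
                ) from exc
            name = line[12:16].strip()
            element = line[76:78].strip()
            if not element:
                # Fall back to the leading letter of the atom name.
                element = "".join(c for c in name if c.isalpha())[:1]
            names.append(name)
            elements.append(element.capitalize())
            chains.append(chain)
            res_names.append(line[17:20].strip())
            try:
                res_seq.append(int(line[22:26]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed residue number on line {lineno}"
                ) from exc
            coords.append((x, y, z))
    if not names:
        raise ValueError(f"{path}: no atoms" + (" after chain filter" if chain_filter else ""))
    return AtomicStructure(
        names=np.array(names),
        elements=np.array(elements),
        chains=np.array(chains),
        res_names=np.array(res_names),
        res_seq=np.array(res_seq, dtype=int),
        coords=np.array(coords, dtype=float),
    )


def write_pdb(path, coords: np.ndarray, names=None, res_names=None, chains=None,
              res_seq=None, elements=None) -> None:
    """Write bare ATOM records; missing metadata falls back to generic beads."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names if names is not None else ["CA"] * n
    res_names = res_names if res_names is not None else ["BEA"] * n
    chains = chains if chains is not None else ["A"] * n
    res_seq = res_seq if res_seq is not None else np.arange(1, n + 1)
    elements = elements if elements is not None else ["C"] * n
    with open(path, "w") as fh:
        for i in range(n):
            x, y, z = coords[i]
            fh.write(
                f"ATOM  {i + 1:>5d} {names[i]:<4s}{res_names[i]:<3s} "
                f"{chains[i]:1s}{int(res_seq[i]):>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elements[i]:>2s}\n"
            )
        fh.write("END\n")


def _atomic_mass(element: str) -> float:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element {element!r}")
    return float(el.weight)


def coarse_grain(structure: AtomicStructure, scheme: str = "calpha+sidechain-centroid"):
    """Reduce an atomic structure to a CoarseModel.

    Default scheme: per residue, one backbone bead at the C-alpha position
    (weight = summed backbone heavy-atom masses) and one sidechain bead at the
    sidechain heavy-atom centroid (weight = summed sidechain masses); glycine
    gets a backbone bead only.  The 'all-atom' scheme passes every heavy atom
    through as its own bead.  Returns ``(model, n_skipped)`` where n_skipped
    counts residues without a C-alpha atom.
    """
    if scheme == "all-atom":
        heavy = structure.elements != "H"
        model = CoarseModel(
            bead_positions=structure.coords[heavy],
            bead_weights=np.array([_atomic_mass(e) for e in structure.elements[heavy]]),
            bead_kinds=np.where(np.isin(structure.names[heavy], list(_BACKBONE_ATOMS)), "BB", "SC"),
            residue_index=structure.res_seq[heavy],
        )
        return model, 0
    if scheme != "calpha+sidechain-centroid":
        raise ValueError(f"unknown coarse-grain scheme {scheme!r}")

    positions, weights, kinds, res_idx = [], [], [], []
    n_skipped = 0
    # Group atoms by (chain, residue number) preserving order of appearance.
    keys = list(zip(structure.chains, structure.res_seq))
    seen, order = set(), []
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    index = {k: [] for k in order}
    for i, k in enumerate(keys):
        index[k].append(i)
    for k in order:
        idx = np.array(index[k])
        names = structure.names[idx]
        elems = structure.elements[idx]
        heavy = elems != "H"
        idx, names, elems = idx[heavy], names[heavy], elems[heavy]
        ca = idx[names == "CA"]
        if len(ca) == 0:
            n_skipped += 1
            continue
        backbone = np.isin(names, list(_BACKBONE_ATOMS))
        bb_mass = sum(_atomic_mass(e) for e in elems[backbone])
        positions.append(structure.coords[ca[0]])
        weights.append(bb_mass)
        kinds.append("BB")
        res_idx.append(k[1])
        side = ~backbone
        if side.any():
            sc_coords = structure.coords[idx[side]]
            sc_mass = sum(_atomic_mass(e) for e in elems[side])
            positions.append(sc_coords.mean(axis=0))
            weights.append(sc_mass)
            kinds.append("SC")
            res_idx.append(k[1])
    if not positions:
        raise ValueError("no residues with a C-alpha atom")
    model = CoarseModel(
        bead_positions=np.array(positions),
        bead_weights=np.array(weights),
        bead_kinds=np.array(kinds),
        residue_index=np.array(res_idx, dtype=int),
    )
    return model, n_skipped


# ---------------------------------------------------------------------------
# Transforms and metrics

def apply_pose(model: CoarseModel, pose: RigidPose) -> np.ndarray:
    """Placed bead coordinates x' = R.x + t."""
    return pose.apply(model.bead_positions)


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns ``(pose, rmsd)`` where ``pose.apply(mobile)`` best fits ``target``.
    Reflections are excluded (det = +1).  Degenerate inputs (< 3 points or a
    collinear point set) raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point counts differ")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points to superpose")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    A = mobile - mc
    B = target - tc
    # Collinearity check: a rank-deficient covariance leaves a free rotation.
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    pose = RigidPose(R, t)
    fitted = pose.apply(mobile)
    return pose, rmsd(fitted, target)


def rmsd(model_coords: np.ndarray, reference_coords: np.ndarray) -> float:
    """Plain unfitted root-mean-square deviation over matched points."""
    a = np.asarray(model_coords, dtype=float)
    b = np.asarray(reference_coords, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    d = a - b
    return float(np.sqrt((d * d).sum() / len(a)))


def assembly_rmsd(model: Assembly, reference: Assembly) -> float:
    """Unfitted RMSD over all beads of two assemblies in matched component order."""
    return rmsd(model.coordinates(), reference.coordinates())


def ligand_rmsd(model: Assembly, reference: Assembly, pairs) -> float:
    """Average pairwise ligand RMSD over (receptor, ligand) component pairs.

    For each pair the model receptor is least-squares fitted onto the
    reference receptor, the fitted transform is applied to the model ligand,
    and the unfitted RMSD of the ligand is measured; the mean over all pairs
    is returned.  This measures relative, not absolute, placement.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    vals = []
    for rec, lig in pairs:
        if not (0 <= rec < model.n_components and 0 <= lig < model.n_components):
            raise IndexError(f"pair ({rec}, {lig}) out of range")
        m_rec = model.poses[rec].apply(model.components[rec].bead_positions)
        r_rec = reference.poses[rec].apply(reference.components[rec].bead_positions)
        fit, _ = superpose(m_rec, r_rec)
        m_lig = fit.apply(model.poses[lig].apply(model.components[lig].bead_positions))
        r_lig = reference.poses[lig].apply(reference.components[lig].bead_positions)
        vals.append(rmsd(m_lig, r_lig))
    return float(np.mean(vals))
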