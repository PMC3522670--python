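"""Stand-in coarse-grained intermolecular potential for refinement stages.

A soft 8-6 pair potential between beads of different components:

    V(r) = depth * (3*(rmin/r)**8 - 4*(rmin/r)**6)

which has its minimum V(rmin) = -depth at r = rmin.  Interactions are
smoothly switched off between ``switch_start`` and ``cutoff``.  A single
generic bead type is the default; per-kind parameter tables can be loaded
from a simple text format.  This is a stand-in packing potential: the
refinement stages need short-range attraction/repulsion between subunits,
not any particular published parameterisation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Assembly

__all__ = ["PairPotentialParams", "intermolecular_energy"]


@dataclasses.dataclass
class PairPotentialParams:
    """Per-bead-kind 8-6 parameters; ``radii``/``depths`` map kind -> value.

    ``default_radius`` is the pair minimum-energy distance rmin (Angstrom)
    used when a kind has no entry; pair rmin is the arithmetic mean of the
    two kinds' radii, pair depth the geometric mean.
    """

    default_radius: float = 6.0       # Angstrom; bead-sized packing distance
    default_depth: float = 0.1        # kcal/mol
    radii: dict = dataclasses.field(default_factory=dict)
    depths: dict = dataclasses.field(default_factory=dict)
    cutoff: float = 15.0              # Angstrom
    switch_start: float = 12.0        # switching region start

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be positive")
        if self.default_depth < 0 or any(d < 0 for d in self.depths.values()):
            raise ValueError("well depths must be non-negative")
        if not 0 < self.switch_start < self.cutoff:
            raise ValueError("require 0 < switch_start < cutoff")

    def radius_of(self, kind: str) -> float:
        return self.radii.get(kind, self.default_radius)

    def depth_of(self, kind: str) -> float:
        return self.depths.get(kind, self.default_depth)

    @classmethod
    def from_text(cls, text: str, **kwargs) -> "PairPotentialParams":
        """Parse 'kind radius depth' lines into per-kind tables."""
        radii, depths = {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, r, d = line.split()
            radii[kind] = float(r)
            depths[kind] = float(d)
        return cls(radii=radii, depths=depths, **kwargs)


def _switch(r: np.ndarray, r_on: float, r_off: float):
    """Quintic switching function S (1 below r_on, 0 above r_off) and dS/dr."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    x = (r[mid] - r_on) / (r_off - r_on)
    s[mid] = 1 - x**3 * (10 - 15 * x + 6 * x**2)
    ds[mid] = -(30 * x**2 - 60 * x**3 + 30 * x**4) / (r_off - r_on)
    s[r >= r_off] = 0.0
    return s, ds


def intermolecular_energy(
    assembly: Assembly,
    params: Optional[PairPotentialParams] = None,
    weight: float = 1.0,
    coords: Optional[np.ndarray] = None,
):
    """Soft 8-6 energy and forces over all inter-component bead pairs.

    Component pairs whose bounding spheres are farther apart than the cutoff
    are skipped.  ``weight`` scales both energy and forces (stage schedules
    use 0.01 -> 1).  Pairwise forces are equal and opposite; there are no
    intra-component terms (rigid bodies).
    """
    if params is None:
        params = PairPotentialParams()
    slices = assembly.component_slices()
    if coords is None:
        coords = assembly.coordinates()
    forces = np.zeros_like(coords)
    if weight == 0.0 or assembly.n_components < 2:
        return 0.0, forces
    kinds = [np.asarray(m.bead_kinds) for m in assembly.components]
    missing = {k for ks in kinds for k in np.unique(ks)
               if k not in params.radii and params.default_radius is None}
    if missing:
        raise KeyError(f"no pair parameters for bead kinds {sorted(missing)}")
    rmins = [np.array([params.radius_of(k) for k in ks]) for ks in kinds]
    deps = [np.array([params.depth_of(k) for k in ks]) for ks in kinds]

    centers = [coords[s].mean(axis=0) for s in slices]
    radii = [np.linalg.norm(coords[s] - c, axis=1).max() for s, c in zip(slices, centers)]
    energy = 0.0
    n = assembly.n_components
    for i in range(n):
        for j in range(i + 1, n):
            if (np.linalg.norm(centers[i] - centers[j])
                    > radii[i] + radii[j] + params.cutoff):
                continue
            ci, cj = coords[slices[i]], coords[slices[j]]
            d = cdist(ci, cj)
            within = d < params.cutoff
            if not within.any():
                continue
            ii, jj = np.nonzero(within)
            r = d[ii, jj]
            r = np.maximum(r, 1e-6)
            rm = 0.5 * (rmins[i][ii] + rmins[j][jj])
            eps = np.sqrt(deps[i][ii] * deps[j][jj])
            q6 = (rm / r) ** 6
            q8 = q6 * (rm / r) ** 2
            v = eps * (3 * q8 - 4 * q6)
            dv = eps * (-24 * q8 + 24 * q6) / r       # dV/dr
            s, ds = _switch(r, params.switch_start, params.cutoff)
            e_pair = v * s
            de_dr = dv * s + v * ds
            energy += float(e_pair.sum())
            u = (ci[ii] - cj[jj]) / r[:, None]
            f = (-de_dr)[:, None] * u                  # force on bead i
            np.add.at(forces, np.arange(*slices[i].indices(len(coords)))[ii], f)
            np.add.at(forces, np.arange(*slices[j].indices(len(coords)))[jj], -f)
    return weight * energy, weight * forces
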