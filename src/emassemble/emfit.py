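"""The Gaussian-overlap cryo-EM fitting energy and voxel atom-density clash term.

Every bead and every map voxel is an isotropic Gaussian.  The overlap of two
Gaussians is itself a Gaussian of the inter-center distance D:

    O(D) = A1 * A2 * (pi / (s1 + s2))**1.5 * exp(-(s1*s2/(s1+s2)) * D**2)

with decay factors s = 1/(2 sigma^2).  Summing a probe atom's overlap over
ALL map voxels (far voxels contribute non-negligibly) is precomputed once
per map voxel; at run time an atom's overlap is obtained by trilinear
interpolation among its eight neighbouring voxels.  The same trilinear
weights fractionally deposit bead weights into the "voxel atom density"
grid used for the clash penalty and for gradient-vector-matching.

The fitting energy is a harmonic penalty on the *deficiency* of each bead's
overlap relative to its calibrated maximum: a hard penalty below the bead's
own-map maximum (F = 1) and a soft penalty below F times it, F >= 1 being
the intermolecular-spillover factor.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import scipy.signal

from .densmap import DensityGrid, GaussianParams, deconvolve, simulate_map
from .structures import Assembly, CoarseModel

__all__ = [
    "OverlapGrid",
    "MaxOverlapTable",
    "VoxelDensityGrid",
    "gaussian_overlap",
    "precompute_overlap_grid",
    "interpolate_overlap",
    "calibrate_max_overlap",
    "build_assembly_table",
    "save_overlap_grid",
    "load_overlap_grid",
    "em_fit_energy",
    "accumulate_voxel_density",
    "density_clash_energy",
    "EmFitWeights",
]

# Default hard/soft penalty ratio ("large" vs "much smaller" violation penalty).
DEFAULT_K_HARD = 100.0
DEFAULT_K_SOFT = 1.0
DEFAULT_K_CLASH = 1.0


def gaussian_overlap(D, g1: GaussianParams, g2: GaussianParams):
    """Closed-form 3D integral of the product of two isotropic Gaussians.

    Returns ``(O, dO_dD)``.  The Cartesian derivative along axis d is
    ``O * (-2 * s1*s2/(s1+s2)) * delta_d`` for separation vector delta.
    """
    s1, s2 = g1.s, g2.s
    ssum = s1 + s2
    if ssum == 0:
        raise ValueError("degenerate decay factors (s1 + s2 = 0)")
    gamma = s1 * s2 / ssum
    D = np.asarray(D, dtype=float)
    O = g1.amplitude * g2.amplitude * (np.pi / ssum) ** 1.5 * np.exp(-gamma * D**2)
    dO_dD = -2.0 * gamma * D * O
    return O, dO_dD


def pair_overlap_gradient(delta, g1: GaussianParams, g2: GaussianParams):
    """Overlap and its Cartesian gradient for separation vector(s) ``delta``."""
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    D = np.linalg.norm(delta, axis=-1)
    O, _ = gaussian_overlap(D, g1, g2)
    gamma = g1.s * g2.s / (g1.s + g2.s)
    grad = (-2.0 * gamma) * delta * O[..., None]
    return np.squeeze(O), np.squeeze(grad)


@dataclasses.dataclass
class OverlapGrid:
    """Precomputed probe-atom overlap O and its analytic derivatives per voxel.

    ``gradient`` holds (dO/dx, dO/dy, dO/dz); ``mixed`` optionally holds the
    analytic mixed partials (Oxy, Oxz, Oyz, Oxyz) that upgrade cell
    interpolation from gradient-corrected to full tricubic Hermite.
    """

    grid: DensityGrid                 # O values, co-registered with the map
    gradient: np.ndarray              # (nx, ny, nz, 3) analytic dO/dxyz
    atom_params: GaussianParams       # probe-atom Gaussian
    mixed: Optional[np.ndarray] = None   # (nx, ny, nz, 4): Oxy, Oxz, Oyz, Oxyz

    @property
    def origin(self) -> np.ndarray:
        return self.grid.origin

    @property
    def voxel_size(self) -> float:
        return self.grid.voxel_size

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def save_overlap_grid(path, ogrid: "OverlapGrid") -> None:
    """Serialize an overlap grid (values, gradient, mixed partials and the
    geometry header) to a NumPy .npz container."""
    np.savez_compressed(
        path,
        origin=ogrid.grid.origin,
        voxel_size=ogrid.grid.voxel_size,
        values=ogrid.values,
        gradient=ogrid.gradient,
        mixed=ogrid.mixed if ogrid.mixed is not None else np.zeros(0),
        atom_sigma=ogrid.atom_params.sigma,
        atom_amplitude=ogrid.atom_params.amplitude,
    )


def load_overlap_grid(path) -> "OverlapGrid":
    with np.load(path) as z:
        grid = DensityGrid(z["origin"], float(z["voxel_size"]), z["values"])
        mixed = z["mixed"] if z["mixed"].size else None
        return OverlapGrid(grid=grid, gradient=z["gradient"],
                           atom_params=GaussianParams(float(z["atom_sigma"]),
                                                      float(z["atom_amplitude"])),
                           mixed=mixed)


@dataclasses.dataclass
class MaxOverlapTable:
    """Per-bead maximum (own-map) overlap per component, plus the F factor."""

    per_component: list               # list of (n_beads,) arrays
    F: float = 1.0

    def __post_init__(self) -> None:
        if self.F < 1.0:
            raise ValueError("spillover factor F must be >= 1")
        for vals in self.per_component:
            if np.any(np.asarray(vals) <= 0):
                raise ValueError("maximum overlap values must be positive")

    def concatenated(self) -> np.ndarray:
        return np.concatenate([np.asarray(v, dtype=float) for v in self.per_component])

    def to_text(self) -> str:
        """Whitespace table: component index, bead index, maximum overlap."""
        lines = [f"# F {self.F}"]
        for ci, vals in enumerate(self.per_component):
            for bi, v in enumerate(np.asarray(vals, dtype=float)):
                lines.append(f"{ci} {bi} {v:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MaxOverlapTable":
        F = 1.0
        per = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if "F" in parts:
                    F = float(parts[parts.index("F") + 1])
                continue
            ci, bi, v = line.split()
            per.setdefault(int(ci), []).append((int(bi), float(v)))
        comps = []
        for ci in sorted(per):
            comps.append(np.array([v for _, v in sorted(per[ci])]))
        return cls(per_component=comps, F=F)


@dataclasses.dataclass
class VoxelDensityGrid:
    """Accumulated fractional bead weights per voxel ("voxel atom density")."""

    grid: DensityGrid
    n_outside: int = 0                # beads that fell off the grid
    max_density: Optional[float] = None


@dataclasses.dataclass
class EmFitWeights:
    k_hard: float = DEFAULT_K_HARD
    k_soft: float = DEFAULT_K_SOFT


# ---------------------------------------------------------------------------
# Precomputation

def precompute_overlap_grid(density: DensityGrid, atom_params: GaussianParams,
                            voxel_params: Optional[GaussianParams] = None) -> OverlapGrid:
    """Precompute, for every voxel, the overlap of a probe atom at that voxel
    center with the ENTIRE map (full summation over all voxel Gaussians, not
    truncated), plus the Cartesian gradient of that overlap.

    Voxel Gaussian amplitudes are proportional to the voxel density values;
    the proportionality constant cancels in calibrated deficiencies.  The
    summation is a discrete convolution with the pair-overlap kernel and is
    evaluated exactly via FFT convolution with a full-extent kernel.
    """
    if voxel_params is None:
        voxel_params = GaussianParams(atom_params.sigma, 1.0)
    s1, s2 = atom_params.s, voxel_params.s
    gamma = s1 * s2 / (s1 + s2)
    C = atom_params.amplitude * voxel_params.amplitude * (np.pi / (s1 + s2)) ** 1.5

    shape = density.values.shape
    h = density.voxel_size
    # Separable full-extent kernel over offsets -(n-1) .. n-1 per axis.
    axes = [h * np.arange(-(n - 1), n) for n in shape]
    g1d = [np.exp(-gamma * a**2) for a in axes]
    kernel = C * g1d[0][:, None, None] * g1d[1][None, :, None] * g1d[2][None, None, :]
    O = scipy.signal.fftconvolve(density.values, kernel, mode="same")
    O = np.clip(O, 0.0, None)

    def _axis_factor(d, power1=True):
        sl = [None, None, None]
        sl[d] = slice(None)
        return (-2.0 * gamma * axes[d])[tuple(sl)]

    grad = np.empty(shape + (3,))
    for d in range(3):
        grad[..., d] = scipy.signal.fftconvolve(
            density.values, kernel * _axis_factor(d), mode="same")

    # Exact mixed partials of the kernel: each differentiation multiplies by
    # (-2*gamma*offset) along that axis.  They feed tricubic interpolation.
    mixed = np.empty(shape + (4,))
    for m, (a, b) in enumerate([(0, 1), (0, 2), (1, 2)]):
        mixed[..., m] = scipy.signal.fftconvolve(
            density.values, kernel * _axis_factor(a) * _axis_factor(b), mode="same")
    mixed[..., 3] = scipy.signal.fftconvolve(
        density.values,
        kernel * _axis_factor(0) * _axis_factor(1) * _axis_factor(2), mode="same")

    ogrid = DensityGrid(density.origin.copy(), density.voxel_size, O,
                        density.resolution_label)
    return OverlapGrid(grid=ogrid, gradient=grad, atom_params=atom_params,
                       mixed=mixed)


# ---------------------------------------------------------------------------
# Trilinear interpolation

def _trilinear_ingredients(ogrid_geometry: DensityGrid, positions: np.ndarray):
    """Cell indices, fractional offsets and clamp mask for world positions.

    Positions outside the grid interior are clamped into the boundary cell;
    the returned mask flags them.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    g = ogrid_geometry.world_to_grid(pos)
    shape = np.array(ogrid_geometry.values.shape)
    hi = shape - 1
    eps = 1e-9
    clamped = np.clip(g, 0.0, hi - eps)
    outside = np.any((g < 0.0) | (g > hi), axis=1)
    i0 = np.floor(clamped).astype(int)
    i0 = np.minimum(i0, shape - 2)
    f = clamped - i0
    return i0, f, outside


_CORNERS = np.array([(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)])


def _corner_weights(f: np.ndarray):
    """Trilinear weights (n, 8) and their position-gradients (n, 8, 3)."""
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    wx = np.stack([1 - fx, fx], axis=1)
    wy = np.stack([1 - fy, fy], axis=1)
    wz = np.stack([1 - fz, fz], axis=1)
    dwx = np.stack([-np.ones_like(fx), np.ones_like(fx)], axis=1)
    w = (wx[:, _CORNERS[:, 0]] * wy[:, _CORNERS[:, 1]] * wz[:, _CORNERS[:, 2]])
    dw = np.empty(w.shape + (3,))
    dw[..., 0] = dwx[:, _CORNERS[:, 0]] * wy[:, _CORNERS[:, 1]] * wz[:, _CORNERS[:, 2]]
    dw[..., 1] = wx[:, _CORNERS[:, 0]] * dwx[:, _CORNERS[:, 1]] * wz[:, _CORNERS[:, 2]]
    dw[..., 2] = wx[:, _CORNERS[:, 0]] * wy[:, _CORNERS[:, 1]] * dwx[:, _CORNERS[:, 2]]
    return w, dw


def _hermite_bases(t: np.ndarray):
    """Cubic Hermite basis values and derivatives for fractions t in [0, 1].

    Returns (A, B, dA, dB) each shaped (n, 2): column s is the basis for the
    corner on side s (0 = lower, 1 = upper); A weights corner values, B
    (times the cell size) weights corner derivatives.
    """
    t2, t3 = t * t, t * t * t
    A = np.stack([2 * t3 - 3 * t2 + 1, 3 * t2 - 2 * t3], axis=-1)
    B = np.stack([t3 - 2 * t2 + t, t3 - t2], axis=-1)
    dA = np.stack([6 * t2 - 6 * t, 6 * t - 6 * t2], axis=-1)
    dB = np.stack([3 * t2 - 4 * t + 1, 3 * t2 - 2 * t], axis=-1)
    return A, B, dA, dB


def _hermite_interp(ogrid: OverlapGrid, positions: np.ndarray):
    """Tricubic Hermite interpolation of O from the 8 corner values,
    analytic gradients and (when stored) analytic mixed partials, plus the
    EXACT spatial gradient of that interpolant.  Clamped out-of-grid
    positions get the boundary-cell behaviour.
    """
    i0, f, outside = _trilinear_ingredients(ogrid.grid, positions)
    h = ogrid.voxel_size
    idx = i0[:, None, :] + _CORNERS[None, :, :]
    ix, iy, iz = idx[..., 0], idx[..., 1], idx[..., 2]
    Ov = ogrid.values[ix, iy, iz]                 # (n, 8)
    Gv = ogrid.gradient[ix, iy, iz]               # (n, 8, 3)
    if ogrid.mixed is not None:
        Mv = ogrid.mixed[ix, iy, iz]              # (n, 8, 4)
        mxy, mxz, myz, mxyz = (Mv[..., 0], Mv[..., 1], Mv[..., 2], Mv[..., 3])
    else:
        mxy = mxz = myz = mxyz = 0.0
    bases = [_hermite_bases(f[:, d]) for d in range(3)]
    cs = _CORNERS
    Ax = bases[0][0][:, cs[:, 0]]; Bx = bases[0][1][:, cs[:, 0]]
    Ay = bases[1][0][:, cs[:, 1]]; By = bases[1][1][:, cs[:, 1]]
    Az = bases[2][0][:, cs[:, 2]]; Bz = bases[2][1][:, cs[:, 2]]
    dAx = bases[0][2][:, cs[:, 0]]; dBx = bases[0][3][:, cs[:, 0]]
    dAy = bases[1][2][:, cs[:, 1]]; dBy = bases[1][3][:, cs[:, 1]]
    dAz = bases[2][2][:, cs[:, 2]]; dBz = bases[2][3][:, cs[:, 2]]
    gx, gy, gz = Gv[..., 0], Gv[..., 1], Gv[..., 2]

    def combine(fx_basis, fy_basis, fz_basis, gx_basis, gy_basis, gz_basis):
        """Tensor contraction with the x-axis bases swapped in for value vs
        derivative terms; used for both O and dO/dx-style outputs."""
        return (fx_basis * fy_basis * fz_basis * Ov
                + h * (gx_basis * fy_basis * fz_basis * gx
                       + fx_basis * gy_basis * fz_basis * gy
                       + fx_basis * fy_basis * gz_basis * gz)
                + h * h * (gx_basis * gy_basis * fz_basis * mxy
                           + gx_basis * fy_basis * gz_basis * mxz
                           + fx_basis * gy_basis * gz_basis * myz)
                + h * h * h * gx_basis * gy_basis * gz_basis * mxyz).sum(axis=1)

    O = combine(Ax, Ay, Az, Bx, By, Bz)
    G = np.empty((len(O), 3))
    G[:, 0] = combine(dAx, Ay, Az, dBx, By, Bz) / h
    G[:, 1] = combine(Ax, dAy, Az, Bx, dBy, Bz) / h
    G[:, 2] = combine(Ax, Ay, dAz, Bx, By, dBz) / h
    return O, G, outside


def interpolate_overlap(ogrid: OverlapGrid, positions: np.ndarray,
                        method: str = "hermite"):
    """Interpolate O and its gradient at world positions from the 8
    neighbouring voxels' precomputed values and analytic gradients.

    The default 'hermite' method is a tensor-product cubic Hermite
    combination of both the values and the gradients, which tracks the full
    summation closely on ratio-4 grids; 'trilinear' is the plain weighted
    mean of corner values/gradients.  Returns ``(O, gradient, weights,
    outside)`` where ``weights`` are always the eight fractional trilinear
    weights (summing to 1; reused for voxel atom density) and ``outside``
    flags clamped out-of-grid positions.
    """
    single = np.asarray(positions).ndim == 1
    i0, f, outside = _trilinear_ingredients(ogrid.grid, positions)
    w, _ = _corner_weights(f)
    if method == "hermite":
        O, G, _ = _hermite_interp(ogrid, positions)
    elif method == "trilinear":
        idx = i0[:, None, :] + _CORNERS[None, :, :]
        Ov = ogrid.values[idx[..., 0], idx[..., 1], idx[..., 2]]
        Gv = ogrid.gradient[idx[..., 0], idx[..., 1], idx[..., 2]]
        O = (w * Ov).sum(axis=1)
        G = (w[..., None] * Gv).sum(axis=1)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    if single:
        return O[0], G[0], w[0], bool(outside[0])
    return O, G, w, outside


def _interp_value_and_exact_grad(ogrid: OverlapGrid, positions: np.ndarray):
    """Interpolant used by the fitting energy: Hermite O and its exact
    spatial gradient (so analytic forces match finite differences)."""
    return _hermite_interp(ogrid, positions)


# ---------------------------------------------------------------------------
# Calibration and energy

def calibrate_max_overlap(
    model: CoarseModel,
    resolution: float,
    voxel_size: Optional[float] = None,
    apply_deconvolution: bool = False,
    F: float = 1.0,
    padding: Optional[float] = None,
) -> tuple:
    """Calibrate each bead's maximum overlap from the component's own map.

    Simulates the component's density map at the working resolution,
    optionally deconvolves it, precomputes its overlap grid and records each
    bead's interpolated overlap at its own (reference-frame) position.
    Returns ``(table, overlap_grid)``; the table holds one value per bead.
    """
    atom = GaussianParams.from_resolution(resolution)
    own = simulate_map(model, resolution, voxel_size=voxel_size, padding=padding)
    if apply_deconvolution:
        own = deconvolve(own, psf_sigma=atom.sigma)
    ogrid = precompute_overlap_grid(own, atom)
    O, _, _, outside = interpolate_overlap(ogrid, model.bead_positions)
    O = np.atleast_1d(O)
    if np.any(O <= 0):
        raise ValueError("non-positive calibrated overlap; increase map padding")
    return MaxOverlapTable(per_component=[O], F=F), ogrid


def build_assembly_table(tables: Sequence[MaxOverlapTable], F: float) -> MaxOverlapTable:
    """Concatenate per-component calibration tables into one assembly table."""
    per = []
    for t in tables:
        per.extend(np.asarray(v, dtype=float) for v in t.per_component)
    return MaxOverlapTable(per_component=per, F=F)


def em_fit_energy(
    assembly: Assembly,
    ogrid: OverlapGrid,
    table: MaxOverlapTable,
    weights: Optional[EmFitWeights] = None,
    coords: Optional[np.ndarray] = None,
):
    """Harmonic overlap-deficiency energy and per-bead forces.

    Per bead, with maximum overlap m and interpolated overlap O, the
    deficiencies are measured relative to the bead's own maximum (the
    amplitude constants of probe and voxel Gaussians cancel exactly):
    hard deficiency d1 = max(0, 1 - O/m), soft dF = max(0, F - O/m)/F;
    E = sum k_hard*d1^2 + k_soft*dF^2, so a bead entirely outside the map
    contributes k_hard + k_soft.  Forces are the exact negative gradient of
    this energy through the cell interpolant.
    """
    if weights is None:
        weights = EmFitWeights()
    maxO = table.concatenated()
    if coords is None:
        coords = assembly.coordinates()
    if len(maxO) != len(coords):
        raise ValueError("calibration table does not match the assembly bead count")
    O, G, _ = _interp_value_and_exact_grad(ogrid, coords)
    rel = O / maxO
    d1 = np.clip(1.0 - rel, 0.0, None)
    dF = np.clip(1.0 - rel / table.F, 0.0, None)
    energy = float(weights.k_hard * (d1**2).sum() + weights.k_soft * (dF**2).sum())
    # force = -dE/dx = (2 k_hard d1 + 2 k_soft dF / F) * dO/dx / m
    coeff = (2.0 * weights.k_hard * d1 + 2.0 * weights.k_soft * dF / table.F) / maxO
    forces = coeff[:, None] * G
    return energy, forces


# ---------------------------------------------------------------------------
# Voxel atom density and clash penalty

def accumulate_voxel_density(
    coords: np.ndarray,
    bead_weights: np.ndarray,
    geometry: DensityGrid,
    max_density: Optional[float] = None,
) -> VoxelDensityGrid:
    """Deposit each bead's weight fractionally onto its 8 neighbouring voxels.

    The deposit uses the same trilinear weights as overlap interpolation, so
    the total deposited weight equals the total bead weight for interior
    beads; out-of-grid beads deposit nothing and are counted.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    bead_weights = np.atleast_1d(np.asarray(bead_weights, dtype=float))
    i0, f, outside = _trilinear_ingredients(geometry, coords)
    w, _ = _corner_weights(f)
    w = w * bead_weights[:, None]
    inside = ~outside
    values = np.zeros(geometry.values.shape)
    idx = i0[inside][:, None, :] + _CORNERS[None, :, :]
    np.add.at(values, (idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()),
              w[inside].ravel())
    vgrid = DensityGrid(geometry.origin.copy(), geometry.voxel_size, values)
    return VoxelDensityGrid(grid=vgrid, n_outside=int(outside.sum()),
                            max_density=max_density)


def density_clash_energy(
    coords: np.ndarray,
    bead_weights: np.ndarray,
    geometry: DensityGrid,
    cap: float,
    k_clash: float = DEFAULT_K_CLASH,
):
    """Quadratic penalty on voxel atom densities exceeding ``cap``.

    E = k_clash * sum_v max(0, density_v - cap)^2.  Each bead's force is the
    exact negative gradient through its fractional deposits: beads are pushed
    from over-dense toward under-dense regions, and the penalty vanishes
    wherever the density is below the cap.  Returns (energy, forces, vgrid).
    """
    if cap <= 0:
        raise ValueError("density cap must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    bead_weights = np.atleast_1d(np.asarray(bead_weights, dtype=float))
    i0, f, outside = _trilinear_ingredients(geometry, coords)
    w, dw = _corner_weights(f)
    inside = ~outside
    idx = i0[:, None, :] + _CORNERS[None, :, :]
    values = np.zeros(geometry.values.shape)
    wdep = w * bead_weights[:, None]
    np.add.at(values, (idx[inside][..., 0].ravel(), idx[inside][..., 1].ravel(),
                       idx[inside][..., 2].ravel()), wdep[inside].ravel())
    vgrid = VoxelDensityGrid(
        grid=DensityGrid(geometry.origin.copy(), geometry.voxel_size, values),
        n_outside=int(outside.sum()), max_density=cap)
    excess = np.clip(values - cap, 0.0, None)
    energy = float(k_clash * (excess**2).sum())
    forces = np.zeros_like(coords)
    if energy > 0.0:
        ev = excess[idx[..., 0], idx[..., 1], idx[..., 2]]
        # dE/dx_b = 2 k sum_c e_c * w_b * dw_c/dx
        g = 2.0 * k_clash * (ev[..., None] * dw).sum(axis=1) / geometry.voxel_size
        forces[inside] = -bead_weights[inside, None] * g[inside]
    return energy, forces, vgrid
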