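"""Density grids: simulation from bead models, resampling, filtering and I/O.

Conventions
-----------
Values live at voxel centers: the world coordinate of voxel (i, j, k) is
``origin + voxel_size * (i, j, k)``.  Voxels are isotropic.  Simulated maps
are in density units (weight per cubic Angstrom): each bead contributes an
isotropic Gaussian whose integral equals the bead weight, so
``values.sum() * voxel_size**3`` approximates the total bead weight.

The width of every Gaussian (atom and voxel alike) is tied to the nominal
map resolution: sigma = (resolution / 2) / sqrt(3) per Cartesian axis, so
that the full 3D Gaussian's width matches half the resolution.  The divisor
is configurable.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import scipy.fft
import scipy.ndimage as ndi

from .structures import Assembly, CoarseModel

__all__ = [
    "DensityGrid",
    "GaussianParams",
    "sigma_from_resolution",
    "simulate_map",
    "downsample_join",
    "lowpass_filter",
    "deconvolve",
    "rescale_to_sum",
    "read_map",
    "write_map",
]

DEFAULT_SIGMA_DIVISOR = float(np.sqrt(3.0))
#: Enforced (with a warning) default ratio between resolution and voxel size.
RESOLUTION_TO_VOXEL_RATIO = 4.0


@dataclasses.dataclass
class DensityGrid:
    """A regular isotropic 3D grid of density values.

    ``origin`` is the world position of the *center* of voxel (0, 0, 0);
    ``resolution_label`` is metadata recording the nominal resolution the
    grid was simulated or filtered at (None for raw experimental grids).
    """

    origin: np.ndarray           # (3,) Angstrom
    voxel_size: float            # Angstrom, isotropic
    values: np.ndarray           # (nx, ny, nz) float
    resolution_label: Optional[float] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("values must be a 3D array with dims >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite density values")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def density_sum(self) -> float:
        return float(self.values.sum())

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_size * np.arange(self.values.shape[axis])

    def world_to_grid(self, positions: np.ndarray) -> np.ndarray:
        """Continuous grid coordinates of world positions."""
        return (np.asarray(positions, dtype=float) - self.origin) / self.voxel_size

    def grid_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(ijk, dtype=float)

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.voxel_size, self.values.copy(),
                           self.resolution_label)


@dataclasses.dataclass
class GaussianParams:
    """Isotropic Gaussian: A * exp(-s * r^2) with decay s = 1 / (2 sigma^2)."""

    sigma: float     # Angstrom per Cartesian axis
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def s(self) -> float:
        """Decay factor (1/Angstrom^2)."""
        return 1.0 / (2.0 * self.sigma**2)

    @classmethod
    def from_resolution(cls, resolution: float, amplitude: float = 1.0,
                        divisor: float = DEFAULT_SIGMA_DIVISOR) -> "GaussianParams":
        return cls(sigma_from_resolution(resolution, divisor), amplitude)


def sigma_from_resolution(resolution: float,
                          divisor: float = DEFAULT_SIGMA_DIVISOR) -> float:
    """Per-axis Gaussian sigma for a map of the given nominal resolution.

    sigma = (resolution / 2) / divisor, with divisor sqrt(3) by default so
    the three-dimensional width matches half the resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return (resolution / 2.0) / divisor


def _gather_beads(obj: Union[CoarseModel, Assembly]):
    if isinstance(obj, Assembly):
        return obj.coordinates(), obj.weights()
    if isinstance(obj, CoarseModel):
        return obj.bead_positions, obj.bead_weights
    raise TypeError("expected a CoarseModel or Assembly")


def simulate_map(
    obj: Union[CoarseModel, Assembly],
    resolution: float,
    voxel_size: Optional[float] = None,
    padding: Optional[float] = None,
    origin: Optional[np.ndarray] = None,
    dims: Optional[tuple] = None,
    sigma_divisor: float = DEFAULT_SIGMA_DIVISOR,
) -> DensityGrid:
    """Simulate a density map from a bead model or assembly.

    Each bead contributes an isotropic Gaussian (sigma from the resolution
    rule) normalised to integrate to the bead weight, sampled at voxel
    centers.  The grid covers the coordinates plus ``padding`` (default
    3 sigma) unless an explicit origin/dims geometry is given.
    """
    positions, weights = _gather_beads(obj)
    if voxel_size is None:
        voxel_size = resolution / RESOLUTION_TO_VOXEL_RATIO
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    ratio = resolution / voxel_size
    if not np.isclose(ratio, RESOLUTION_TO_VOXEL_RATIO, rtol=0.26):
        warnings.warn(
            f"resolution-to-voxel ratio {ratio:.2f} deviates from the "
            f"recommended {RESOLUTION_TO_VOXEL_RATIO:g}; gradient matching "
            "may behave poorly",
            stacklevel=2,
        )
    sigma = sigma_from_resolution(resolution, sigma_divisor)
    if padding is None:
        padding = 3.0 * sigma
    if origin is None or dims is None:
        lo = positions.min(axis=0) - padding
        hi = positions.max(axis=0) + padding
        n = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
        origin = lo
        dims = tuple(n)
    origin = np.asarray(origin, dtype=float)

    s = 1.0 / (2.0 * sigma**2)
    # amplitude such that the 3D integral equals the bead weight
    amp = weights / (2.0 * np.pi * sigma**2) ** 1.5
    axes = [origin[a] + voxel_size * np.arange(dims[a]) for a in range(3)]
    # separable evaluation: per bead, outer product of 1D Gaussians
    gx = np.exp(-s * (axes[0][None, :] - positions[:, 0:1]) ** 2) * amp[:, None]
    gy = np.exp(-s * (axes[1][None, :] - positions[:, 1:2]) ** 2)
    gz = np.exp(-s * (axes[2][None, :] - positions[:, 2:3]) ** 2)
    values = np.einsum("bi,bj,bk->ijk", gx, gy, gz)
    return DensityGrid(origin, float(voxel_size), values, resolution_label=resolution)


def downsample_join(grid: DensityGrid, factor: int) -> DensityGrid:
    """Join neighbouring voxels by summation, multiplying the voxel size.

    Zero-pads dims not divisible by the factor.  The density sum is conserved
    exactly.  The output origin keeps the voxel-center convention: the first
    output voxel center sits at the centroid of the joined block.
    """
    if factor < 2 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)
    v = grid.values
    pad = [(0, (-v.shape[a]) % factor) for a in range(3)]
    if any(p[1] for p in pad):
        v = np.pad(v, pad)
    nx, ny, nz = (v.shape[0] // factor, v.shape[1] // factor, v.shape[2] // factor)
    joined = v.reshape(nx, factor, ny, factor, nz, factor).sum(axis=(1, 3, 5))
    new_origin = grid.origin + grid.voxel_size * (factor - 1) / 2.0
    return DensityGrid(new_origin, grid.voxel_size * factor, joined,
                       grid.resolution_label)


def lowpass_filter(grid: DensityGrid, target_resolution: float,
                   sigma_divisor: float = DEFAULT_SIGMA_DIVISOR) -> DensityGrid:
    """Gaussian low-pass so the combined width matches the target resolution.

    Requires the grid's resolution label to be set and finer than the target.
    The added kernel sigma satisfies sigma_add^2 = sigma_target^2 -
    sigma_current^2.  Edge losses are tolerated but warned about beyond 0.1%.
    """
    if grid.resolution_label is None:
        raise ValueError("grid has no resolution label to filter from")
    if target_resolution <= grid.resolution_label:
        raise ValueError("target resolution must be coarser than the current one")
    s_cur = sigma_from_resolution(grid.resolution_label, sigma_divisor)
    s_tgt = sigma_from_resolution(target_resolution, sigma_divisor)
    s_add = float(np.sqrt(s_tgt**2 - s_cur**2))
    filtered = ndi.gaussian_filter(grid.values, s_add / grid.voxel_size,
                                   mode="constant", cval=0.0)
    loss = abs(filtered.sum() - grid.values.sum()) / max(abs(grid.values.sum()), 1e-300)
    if loss > 1e-3:
        warnings.warn(f"low-pass filtering lost {loss:.2%} of the density sum at the edges",
                      stacklevel=2)
    return DensityGrid(grid.origin.copy(), grid.voxel_size, filtered,
                       resolution_label=target_resolution)


def _gaussian_transfer(shape, sigma_vox: float) -> np.ndarray:
    """Fourier transfer function of a Gaussian blur (real, positive)."""
    h = 1.0
    for a, n in enumerate(shape):
        f = scipy.fft.fftfreq(n)
        g = np.exp(-2.0 * np.pi**2 * sigma_vox**2 * f**2)
        sl = [None] * len(shape)
        sl[a] = slice(None)
        h = h * g[tuple(sl)]
    return h


def deconvolve(grid: DensityGrid, psf_sigma: float, method: str = "wiener",
               iterations: int = 30, regularizer: float = 1e-8) -> DensityGrid:
    """Approximately invert a Gaussian blur of width ``psf_sigma`` (Angstrom).

    'wiener' divides by the Gaussian transfer function with a small Tikhonov
    regularizer; 'richardson-lucy' runs the standard iterative scheme on the
    non-negative part.  Re-blurring the result with the same PSF recovers a
    noise-free input closely.
    """
    if psf_sigma < 0:
        raise ValueError("psf sigma must be non-negative")
    if psf_sigma == 0:
        return grid.copy()
    sig_vox = psf_sigma / grid.voxel_size
    if method == "wiener":
        H = _gaussian_transfer(grid.values.shape, sig_vox)
        F = scipy.fft.fftn(grid.values)
        out = scipy.fft.ifftn(F * H / (H * H + regularizer)).real
        return DensityGrid(grid.origin.copy(), grid.voxel_size, out,
                           grid.resolution_label)
    if method == "richardson-lucy":
        from skimage.restoration import richardson_lucy

        v = np.clip(grid.values, 0.0, None)
        scale = v.max() if v.max() > 0 else 1.0
        # Build an explicit PSF kernel covering +-4 sigma.
        r = max(int(np.ceil(4 * sig_vox)), 1)
        ax = np.arange(-r, r + 1)
        g1 = np.exp(-(ax**2) / (2 * sig_vox**2))
        psf = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        psf /= psf.sum()
        out = richardson_lucy(v / scale, psf, num_iter=iterations, clip=False) * scale
        return DensityGrid(grid.origin.copy(), grid.voxel_size, out,
                           grid.resolution_label)
    raise ValueError(f"unknown deconvolution method {method!r}")


def rescale_to_sum(grid: DensityGrid, target_sum: float) -> DensityGrid:
    """Multiply values so the density sum equals ``target_sum``."""
    cur = grid.values.sum()
    if cur == 0:
        raise ValueError("cannot rescale a zero-sum grid")
    return DensityGrid(grid.origin.copy(), grid.voxel_size,
                       grid.values * (target_sum / cur), grid.resolution_label)


# ---------------------------------------------------------------------------
# Map I/O: MRC/CCP4 (via gemmi) and Situs ASCII

def write_map(path, grid: DensityGrid, fmt: Optional[str] = None) -> None:
    path = Path(path)
    fmt = fmt or _guess_format(path)
    if fmt == "mrc":
        _write_mrc(path, grid)
    elif fmt == "situs-ascii":
        _write_situs(path, grid)
    else:
        raise ValueError(f"unknown map format {fmt!r}")


def read_map(path, fmt: Optional[str] = None) -> DensityGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _guess_format(path)
    if fmt == "mrc":
        return _read_mrc(path)
    if fmt == "situs-ascii":
        return _read_situs(path)
    raise ValueError(f"unknown map format {fmt!r}")


def _guess_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in {".mrc", ".map", ".ccp4"}:
        return "mrc"
    if suf in {".sit", ".situs"}:
        return "situs-ascii"
    raise ValueError(f"cannot guess map format from suffix {suf!r}")


def _write_mrc(path: Path, grid: DensityGrid) -> None:
    import gemmi

    nx, ny, nz = grid.values.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(nx * grid.voxel_size, ny * grid.voxel_size,
                                      nz * grid.voxel_size, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    # MRC2014 ORIGIN words (50-52): world position of the first voxel center.
    m.set_header_float(50, float(grid.origin[0]))
    m.set_header_float(51, float(grid.origin[1]))
    m.set_header_float(52, float(grid.origin[2]))
    m.write_ccp4_map(str(path))


def _read_mrc(path: Path) -> DensityGrid:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True, dtype=float)
    nx, ny, nz = values.shape
    cell = m.grid.unit_cell
    vox = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if not np.allclose(vox, vox[0], rtol=1e-5):
        raise ValueError(f"{path}: anisotropic voxels {vox} are not supported")
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.allclose(origin, 0.0):
        # Fall back to NCSTART/NYSTART/NZSTART words (header words 5-7).
        starts = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = starts * vox[0]
    return DensityGrid(origin, float(vox[0]), values)


def _write_situs(path: Path, grid: DensityGrid) -> None:
    nx, ny, nz = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"{grid.voxel_size:.6f} {grid.origin[0]:.6f} {grid.origin[1]:.6f} "
                 f"{grid.origin[2]:.6f} {nx} {ny} {nz}\n\n")
        # Situs stores x fastest
        flat = grid.values.transpose(2, 1, 0).ravel()
        for i in range(0, len(flat), 10):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 10]) + "\n")


def _read_situs(path: Path) -> DensityGrid:
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 7:
        raise ValueError(f"{path}: truncated Situs header")
    vox = float(tokens[0])
    origin = np.array([float(t) for t in tokens[1:4]])
    nx, ny, nz = (int(tokens[4]), int(tokens[5]), int(tokens[6]))
    data = np.array([float(t) for t in tokens[7:]])
    if len(data) != nx * ny * nz:
        raise ValueError(f"{path}: expected {nx * ny * nz} values, got {len(data)}")
    values = data.reshape(nz, ny, nx).transpose(2, 1, 0)
    return DensityGrid(origin, vox, values)
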