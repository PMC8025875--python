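"""Voxel-grid density maps: simulation from structures, MRC/CCP4 and Situs
I/O, preprocessing, cross-correlation and its analytic gradient.

The calculated map is a sum of isotropic Gaussians, one per bead, with
width set by the nominal resolution through the FWHM convention
(FWHM = resolution, i.e. sigma = resolution / (2*sqrt(2*ln 2))).  During
fitting each Gaussian is truncated to zero below a fraction of its peak
(1% by default, following common flexible-fitting practice), which gives
every bead a compact voxel support and bounded force stencils.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import gemmi

from . import _kernels
from .structure import Structure

__all__ = [
    "DensityGrid",
    "sigma_from_resolution",
    "truncation_radius",
    "simulate_map",
    "remove_negative",
    "cross_correlation",
    "cc_gradient",
    "read_mrc",
    "write_mrc",
    "read_situs",
    "write_situs",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class DensityGrid:
    """3-D voxel density grid.

    ``values[i, j, k]`` is the density at the voxel *center*
    ``origin + (i, j, k) * spacing``; array axes map to x, y, z.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=np.float64))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other: "DensityGrid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.spacing, other.spacing, atol=tol))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.origin.copy(),
                           self.spacing.copy())


def sigma_from_resolution(resolution: float, multiplier: float = 1.0) -> float:
    """Gaussian sigma for a nominal resolution (FWHM convention)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return multiplier * resolution / FWHM_FACTOR


def truncation_radius(sigma: float, fraction: float) -> float:
    """Radius at which a Gaussian falls to ``fraction`` of its peak.

    Solves exp(-r^2 / 2 sigma^2) = fraction; ``fraction = 0`` means no
    truncation (infinite radius).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return np.inf
    return sigma * math.sqrt(-2.0 * math.log(fraction))


def _weights(s: Structure, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(s))
    w = np.asarray(weights, dtype=np.float64)
    if len(w) != len(s):
        raise ValueError("weights length mismatch")
    return w


def simulate_map(s: Structure, resolution: float = 5.0, voxel: float = 2.0,
                 padding: float = 10.0, truncate_fraction: float = 0.0,
                 sigma_multiplier: float = 1.0, weights=None,
                 lattice: DensityGrid | None = None) -> DensityGrid:
    """Simulate a density map from a structure.

    One isotropic Gaussian per bead; ``truncate_fraction`` sets per-bead
    compact support (see :func:`truncation_radius`).  The lattice is the
    structure bounding box plus ``padding`` on all sides, unless an
    explicit ``lattice`` grid is given (then its lattice is reused, as
    required for voxel-wise CC against a target map).
    """
    if len(s) == 0:
        raise ValueError("empty structure")
    sigma = sigma_from_resolution(resolution, sigma_multiplier)
    if lattice is not None:
        origin = lattice.origin.copy()
        spacing = lattice.spacing.copy()
        shape = lattice.shape
    else:
        if voxel <= 0:
            raise ValueError("voxel must be positive")
        lo = s.positions.min(axis=0) - padding
        hi = s.positions.max(axis=0) + padding
        extent = hi - lo
        if np.any(voxel > extent):
            raise ValueError("voxel size exceeds the padded box extent")
        shape = tuple(int(math.floor(e / voxel)) + 1 for e in extent)
        origin = lo
        spacing = np.full(3, float(voxel))
    rcut = truncation_radius(sigma, truncate_fraction)
    if not np.isfinite(rcut):
        # no truncation: cover the whole grid from any bead
        span = np.asarray(shape) * spacing
        rcut = float(np.linalg.norm(span) + np.linalg.norm(
            np.abs(s.positions).max(axis=0)) + 10.0 * sigma)
    vals = np.zeros(shape, dtype=np.float64)
    _kernels.synthesize_map(
        np.ascontiguousarray(s.positions), _weights(s, weights),
        origin.astype(np.float64), spacing.astype(np.float64),
        vals, sigma, rcut)
    return DensityGrid(vals, origin, spacing)


def remove_negative(g: DensityGrid) -> DensityGrid:
    """Clamp negative voxel values to zero (experimental-map hygiene)."""
    out = g.copy()
    np.maximum(out.values, 0.0, out=out.values)
    return out


def cross_correlation(target: DensityGrid, calc: DensityGrid) -> float:
    """Voxel-wise cross-correlation coefficient of two maps on one lattice:

        CC = sum(t * c) / sqrt(sum(t^2) * sum(c^2))
    """
    if not target.same_lattice(calc):
        raise ValueError("maps are not on the same lattice")
    t = target.values.ravel()
    c = calc.values.ravel()
    nt = float(t @ t)
    nc = float(c @ c)
    if nt == 0.0 or nc == 0.0:
        raise ValueError("cross-correlation undefined for an all-zero map")
    return float(t @ c) / math.sqrt(nt * nc)


def cc_gradient(target: DensityGrid, s: Structure, resolution: float = 5.0,
                truncate_fraction: float = 0.01, sigma_multiplier: float = 1.0,
                weights=None) -> tuple[float, np.ndarray]:
    """CC of the simulated map of ``s`` on the target lattice, and its
    analytic gradient dCC/dr per bead (1/Angstrom).

    Beads whose truncated Gaussian support misses the grid contribute a
    zero gradient.  Raises when the calculated density is identically
    zero on the lattice.
    """
    sigma = sigma_from_resolution(resolution, sigma_multiplier)
    rcut = truncation_radius(sigma, truncate_fraction)
    if not np.isfinite(rcut):
        rcut = 20.0 * sigma
    t = np.ascontiguousarray(target.values)
    buf = np.zeros_like(t)
    cc, grad = _kernels.cc_and_gradient(
        np.ascontiguousarray(s.positions), _weights(s, weights),
        target.origin.astype(np.float64), target.spacing.astype(np.float64),
        t, float((t * t).sum()), sigma, rcut, buf)
    if np.isnan(cc):
        raise ValueError("calculated density is zero everywhere on the lattice")
    return float(cc), grad


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mrc(path) -> DensityGrid:
    """Read an MRC/CCP4 map.  Axis order is normalized to x, y, z using
    the file's MAPC/MAPR/MAPS mapping; the ORIGIN record is preferred,
    falling back to NCSTART * spacing."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(m.grid, copy=True, dtype=np.float64)
    nan_mask = np.isnan(arr)
    if nan_mask.any():
        arr[nan_mask] = 0.0
    cell = m.grid.unit_cell
    spacing = np.array([cell.a / m.grid.nu, cell.b / m.grid.nv,
                        cell.c / m.grid.nw])
    hdr_origin = np.array([m.header_float(50), m.header_float(51),
                           m.header_float(52)])
    if np.any(hdr_origin != 0.0):
        origin = hdr_origin
    else:
        start = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)],
                         dtype=float)
        origin = start * spacing
    return DensityGrid(arr, origin, spacing)


def write_mrc(path, g: DensityGrid):
    """Write a map as MRC/CCP4 mode-2 (float32)."""
    m = gemmi.Ccp4Map()
    nx, ny, nz = g.shape
    m.grid = gemmi.FloatGrid(np.asarray(g.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        nx * g.spacing[0], ny * g.spacing[1], nz * g.spacing[2], 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2)
    for idx, val in zip((50, 51, 52), g.origin):
        m.set_header_float(idx, float(val))
    m.write_ccp4_map(str(path))


def read_situs(path) -> DensityGrid:
    """Read a Situs ASCII map (header: voxel, origin x y z, nx ny nz)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 7:
        raise ValueError(f"truncated Situs file: {path!s}")
    voxel = float(tokens[0])
    origin = np.array([float(t) for t in tokens[1:4]])
    nx, ny, nz = (int(t) for t in tokens[4:7])
    vals = np.array([float(t) for t in tokens[7:]])
    if vals.size != nx * ny * nz:
        raise ValueError(
            f"Situs file {path!s}: expected {nx * ny * nz} values, "
            f"got {vals.size}")
    # Situs stores x fastest; our arrays are indexed [x, y, z]
    arr = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
    return DensityGrid(arr, origin, np.full(3, voxel))


def write_situs(path, g: DensityGrid):
    if not np.allclose(g.spacing, g.spacing[0]):
        raise ValueError("Situs format requires cubic voxels")
    nx, ny, nz = g.shape
    flat = g.values.transpose(2, 1, 0).ravel()
    with open(path, "w") as fh:
        fh.write(f"{g.spacing[0]:.6f} {g.origin[0]:.6f} {g.origin[1]:.6f} "
                 f"{g.origin[2]:.6f} {nx} {ny} {nz}\n\n")
        for i in range(0, flat.size, 10):
            fh.write(" ".join(f"{v:.6f}" for v in flat[i:i + 10]) + "\n")
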