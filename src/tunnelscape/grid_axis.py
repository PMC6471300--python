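"""Pocket-frequency grids and the diffusion axis.

Pocket-detection tools scan a molecular-dynamics trajectory and report, on a
regular voxel grid, the fraction of frames in which each voxel belongs to a
cavity.  For a tunnel-shaped cavity the high-frequency voxels form an
elongated cloud; the leading eigenvector of the coordinate covariance of that
cloud is the direction of greatest cavity extent — the *diffusion axis* along
which a harbored ligand can slide.

This module reads/writes such grids in OpenDX text format, thresholds them
into world-coordinate point clouds, and extracts the orthonormal covariance
axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from gridData import Grid as _DXGrid

__all__ = [
    "FrequencyGrid",
    "AxisSet",
    "read_dx_grid",
    "write_dx_grid",
    "threshold_points",
    "diffusion_axes",
]


@dataclass
class FrequencyGrid:
    """Voxelized pocket-frequency map.

    Parameters
    ----------
    origin : (3,) array
        World coordinate (Å) of voxel index (0, 0, 0).
    spacing : (3,) array
        Voxel edge lengths (Å) along x, y, z.
    values : (nx, ny, nz) array
        Pocket frequency per voxel, nominally in [0, 1].
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if min(self.values.shape) < 1:
            raise ValueError("grid must have at least one voxel per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            warnings.warn(
                f"frequency values outside [0, 1] (range [{lo:.4g}, {hi:.4g}]); "
                "proceeding anyway",
                stacklevel=3,
            )

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nx*ny*nz, 3)."""
        idx = np.indices(self.values.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class AxisSet:
    """Orthonormal covariance axes of a point cloud, sorted by variance.

    ``axes[0]`` is the diffusion axis.  ``degenerate`` is set when the result
    is not uniquely determined: near-tied eigenvalues, a rank-deficient cloud,
    or fewer than 4 points.
    """

    axes: np.ndarray  # (3, 3), rows are unit vectors
    variances: np.ndarray  # (3,), descending, Å²
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def diffusion_axis(self) -> np.ndarray:
        return self.axes[0]


def read_dx_grid(path) -> FrequencyGrid:
    """Read an OpenDX scalar field (the common pocket-tool output dialect).

    Raises
    ------
    ValueError
        On a malformed header or when the number of data values does not
        match the declared ``counts``.
    """
    try:
        g = _DXGrid(str(path))
    except Exception as exc:  # gridData raises assorted parse errors
        raise ValueError(f"malformed OpenDX file {path!r}: {exc}") from exc
    values = np.asarray(g.grid, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D scalar field in {path!r}, got shape {values.shape}")
    spacing = np.asarray(g.delta, dtype=float)
    if spacing.ndim == 2:  # gridData may return a diagonal delta matrix
        spacing = np.diag(spacing)
    origin = np.asarray(g.origin, float)
    # re-read origin/delta verbatim from the header: gridData reconstructs
    # them through edge midpoints, which can cost one ulp and break exact
    # round trips
    hdr_origin, hdr_delta = _header_origin_delta(path)
    if hdr_origin is not None and np.allclose(hdr_origin, origin, atol=1e-9):
        origin = hdr_origin
    if hdr_delta is not None and np.allclose(hdr_delta, spacing, atol=1e-9):
        spacing = hdr_delta
    return FrequencyGrid(origin=origin, spacing=spacing, values=values)


def _header_origin_delta(path):
    """Exact origin and per-axis delta from the DX header text, if present."""
    origin = None
    deltas: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if tok[0] == "origin" and len(tok) == 4:
                origin = np.array([float(v) for v in tok[1:]])
            elif tok[0] == "delta" and len(tok) == 4:
                deltas.append(np.array([float(v) for v in tok[1:]]))
            elif tok[0] == "object" and "array" in tok:
                break
    if len(deltas) == 3:
        D = np.stack(deltas)
        if np.allclose(D, np.diag(np.diag(D))):
            return origin, np.diag(D).copy()
        return origin, None
    return origin, None


def write_dx_grid(grid: FrequencyGrid, path) -> None:
    """Write a :class:`FrequencyGrid` as OpenDX text.

    Values are written with full float precision so a read/write cycle is an
    exact round trip.
    """
    nx, ny, nz = grid.counts
    vals = grid.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar field written by tunnelscape\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.17g} {:.17g} {:.17g}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.17g} 0 0\n")
        fh.write(f"delta 0 {grid.spacing[1]:.17g} 0\n")
        fh.write(f"delta 0 0 {grid.spacing[2]:.17g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.17g}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def threshold_points(grid: FrequencyGrid, cutoff: float) -> np.ndarray:
    """World coordinates of voxels with frequency strictly above ``cutoff``.

    The conventional cutoff for pocket-frequency maps is 0.2.  Returns an
    (n, 3) array; n may be zero.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    idx = np.argwhere(grid.values > cutoff)
    return grid.origin + idx * grid.spacing


def diffusion_axes(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    degeneracy_rtol: float = 0.01,
) -> AxisSet:
    """Principal covariance axes of a 3-D point cloud.

    The axes are the eigenvectors of the sample covariance matrix (unbiased,
    n−1 denominator), sorted by descending eigenvalue; the first axis is the
    diffusion axis.  Each eigenvector is oriented so that its
    largest-magnitude component is positive, making the output deterministic
    across eigensolvers.

    Parameters
    ----------
    points : (n, 3) array
    weights : optional per-point weights for a frequency-weighted covariance.
        Unweighted points are the default treatment of thresholded grids.
    degeneracy_rtol : adjacent eigenvalues closer than this relative
        difference mark the result degenerate (axes are then not unique).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for covariance axes")
    notes: list[str] = []
    degenerate = False
    if pts.shape[0] < 4:
        degenerate = True
        notes.append(f"only {pts.shape[0]} points; full-rank covariance not guaranteed")
    cov = np.cov(pts.T, ddof=1, aweights=weights)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    # deterministic sign: largest-|component| positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scale = max(evals[0], np.finfo(float).tiny)
    for i in (0, 1):
        if (evals[i] - evals[i + 1]) <= degeneracy_rtol * max(evals[i], scale * 1e-12):
            if evals[i] > 0:
                degenerate = True
                notes.append(
                    f"eigenvalues {i} and {i + 1} within {degeneracy_rtol:.0%} "
                    f"({evals[i]:.4g} vs {evals[i + 1]:.4g}); axes not unique"
                )
    rank = int(np.sum(evals > 1e-12 * scale))
    if rank < 3:
        degenerate = True
        notes.append(f"point cloud covariance has rank {rank}")
    return AxisSet(axes=axes, variances=evals, degenerate=degenerate, notes=notes)
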