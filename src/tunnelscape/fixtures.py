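"""Synthetic systems with known ground truth.

Every stage of the tunnel-ligand protocol can be exercised without any
external data: toy potentials whose free-energy profile is analytic, a
scaffold-plus-ligand trajectory whose collective-variable course is scripted,
and pocket-frequency grids whose principal axis is chosen in advance.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .contacts import LigandParts
from .frames_cv import Trajectory
from .grid_axis import FrequencyGrid

__all__ = [
    "ToyPotential",
    "make_double_well",
    "make_harmonic_well",
    "make_tunnel_potential",
    "make_toy_complex_trajectory",
    "make_pocket_grid",
    "make_volume_series",
]


@dataclass
class ToyPotential:
    """Analytic toy energy surface over 1–3 collective variables.

    The axial profile acts on the first coordinate; for multi-dimensional
    potentials a harmonic confinement of stiffness ``radial_k`` acts on the
    remaining coordinates, so the marginal free energy along the first
    coordinate equals the axial profile up to a constant.
    """

    dim: int
    axial_energy: Callable[[np.ndarray], np.ndarray]
    axial_gradient: Callable[[np.ndarray], np.ndarray]
    radial_k: float = 0.0
    profile: Callable[[np.ndarray], np.ndarray] | None = None
    params: dict = field(default_factory=dict)

    def energy(self, s) -> float:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        e = float(self.axial_energy(s[0]))
        if self.dim > 1:
            e += 0.5 * self.radial_k * float(np.sum(s[1:] ** 2))
        return e

    def gradient(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        g = np.zeros_like(s)
        g[0] = float(self.axial_gradient(s[0]))
        if self.dim > 1:
            g[1:] = self.radial_k * s[1:]
        return g


def make_double_well(barrier: float = 5.0, minima: tuple[float, float] = (-2.0, 2.0)) -> ToyPotential:
    """Symmetric quartic double well.

    U(x) = B·((x − m)² − a²)²/a⁴ with m the midpoint of the minima and
    a their half-separation, so U(minima) = 0 and U(m) − U(minima) = B
    exactly.  The analytic free-energy profile along x is U itself.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    s1, s2 = minima
    if not s1 < s2:
        raise ValueError("minima must satisfy s1 < s2")
    m = 0.5 * (s1 + s2)
    a = 0.5 * (s2 - s1)
    B = float(barrier)

    def energy(x):
        return B * ((np.asarray(x, float) - m) ** 2 - a**2) ** 2 / a**4

    def gradient(x):
        x = np.asarray(x, float)
        return 4.0 * B * ((x - m) ** 2 - a**2) * (x - m) / a**4

    return ToyPotential(
        dim=1, axial_energy=energy, axial_gradient=gradient, profile=energy,
        params={"kind": "double_well", "barrier": B, "minima": (s1, s2)},
    )


def make_harmonic_well(k: float = 5.0, center: float = 0.0) -> ToyPotential:
    """U(x) = (k/2)(x − center)²; Boltzmann variance kB·T/k."""
    if k <= 0:
        raise ValueError("k must be positive")

    def energy(x):
        return 0.5 * k * (np.asarray(x, float) - center) ** 2

    def gradient(x):
        return k * (np.asarray(x, float) - center)

    return ToyPotential(
        dim=1, axial_energy=energy, axial_gradient=gradient, profile=energy,
        params={"kind": "harmonic", "k": k, "center": center},
    )


def make_tunnel_potential(axial_profile: ToyPotential, radial_k: float = 2.0) -> ToyPotential:
    """3-D tunnel: U(x, y, z) = w(x) + (radial_k/2)(y² + z²).

    Longitudinal motion follows the 1-D axial profile; the harmonic radial
    term mimics the confinement of a ligand inside a tunnel cavity.  The
    marginal free energy along x is w(x) + constant.
    """
    if radial_k <= 0:
        raise ValueError("radial_k must be positive")
    return ToyPotential(
        dim=3,
        axial_energy=axial_profile.axial_energy,
        axial_gradient=axial_profile.axial_gradient,
        radial_k=float(radial_k),
        profile=axial_profile.profile,
        params={"kind": "tunnel", "radial_k": radial_k, "axial": dict(axial_profile.params)},
    )


# ---------------------------------------------------------------------------
# scaffold + ligand trajectory
# ---------------------------------------------------------------------------

def _helix_arc(n: int, origin: np.ndarray, direction: np.ndarray, phase: float) -> np.ndarray:
    """n pseudo-alpha-carbons on a helical arc (rise 1.5 Å, radius 2.3 Å)."""
    t = np.arange(n, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the helix axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(direction[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    ang = 2.0 * np.pi * t / 3.6 + phase
    return (origin + t[:, None] * 1.5 * direction
            + 2.3 * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_toy_complex_trajectory(
    n_frames: int = 50,
    ligand_course: Sequence[float] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
    global_motion: bool = False,
    axis: Sequence[float] = (1.0, 0.0, 0.0),
    n_loop_atoms: int = 8,
    loop_amplitude: float = 1.8,
):
    """Rigid four-helix scaffold with a ligand sliding along a tunnel axis.

    The scaffold is 40 pseudo-alpha-carbons on four helical arcs around the
    axis plus ``n_loop_atoms`` floppy loop atoms (fluctuation amplitude
    ``loop_amplitude``), so a 1.0 Å RMSF threshold selects exactly the
    helices.  The ligand is a 12-carbon aliphatic tail flanked by a bulky
    polar head and a short bridge; only the tail enters the CVs.  Per frame
    the tail centroid is displaced by ``ligand_course[f]`` Å along ``axis``
    (the scripted CV1 course), scaffold atoms receive Gaussian ``jitter``,
    and, if ``global_motion``, a random rigid roto-translation is applied to
    the whole frame to exercise the reference-frame fitting.

    Returns
    -------
    traj : Trajectory
    ground_truth : (n_frames, 2) array of the scripted (cv1, cv2), measured
        before the global roto-translation.
    parts : LigandParts (head/tail/bridge atom indices)
    info : dict with ``scaffold_atoms``, ``loop_atoms``, ``ligand_atoms``,
        ``candidate_atoms`` (all alpha-carbons) and ``axis``.
    """
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if ligand_course is None:
        ligand_course = np.zeros(n_frames)
    ligand_course = np.asarray(ligand_course, dtype=float)
    if ligand_course.size != n_frames:
        raise ValueError("ligand_course must have one value per frame")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")

    # orthonormal frame with e0 = tunnel axis
    e0 = axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(e0[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e0, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e0, e1)
    to_world = np.stack([e0, e1, e2], axis=1)  # local (a, b, c) -> world

    # four helices around the tunnel, in local coordinates then rotated
    helix_local = []
    for kx, ky in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        origin = np.array([-7.0, 6.0 * kx, 6.0 * ky])
        helix_local.append(_helix_arc(10, origin, np.array([1.0, 0.0, 0.0]),
                                      phase=0.7 * (kx + 2 * ky)))
    scaffold0 = np.concatenate(helix_local) @ to_world.T

    # floppy loop atoms, off to one side
    loop0 = (np.array([2.0, 14.0, 0.0])
             + rng.normal(scale=3.0, size=(n_loop_atoms, 3))) @ to_world.T

    # ligand: 12 tail carbons along the axis, bridge, bulky head
    tail_local = np.stack([np.linspace(-5.5, 5.5, 12),
                           0.4 * np.cos(np.arange(12)),
                           0.4 * np.sin(np.arange(12))], axis=1)
    bridge_local = np.array([[6.5, 0.3, 0.0], [7.3, -0.3, 0.2]])
    head_local = np.array([[8.5, 0.0, 0.0], [9.3, 1.0, 0.4], [9.3, -1.0, -0.4],
                           [10.2, 0.5, -0.8], [10.2, -0.5, 0.8]])
    lig0 = np.concatenate([head_local, tail_local, bridge_local]) @ to_world.T

    n_scaffold, n_loop, n_lig = scaffold0.shape[0], n_loop_atoms, lig0.shape[0]
    n_atoms = n_scaffold + n_loop + n_lig
    scaffold_atoms = np.arange(n_scaffold)
    loop_atoms = np.arange(n_scaffold, n_scaffold + n_loop)
    lig_start = n_scaffold + n_loop
    head = lig_start + np.arange(5)
    tail = lig_start + 5 + np.arange(12)
    bridge = lig_start + 17 + np.arange(2)
    parts = LigandParts(head=head, tail=tail, bridge=bridge)

    coords = np.zeros((n_frames, n_atoms, 3))
    ground_truth = np.zeros((n_frames, 2))
    # deterministic loop wobble: each loop atom oscillates with its own phase
    loop_phase = rng.uniform(0, 2 * np.pi, size=n_loop)
    loop_dir = rng.normal(size=(n_loop, 3))
    loop_dir /= np.linalg.norm(loop_dir, axis=1, keepdims=True)
    for f in range(n_frames):
        frame = np.zeros((n_atoms, 3))
        frame[scaffold_atoms] = scaffold0
        if jitter > 0:
            frame[scaffold_atoms] += rng.normal(scale=jitter, size=(n_scaffold, 3))
        wobble = loop_amplitude * np.sin(2 * np.pi * f / max(n_frames - 1, 1) * 3 + loop_phase)
        frame[loop_atoms] = loop0 + wobble[:, None] * loop_dir
        if jitter > 0:
            frame[loop_atoms] += rng.normal(scale=jitter, size=(n_loop, 3))
        frame[lig_start:] = lig0 + ligand_course[f] * e0
        # CVs are measured relative to the reference (first) frame
        ground_truth[f] = (ligand_course[f] - ligand_course[0], 0.0)
        # frame 0 is the reference: it stays in the frame in which the
        # diffusion axis is expressed, so CV ground truth is well defined
        if global_motion and f > 0:
            R = _random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            frame = frame @ R.T + t
        coords[f] = frame

    names = (["CA"] * (n_scaffold + n_loop)
             + [f"CH{i + 1}" for i in range(5)]
             + [f"CT{i + 1}" for i in range(12)]
             + [f"CB{i + 1}" for i in range(2)])
    resids = np.concatenate([np.arange(1, n_scaffold + n_loop + 1),
                             np.full(n_lig, n_scaffold + n_loop + 1)])
    resnames = ["ALA"] * (n_scaffold + n_loop) + ["LIG"] * n_lig
    elements = ["C"] * n_atoms
    traj = Trajectory(coords, names=names, resids=resids, resnames=resnames,
                      elements=elements, times=np.arange(n_frames, dtype=float))
    info = {
        "scaffold_atoms": scaffold_atoms,
        "loop_atoms": loop_atoms,
        "ligand_atoms": np.arange(lig_start, n_atoms),
        "candidate_atoms": np.arange(n_scaffold + n_loop),
        "axis": e0,
    }
    return traj, ground_truth, parts, info


# ---------------------------------------------------------------------------
# pocket grid
# ---------------------------------------------------------------------------

def make_pocket_grid(
    axis: Sequence[float] = (1.0, 0.0, 0.0),
    half_lengths: tuple[float, float, float] = (8.0, 3.0, 2.0),
    noise_level: float = 0.05,
    seed: int = 0,
    spacing: float = 0.8,
    margin: float = 4.0,
) -> FrequencyGrid:
    """Pocket-frequency grid for an ellipsoidal tunnel of known orientation.

    Voxels inside an ellipsoid with semi-axes ``half_lengths`` (a > b >= c),
    elongated along ``axis``, carry high frequencies (0.5–1.0, tapering
    toward the surface); all other voxels carry uniform background noise in
    [0, noise_level].  With ``noise_level`` below the conventional 0.2 cutoff
    the thresholded point cloud is exactly the ellipsoid interior, whose
    principal covariance axis is the requested tunnel axis.
    """
    a, b, c = half_lengths
    if not (a > b >= c > 0):
        raise ValueError("half_lengths must satisfy a > b >= c > 0")
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    extent = a + margin
    n = int(np.ceil(2 * extent / spacing)) + 1
    origin = np.full(3, -extent)
    sp = np.full(3, spacing)
    idx = np.indices((n, n, n)).reshape(3, -1).T
    world = origin + idx * sp
    # ellipsoid coordinates
    q = np.stack([world @ axis, world @ e1, world @ e2], axis=1)
    r2 = (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 + (q[:, 2] / c) ** 2
    values = rng.uniform(0.0, noise_level, size=world.shape[0])
    inside = r2 <= 1.0
    values[inside] = 1.0 - 0.5 * r2[inside]  # 1 at center, 0.5 at the surface
    return FrequencyGrid(origin=origin, spacing=sp, values=values.reshape(n, n, n))


def make_volume_series(
    cv1: Sequence[float],
    slope: float = 25.0,
    intercept: float = 700.0,
    noise: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic cavity-volume series linearly coupled to CV1 (Å³).

    Emulates the behavior of a breathing tunnel whose volume tracks the
    ligand position; the sign of ``slope`` plays the role of the ligand
    orientation.
    """
    rng = np.random.default_rng(seed)
    cv1 = np.asarray(cv1, dtype=float)
    return intercept + slope * cv1 + rng.normal(scale=noise, size=cv1.shape)
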