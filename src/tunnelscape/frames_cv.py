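"""Reference-frame fitting and the two tunnel collective variables.

A ligand sliding through a tunnel-shaped cavity is described by two collective
variables measured in a body-fixed frame of the protein:

* **CV1** — signed displacement of the ligand-tail centroid along the tunnel's
  diffusion axis, relative to its starting position;
* **CV2** — distance of that centroid from the axis, i.e. the displacement in
  the plane orthogonal to CV1 (non-negative by construction).

Measuring the displacement in a body-fixed frame removes overall diffusion
and tumbling: each frame is superposed onto a reference structure by the
optimal rigid (Kabsch) transform computed over a set of low-RMSF anchor
atoms — in practice the alpha-carbons of the rigid helical core.  The origin
of both CVs is the ligand position in the reference frame, so the starting
structure maps to (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ReferenceState",
    "CVPair",
    "RigidTransform",
    "load_trajectory",
    "write_trajectory_pdb",
    "write_trajectory_xyz",
    "compute_rmsf",
    "select_reference_atoms",
    "kabsch_fit",
    "compute_cvs",
    "cv_timeseries",
    "make_reference_state",
]


@dataclass
class Trajectory:
    """In-memory trajectory: (n_frames, n_atoms, 3) coordinates plus metadata.

    Every frame has identical atom count and ordering; coordinates are
    Cartesian Å, frames 0-indexed.
    """

    coords: np.ndarray
    names: list[str] = field(default_factory=list)
    resids: np.ndarray | None = None
    resnames: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.n_atoms
        if not self.names:
            self.names = [f"C{i + 1}" for i in range(n)]
        if self.resids is None:
            self.resids = np.arange(1, n + 1)
        self.resids = np.asarray(self.resids, dtype=int)
        if not self.resnames:
            self.resnames = ["UNK"] * n
        if not self.elements:
            self.elements = [nm.strip()[0] for nm in self.names]
        for attr in ("names", "resnames", "elements"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match atom count {n}")
        if self.resids.shape != (n,):
            raise ValueError("resids length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_groups(self) -> dict[int, np.ndarray]:
        """Atom indices grouped by residue id, in residue order."""
        groups: dict[int, list[int]] = {}
        for i, r in enumerate(self.resids):
            groups.setdefault(int(r), []).append(i)
        return {r: np.asarray(ix) for r, ix in groups.items()}


class CVPair(NamedTuple):
    cv1: float  #: signed distance along the diffusion axis (Å)
    cv2: float  #: distance in the orthogonal plane (Å), >= 0


class RigidTransform(NamedTuple):
    """x -> rotation @ x + translation (rotation is proper, det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class ReferenceState:
    """Everything needed to evaluate the CVs for one frame."""

    coords: np.ndarray  # reference coordinates, (n_atoms, 3)
    fit_atoms: np.ndarray  # low-RMSF anchor atoms used for superposition
    ligand_atoms: np.ndarray  # aliphatic tail carbons entering the CVs
    axis: np.ndarray  # unit diffusion axis
    origin_com: np.ndarray  # ligand-tail centroid in the reference frame
    rmsf_threshold: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.fit_atoms = np.asarray(self.fit_atoms, dtype=int)
        self.ligand_atoms = np.asarray(self.ligand_atoms, dtype=int)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        self.origin_com = np.asarray(self.origin_com, dtype=float).reshape(3)
        if self.fit_atoms.size == 0:
            raise ValueError("fit_atoms must be non-empty")
        if self.ligand_atoms.size == 0:
            raise ValueError("ligand_atoms must be non-empty")
        if np.intersect1d(self.fit_atoms, self.ligand_atoms).size:
            raise ValueError("fit_atoms and ligand_atoms must be disjoint")
        nrm = np.linalg.norm(self.axis)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            self.axis = self.axis / nrm


# ---------------------------------------------------------------------------
# trajectory I/O (multi-model PDB / XYZ via MDAnalysis)
# ---------------------------------------------------------------------------

def load_trajectory(path) -> Trajectory:
    """Load a multi-model PDB or XYZ trajectory."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
        names = [str(n) for n in u.atoms.names]
        try:
            resids = np.array([int(a.resid) for a in u.atoms])
            resnames = [str(a.resname) for a in u.atoms]
        except (AttributeError, mda.exceptions.NoDataError):
            resids, resnames = None, []
        try:
            elements = [str(e) for e in u.atoms.elements]
        except (AttributeError, mda.exceptions.NoDataError):
            elements = []
        times = np.array([ts.time for ts in u.trajectory])
    return Trajectory(coords, names=names, resids=resids, resnames=resnames,
                      elements=elements, times=times)


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Write a multi-frame XYZ file (element symbol + coordinates)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                fh.write(f"{traj.elements[i]:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model (MODEL/ENDMDL) PDB file."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                name = traj.names[i][:4]
                fh.write(
                    "ATOM  {serial:5d} {name:<4s}{alt:1s}{res:<4s}{chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=i + 1, name=name, alt=" ",
                        res=traj.resnames[i][:4], chain="A",
                        resid=int(traj.resids[i]) % 10000,
                        x=x, y=y, z=z, occ=1.0, b=0.0,
                        el=traj.elements[i][:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# RMSF and reference-atom selection
# ---------------------------------------------------------------------------

def compute_rmsf(
    traj: Trajectory,
    atom_indices: Sequence[int] | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å).

    RMSF_i = sqrt( mean_t |r_i(t) − <r_i>|² ).  Unless ``align=False``, every
    frame is first superposed onto frame 0 using the given atoms (a single
    alignment pass, not iterative superposition).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = np.arange(traj.n_atoms) if atom_indices is None else np.asarray(atom_indices, int)
    X = traj.coords[:, idx, :]
    if align:
        ref = X[0]
        X = np.stack([kabsch_fit(frame, ref).apply(frame) for frame in X])
    mean = X.mean(axis=0)
    return np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))


def select_reference_atoms(rmsf: np.ndarray, threshold: float) -> np.ndarray:
    """Indices (into the rmsf array) with fluctuation strictly below threshold.

    An empty selection is an error: the fitting frame would be undefined.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rmsf = np.asarray(rmsf, dtype=float)
    sel = np.flatnonzero(rmsf < threshold)
    if sel.size == 0:
        raise ValueError(
            f"no atoms with RMSF below {threshold} Å "
            f"(min observed {rmsf.min():.3f} Å); raise the threshold"
        )
    return sel


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1) and translation minimizing the
    RMSD between the transformed mobile points and the reference.  Mirrored
    inputs still yield a proper rotation, at the cost of residual RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1e-300) or S[0] == 0.0:
        raise ValueError("rank-deficient point set: rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform(rotation=R, translation=qc - R @ pc)


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------

def compute_cvs(frame: np.ndarray, ref: ReferenceState) -> CVPair:
    """CV1/CV2 of one frame in the optimally fitted reference frame.

    Procedure: superpose the frame's anchor atoms onto the reference anchors,
    apply the resulting rigid transform to the ligand-tail atoms, and measure
    the displacement ``d`` of their centroid from the reference centroid.
    CV1 = d·axis, CV2 = |d − (d·axis) axis|.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != ref.coords.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match reference {ref.coords.shape}"
        )
    tf = kabsch_fit(frame[ref.fit_atoms], ref.coords[ref.fit_atoms])
    lig = tf.apply(frame[ref.ligand_atoms])
    d = lig.mean(axis=0) - ref.origin_com
    cv1 = float(d @ ref.axis)
    cv2 = float(np.linalg.norm(d - cv1 * ref.axis))
    return CVPair(cv1=cv1, cv2=cv2)


def cv_timeseries(traj: Trajectory, ref: ReferenceState) -> pd.DataFrame:
    """CV1/CV2 for every frame; columns ``time``, ``cv1``, ``cv2``."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    pairs = [compute_cvs(traj.coords[f], ref) for f in range(traj.n_frames)]
    times = traj.times if traj.times is not None else np.arange(traj.n_frames, dtype=float)
    return pd.DataFrame(
        {"time": times, "cv1": [p.cv1 for p in pairs], "cv2": [p.cv2 for p in pairs]}
    )


def make_reference_state(
    traj: Trajectory,
    axis: np.ndarray,
    ligand_atoms: Sequence[int],
    candidate_atoms: Sequence[int] | None = None,
    rmsf_threshold: float = 1.0,
    reference_frame: int = 0,
) -> ReferenceState:
    """Build a :class:`ReferenceState` from a trajectory.

    ``candidate_atoms`` are the atoms eligible as anchors (typically the
    alpha-carbons); those whose RMSF falls strictly below ``rmsf_threshold``
    become the fit set.  The CV origin is the ligand-tail centroid in the
    chosen reference frame.
    """
    ligand_atoms = np.asarray(ligand_atoms, int)
    if candidate_atoms is None:
        candidate_atoms = np.setdiff1d(np.arange(traj.n_atoms), ligand_atoms)
    candidate_atoms = np.asarray(candidate_atoms, int)
    rmsf = compute_rmsf(traj, candidate_atoms)
    fit_atoms = candidate_atoms[select_reference_atoms(rmsf, rmsf_threshold)]
    ref_coords = traj.coords[reference_frame]
    return ReferenceState(
        coords=ref_coords,
        fit_atoms=fit_atoms,
        ligand_atoms=ligand_atoms,
        axis=axis,
        origin_com=ref_coords[ligand_atoms].mean(axis=0),
        rmsf_threshold=rmsf_threshold,
    )
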