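"""Map of interacting residues from logistic contact covariance.

The ligand is split into three named parts — head, tail and bridge.  For each
frame, the minimum heavy-atom distance between every protein residue and every
ligand part is passed through a logistic switch spanning (−1, 1) (positive in
contact, negative apart).  The covariance of these contact signals over time
measures which residues engage the ligand together; hierarchical clustering
of the covariance matrix groups residues into interaction modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .frames_cv import Trajectory

__all__ = [
    "LigandParts",
    "part_min_distances",
    "logistic_contact",
    "contact_series",
    "contact_covariance",
    "cluster_residues",
    "aggregate_residue_clusters",
]

PART_NAMES = ("head", "tail", "bridge")


@dataclass
class LigandParts:
    """Atom-index sets for the three ligand parts (pairwise disjoint)."""

    head: np.ndarray
    tail: np.ndarray
    bridge: np.ndarray

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=int)
        self.tail = np.asarray(self.tail, dtype=int)
        self.bridge = np.asarray(self.bridge, dtype=int)
        for name in PART_NAMES:
            if getattr(self, name).size == 0:
                raise ValueError(f"ligand part {name!r} must be non-empty")
        for i, a in enumerate(PART_NAMES):
            for b in PART_NAMES[i + 1 :]:
                if np.intersect1d(getattr(self, a), getattr(self, b)).size:
                    raise ValueError(f"ligand parts {a!r} and {b!r} overlap")

    def items(self):
        return [(name, getattr(self, name)) for name in PART_NAMES]


def part_min_distances(
    frame: np.ndarray,
    residues: Mapping[int, Sequence[int]],
    parts: LigandParts,
) -> pd.DataFrame:
    """Minimum atom–atom distance (Å) per (residue, ligand part).

    Rows are residue ids, columns part names; entry (r, p) is the minimum over
    all atom pairs between residue r and part p.
    """
    frame = np.asarray(frame, dtype=float)
    out = np.empty((len(residues), len(PART_NAMES)))
    for i, (rid, atoms) in enumerate(residues.items()):
        atoms = np.asarray(atoms, dtype=int)
        if atoms.size == 0:
            raise ValueError(f"residue {rid} has no atoms")
        for j, (_, pidx) in enumerate(parts.items()):
            out[i, j] = cdist(frame[atoms], frame[pidx]).min()
    return pd.DataFrame(out, index=list(residues.keys()), columns=list(PART_NAMES))


def logistic_contact(d, d0: float = 4.5, lam: float = 1.0):
    """Logistic contact switch f(d) = 2/(1 + exp((d − d0)/λ)) − 1 ∈ (−1, 1).

    Strictly decreasing and odd around the midpoint d0 (f(d0) = 0); λ sets
    the steepness of the transition.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    d = np.asarray(d, dtype=float)
    out = 2.0 / (1.0 + np.exp((d - d0) / lam)) - 1.0
    return float(out) if out.ndim == 0 else out


def contact_series(
    traj: Trajectory,
    parts: LigandParts,
    residues: Mapping[int, Sequence[int]] | None = None,
    d0: float = 4.5,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Logistic contact value per frame and (residue, part) channel.

    Returns a DataFrame indexed by frame with MultiIndex columns
    (residue id, part name); values lie strictly within (−1, 1).
    """
    if residues is None:
        lig = np.concatenate([parts.head, parts.tail, parts.bridge])
        groups = traj.residue_groups()
        residues = {r: ix for r, ix in groups.items()
                    if not np.intersect1d(ix, lig).size}
    rows = []
    for f in range(traj.n_frames):
        dists = part_min_distances(traj.coords[f], residues, parts)
        rows.append(logistic_contact(dists.to_numpy(), d0=d0, lam=lam).ravel())
    cols = pd.MultiIndex.from_product(
        [list(residues.keys()), list(PART_NAMES)], names=["residue", "part"]
    )
    return pd.DataFrame(np.asarray(rows), columns=cols)


def contact_covariance(series: pd.DataFrame) -> pd.DataFrame:
    """Sample covariance (over time) between contact channels."""
    if len(series) < 2:
        raise ValueError("need at least 2 time points for a covariance")
    X = series.to_numpy(dtype=float)
    cov = np.cov(X.T, ddof=1)
    cov = np.atleast_2d(cov)
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return pd.DataFrame(cov, index=series.columns, columns=series.columns)


def cluster_residues(cov: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Agglomerative clustering of contact channels from their covariance.

    Channels are embedded with the dissimilarity 1 − C/max|C| (scale-free in
    the covariance) and clustered with average linkage; the dendrogram is cut
    at ``n_clusters``.  Deterministic for fixed input.  Returns cluster ids
    (0-based) indexed like the covariance matrix.
    """
    C = cov.to_numpy(dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("covariance matrix must be square")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n_clusters == n:
        labels = np.arange(n)
    elif n_clusters == 1:
        labels = np.zeros(n, dtype=int)
    else:
        scale = np.abs(C).max()
        D = 1.0 - C / scale if scale > 0 else np.ones_like(C)
        np.fill_diagonal(D, 0.0)
        D = np.clip(0.5 * (D + D.T), 0.0, None)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return pd.Series(labels, index=cov.index, name="cluster")


def aggregate_residue_clusters(cov: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """One cluster id per residue, from its strongest-covariance channel.

    Each residue has one channel per ligand part; the residue inherits the
    cluster of the channel with the largest total |covariance| against all
    other channels (its dominant interaction mode).
    """
    if not isinstance(cov.index, pd.MultiIndex):
        raise ValueError("expected (residue, part) channels")
    strength = pd.Series(np.abs(cov.to_numpy()).sum(axis=1), index=cov.index)
    out = {}
    for rid in cov.index.get_level_values("residue").unique():
        sub = strength.loc[rid]
        best_part = sub.idxmax()
        out[rid] = int(labels.loc[(rid, best_part)])
    return pd.Series(out, name="cluster").rename_axis("residue")
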