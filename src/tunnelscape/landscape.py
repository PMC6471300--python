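"""Free-energy landscape and trajectory analyses.

Basin/barrier detection on a 1-D free-energy curve, the mean-distance radius
of gyration, protein–ligand contact counts, and the correlation between
cavity volume and the ligand position along the diffusion axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .wtmeta import FESCurve

__all__ = [
    "Basin",
    "Barrier",
    "BasinSet",
    "find_basins",
    "radius_of_gyration_mean",
    "radius_of_gyration_rms",
    "count_contacts",
    "load_volume_series",
    "CorrelationResult",
    "volume_cv_correlation",
]


@dataclass(frozen=True)
class Basin:
    label: int          # energy rank within the landscape; 0 = deepest
    location: float     # CV1 of the minimum (Å)
    energy: float       # kcal/mol


@dataclass(frozen=True)
class Barrier:
    left: int           # label of the basin on the low-CV side
    right: int          # label of the basin on the high-CV side
    location: float     # CV1 of the saddle (Å)
    energy: float       # saddle energy (kcal/mol)
    height: float       # saddle − shallower adjacent minimum, >= 0


@dataclass
class BasinSet:
    """Basins of a 1-D free-energy curve, labeled by energy rank (0 = deepest),
    plus the barrier separating each adjacent pair."""

    basins: list[Basin] = field(default_factory=list)
    barriers: list[Barrier] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.basins)

    def by_label(self, label: int) -> Basin:
        for b in self.basins:
            if b.label == label:
                return b
        raise KeyError(label)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


def find_basins(fes: FESCurve, smooth_window: int = 1, min_depth: float = 0.0) -> BasinSet:
    """Detect basins and barriers of a free-energy curve.

    Local minima of the (optionally moving-average smoothed) curve are the
    basin candidates; the maximum between consecutive minima is the saddle.
    Basins whose depth — lowest adjacent saddle minus basin minimum — falls
    below ``min_depth`` are merged into their neighbor, shallowest first.
    Endpoints count as minima when the curve rises away from them, so a
    monotone ramp yields a single basin at its low end.  Labels are energy
    ranks (0 = deepest); barrier height is measured from the shallower
    (higher-energy) of its two adjacent minima.
    """
    y = np.asarray(fes.free_energy, dtype=float)
    x = np.asarray(fes.grid, dtype=float)
    if y.size == 0:
        raise ValueError("empty curve")
    if y.size < 3:
        i = int(np.argmin(y))
        return BasinSet(basins=[Basin(0, float(x[i]), float(y[i]))])
    ys = _moving_average(y, smooth_window)

    # local minima (plateau-safe: strict drop before, no rise after)
    minima: list[int] = []
    if ys[0] < ys[1]:
        minima.append(0)
    for i in range(1, ys.size - 1):
        if ys[i] < ys[i - 1] and ys[i] <= ys[i + 1]:
            minima.append(i)
    if ys[-1] < ys[-2]:
        minima.append(ys.size - 1)
    if not minima:
        minima = [int(np.argmin(ys))]

    # saddle between consecutive minima = interval maximum
    def saddle(i: int, j: int) -> int:
        return i + int(np.argmax(ys[i : j + 1]))

    saddles = [saddle(minima[i], minima[i + 1]) for i in range(len(minima) - 1)]

    # prune shallow basins, shallowest first
    while len(minima) > 1:
        depths = []
        for i, m in enumerate(minima):
            adj = []
            if i > 0:
                adj.append(ys[saddles[i - 1]])
            if i < len(saddles):
                adj.append(ys[saddles[i]])
            depths.append(min(adj) - ys[m])
        i = int(np.argmin(depths))
        if depths[i] >= min_depth:
            break
        # merge basin i across its lower adjacent saddle
        if i == 0:
            del minima[0], saddles[0]
        elif i == len(minima) - 1:
            del minima[-1], saddles[-1]
        else:
            if ys[saddles[i - 1]] <= ys[saddles[i]]:
                k = i - 1  # merge left
            else:
                k = i      # merge right
            # keep the deeper of the two minima joined by the removed saddle
            keep = minima[k] if ys[minima[k]] <= ys[minima[k + 1]] else minima[k + 1]
            minima[k] = keep
            del minima[k + 1], saddles[k]

    # labels: rank by the reported (unsmoothed) energy (0 = deepest)
    order = np.argsort([y[m] for m in minima], kind="stable")
    rank = {minima[int(i)]: r for r, i in enumerate(order)}
    basins = [Basin(rank[m], float(x[m]), float(y[m])) for m in minima]
    barriers = []
    for i in range(len(minima) - 1):
        s = saddles[i]
        shallower = max(y[minima[i]], y[minima[i + 1]])
        barriers.append(
            Barrier(
                left=rank[minima[i]], right=rank[minima[i + 1]],
                location=float(x[s]), energy=float(y[s]),
                height=float(y[s] - shallower),
            )
        )
    return BasinSet(basins=basins, barriers=barriers)


def barrier_between(fes: FESCurve, loc_a: float, loc_b: float) -> float:
    """Barrier (kcal/mol) separating two minima of a free-energy curve.

    The saddle is the maximum of the curve between the two locations; the
    height is measured from the shallower (higher-energy) of the two minima,
    each taken as the curve minimum within a small neighborhood (±2% of the
    grid span) of the given location.
    """
    x = fes.grid
    y = fes.free_energy
    if loc_a > loc_b:
        loc_a, loc_b = loc_b, loc_a
    span = x[-1] - x[0]
    tol = 0.02 * span

    def local_min(loc):
        sel = (x >= loc - tol) & (x <= loc + tol)
        if not sel.any():
            raise ValueError(f"location {loc} outside the FES grid")
        return y[sel].min()

    inner = (x >= loc_a) & (x <= loc_b)
    if not inner.any():
        raise ValueError("no grid points between the two locations")
    saddle = y[inner].max()
    return float(saddle - max(local_min(loc_a), local_min(loc_b)))


def main_barrier(fes: FESCurve, smooth_window: int = 1, min_depth: float = 0.5) -> float:
    """Barrier between the two deepest basins of the curve.

    Convenience wrapper: detects basins (with optional smoothing and depth
    pruning), takes the two lowest-energy ones, and measures the saddle
    between them on the smoothed curve via :func:`barrier_between`.
    """
    bs = find_basins(fes, smooth_window=smooth_window, min_depth=min_depth)
    if len(bs) < 2:
        raise ValueError("fewer than two basins detected")
    a, b = bs.by_label(0), bs.by_label(1)
    # measure on the smoothed curve: extrema of the raw noisy curve are
    # systematically biased (max picks up positive noise, min negative)
    smoothed = FESCurve(fes.grid, _moving_average(fes.free_energy, smooth_window))
    return barrier_between(smoothed, a.location, b.location)


def radius_of_gyration_mean(coords: np.ndarray) -> float:
    """Mean distance between atoms and their centroid (Å).

    This is the *mean-distance* convention, a robust proxy for protein size;
    it is bounded above by the conventional root-mean-square radius of
    gyration (:func:`radius_of_gyration_rms`) by Jensen's inequality.
    """
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    if X.shape[0] < 1:
        raise ValueError("need at least one atom")
    return float(np.mean(np.linalg.norm(X - X.mean(axis=0), axis=1)))


def radius_of_gyration_rms(coords: np.ndarray) -> float:
    """Conventional (mass-uniform) radius of gyration, sqrt(mean |r − r̄|²)."""
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    if X.shape[0] < 1:
        raise ValueError("need at least one atom")
    return float(np.sqrt(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1))))


def count_contacts(frame: np.ndarray, group_a, group_b, cutoff: float = 4.5) -> int:
    """Number of atom pairs between two disjoint groups closer than ``cutoff`` Å."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    frame = np.asarray(frame, dtype=float)
    return int(np.count_nonzero(cdist(frame[a], frame[b]) < cutoff))


def load_volume_series(path) -> np.ndarray:
    """Cavity-volume series (Å³) from a TSV with columns frame, volume_A3.

    External pocket tools report per-frame cavity volumes in this form; the
    returned array is ordered by frame.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (frame, volume)")
    return df.sort_values(df.columns[0]).iloc[:, 1].to_numpy(dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    sign: int             # −1, 0 or +1
    degenerate: bool      # True when a series had zero variance

    @property
    def orientation_note(self) -> str:
        """Human-readable sign report: the sign of the cavity-volume/CV1
        coupling distinguishes the two ligand orientations."""
        if self.degenerate:
            return "undefined (zero-variance input)"
        return {1: "positive coupling", -1: "negative coupling", 0: "no coupling"}[self.sign]


def volume_cv_correlation(volumes, cv1) -> CorrelationResult:
    """Pearson correlation between cavity volume and CV1.

    Zero-variance inputs yield a flagged zero instead of an error.
    """
    v = np.asarray(volumes, dtype=float)
    s = np.asarray(cv1, dtype=float)
    if v.shape != s.shape:
        raise ValueError("volumes and cv1 must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(v) == 0 or np.ptp(s) == 0:
        return CorrelationResult(r=0.0, p_value=1.0, sign=0, degenerate=True)
    res = pearsonr(v, s)
    r = float(res.statistic)
    return CorrelationResult(r=r, p_value=float(res.pvalue),
                             sign=int(np.sign(r)), degenerate=False)
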