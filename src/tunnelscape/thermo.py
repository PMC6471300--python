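"""Binding thermodynamics post-processing.

End-point binding estimates combine an enthalpy ΔH (computed upstream, e.g.
by MM–PBSA) with a configurational entropy term TΔS into

    ΔG = ΔH − TΔS        (at T = 298 K by default).

The entropy itself is estimated with a PCA-histogram approximation: frames of
an aligned trajectory are projected onto their principal components, each
retained component is histogrammed independently, and the Shannon entropy of
the bin occupancies is summed over components,

    S = −kB Σ_components Σ_bins p ln p .

This discrete estimate depends on the binning, so comparisons are only
meaningful at fixed (n_components, n_bins).

The module also converts free-energy differences between two binding poses
into an affinity fold change, exp(ΔΔG / RT).

A reference table of MM–PBSA binding estimates for the lipid transfer protein
Pru p 3 with its natural ligand, phytosphingosine, and sphingosine in both
tunnel orientations ships with the package for consistency checking.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KB
from .frames_cv import kabsch_fit

__all__ = [
    "ThermoRecord",
    "gibbs_combine",
    "fold_change",
    "pca_histogram_entropy",
    "binding_entropy_delta",
    "load_thermo_table",
    "check_thermo_table",
]


@dataclass(frozen=True)
class ThermoRecord:
    """One ligand/orientation row: ΔH, TΔS and ΔG (kcal/mol) at temperature T."""

    ligand: str
    orientation: str
    dH: float
    TdS: float
    dG: float
    T: float = DEFAULT_TEMPERATURE

    def is_consistent(self, tol: float = 0.01) -> bool:
        """Whether ΔG = ΔH − TΔS holds within rounding of printed values."""
        return abs(self.dG - (self.dH - self.TdS)) <= tol


def gibbs_combine(dH: float, TdS: float) -> float:
    """ΔG = ΔH − TΔS (all in kcal/mol, TΔS already multiplied by T)."""
    return dH - TdS


def fold_change(dG_weak: float, dG_strong: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Affinity ratio between two binding modes, exp((ΔG_weak − ΔG_strong)/RT).

    ≥ 1 whenever the "strong" mode binds at least as tightly (more negative
    ΔG).  fold_change(a, b)·fold_change(b, a) = 1.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp((dG_weak - dG_strong) / (KB * T))


def binding_entropy_delta(S_complex: float, S_receptor: float, S_ligand: float) -> float:
    """ΔS of binding = S_complex − S_receptor − S_ligand (same units/T)."""
    return S_complex - S_receptor - S_ligand


def pca_histogram_entropy(
    coords: np.ndarray,
    n_components: int = 10,
    n_bins: int = 30,
    T: float = DEFAULT_TEMPERATURE,
    superpose: bool = True,
) -> tuple[float, float]:
    """Configurational entropy from histogrammed principal components.

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) aligned trajectory of the selection.
    n_components : principal components retained (capped at the data rank).
    n_bins : histogram bins per component, spanning each component's range.
    superpose : rigidly superpose every frame onto the first before the PCA,
        removing global translation/rotation (requires >= 3 atoms).

    Returns
    -------
    (S, TdS) : entropy in kcal/(mol·K) and T·S in kcal/mol.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    n_frames = X.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if n_components < 1 or n_bins < 2:
        raise ValueError("need n_components >= 1 and n_bins >= 2")
    if n_frames < n_components:
        raise ValueError("fewer frames than requested components")
    if superpose:
        ref = X[0]
        X = np.stack([kabsch_fit(f, ref).apply(f) for f in X])
    flat = X.reshape(n_frames, -1)
    flat = flat - flat.mean(axis=0)
    # PCA via SVD of the centered data matrix
    _, svals, Vt = np.linalg.svd(flat, full_matrices=False)
    k = min(n_components, svals.size)
    proj = flat @ Vt[:k].T
    S = 0.0
    for j in range(k):
        col = proj[:, j]
        lo, hi = col.min(), col.max()
        if hi - lo <= 1e-12:  # frozen component: a single microstate
            continue
        counts, _ = np.histogram(col, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / n_frames
        S += -KB * float(np.sum(p * np.log(p)))
    return S, T * S


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

def load_thermo_table(path=None) -> pd.DataFrame:
    """Load a binding-thermodynamics table (TSV).

    Without a path, loads the packaged Pru p 3 reference table (columns
    ligand, orientation, dG_kcal, dH_kcal, TdS_kcal and their uncertainties).
    """
    if path is None:
        ref = importlib.resources.files("tunnelscape").joinpath(
            "data/prup3_binding_thermo.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def check_thermo_table(
    table: pd.DataFrame | None = None,
    tol: float = 0.01,
    T: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Check every row of a thermo table for ΔG = ΔH − TΔS consistency.

    Returns the table with ``dG_recomputed``, ``residual`` and ``consistent``
    columns.  Inconsistent rows are flagged, not rejected — a printed table
    may carry sign typos in the TΔS column (the packaged reference table has
    one such row: phytosphingosine in orientation A).
    """
    if table is None:
        table = load_thermo_table()
    out = table.copy()
    out["dG_recomputed"] = [
        gibbs_combine(h, ts) for h, ts in zip(out["dH_kcal"], out["TdS_kcal"])
    ]
    out["residual"] = out["dG_kcal"] - out["dG_recomputed"]
    out["consistent"] = out["residual"].abs() <= tol
    return out


def records_from_table(table: pd.DataFrame, T: float = DEFAULT_TEMPERATURE) -> list[ThermoRecord]:
    return [
        ThermoRecord(ligand=str(r.ligand), orientation=str(r.orientation),
                     dH=float(r.dH_kcal), TdS=float(r.TdS_kcal),
                     dG=float(r.dG_kcal), T=T)
        for r in table.itertuples()
    ]
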