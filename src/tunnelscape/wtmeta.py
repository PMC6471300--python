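"""Well-tempered metadynamics on toy potentials.

Metadynamics discourages revisits of already-sampled regions of a collective
variable (CV) by depositing a history-dependent bias: a sum of Gaussian hills
centered at the CV values visited so far.  In the *well-tempered* variant the
height of each new hill shrinks as the accumulated bias grows,

    h(t) = H · exp( −V_bias(s(t), t) / (kB ΔT) ),

where ΔT is the bias temperature.  As the landscape fills, deposition decays
toward zero and the free energy along the CV is recovered from the converged
bias up to the well-tempered scale factor:

    F(s) = −(T + ΔT)/ΔT · V_bias(s) + const.

The bias factor γ = (T + ΔT)/T controls how much of the barrier is
effectively removed; ΔT → 0 recovers unbiased dynamics and ΔT → ∞ standard
(non-tempered) metadynamics.

The CV dynamics are propagated with an overdamped (Brownian) Langevin
integrator on analytic toy potentials — a desk-scale surrogate for running
the bias inside an all-atom MD engine.  Half-harmonic walls confine the CV,
playing the role of the restraints that keep a ligand from diffusing into
solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import _kernels
from .constants import DEFAULT_TEMPERATURE, KB

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import ToyPotential

__all__ = [
    "WTParams",
    "WallParams",
    "Hill",
    "HillsLog",
    "FESCurve",
    "wall_energy",
    "bias_energy",
    "next_hill_height",
    "bias_factor",
    "run_wt_metadynamics",
    "MetadRun",
    "reconstruct_fes",
    "reweighted_fes",
    "deposition_profile",
    "write_hills",
    "read_hills",
]


@dataclass(frozen=True)
class WTParams:
    """Well-tempered metadynamics parameters.

    Defaults are a production setting for a ligand sliding along a tunnel
    axis: initial hill height H = 0.1 kcal/mol, hill width δ = 0.05 Å, bias
    temperature ΔT = 4500 K, deposition period τ_G = 1000 fs, at T = 298 K.
    """

    H: float = 0.1          # initial hill height, kcal/mol
    delta: float = 0.05     # hill width δ, Å
    deltaT: float = 4500.0  # bias temperature ΔT, K
    tauG: float = 1000.0    # deposition period τ_G, fs
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("H", "delta", "deltaT", "tauG", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gamma(self) -> float:
        """Bias factor γ = (T + ΔT)/T."""
        return (self.T + self.deltaT) / self.T


@dataclass(frozen=True)
class WallParams:
    """Half-harmonic wall: zero inside [s_lo, s_hi], (K/2)(s − bound)² outside."""

    K: float = 40.0      # kcal/(mol·Å²)
    s_lo: float = -20.0  # Å
    s_hi: float = 12.5   # Å

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("wall force constant K must be non-negative")
        if not self.s_lo < self.s_hi:
            raise ValueError("wall bounds must satisfy s_lo < s_hi")


class Hill:
    """One deposited Gaussian: time (fs), center (Å), width (Å), height (kcal/mol)."""

    __slots__ = ("time", "center", "width", "height")

    def __init__(self, time: float, center: float, width: float, height: float):
        if width <= 0:
            raise ValueError("hill width must be positive")
        if height <= 0:
            raise ValueError("hill height must be positive")
        self.time, self.center, self.width, self.height = (
            float(time), float(center), float(width), float(height),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Hill(time={self.time}, center={self.center}, "
                f"width={self.width}, height={self.height})")

    def __eq__(self, other) -> bool:
        return isinstance(other, Hill) and (
            (self.time, self.center, self.width, self.height)
            == (other.time, other.center, other.width, other.height)
        )


@dataclass
class HillsLog:
    """Time-ordered deposited hills plus the parameters that produced them."""

    times: np.ndarray    # fs, strictly increasing
    centers: np.ndarray  # Å
    widths: np.ndarray   # Å
    heights: np.ndarray  # kcal/mol
    params: WTParams = field(default_factory=WTParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = self.times.size
        if not (self.centers.size == self.widths.size == self.heights.size == n):
            raise ValueError("hill columns must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("hill times must be strictly increasing")
        if np.any(self.widths <= 0) or np.any(self.heights <= 0):
            raise ValueError("hill widths and heights must be positive")

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, i: int) -> Hill:
        return Hill(self.times[i], self.centers[i], self.widths[i], self.heights[i])

    def __eq__(self, other) -> bool:
        if not isinstance(other, HillsLog):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.widths, other.widths)
            and np.array_equal(self.heights, other.heights)
        )

    @classmethod
    def empty(cls, params: WTParams | None = None) -> "HillsLog":
        return cls(np.empty(0), np.empty(0), np.empty(0), np.empty(0),
                   params=params or WTParams())


@dataclass
class FESCurve:
    """Free energy vs CV1 on a regular grid, shifted so its minimum is zero."""

    grid: np.ndarray          # Å, strictly increasing
    free_energy: np.ndarray   # kcal/mol, min = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.size == 0:
            raise ValueError("FES grid must be non-empty")
        if self.grid.size != self.free_energy.size:
            raise ValueError("grid and free_energy must have equal length")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("FES grid must be strictly increasing")
        # normalize: free energies are defined up to a constant
        self.free_energy = self.free_energy - self.free_energy.min()


def wall_energy(s, wall: WallParams):
    """Half-harmonic wall energy and gradient at CV value(s) ``s``.

    Zero on [s_lo, s_hi]; (K/2)(s − s_hi)² above, (K/2)(s − s_lo)² below.
    Returns ``(energy, gradient)`` with the shape of ``s``.
    """
    s = np.asarray(s, dtype=float)
    over = np.clip(s - wall.s_hi, 0.0, None) + np.clip(s - wall.s_lo, None, 0.0)
    energy = 0.5 * wall.K * over**2
    grad = wall.K * over
    if s.ndim == 0:
        return float(energy), float(grad)
    return energy, grad


def bias_energy(hills: HillsLog, s) -> float | np.ndarray:
    """Exact metadynamics bias V(s) = Σ_i h_i exp(−(s − c_i)²/(2 δ_i²)).

    Evaluates the full Gaussian summation (no caching); vectorized over ``s``.
    """
    s = np.asarray(s, dtype=float)
    if len(hills) == 0:
        out = np.zeros(s.shape)
        return float(out) if s.ndim == 0 else out
    flat = np.atleast_1d(s).astype(float)
    out = np.zeros(flat.shape)
    # chunk over hills to bound memory on long logs
    step = max(1, int(4e6 // max(flat.size, 1)))
    for i in range(0, len(hills), step):
        c = hills.centers[i : i + step]
        w = hills.widths[i : i + step]
        h = hills.heights[i : i + step]
        out += np.sum(
            h * np.exp(-((flat[:, None] - c[None, :]) ** 2) / (2.0 * w[None, :] ** 2)),
            axis=1,
        )
    return float(out[0]) if s.ndim == 0 else out.reshape(s.shape)


def next_hill_height(params: WTParams, v_bias_here: float) -> float:
    """Tempered height of the next hill, H·exp(−V/(kB ΔT)) ∈ (0, H]."""
    if v_bias_here < 0:
        raise ValueError("bias energy must be non-negative")
    return params.H * math.exp(-v_bias_here / (KB * params.deltaT))


def bias_factor(params: WTParams) -> float:
    """γ = (T + ΔT)/T."""
    return params.gamma


@dataclass
class MetadRun:
    """Result of :func:`run_wt_metadynamics`."""

    cv_traj: np.ndarray   # (n_saved, n_cv)
    hills: HillsLog
    times: np.ndarray     # fs, per saved sample
    params: WTParams
    walls: tuple[WallParams | None, ...]
    seed: int
    dt: float
    diffusion_coeff: float


def run_wt_metadynamics(
    potential: "ToyPotential",
    params: WTParams | None = None,
    walls: "WallParams | list[WallParams | None] | None" = None,
    n_steps: int = 1_000_000,
    dt: float = 0.5,
    diffusion_coeff: float = 0.1,
    seed: int = 0,
    x0: np.ndarray | float | None = None,
    sample_stride: int = 1,
    sanity_bound: float | None = None,
    bias: bool = True,
    grid_spacing: float | None = None,
) -> MetadRun:
    """Well-tempered metadynamics with an overdamped Langevin integrator.

    The CV evolves by the Euler–Maruyama update
    ``s ← s − (D/kB T)·∇(U + V_bias + V_walls)·dt + sqrt(2 D dt)·η`` with
    standard-normal η; a hill is deposited every ``tauG`` of simulated time at
    the current CV with the tempered height.  The run is deterministic for a
    fixed seed.

    Parameters
    ----------
    potential : ToyPotential
        Toy energy surface (1-D axial, or axial + harmonic radial).
    walls : WallParams, list thereof (one per CV, None = no wall), or None.
    bias : set False to run plain (unbiased) Langevin dynamics.
    grid_spacing : spacing of the internal gridded-bias cache; defaults to
        δ/100, which keeps cached energies within 1e-6 kcal/mol of the exact
        Gaussian summation.
    sanity_bound : abort with a diagnostic if |CV1| exceeds this (default:
        20 Å past the outermost wall bound, or 60 Å without walls).
    """
    params = params or WTParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = potential.dim
    if isinstance(walls, WallParams):
        walls = [walls] + [None] * (d - 1)
    elif walls is None:
        walls = [None] * d
    walls = list(walls) + [None] * (d - len(walls))
    wall_k = np.array([w.K if w else 0.0 for w in walls], dtype=float)
    wall_lo = np.array([w.s_lo if w else 0.0 for w in walls], dtype=float)
    wall_hi = np.array([w.s_hi if w else 0.0 for w in walls], dtype=float)

    if sanity_bound is None:
        if walls[0] is not None:
            sanity_bound = max(abs(walls[0].s_lo), abs(walls[0].s_hi)) + 20.0
        else:
            sanity_bound = 60.0

    if x0 is None:
        x = np.zeros(d)
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
        if x.size != d:
            raise ValueError(f"x0 must have {d} components")

    # tabulate the axial potential gradient over the reachable domain
    tab_lo, tab_hi = -sanity_bound - 2.0, sanity_bound + 2.0
    tab_h = 1e-3
    xs = np.arange(tab_lo, tab_hi + tab_h, tab_h)
    u_grad_tab = np.asarray(potential.axial_gradient(xs), dtype=float)

    # gridded bias cache on the same domain
    bias_h = grid_spacing if grid_spacing is not None else params.delta / 100.0
    n_bias = int(math.ceil((tab_hi - tab_lo) / bias_h)) + 1
    bias_val = np.zeros(n_bias)
    bias_grad = np.zeros(n_bias)

    tau_steps = max(1, int(round(params.tauG / dt)))
    max_hills = n_steps // tau_steps + 2
    hill_t = np.zeros(max_hills)
    hill_c = np.zeros(max_hills)
    hill_h = np.zeros(max_hills)
    n_saved_max = n_steps // sample_stride + 1
    traj_out = np.zeros((n_saved_max, d))

    kT = KB * params.T
    n_hills, n_saved, status, at_step = _kernels.run_langevin(
        x, n_steps, dt, diffusion_coeff / kT, math.sqrt(2.0 * diffusion_coeff * dt),
        tab_lo, tab_h, u_grad_tab,
        float(getattr(potential, "radial_k", 0.0) or 0.0),
        wall_k, wall_lo, wall_hi,
        bool(bias), params.H, params.delta, KB * params.deltaT, tau_steps,
        tab_lo, bias_h, bias_val, bias_grad,
        float(sanity_bound), int(sample_stride),
        traj_out, hill_t, hill_c, hill_h,
        int(seed),
    )
    if status == _kernels.DIVERGED:
        raise RuntimeError(
            f"CV1 exceeded the sanity bound ({sanity_bound:g} Å) at step {at_step} "
            f"(t = {at_step * dt:g} fs); the integration diverged or the walls "
            "do not confine the dynamics — reduce dt or tighten the walls"
        )
    hills = HillsLog(
        times=hill_t[:n_hills], centers=hill_c[:n_hills],
        widths=np.full(n_hills, params.delta), heights=hill_h[:n_hills],
        params=params, seed=int(seed),
    )
    times = (np.arange(1, n_saved + 1) * sample_stride) * dt
    return MetadRun(
        cv_traj=traj_out[:n_saved], hills=hills, times=times, params=params,
        walls=tuple(walls), seed=int(seed), dt=dt, diffusion_coeff=diffusion_coeff,
    )


def reconstruct_fes(hills: HillsLog, grid: np.ndarray, time_average: float = 0.0) -> FESCurve:
    """Free energy from the converged well-tempered bias.

    F(s) = −(T + ΔT)/ΔT · V_bias(s), shifted so min over the grid is zero.

    Parameters
    ----------
    time_average : fraction of the run (from the end) over which the bias is
        time-averaged before rescaling.  0 uses the final bias only.
        Averaging the slowly-varying late-stage bias suppresses the
        high-frequency noise left by individual narrow hills without biasing
        the converged profile, and is the standard way to read out a
        well-tempered run.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("FES grid must be non-empty")
    if not 0.0 <= time_average < 1.0:
        raise ValueError("time_average must be in [0, 1)")
    p = hills.params
    scale = (p.T + p.deltaT) / p.deltaT
    n = len(hills)
    if time_average > 0.0 and n > 1:
        # mean over t in the averaging window of V(s, t) = sum of hills up to t:
        # hill i contributes with weight = fraction of window times >= time_i
        i0 = int(np.floor((1.0 - time_average) * n))
        i0 = min(i0, n - 1)
        m = n - i0  # checkpoints: after hills i0 .. n-1
        w = np.ones(n)
        w[i0:] = (n - np.arange(i0, n)) / m
        weighted = HillsLog(
            times=hills.times, centers=hills.centers, widths=hills.widths,
            heights=hills.heights * w, params=p, seed=hills.seed,
        )
        v = np.atleast_1d(bias_energy(weighted, grid))
    else:
        v = np.atleast_1d(bias_energy(hills, grid))
    f = -scale * v
    f = f - f.min()
    return FESCurve(grid=grid, free_energy=f)


def reweighted_fes(run: MetadRun, grid: np.ndarray, discard: float = 0.5) -> FESCurve:
    """Histogram-reweighted free energy from the late, quasi-static stage.

    Once the well-tempered bias varies slowly, the sampled CV density obeys
    ρ(s) ∝ exp(−(F(s) + V(s))/kB T), so

        F(s) = −kB T · ln ρ(s) − V̄(s) + const,

    with V̄ the bias time-averaged over the same window.  Because the walker
    responds to the *actual* deposited bias, the shot noise frozen into V by
    the early large hills cancels between the two terms; this readout
    therefore converges faster than rescaling the bias alone
    (:func:`reconstruct_fes`) and is the recommended high-precision estimate.

    Parameters
    ----------
    run : result of :func:`run_wt_metadynamics` (needs the CV trajectory).
    discard : fraction of the run dropped from the start (burn-in while the
        bias is still filling).
    Grid points never visited in the window carry +inf.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("need a grid of at least 2 points")
    if not 0.0 <= discard < 1.0:
        raise ValueError("discard must be in [0, 1)")
    p = run.params
    kT = KB * p.T
    n = run.cv_traj.shape[0]
    samples = run.cv_traj[int(discard * n):, 0]
    dg = grid[1] - grid[0]
    edges = np.concatenate([grid - dg / 2, [grid[-1] + dg / 2]])
    counts, _ = np.histogram(samples, bins=edges)
    # time-averaged bias over the same late window, up to a constant
    fes_v = reconstruct_fes(run.hills, grid, time_average=1.0 - discard)
    vbar = -fes_v.free_energy * (p.deltaT / (p.T + p.deltaT))
    with np.errstate(divide="ignore"):
        f = np.where(counts > 0, -kT * np.log(np.maximum(counts, 1)) - vbar, np.inf)
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("no samples fell on the grid")
    f = f - f[finite].min()
    return FESCurve(grid=grid, free_energy=f)


def deposition_profile(hills: HillsLog, window: float):
    """Deposited bias energy per consecutive time window.

    Returns ``(window_starts, deposited)``: windows [0, w), [w, 2w), … up to
    the last hill; ``deposited`` is the sum of hill heights in each window.
    Flat at early times and decaying toward zero as the run converges.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(hills) == 0:
        return np.empty(0), np.empty(0)
    # a hill exactly on the last boundary belongs to the final window, so an
    # end time that is an exact multiple of the window yields t/window whole
    # windows, not one more holding a single hill
    n_win = max(1, int(math.ceil(hills.times[-1] / window - 1e-9)))
    idx = np.minimum((hills.times // window).astype(int), n_win - 1)
    deposited = np.bincount(idx, weights=hills.heights, minlength=n_win)
    return np.arange(n_win) * window, deposited


# ---------------------------------------------------------------------------
# hills TSV I/O
# ---------------------------------------------------------------------------

def write_hills(hills: HillsLog, path) -> None:
    """TSV with columns time_fs, center_A, width_A, height_kcal.

    Header comments carry the run parameters and seed so the log is
    self-contained for FES reconstruction.
    """
    p = hills.params
    with open(path, "w") as fh:
        fh.write(f"# wtmeta H={p.H:.17g} delta={p.delta:.17g} "
                 f"deltaT={p.deltaT:.17g} tauG={p.tauG:.17g} T={p.T:.17g}"
                 + (f" seed={hills.seed}" if hills.seed is not None else "") + "\n")
        fh.write("time_fs\tcenter_A\twidth_A\theight_kcal\n")
        for t, c, w, h in zip(hills.times, hills.centers, hills.widths, hills.heights):
            fh.write(f"{t:.17g}\t{c:.17g}\t{w:.17g}\t{h:.17g}\n")


def read_hills(path) -> HillsLog:
    """Read a hills TSV written by :func:`write_hills` (exact round trip)."""
    params_kw: dict[str, float] = {}
    seed = None
    rows: list[tuple[float, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "seed":
                            seed = int(v)
                        elif k in ("H", "delta", "deltaT", "tauG", "T"):
                            params_kw[k] = float(v)
                continue
            if line.startswith("time_fs"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                rows.append(tuple(float(v) for v in parts))  # type: ignore[arg-type]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    arr = np.array(rows, dtype=float).reshape(-1, 4)
    params = WTParams(**params_kw) if params_kw else WTParams()
    return HillsLog(times=arr[:, 0], centers=arr[:, 1], widths=arr[:, 2],
                    heights=arr[:, 3], params=params, seed=seed)


def write_fes(fes: FESCurve, path) -> None:
    """TSV with columns cv1_A, free_energy_kcal."""
    with open(path, "w") as fh:
        fh.write("cv1_A\tfree_energy_kcal\n")
        for s, f in zip(fes.grid, fes.free_energy):
            fh.write(f"{s:.17g}\t{f:.17g}\n")


def read_fes(path) -> FESCurve:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return FESCurve(grid=df.iloc[:, 0].to_numpy(), free_energy=df.iloc[:, 1].to_numpy())
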