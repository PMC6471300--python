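# Methods

`tunnelscape` implements a protocol for characterizing the motion of a
lipid-like ligand inside a tunnel-shaped protein cavity, of the kind found in
plant lipid transfer proteins (LTPs) such as Pru p 3. The protocol has four
stages: (1) derive a *diffusion axis* from pocket-occupancy grids, (2) define
two collective variables (CVs) in a body-fixed reference frame, (3) explore
the free-energy landscape along the axis with well-tempered metadynamics
confined by harmonic walls, and (4) analyze the resulting landscape and
trajectories (basins and barriers, residue contact modes, configurational
entropy, cavity-volume coupling). This note records the model, the
assumptions, the defaults, and the numerical choices.

## Diffusion axis from pocket grids

Pocket-detection tools emit a voxel grid of pocket frequencies in [0, 1]
(OpenDX format). All voxels with frequency strictly above a cutoff
(default 0.2) become a world-coordinate point cloud; the eigenvectors of the
sample covariance (unbiased, n−1 denominator) of those points, sorted by
descending eigenvalue, are the cavity axes. The leading axis — the direction
of greatest cavity extent — is the diffusion axis.

Choices:

* Thresholding is strict (`>`), and points are unweighted by default; a
  frequency-weighted covariance is available (`weights=` in
  `diffusion_axes`) but not the default, since the threshold already selects
  the high-confidence cavity region.
* Eigenvector sign is fixed by orienting each axis so its largest-magnitude
  component is positive — deterministic across eigensolver implementations.
* Adjacent eigenvalues within 1% relative difference, rank deficiency, or
  clouds of fewer than 4 points set a `degenerate` flag (with notes) rather
  than raising: the protocol still runs, the user is warned that the axes are
  not unique.

## Collective variables in the fitted frame

To remove overall diffusion and tumbling, every frame is superposed onto a
reference structure by the optimal rigid (Kabsch) transform computed over
*anchor atoms*: alpha-carbons whose RMSF lies strictly below a threshold
(default 1.0 Å), which in a helix-bundle protein selects the rigid helical
core. RMSF uses a single alignment pass onto the first frame (not iterative
superposition); with well-separated rigid and floppy regions the selection is
insensitive to this choice, but it is a documented divergence risk for
borderline atoms.

With the frame fitted, let **d** be the displacement of the ligand-tail
centroid from its reference position and **u** the unit diffusion axis:

    CV1 = d · u                  (signed, Å)
    CV2 = ‖d − (d·u) u‖          (≥ 0, Å)

The tail is the aliphatic-chain carbons only; a bulky polar head (and the
short bridge linking it to the tail) is excluded from the centroid because
its internal torsions would contaminate the diffusion coordinate. The
centroid is unweighted (equal carbon masses make geometric centroid and
center of mass identical). The CV origin is the starting structure, which
therefore maps to (0, 0).

`kabsch_fit` is an SVD implementation with the determinant correction, so
mirrored inputs still return a proper rotation (det = +1) with residual RMSD;
collinear or otherwise rank-deficient anchor sets raise.

## Well-tempered metadynamics engine

The engine biases one CV (the diffusion axis) with Gaussian hills of width
δ deposited every τ_G of simulated time. Hill heights are tempered:

    h(t) = H · exp(−V(s(t), t) / (kB ΔT)),

and the free energy is read out from the accumulated bias as

    F(s) = −(T + ΔT)/ΔT · V(s) + const.

Half-harmonic walls U_w = (K/2)(s − s₀)² outside [s₀⁻, s₀⁺] confine the CV,
standing in for the restraints that keep a real ligand out of bulk solvent.

Defaults (production setting for the tunnel problem): H = 0.1 kcal/mol,
δ = 0.05 Å, ΔT = 4500 K (bias factor γ = (T+ΔT)/T ≈ 16.1), τ_G = 1000 fs,
T = 298 K, wall K = 40 kcal/(mol·Å²) with the longitudinal wall at
[−20, 12.5] Å on CV1 and a radial upper wall at 9 Å on CV2 (CV2 ≥ 0 needs no
lower wall); the assignment is configurable. kB = 1.987204×10⁻³
kcal/(mol·K). τ_G counts *simulated time*, not steps.

### Dynamics

Desk-scale surrogate dynamics are overdamped (Brownian) Langevin with the
Euler–Maruyama update

    s ← s − (D/kB T)·∇(U + V + U_walls)·dt + sqrt(2 D dt)·η,

with D = 0.1 Å²/fs by default. Two accuracy rules govern dt:

* **Stability**: the scheme requires dt < 2 kB T/(D·k_max) where k_max is the
  largest curvature encountered. The default wall stiffness K = 40 gives a
  bound of ≈ 0.3 fs; the default dt = 0.1 fs. At dt = 0.2 fs the wall region
  is weakly unstable and measurably corrupts the landscape tails.
* **Accuracy**: the discrete stationary variance of a harmonic well of
  stiffness k exceeds kB T/k by the factor 2/(2 − θ), θ = D k dt/(kB T);
  keeping θ ≲ 0.05 keeps the bias under ~3%.

Trajectories that leave a sanity bound on |CV1| (default: 20 Å beyond the
outermost wall) abort with a diagnostic rather than producing silent garbage.

### Gridded-bias cache

The inner loop is JIT-compiled (numba) and O(1) per step: the axial potential
gradient is pre-tabulated (1 mÅ spacing), and the bias plus its gradient are
accumulated on a fine grid (spacing δ/100) as hills are deposited, truncating
each Gaussian at ±8δ (relative truncation < 1e-14). The public `bias_energy`
is the exact Gaussian summation; tests verify cache and exact summation agree
to < 1e-6 kcal/mol. At the problem sizes used (10⁹ steps, 10⁵ hills) exact
per-step summation would be ~10⁹× slower and is not an option.

Determinism: the kernel seeds its own generator; identical seeds give
bit-identical trajectories and hills logs, and the seed is recorded in the
hills-file header.

### Free-energy readout

`reconstruct_fes` rescales the bias, optionally *time-averaged* over the late
fraction of the run (`time_average=0.5` recommended): with hills as narrow as
δ = 0.05 Å the instantaneous bias carries visible shot noise from individual
hills, which averaging suppresses without biasing the converged profile.
`reweighted_fes` additionally combines the late-stage CV histogram with the
time-averaged bias, F = −kB T ln ρ − V̄; because the walker responds to the
actually-deposited bias, frozen-in deposition noise cancels between the two
terms. For barrier measurements, `landscape.main_barrier` detects the two
deepest basins and measures the saddle on a moving-average-smoothed curve:
extrema of the raw noisy curve are biased (a max systematically picks up
positive noise).

### Convergence

`deposition_profile` sums deposited hill energy per time window; a converged
well-tempered run deposits a small fraction of its early rate at the end.
On the double-well benchmark (5 kcal/mol barrier, minima ±2 Å) the
fill-up crossover time is ~5×10⁶ fs with the default parameters, so runs of
1.5×10⁸ fs (1.5×10⁹ steps at dt = 0.1 fs) are used where the final-decile to
first-decile deposition ratio is required to drop below 0.1. At that length
the recovered barrier across seeds is 5.0 ± ~0.4 kcal/mol.

## Contact-covariance residue clustering

The ligand is split into head/tail/bridge parts. Per frame and per
(residue, part) pair the minimum heavy-atom distance feeds a logistic switch

    f(d) = 2/(1 + exp((d − d₀)/λ)) − 1 ∈ (−1, 1),

with d₀ = 4.5 Å and λ = 1.0 Å by default (typical heavy-atom contact scale;
both configurable). The covariance of these signals over time is embedded
with the scale-free dissimilarity 1 − C/max|C| and clustered with
average-linkage agglomeration, cut at k clusters (k = 4 by default, matching
common practice of cutting after dendrogram inspection). Channels are
(residue, part) pairs; residues inherit the cluster of their
largest-total-|covariance| channel. Aggregation over atom pairs (minimum
distance), the dissimilarity, and the residue rule are package choices where
the protocol leaves them open; all are deterministic.

## Thermodynamics

ΔG = ΔH − TΔS at T = 298 K assembles an externally computed enthalpy
(MM–PBSA in the original protocol; consumed as input here, never computed)
with a configurational entropy estimated by the PCA-histogram method:
superpose frames, PCA on flattened Cartesian deviations, histogram each
retained component independently (defaults: 10 components, 30 bins), and sum
the discrete Shannon entropies, S = −kB ΣΣ p ln p. The estimate is
bin-width dependent; comparisons are only meaningful at fixed binning, and
results should be reported with the binning. Affinity ratios between poses
follow exp(ΔΔG/RT).

The packaged reference table of Pru p 3 binding estimates contains one row
(phytosphingosine, orientation A) whose printed TΔS entry lacks a minus sign
and violates ΔG = ΔH − TΔS; `check_thermo_table` flags rather than asserts
such rows.

## Landscape analyses

* `find_basins`: local minima of the (optionally smoothed) curve; saddles are
  interval maxima between adjacent minima; basins shallower than `min_depth`
  relative to their lowest adjacent saddle are merged, shallowest first.
  Labels are energy ranks (0 = deepest); barrier heights are measured from
  the shallower adjacent minimum. Curve endpoints count as minima when the
  curve rises away from them (a monotone ramp has one basin at its low end).
* Radius of gyration uses the *mean-distance* convention, mean‖r − r̄‖ (a
  robust size proxy); the conventional RMS version is available separately
  as `radius_of_gyration_rms`, and mean ≤ RMS by Jensen's inequality.
* Contact counts are strict-inequality pair counts at a 4.5 Å heavy-atom
  cutoff (configurable).
* Cavity-volume/CV1 coupling is a Pearson correlation with a flagged zero for
  zero-variance inputs; the *sign* of the coupling distinguishes the two
  ligand orientations. Volume series come from external pocket tools or the
  synthetic generator — pocket-volume computation itself is out of scope.

## Synthetic systems and what they do (not) show

The fixture generators make every stage testable without external data:

* **Toy potentials** (double well with exact barrier by construction,
  harmonic well, 3-D tunnel = axial profile + harmonic radial confinement)
  have analytic gradients and free-energy profiles, so engine output is
  checked against closed forms.
* **Scaffold + ligand trajectories**: 40 pseudo-alpha-carbons on four helical
  arcs (echoing the four-helix LTP fold) with sub-threshold jitter, plus 8
  floppy loop atoms whose wobble exceeds the 1 Å RMSF threshold, so the
  anchor selection has realistic structure; a 19-atom ligand (5-atom head,
  12-carbon tail, 2-atom bridge) follows a scripted CV1 course along a
  declared axis; optional per-frame random rigid roto-translations exercise
  the frame fitting. Frame 0 (the reference) stays unrotated, because the
  diffusion axis and CV origin are defined in the reference structure's
  coordinates. Ground truth is the script.
* **Pocket grids**: frequencies high inside an ellipsoid elongated along a
  known axis (semi-axes 8/3/2 Å by default), background noise below the 0.2
  cutoff.

These fixtures have rigid scaffolds, isotropic noise, a quadratic radial
cavity, and no solvent, force field, or slow conformational modes. Passing
tests therefore demonstrate the correctness of the *computational protocol*
(axis extraction, frame fitting, bias accumulation, readouts), not the
behavior of real all-atom systems; quantities that depend on the real
trajectories (specific residue clusters, absolute entropies, cavity volumes)
are validated only structurally (block recovery, closed-form limits,
constructed correlations).

## Problem sizes

Default test/analysis scales, chosen as desk-scale equivalents of the
production regime: metadynamics benchmark 3 seeds × 1.5×10⁹ steps at
dt = 0.1 fs (1.5×10⁸ fs each, ~1.5×10⁵ hills); unbiased harmonic check 10⁶
steps at dt = 0.05 fs; pocket grids of ~30³ voxels; trajectories of 25–50
frames and ~70 atoms.

## Known limitations

* One biased CV only (the diffusion axis); 2-D (CV1, CV2) surfaces and
  multiple-walker or funnel variants are out of scope.
* Overdamped point dynamics on analytic potentials — no inertia, hydrodynamics
  or explicit coupling to an all-atom engine.
* The Euler–Maruyama scheme over-populates very steep regions at finite dt;
  with the default dt this matters only where the potential exceeds ~20
  kcal/mol above the wells (negligible Boltzmann weight).
* The discrete entropy estimator is binning-dependent and not an absolute
  entropy.
* Trajectory I/O covers multi-model PDB and XYZ (text); binary formats can be
  added behind the same `Trajectory` contract but are not in the core.
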