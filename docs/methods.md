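# Methods

This note records the models, conventions, and numerical choices behind
`lovspec`, and what its synthetic-data studies do and do not demonstrate.

## Pocket states and conformational clustering

Tracked side chains are classified from heavy-atom H-bond distances only
(hydrogens are ignored throughout the geometry stack): *in* below 4.0 Å,
*out* above 5.0 Å, *intermediate* in the 4–5 Å gap. The gap frames enter no
in/out population statistic — only the two outer regimes are physically
defined. Frame classes follow the joint rule: IN requires every tracked
residue in; OUT requires at least one residue out; a frame with an
intermediate residue and no out residue is unassigned. The classification is
monotone by construction: increasing a distance can only move a state toward
*out*.

Distance features are used in raw Å (no standardization — all features share
units, and standardizing would inflate near-constant H-bonds). PCA retains
the smallest number of components reaching the configured cumulative
explained variance (default 0.9). Density clustering (HDBSCAN, via
scikit-learn) runs in the retained PCA space; clusters below the population
floor (default 1 %) are relabeled noise, and retained clusters are re-indexed
by decreasing population so ids are deterministic (cluster 0 is always the
dominant conformation — arbitrary external cluster names are not
reproduced). `min_samples` is exposed separately from `min_cluster_size`:
the pipeline default, max(min_cluster_size, 1 % of frames), smooths the
density estimate enough that a large dense cluster is not split in
low-dimensional projections, while a caller hunting for small clusters can
lower both. A zero-variance point cloud is a degenerate input for density
clustering; it is returned as a single cluster holding all points.
Cluster IN/OUT labels need a strict majority (> 50 % of the cluster's
frames) of IN or OUT frame classes; ties and intermediate-dominated clusters
stay unassigned. Representatives are sampled uniformly without replacement,
seeded.

## Crowding metric

Each fragment's pseudo-density is a sum of *unit-normalized* isotropic 3-D
Gaussians on its heavy atoms, σ = Bondi van der Waals radius (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å; overridable by a CSV radius table). Unit
normalization makes the raw overlap integral well-defined (Å⁻³) and the
Carbó-normalized index scale-free; the normalized index is the default
reported quantity because it is comparable across fragments with different
atom counts, but both are emitted since either may be the quantity a reader
wants. The pairwise overlap has the closed form
(2π(σᵢ²+σⱼ²))^(−3/2)·exp(−dᵢⱼ²/2(σᵢ²+σⱼ²)); tests verify it against an
independent 3-D grid quadrature (0.05 Å spacing, 12 Å padding), evaluated by
exact per-axis factorization of the Riemann sum. Argument order is
canonicalized internally so O(A,B) = O(B,A) holds exactly in floating point.

## Ring RMSD

Superposition uses the least-squares (Kabsch) rotation, determinant-corrected
to exclude reflections, computed on the *fit* atom set (a backbone scaffold);
the RMSD is then evaluated over the *target* atoms (the isoalloxazine ring)
without refitting, so it measures residual chromophore motion relative to the
fitted frame. Fewer than three fit atoms is an error; frames failing a
geometric precondition elsewhere (e.g. a collinear dihedral triple) yield
flagged missing values rather than aborting a long trajectory.

Dihedrals use the standard sign convention: positive when, viewed along the
central bond, the far bond is rotated clockwise; values lie in (−180°, 180°].

## Vibronic lineshapes

The homogeneous absorption profile is the second-order cumulant lineshape for
the displaced harmonic oscillator (for which the cumulant expansion is
exact):

    g(t) = Σₖ Sₖ [coth(ħωₖ / 2k_BT)(1 − cos ωₖt) + i sin ωₖt]
    σ(Δω) = Re ∫₀^∞ exp(i Δω t − g(t) − Γ t) dt,   area-normalized on its grid.

Conventions and numerics:

* **Origin.** σ is computed relative to the 0-0 line; on ensemble assembly
  each snapshot's *vertical* excitation energy is placed at the origin. The
  absolute-position convention is free because reported spectra are rigidly
  shifted and max-normalized anyway; the metadata records both operations.
* **Temperature.** Default 300 K (the simulation temperature); T = 0 is
  supported (coth → 1) and used by the Franck–Condon oracle tests, where the
  single-mode spectrum must reproduce Poisson peak weights e^(−S)Sⁿ/n!
  convolved with the Lorentzian damping.
* **Damping.** Homogeneous Lorentzian with HWHM Γ, default 100 cm⁻¹
  (configurable, logged). Lorentzian tails hold ~Γ/(πW) of area beyond ±W, so
  the default grid pads by 64 Γ to keep >99 % of the line on-grid; a grid
  missing ≥1 % of the analytic area (π·f(0) in angular measure) raises a
  coverage error rather than silently truncating.
* **Transform.** e^(−g(t)−Γt) is sampled at 0.25 fs up to the time where it
  decays below 10⁻⁹, Fourier-transformed by FFT (zero-padded 4×) and
  interpolated onto the requested wavenumber grid. Tiny negative truncation
  ripples are clipped to zero after the coverage check. The first moment of
  the T→0 spectrum above the origin equals the reorganization energy
  λ = Σₖ Sₖωₖ, which the tests check.
* **Huang–Rhys from gradients.** Sₖ = gₖ²/(2ħωₖ³) in a consistent unit system
  (ħ = 1 by default); this is the vertical-gradient approximation,
  algebraically identical to Δₖ = gₖ/ωₖ², Sₖ = ωₖΔₖ²/2ħ, which the tests use
  as a second route. Huang–Rhys sets are computed once per system (from a
  reference structure) and shared across snapshots.
* **Ensemble and averages.** I(ω) = Σⱼ |μ₀₁⁽ʲ⁾|² σ(ω − ω₀₁⁽ʲ⁾), energies
  converted at 1 eV = 8065.544 cm⁻¹; transition-dipole units are arbitrary
  but must be consistent (spectra are normalized for reporting).
  Population-weighted averages renormalize populations over the supplied
  clusters and require a shared grid.

## Stokes tables

Per-record Stokes shifts (EXC − EMI)·8065.544 cm⁻¹ are averaged per cluster
*before* any rounding; the weighted row uses populations renormalized over
retained clusters. Reported tables round energies to 2 decimals (eV) and
shifts to integers (cm⁻¹), keeping unrounded values internally. A consistency
helper bounds |SS − (EXC−EMI)·8065.544| for a rounded row by 81 cm⁻¹ (two
2-decimal roundings move the gap by at most 0.01 eV ≈ 80.7 cm⁻¹).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* of the real problem at
toy scale, with exact ground truth:

* **Side-chain dynamics** are discrete-time Markov chains on the frame grid
  (an exponential/geometric dwell approximation of the few-hundred-ns in/out
  switching of pocket side chains). Default in-state distance 2.9 ± 0.2 Å and
  out-state 6.5 ± 0.8 Å straddle the 4/5 Å thresholds with a clear gap;
  distances are truncated below 1.5 Å (redrawn, not clipped) to avoid
  unphysical contacts. Default dwell times are 250 ns per state at 1 ns frame
  spacing.
* **Planted classes.** A config may instead prescribe joint pocket classes
  with stationary populations. The class chain leaves class i with
  probability (Δt/τ)(1 − πᵢ) per frame and re-enters j ∝ πⱼ, which makes the
  prescribed populations exactly stationary while dominant classes dwell
  longer. The planted-class recovery study (populations 77.5/17/5/0.5 %,
  n = 5000) uses a 2 ns base dwell so the rare class is realised in many
  short sojourns — at long dwells its realised population swings by factors
  of two and the study would measure realisation noise, not the clustering.
  That study retains PCA variance 0.99 (the rare class lives on the second
  feature axis, which a 0.9 target projects away) and min_cluster_size 10
  (the 1 % filter can only remove a cluster HDBSCAN is allowed to form).
* **Energies.** Excitation and emission are jointly Gaussian per class with
  correlation 0.97 by default: in per-cluster flavin tables the
  excitation–emission gap is far stiffer (~0.01 eV spread) than the energies
  themselves (~0.05 eV across clusters), and independent draws would inflate
  per-record Stokes-shift noise by ~4×. Records always satisfy EXC > EMI
  (violating pairs are redrawn).
* **Coordinates.** Distance series are embedded exactly: acceptors sit on a
  fixed scaffold, donors move along per-residue axes, so the distance ↔
  coordinate round trip is exact and files stay tiny. The toy ring system
  adds a jittered rigid ring, a rotamer-bearing side chain, and a random
  global rigid motion per frame so RMSD analyses must genuinely superpose.

Passing these studies shows the *pipeline* recovers planted truth under
clean two-state statistics. It does not demonstrate performance on real MD:
real pockets have water-mediated bridging states, correlated multi-residue
motions, non-Gaussian distance distributions, and force-field artifacts, none
of which the generator emulates. No force-field realism, water molecules, or
full-protein topology is attempted.

## Pipeline

One YAML config drives all variants through identical stages so cross-variant
deltas are a controlled in-silico experiment. Stages are re-runnable from
cached intermediates (the spectroscopy side can be recomputed without
re-clustering); every output carries the config hash; per-variant seeds are
derived deterministically from the base seed. Validation rejects unknown
keys by name. Study sizes in the bundled example (2000 frames per variant,
250-frame ring trajectories, 2000-record Stokes contrasts) were chosen so
the statistical checks resolve their planted effects with comfortable
margins at desktop scale.

## Known limitations

* The cumulant machinery computes absorption lineshapes only; emission
  lineshapes (and hence fluorescence band shapes) are out of scope.
* Only multi-model PDB and XYZ trajectories are read; XYZ carries no residue
  labels, so selectors there address atoms by file order.
* The Lorentzian damping model has no inhomogeneous (Gaussian) component;
  ensemble broadening comes from the snapshot energy distribution itself.
* HDBSCAN hyperparameters are surfaced, not auto-tuned; strongly
  non-Gaussian or high-dimensional feature sets may need caller judgement on
  `min_cluster_size`/`min_samples`.
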