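# Methods

## Toy landscapes

The receptor–ligand system is reduced to a single ligand pseudo-particle
moving in an analytic potential

U(r) = Σᵢ −dᵢ·exp(−|r−cᵢ|²/2wᵢ²) + Σⱼ hⱼ·exp(−|r−cⱼ|²/2wⱼ²) + U_wall(r),

a sum of attractive Gaussian wells (binding sites, depth dᵢ > 0),
repulsive Gaussian bumps (unfavourable patches, height hⱼ > 0) and a
harmonic wall U_wall = ½k·Σ max(|xₐ|−L, 0)² outside a box of half-length L
(default 25 Å, k = 10 kcal/mol/Å²).  Units are Å, ps, amu and kcal/mol
with kB = 0.0019872 kcal·mol⁻¹·K⁻¹, so standard MD settings (310 K, 2 fs
steps, 5 Å thresholds) are usable verbatim.  Harmonic walls were chosen
over periodic boundaries because the supervision method needs bounded
diffusion and a meaningful "far from the site" region; setting L = 0
degenerates the wall into an isotropic harmonic trap, which the integrator
tests exploit.  Dimensionality is 1–3: production-like scenarios are 3-D,
analyses and statistical tests use 1-D/2-D where the physics under test is
dimension-independent.

### Presets

* **binder** — orthosteric well (depth 8, width 2.5 Å) at the origin is
  the global minimum; a shallow metastable well (3, 2 Å) 15 Å out and a
  weak bump (1.5, 1.5 Å) at 10 Å shape the approach.
* **pam** — the metastable vestibule is a *shell* of deep wells (7, 2 Å)
  at radius 15 Å with repulsive patches (5, 2 Å) on the 11 Å shell
  between vestibule and orthosteric site, and a shallow orthosteric well
  (3, 2 Å).  A shell is used rather than a single well because a
  center-of-mass distance of 15 Å is a radius: a ligand approaching from
  any direction should encounter the vestibule before the pocket, which
  is what the receptor's extracellular mouth enforces in reality.  Shell
  points are equidistant (Fibonacci sphere in 3-D).
* **diffusive** — one very shallow well (0.5 kcal/mol); essentially free
  diffusion.

Depths and widths are package choices constrained only by the qualitative
ordering they must reproduce (pam: metastable deeper than orthosteric
behind a barrier between 8 and 12 Å; binder: orthosteric global minimum);
every value is overridable per run via dotted-path overrides or scenario
YAML/JSON files.  Default ligand masses are fragment-like (194–230 amu);
statistical tests override to 2–10 amu so that diffusion across the box
takes hundreds of ps rather than tens of ns — mass rescaling changes time
scales, not the sampled distributions or the supervision logic.

## Langevin dynamics

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
which gives near-exact configurational averages at large steps and reduces
to velocity Verlet when friction and temperature are zero, so ballistic
and energy-conservation limits are limits of the same code path.  Defaults
mirror a standard membrane-protein production setup: 310 K, dt = 2 fs,
friction 1 ps⁻¹.  Velocities are drawn from the Maxwell–Boltzmann
distribution (variance kB·T/m per component).  Frames (and the ligand–site
distance) are recorded every `sample_stride` steps (default 50); the
first and final steps are always recorded.  A non-finite potential energy
aborts the run with the offending step index.  All stochastic operations
take an explicit `numpy.random.Generator`; identical seeds give
bit-identical trajectories.

## Supervision (SuMD)

A window of `window_duration` (default 600 ps; toy studies use 6 ps) is
simulated unbiased; the recorded (time, distance) points are fitted with a
line.  The slope is the ordinary least-squares slope by default; a
literal through-origin fit (m = Σt·d/Σt², times shifted to start at 0) is
implemented as an option but models series that start far from zero
poorly.  Decisions:

* **arrival** if *any* recorded distance in the window is below the
  threshold (default 5 Å) — a first-passage reading of "drops below";
* else **accept** iff slope < 0 (strictly: slope exactly 0 rejects);
* else **reject**: coordinates and the clock are restored bit-identically
  to the window start and velocities are redrawn.

Supervision never modifies forces; an accepted window is distributionally
(and under a shared seed, bit-) identical to a plain MD segment.  After
arrival, supervision is permanently disabled and a classical tail runs
(default 10× the window).  No explicit tabu list is kept — the
reject-and-resample rule is the whole mechanism.  The run aborts
unproductively after `max_windows` (default 2000) attempts.  The
supervision budget accounting (`arrival_simulated_time`) counts rejected
windows too, since that is the simulated effort a practitioner pays.

## Landscape analyses

Interaction energy at a frame is the Gaussian-term sum *excluding* the
confining wall (the wall is an artefact of the toy box, not a
receptor–ligand interaction); stabilisation is negative.  Metastable
states are maximal time-contiguous runs in which the distance stays
within a tolerance of the running mean and whose duration exceeds
`min_dwell`.  Occupancy gaps are contiguous distance bins below an
occupancy threshold (default 0.5%, since "poorly populated" is not a
quantitative notion) strictly flanked by populated bins.  Path nodes
accumulate trapezoidal per-frame time weights in cubic cells, so node
residence times sum exactly to the trajectory duration; the PDB export
writes one HETATM per node with B-factor proportional to residence time.

## Well-tempered metadynamics

Gaussian hills are deposited along 1–2 collective variables every
`stride` ps with the well-tempered height rule
w = w0·exp(−V(s)/(kB(γ−1)T)).  Defaults follow the standard salt-bridge
protocol: w0 = 0.3 kcal/mol, σ = 0.04 Å (distance CV) / 0.3 rad
(dihedral-like CV), stride 0.5 ps, γ = 6, 298 K, 10 ns production.
Exactly ⌊duration/stride⌋ hills are deposited (none at t = 0).  The bias
force is evaluated analytically from the hill parameters through the CV
gradients; a gridded accumulation mode (hill added to a fine grid once,
linear interpolation per step) is available and is used by the long
benchmark runs, where it is orders of magnitude cheaper and agrees with
the analytic path to interpolation error.  Periodic (angle-like) CVs are
wrapped to [−π, π) by minimum image.  The temperature-ramp equilibration
of the original protocol is out of scope; runs start at the target
temperature.

Free energy is estimated as F(s) = −γ/(γ−1)·V(s) on a regular grid,
shifted so min F = 0.  By default the estimate is time-averaged over the
last half of the deposition history, which suppresses late-time
fluctuations of the instantaneous bias without re-weighting.  For basin
free-energy *differences* a reweighting estimator is provided: frames
from the late, quasi-static part of the run are weighted by exp(V(s)/kT)
and ΔF = −kT·ln(p_closed/p_open).  Basin populations integrate over whole
basins, so this estimator is limited by inter-basin crossing statistics
and by the residual shape error of V.

Hill geometry in the toy benchmark studies (σ = 0.3 Å) is matched to the
Å-wide toy wells rather than to the 0.04 Å protocol value, which is tied
to the sub-Å scale of a real atomic-distance collective variable; using
0.04 Å hills on Å-wide wells would deposit ~10× more hills for the same
fill with no accuracy benefit.

## Kinetics

Transition-state theory gives k ∝ exp(−ΔG‡/RT), so a rate pair maps to
ΔΔG‡ = RT·ln(k_ref/k_mod) with the prefactor cancelling; only the change
is computed, never an absolute barrier.  Default temperature is 310 K
(the simulation temperature; the assay temperature is configurable).
Note that for the measured pair 0.015 → 0.0095 min⁻¹ the plain fractional
decrease is 1 − 0.0095/0.015 ≈ 37%, while the effect is reported
elsewhere as "18%" under a different convention; the package exposes the
rate-pair form (authoritative) and a percent-decrease constructor, and
does not attempt to reconcile the two.

## Benchmark studies (`sumdkit.benchmarks`)

The acceptance studies run at deliberately reduced scale so the full set
completes in minutes on one core; sizes below are package choices.

* **Supervision race** — binder preset, 2-D, 10 amu, box 18 Å, start
  14 Å out on a random shell direction, 6 ps windows, 100-window budget
  (600 ps).  20 paired replicas share start states and seeds between SuMD
  and an equal-budget unbiased run.  Expected outcome: SuMD arrives in
  essentially every replica within ~150–300 ps of simulated effort while
  unbiased dynamics rarely arrives within 600 ps.
* **PAM stalling** — pam preset, 2-D, start 18 Å out, 50-window budget.
  Supervised runs are captured by the deep vestibule shell and end within
  2 Å of the 15 Å shell far more often than within 5 Å of the orthosteric
  center.  Terminal distances cluster near 13–14 Å — the supervision
  ratchets the ligand to the inner flank of the vestibule well, which is
  the toy analogue of a fragment sitting at the inner edge of the
  receptor mouth.
* **Barrier recovery** — symmetric 1-D double well (2.5 kcal/mol wells at
  ±1.5 Å, reference barrier 1.64 kcal/mol evaluated on a dense grid; in
  1-D the free-energy profile along the coordinate is the potential
  itself).  One 2 ns walker with low deposition rate (w0 = 0.1, stride
  1 ps) recovers the barrier within ~10%.
* **Salt-bridge shift** — a synthetic double well along a distance-like
  coordinate: closed well at 4.5 Å, open at 8.0 Å, steric wall at short
  distance (a distance CV has a hard-core lower bound), confinement
  beyond 10 Å.  Deepening the closed well by δ = 0.5 kcal/mol emulates
  the modulator-induced stabilisation; three independent 6 ns walkers
  per condition recover the shift of ΔF(closed−open) measured at the
  basin minima of the time-averaged surface.  At the protocol deposition
  rate (0.3 kcal/mol per 0.5 ps) the error of a single well-tempered
  walker on this landscape is ~0.3 kcal/mol — far too coarse to resolve
  δ — so the study combines fast CV dynamics (light mass, low friction),
  a 12-fold lower deposition rate and walker averaging, which brings the
  per-condition error to ~0.05 kcal/mol.

## What the toy model does and does not show

Passing these studies demonstrates the *algorithmic* claims: supervision
accelerates first passage without force bias, rejection restores state
exactly, the well-tempered estimator recovers known free-energy
differences, and the Eyring arithmetic bounds the measured kinetic
effects.  The toy model has no protein flexibility, no explicit solvent
or membrane, no atomistic interaction fingerprints, and a single-particle
ligand; nothing here validates force-field accuracy or the realism of any
specific receptor's vestibule.  Metastable-site energetics in the presets
are constructed, not predicted.

## Numerical notes

* Slope fits require ≥ 2 points and non-constant times; degenerate input
  raises.
* The 2-D/3-D Gaussian terms are evaluated vectorised over all wells and
  barriers; forces are analytic (no finite differences anywhere in the
  dynamics path).
* CSV outputs use fixed 6-decimal formatting; reruns with the same seed
  are byte-identical, which the run manifests (SHA-256 per output file)
  make checkable.
* Tests derandomise hypothesis and seed every stochastic check; the
  statistical tolerances (e.g. 5% on equipartition, KS ≤ 0.05 at 10⁶
  samples) were sized from the estimator standard errors at the chosen
  run lengths.
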