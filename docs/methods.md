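# Methods

This note records the models, estimators, numerical choices and known
limitations behind `glassmd`, in the spirit of a package methods section:
what is computed, under which assumptions, and what the synthetic tests
do and do not demonstrate about real simulation data.

## Units and containers

The analysis layer works in Å, fs, K, kPa and kJ/mol throughout. The toy
simulator integrates in reduced Lennard-Jones units internally and
converts at its boundary through a declared `UnitSystem` (argon-like by
default: σ = 3.4 Å, ε/k_B = 120 K, m = 40 u, giving τ ≈ 2152 fs);
nothing downstream of the conversion knows about reduced units.
Trajectories store wrapped coordinates as read; unwrapping is always an
explicit operation. Only orthogonal cells are supported — the systems
this package targets are simulated in cubic boxes, and triclinic input
is rejected rather than silently mishandled.

## Mean-squared displacement and self-diffusivity

The MSD uses every time origin at stride one frame, computed per
particle with the standard FFT autocorrelation decomposition
(O(n log n) per particle); the implementation is verified in the tests
against a direct O(n²) evaluation. The self-diffusivity is the Einstein
slope, D = (1/6) d MSD/dτ, from a weighted least-squares line over an
explicit lag window, weighted by the number of origins per lag.

The default window is 10–50% of the maximum lag: short lags carry
ballistic/cage transients, long lags few origins. The window is a
visible parameter, not an automatic choice, because near the glass
transition there is no guarantee a clean linear regime exists in a short
trajectory; for plateau (caged) data the caller should place the window
beyond the cage relaxation time.

A fit is flagged *sub-diffusive* when the slope is negative, within two
formal standard deviations of zero, or when the fitted MSD growth across
the window is less than 10% of the mean MSD level. The last criterion is
a deliberate plateau detector: neighbouring MSD points share the same
trajectory noise, so the formal WLS slope error is an underestimate and
a pure significance test misclassifies plateaus. A negative slope is
reported as D = 0. The `diffusion_exponent` helper (log–log MSD slope)
provides the complementary regime diagnostic: α ≈ 1 diffusive, α ≈ 0
caged.

Molecule-level MSDs use mass-weighted molecular centers, which removes
intramolecular vibration from the displacement signal; a single-atom
"molecule" passes through unchanged.

## Structure

Mass density is total mass over box volume per frame (1 u/Å³ =
1.66054 g/cm³), averaged with its standard deviation across frames.
Molar volume is V_m = M̄/ρ with M̄ the mole-fraction-weighted molar
mass; the excess volume is V_E = V_m,mix − Σ x_i V_m,i, also reported as
a percentage of the mixture molar volume (negative values mean better
packing than the ideal mixture).

RDFs are histogrammed under the minimum image with 0.05 Å bins by
default and normalized by the ideal-gas pair expectation of the selected
site populations — N_A·N_B/V ordered pairs (N(N−1) for A = A) times the
exact shell volume, using the per-frame box volume so constant-pressure
trajectories normalize correctly. `coordination_number` integrates
ρ_B·4πr²g(r) and is validated by the closed first shell of a simple
cubic lattice (six neighbours). First peaks are located by argmax plus a
three-point parabolic refinement; a maximum on the search-range boundary
is reported as "no peak" rather than a spurious contact distance.

Hydrogen bonds use a distance-only criterion: an H(donor)···acceptor
pair within 2.5 Å (default) under minimum image, intramolecular pairs
excluded. No angular term is applied — the contact analysis this
supports is presented through site–site distance distributions, and a
distance cutoff keeps the count reproducible from coordinates alone.
Site labels follow the field's conventions (e.g. `O_Z`, `H_A/C1`) so
reported pairs are recognizable.

## Energetics

U_vap = ⟨U_gas⟩ − ⟨U_liq⟩/n, with the gas reference a single-molecule
(intramolecular-only) average: the ideal-vapor assumption, with no
virial correction. ΔH_vap = U_vap + RT holds exactly by construction
(R = 8.31446×10⁻³ kJ/(mol·K)), and U_vap is invariant under shifting the
zero of energy of both phases — both properties are asserted in the
tests. Uncertainties combine the two series' standard errors in
quadrature. Specific (per-mass) cohesion is U_vap/M; the natural scale
for ~100 kJ/mol and 100–250 g/mol molecules is ~0.4–1 kJ/g, and the
function exposes both kJ/g and J/g explicitly because reported
per-mass cohesions in the literature are not always consistent about
this factor of 1000.

The fusion enthalpy is a plain per-molecule enthalpy difference between
a liquid and a crystal series at a common stated temperature, without
superheating or finite-size corrections, and reports itself as such.

## Trend-shift T_g estimation

The break-point model is the continuous hinge
y = c + b_L·min(T−T_b, 0) + b_R·max(T−T_b, 0). For fixed T_b this is
linear least squares; the profiled weighted SSR is evaluated at every
admissible interior knot (at least 3 points per side by default) and
then refined continuously inside *every* bracketing interval — the
profile is only piecewise smooth, so refining around the single best
grid knot could miss the optimum. SSR ties break toward lower
temperature (the conservative, lower T_g). The tests pin the optimum
against an exhaustive 0.1 K knot-grid search.

The break uncertainty is the delta method on the full four-parameter
Jacobian (∂y/∂T_b = −b_L or −b_R per side), with the covariance scaled
by the reduced chi-square. An independent-two-lines variant (two
unconstrained lines, break at their intersection, closed-form gradient
(1, x*, −1, −x*)/(b₂−b₁)) is provided both as an alternative reading of
the trend-shift construction and as an analytic cross-check; on
well-formed fixtures the two parameterizations agree within 10%. The
hinge is the default because continuity makes it better conditioned
when one branch is short.

Density is fitted directly (not volume, though V(T) input works the
same way); diffusivity is fitted on the linear D scale with the glassy
branch a near-zero floor — a log scale is undefined where the glass D
is statistically zero. Points are weighted by 1/sd² when per-point
uncertainties are available, with zero sds floored to the smallest
positive sd.

The two branch estimates combine as their arithmetic mean with
quadrature/2 uncertainty. A consistency flag trips when they disagree by
more than 25 K, the empirical bound for well-behaved scans; a flagged
estimate is still reported, the flag is advisory.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all statistical tests;
they are seeded and bit-reproducible.

**Thermal scans** follow a two-segment density law (glass slope
−2×10⁻⁴, liquid slope −8×10⁻⁴ g/cm³/K around 1.2 g/cm³) and a
diffusivity law with a 10⁻⁷ Å²/fs glassy floor rising to ~5×10⁻⁵ Å²/fs
at 500 K, on a 200–500 K grid in 10 K steps with a break at 350 K;
Gaussian noise defaults to 0.002 g/cm³ on density (minor scatter) and
1.5×10⁻⁶ Å²/fs on diffusivity (transport data from short runs scatter
more). The default liquid-branch rise is *linear* in T: it is the
exactly break-structured law that a two-segment estimator is defined
against, so zero-noise scans are recovered exactly and noisy-scan
errors measure noise response, not model mismatch. An activation-type
(Arrhenius) rise is available as an option; note that its convexity
over a 150 K span displaces the optimal piecewise-linear knot several
kelvin above the true break even at zero noise — a property of the law
itself (the exhaustive knot search shows the same shift), which is why
it is not the default for calibration work.

**Brownian trajectories** use i.i.d. Gaussian increments of variance
2·D·dt per axis; **caged trajectories** use the exact discretization of
an Ornstein–Uhlenbeck reversion to fixed sites with per-axis stationary
sd cage_radius/√3, so the long-lag MSD plateau is 2·cage_radius²; the
relaxation time defaults to 20 dt to keep the cage timescale well
separated from trajectory lengths. Both store their ground truth
(true D, unwrapped coordinates, plateau) for oracle tests.

**The toy glass former** is the canonical 80:20 binary Lennard-Jones
mixture with non-additive cross interaction (ε = 1, 1.5, 0.5; σ = 1,
0.8, 0.88 for AA, AB, BB), 2.5σ shifted-potential cutoff, velocity
Verlet at dt = 0.002, N = 150 by default. Temperature control is
stochastic velocity rescaling (canonical sampling) and pressure control
an isotropic Berendsen box rescale; with both off, NVE conserves energy
to better than 10⁻⁴ relative over 10⁴ steps and momentum to machine
precision, which is the integrator's correctness test. The sequential
cooling protocol (NPT equilibration then production at each grid
temperature, state carried between temperatures) reproduces the
phenomenology the analysis layer is built for: under P* = 2 on a
T* = 1.0→0.1 grid the density develops a slope break near T* ≈ 0.45
with the liquid branch roughly twice as steep, and the A-species
diffusivity collapses toward zero on the cold side. Default protocol
sizes (2000 equilibration + 3000 production steps per temperature)
keep a full scan around a minute on one CPU; they are chosen for a
clear break signal at desk scale, not for equilibrated glass physics.

What passing these tests shows: the estimators are correct and
calibrated against known ground truth, and the pipeline detects
vitrification phenomenology in a real (if small) interacting system.
What they do not show: force-field accuracy, system-size and
cooling-rate effects, electrostatics/constraint handling, or the
quantitative T_g of any real compound — the toy system has no
molecules, charges or hydrogen bonds.

## Validation tables and statistics

The bundled benchmark tables (densities, fusion enthalpies, glass
transition temperatures, vaporization enthalpies for four model drugs
and two nucleobases, with experimental references) are fixtures guarded
by SHA-256 checksums; they are never modified at runtime. All summary
statistics — percent deviations 100(sim/exp − 1), RMSE of percent
deviations, RMSE of absolute differences, mean deviation — are
recomputed from the simulated/experimental value columns, not from the
tables' pre-rounded deviation columns, because rounding first biases
the aggregates (the crystal-density RMSE comes out 1.6% instead of
1.7% by the rounded route). Printed deviations that were evidently
computed from unrounded underlying values are accepted within one unit
of their last printed digit; one bundled row (the cytosine crystal
density, printed deviation −1.6 against value columns implying +2.3)
is internally inconsistent and is flagged by the report rather than
"corrected", since the intended value cannot be inferred from the
table itself. The combined-T_g column is reproduced as the rounded
branch average, with the exact mean (e.g. 290.5) shown alongside the
printed 290.

## Known limitations

* Orthogonal boxes only; no binary trajectory formats (DCD/XTC).
* The H-bond criterion is distance-only; analyses requiring angular
  criteria need a different tool.
* The break-point model is two linear segments; smoothly curved
  observables (e.g. strongly super-Arrhenius transport over wide
  temperature windows) make the located knot law-dependent, as the
  Arrhenius scan option demonstrates.
* Formal diffusivity uncertainties ignore lag–lag correlation of the
  MSD and are best treated as lower bounds; the plateau detector and
  the MSD exponent exist precisely because of this.
* The toy engine is O(N²) per step and intended for hundreds of
  particles, not thousands.
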