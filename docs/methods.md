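# Methods

`lumenflow` simulates luminal fluid flow and passive tracer transport in a
planar network of nanoscale tubules whose walls contract actively. This note
records the model, its numerical choices, the defaults and why they were
chosen, and what the synthetic test conditions can and cannot say about real
ER networks.

## Model overview

The network is a planar graph; each edge is an axisymmetric cylinder of
radius R = 30 nm (0.03 µm) and length ≈ 1 µm. At the relevant scales
(U ~ µm/s, R ~ 10 nm, ν ≥ 1e-6 m²/s) the Reynolds number is ~1e-7, so the
flow is inertialess and the fluid problem is quasi-steady: at every instant
the fluxes follow from a linear resistive-network solve, fully decoupled from
time except through the prescribed wall kinematics.

### Contraction kinematics (prescribed, not force-balanced)

Wall motion is kinematically prescribed; the active machinery is assumed to
win the force balance. Three mechanisms share one renewal structure —
alternating exponential waits and events, started in a stationary wait
(memoryless, so sampling the full exponential for the first wait makes the
process time-translation invariant):

* **Tubule pinches.** One site per edge, at its midpoint. During an event of
  total duration 2T the minimum radius follows
  b(t) = (R+b0)/2 + (R−b0)·cos(πt/T)/2 (smooth at both ends, so the volume
  source is continuous) and the radius profile is linear over the pinch
  region of half-length L. Defaults: 2T ~ Exp(mean 0.0725 s),
  waits ~ Exp(mean 0.370 s), 2L ~ Uniform(mean 0.14 µm, variance
  0.062²/ln10 µm² ≈ (0.0409 µm)², support mean ± √3·sd), b0 = 0.01R. These
  are the measured event statistics; rate multipliers α (faster events) and
  β (more frequent events) scale the two exponential means, and a
  "full-tubule" policy sets 2L equal to the edge length. A pinch injects
  q = −(2π/3)·ḃ·L·(R+2b), the exact rate of change of the pinch-region
  volume, so every completed event nets zero volume.
* **Junctions.** Each junction expels a fixed volume f·ΔV per contraction,
  ΔV drawn once per junction from N(0.0045, 0.0021) µm³ truncated by
  rejection to [0.0020, 0.0081] µm³ (the measured junction-volume range),
  through a sinusoidal source S(τ) = f·ΔV·π·sin(πτ/T)/(2T) over τ ∈ [0, 2T]
  — positive during contraction, negative during relaxation, ∫₀ᵀ S = f·ΔV.
  Junction runs keep the tubule pinches active as well.
* **Sheets.** A perinuclear sheet is a reservoir attached to designated sheet
  nodes, performing one contraction + relaxation (defaults Vsheet = 10 µm³,
  2T = 5 s) with the same sinusoidal waveform applied as a *total* source
  shared by all sheet nodes. Peripheral sheets are modelled through the
  junction machinery with volumes Vk ~ N(0.12, 0.04) µm³: scenario 1 expels
  Vk/6 at every interior node with durations slowed 2.5×; scenario 2 expels
  Vk/2 at a seed-chosen random third of the nodes with durations slowed 5×.
  α here scales durations only (waits keep the original law), mirroring the
  junction model's separation of α and β; the two scenarios then expel the
  same expected volume per contraction cycle.

### Hydraulics

Lubrication theory in a slowly varying axisymmetric tube gives a parabolic
(or slip-modified) axial profile whose cross-sectional integral yields a
linear pressure–flux law. Every edge is split at its pinch site into two
resistor segments joined at a dummy node carrying the pinch source; the
no-slip segment resistance is

r = (8µ/π)·[L_straight/R⁴ + L·(R² + Rb + b²)/(3·b³·R³)]

— an algebraically exact form of the linear-taper integral with no
singularity at b → R, where it reduces to plain Hagen–Poiseuille. With slip
length λ the integrand becomes 1/(a⁴(1+4λ/a)); its antiderivative (partial
fractions) is evaluated by log1p for large λ and by a power series in 4λ/b
when 4λ < b/2, because the closed form loses all significance to cancellation
there (the series keeps the quadrature agreement at 1e-8 relative across the
tested range). Straight segments use 1/(R⁴(1+4λ/R)): the slip factor applies
to every segment of the tubule, which is what makes the λ → 0 and b → R
limits consistent.

The instantaneous fluxes solve: mass conservation at all N + E nodes (K1);
zero pressure drop around each of the E − N + 1 fundamental cycles of a BFS
spanning tree (K2); equal pressure at all exit nodes (M1 − 1 equations); and,
when a perinuclear sheet is active, equal pressure at all sheet nodes plus
one equation fixing their summed source (M2 equations). The BFS starts at the
lowest node index and explores neighbours in ascending order, making the
cycle basis (and hence the assembled system) reproducible. Resistances are
viscosity-scaled, so fluxes are µ-independent. The sparse system is solved by
LU with the pressure rows normalised by the median resistance; the
mass-conservation residual is checked each solve (fallback: dense least
squares) and stays below 1e-12 of the flux scale in practice.

**Quasi-steady update and short events.** Resistances and sources refresh
every δt_flow = 1 ms (≪ mean 2T = 72.5 ms). Because the exponential duration
law occasionally draws sub-millisecond events, sources are *window-averaged*:
each flow interval carries exactly the volume the contraction expels during
it. For a pinch this amounts to using b̄ = (b(t₀)+b(t₁))/2 and
ḃ = (b(t₁)−b(t₀))/δt in the source and flux-profile formulas (exact, because
the source is linear in ḃ·(R+2b)); for the sinusoidal sources the cosine
boundary terms give the expelled volume directly. Instantaneous sampling
would freeze a short event's peak rate for a full interval, injecting up to
three orders of magnitude too much volume and producing artificial
several-thousand-µm/s edge traversals; window averaging removes this while
converging to the instantaneous law as δt_flow → 0.

### Particle transport

Tracers are rigid 5 nm spheres, independent of each other (dilute limit),
advected by the local lubrication velocity (u along the axis, v radially,
including the wall-motion and taper terms required by incompressibility) and
diffusing with D = 0.6 µm²/s, the measured intranode diffusivity. The update
is explicit Euler–Maruyama with Δt = 1e-5 s: the diffusive step
√(2DΔt) ≈ 3.5 nm ≈ R/9 resolves the confinement (a validation error rejects
configurations with √(2DΔt) > R/3). Walls reflect specularly in the radial
coordinate; if the wall overtakes a particle (possible in a deep pinch,
where the neck can be narrower than the particle) the particle is placed on
the axis. Reaching an edge end assigns the particle to the node, where it
exits into tubule i with probability ∝ max(Pe_i + 1, 0), Pe_i = U_i·R/D with
U_i the cross-sectionally averaged outflow speed at the node-side end —
flow-proportional at high Péclet, uniform at low Péclet — and re-enters on
the tubule axis. Radial equilibration across the 30 nm section takes ~1 ms,
far shorter than any traversal, so the on-axis re-entry does not bias the
statistics. The inner loop is compiled with numba; runs are bit-reproducible
for a fixed seed (sub-seeds for placement and noise derive from one
SeedSequence).

### Observables

Instantaneous speeds are |ΔX|/Δt of the global 2D position (axis point plus
in-plane transverse offset) at Δt = 18 ms, the tracking cadence. An edge
traversal is a move from one end node to the other without touching either
in between; its time runs from the most recent departure from the origin
node, and its speed is edge length / time. Network-level distributions pool
the per-edge means (average edge traversal speeds, AETS); the per-event
table is also exported. Flow statistics use the flux entering each edge:
mean speed = ⟨|Q|⟩/(πR²) over edges and 1 ms snapshots, and the alternation
frequency counts per-edge sign changes per second. The mixing measure is the
variance over 20 equal-width vertical strips of (blue − red) particle counts,
colours assigned by initial position relative to the median x.

## Study conditions, and what they show

The reference geometry for quantitative checks is a 10×10-hexagon honeycomb
(240 nodes, 1 µm edges, boundary nodes as exits) — transport statistics were
shown to be insensitive to the real-network geometry, and the honeycomb is
the reproducible idealisation. The benchmark run (300 particles, 10 s,
original pinch parameters) yields a mean AETS of ≈ 5.1 µm/s against the
reference 4.4 µm/s and a mean flow speed of ≈ 1.05 µm/s against 1.3 µm/s,
both within the ±30% sampling/geometry band expected for a stand-in geometry;
the diffusion-only control is statistically indistinguishable from the
active run, which is the model's central result. Property tests use smaller
lattices (5×5, 6×6; 150–400 particles, 2–3 s) — large enough for ≥500
traversal events where a distributional claim needs them, chosen to keep the
full suite in the tens of minutes on one CPU.

The synthetic ER-like generator (clipped Voronoi diagram of random points,
rescaled to the target mean edge length) reproduces the degree-3 planar
topology and summary statistics of reconstructed peripheral-ER networks, but
not their spatial correlations, edge-length tails, or curvature; passing
tests on it demonstrate correctness of the solvers and statistics, not
quantitative agreement with any particular cell. Reported quantities tied to
specific reconstructed geometries (junction-sweep contour levels, perinuclear
and peripheral sheet mean speeds on a particular network) are checked only
qualitatively: ordering, monotonicity, and the spatial decay of V(x) away
from a sheet.

## Numerical choices and degenerate inputs

* Cycle-basis determinism: BFS from the lowest node id, ascending neighbours.
* Near-closed pinches: the no-slip resistance form is exact for all
  b ∈ (0, R]; b ≤ 0 is rejected (b0 > 0 by construction). The b → R limit of
  the slip form switches to a midpoint evaluation below (R−b)/R = 1e-6.
* Sampled pinch lengths are clamped to the host edge length; full-tubule
  pinches set L1 = L2 = 0.
* Ill-conditioned solves (residual > 1e-9 of the flux scale) fall back to
  dense least squares; zero exit nodes raise immediately.
* Wall reflections iterate at most 10 times, then place the particle on the
  axis; a neck narrower than the particle also maps it to the axis.
* Log-normal fits reject non-positive samples; near-zero spread is flagged
  degenerate instead of fitted.
* Empty spatial-profile bins are reported as missing (NaN), never zero.
* Two open reporting conventions were fixed as: alternation frequency counts
  sign changes of the per-edge entering flux Q1 sampled at δt_flow; AETS
  distributions pool per-edge means (per-event speeds remain available).

## Limitations

* Kinematics are prescribed; there is no membrane force balance, wall
  compliance, or fluid–structure feedback, and no osmotic flows.
* One pinch site per tubule (midpoint); multi-site coordination is treated
  only in the closed-form two-pinch bound.
* Particles are passive, dilute, and point-like except at walls; no
  hydrodynamic interactions or size-dependent mobility.
* The junction/sheet waveforms are assumed sinusoidal and
  contraction/relaxation symmetric; scheduling details beyond the scaled
  exponential laws are modelling choices.
* 3D network geometry, image-based reconstruction, and comparisons to
  external tracking data are out of scope.
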