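# Methods

## Physical model

A single spherical cell of radius R sits in an unbounded conductive
medium and is exposed to a uniform pulsed field E(t).  Both bulk phases
are treated as pure conductors (electro-quasistatic, conduction-only):
the bulk charge-relaxation times ε/σ are ≤ ~14 ns even at 0.05 S/m,
short against the 200 ns and 100 μs pulses simulated, so displacement
currents in the bulk are neglected.  For this reason 25 ns pulses are
deliberately *outside* the model's claimed validity, although nothing
stops the code from running them.  The membrane is a thin shell
(d_m = 5 nm) entering only through two areal parameters: capacitance
C_m and conductance g_m = σ_m/d_m.  There is no pore creation, no
conductance nonlinearity, no saturation, no resealing and no cell
deformation: the model is linear in E, and multi-volt transmembrane
values are meaningful within it as the pore-free baseline.

### Closed-form engine

The first-order membrane response at polar angle θ (from the field
direction) is

    Vm(θ, t) = Vss(θ) + (V0(θ) − Vss(θ)) · e^(−(t−t0)/τ)

per constant-field segment, with Vss = f_s·1.5·R·E·cos θ,
τ = R·C_m·(1/σ_i + 1/(2σ_e)) and f_s = 1/(1 + g_m R (1/σ_i + 1/(2σ_e))).
Stepping is exponential segment-to-segment, so the engine has no time
discretization error.  Post-pulse decay reuses the same τ: with the
field off the membrane discharges through the same series access
resistances.

The exact transient of the contact-impedance membrane model carries the
leak correction in the exponent too (τ′ = f_s·τ, a 0.33% difference for
the reference cell).  The closed-form engine keeps the customary form
above by default — it is the form the τ-formula quotes and the one an
exponential fit to the trace recovers to 0.1% — and exposes
`self_consistent=True` where the exact limit is wanted (the convergence
study uses it as its reference, since it is the true discretization-free
limit of the FEM engine).

### FEM engine

2D axisymmetric (r, z) half-plane, Laplace ∇·(σ∇φ) = 0 in each domain,
P1 triangles with exact 2πr-weighted element integrals.  The membrane is
*not* meshed (a 5 nm shell next to 5.5 μm geometry would force extreme
aspect ratios); instead the cell circle carries double nodes and a
contact-impedance condition: φ_in − φ_out = Vm, and the conduction
current J_n arriving from the cytoplasm feeds the membrane,
C_m dVm/dt = J_n − g_m Vm.  Interface-pair elimination (φ_in expressed
through φ_out + Vm) makes the shared test function enforce current
continuity weakly, and the closed-surface integral of J_n vanishes to
solver precision.

Boundary conditions: Dirichlet φ = ∓E·H on the top/bottom of a
truncation box of half-height and radius 10R (configurable, ≥ 5R), zero
normal current on the lateral wall and the symmetry axis.  The sign
convention puts positive Vm on the θ = 0 pole.  Because the problem is
linear, J_n is an affine map A·Vm + c·E; the solver computes A and c
once per mesh by unit-Vm quasistatic solves sharing one sparse LU
factorization, then advances the membrane ODE with backward Euler — a
dense factorized m×m solve per step (m ≈ 130 interface samples), which
makes even the 100 μs case (≈ 7 900 steps) run in well under a second.

### Mesh

Structured polar ladder: rays at uniform θ plus two rays through the box
corners (so the outer node ladder follows the rectangle exactly and the
homogeneous-medium solution is reproduced to machine precision), rings
graded geometrically (growth 1.2) away from the interface with the step
capped at 10× the target edge length.  The cap scales with refinement:
the mid-field dipole region (ρ ≈ 2–5R) otherwise sets an error floor
that refinement near the interface cannot remove.  The interior ends in
a coarse central fan, which is harmless because the intracellular
potential of the dominant cos θ mode is exactly linear and P1-exact.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| R | 5.5 μm | cell radius; the quoted 11 μm cell size read as a diameter, consistent with MC38 cell dimensions.  Reading it as a radius would scale every τ equally and leave the conductivity-ratio results unchanged. |
| d_m | 5 nm | membrane thickness |
| σ_m | 2.5×10⁻⁷ S/m | membrane conductivity (g_m = 50 S/m²) |
| C_m | 0.01 F/m² | areal capacitance; not reported alongside the other cell constants, so set to the standard 1 μF/cm² (≈ relative permittivity 5.65 over 5 nm) and exposed as a config key |
| σ_i | 0.5 S/m | cytoplasm conductivity |
| σ_e | 0.05 S/m | default buffer (HEPES-like); swept over 0.05/0.1/0.5, with fixtures for STM (0.1) and HEPES + 2/5 mM CaCl₂ (0.08/0.1) |
| dt | min(τ/50, t_pulse/100) | backward-Euler step; explicit values > τ/20 are rejected |
| mesh edge | 0.025 R | target interface edge length (≈ 130 θ samples, ≈ 7 400 nodes) |
| box | 10R | truncation half-height/radius |
| plateau fraction | 0.995 | "time to peak" criterion; a first-order system peaks only asymptotically, so the transient time is reported as the first crossing of fraction×(pulse-end value).  0.995 ≈ 5.3τ gives 3.5 μs for the 100 μs/0.05 S/m case, 0.99 ≈ 4.6τ gives 3.0 μs. |

Waveforms are ideal rectangles (zero rise time).  Pulse trains are
simulated as a single pulse plus field-free tail: the shortest
inter-pulse gap in the catalog (1 ms at 1 kHz) exceeds the longest τ
(~0.7 μs) a thousand-fold, so the membrane is fully discharged between
pulses and every pulse in a train is identical in this pore-free model.

## Numerical behaviour

With defaults, the FEM pole trace agrees with the closed-form oracle to
0.1–0.4% (peak-normalized) across σ_e ∈ {0.05, 0.1, 0.5} on both the
200 ns and 100 μs cases; the acceptance band in the tests is 3%.  The
remaining error is dominated by mid-field spatial resolution and the
first-order time stepping, with opposite signs — which is why the
convergence study refines mesh and dt together and measures against the
self-consistent closed form.  Errors can cross zero as they cancel, so
|error| monotonicity is only asserted over the study's default three
levels.  Degenerate inputs are rejected early: non-positive
conductivities, membrane thicker than 0.1 R, unsorted time grids,
zero-duration segments, dt > τ/20, mismatched interface sampling.
Summary statistics interpolate linearly in time with no smoothing; the
relaxation half-time needs the trace to extend ≥ 3τ past field-off, and
traces that never charge raise instead of returning a spurious time.

## What the fixtures emulate — and what they do not

The protocol catalog (EP1–EP8, the four parameter groups, the buffer
conductivities) reproduces the *nominal* study conditions: ideal
rectangular pulses at the printed amplitudes, durations, counts and
repetition rates.  It does not model generator non-idealities (finite
rise times, ringing, impedance mismatch), medium heating, field
non-uniformity in a cuvette, cell-size distributions, or any
permeabilization readout.  Passing tests therefore demonstrate the
passive biophysics of membrane charging under the stated conditions —
the conductivity effect and its time scales — not the downstream biology
(dye uptake, viability, protein expression), for which the model makes
no claim.  In particular the mapping from induced voltage to
permeabilization is monotone only by assumption; the package reports
voltages, never permeabilization probabilities.

## Design choices

* Contact-impedance interface instead of meshing the 5 nm shell:
  standard thin-layer practice; equivalence is established against the
  closed-form solution rather than a second meshed model.
* The two engines share no numerical machinery (exponential stepping vs
  FEM + backward Euler), so their 3%-agreement test is a genuine
  cross-validation, not a tautology.
* Influence-matrix time stepping (precomputed A, c) rather than a
  monolithic coupled system per step: same discrete solution, but the
  per-step cost drops to a small dense solve, making parameter sweeps
  cheap.
* The angular grid doubles as the FEM interface discretization; traces
  report θ from the +z pole, and all published-figure reproductions use
  the pole value θ = 0 (the study does not state its reporting angle;
  the pole is the extremum and the conventional choice).
* Flat one-level TOML configs with units in key names, so runs diff
  cleanly and the metadata JSON alone re-derives any output file.

## Known limitations

Linear pore-free membrane (no electroporation feedback), single cell in
infinite dilution, rigid sphere (no microsecond-range deformation),
conduction-only bulk (no 25 ns claims), ideal rectangular pulses, and a
truncation box at 10R whose residual bias (< 0.1% on the pole voltage)
is documented by the convergence study rather than extrapolated away.
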