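# Methods

`hybridcell` couples a one-dimensional electrical model of a neuron to a
three-dimensional model of its intracellular calcium dynamics.  This note
records the models, the numerical choices, the default parameters with
their rationale, and what the synthetic test geometries do and do not
represent.

## Model overview

**1D electrical model.**  The neuron is reduced to a tree of cylindrical
compartments.  Each compartment carries Hodgkin-Huxley membrane dynamics

    c_m dV/dt = -( n^4 g_K (V-E_K) + m^3 h g_Na (V-E_Na)
                   + g_L (V-E_L) + I_Ca ) + I_axial + I_electrode

with first-order gate kinetics dx/dt = (x_inf - x)/tau_x.  The rate
functions are the classical 1952 squid forms, written internally in the
original displacement convention (V = 0 at rest, depolarization negative)
and exposed in absolute mV with rest at -65 mV.  Axial coupling uses
R_a = 4 R_i l / (pi d^2) between compartment midpoints; at branch points
the axial currents of all children sum into the shared node.  I_Ca is a
GHK calcium current evaluated with the compartment's back-mapped
intracellular calcium concentration.

**3D calcium model.**  On the cytosolic volume Omega with plasma membrane
Gamma, free calcium c and free mobile buffer b obey

    dc/dt = div(D grad c) - B(c,b),   db/dt = D_B lap b - B(c,b)
    dc/dn = Phi(V_m(x,t), c(x,t))     on Gamma

with the mass-action reaction B = k_on c b - k_off (B_total - b).  The
bound complex CaB = B_total - b is never stored, so buffer conservation is
an identity, not a solver property.  D may be a full 3x3 tensor
(anisotropic diffusion); a stationary buffer is D_B = 0.

**Membrane channels.**  The Neumann flux Phi comes from Borg-Graham
N-type voltage-gated calcium channels: open fraction G = k l^2 with
exponential-rate gates (alpha = K e^{z gamma (V-V_half) F/RT},
beta = K e^{-z (1-gamma)(V-V_half) F/RT}), single-channel GHK current,
and surface density rho (spatially uniform by default; per-region
placement is supported).  The conversion from current to molar flux
divides by z F; influx (inward current) is positive Phi.

**Coupling.**  Both models share one timestep.  Per step: (1) cable step
with I_Ca from the previous back-mapped concentrations (a documented
one-step lag); (2) compartment potentials mapped to membrane surface
vertices by exact nearest-neighbor search on the compartment nodes
(k-d tree; optional linear/bilinear interpolation over k pseudo nearest
neighbors with a distance cutoff); (3) explicit-Euler gate update and GHK
flux at the mapped potentials and local surface concentrations; (4)
implicit 3D step; (5) back-mapping: per compartment, the area-weighted
mean of c over the compartment's membrane patch times the correction
factor pi*d*l / ||patch|| (the ratio of the ideal cylinder lateral area to
the actual mesh patch area).  The exchange is explicit and staggered (one
exchange per step, no sub-iteration), so the coupling is formally first
order; halving dt moves the reference run's peak by well under 2%.

Note the correction factor is applied literally: where patch and cylinder
areas differ strongly (terminal compartments whose patches include end
caps), the back-mapped value is scaled below the patch mean.  This is a
property of the mapping definition, not a bug; the factor exists to
reconcile the non-identical 1D and 3D surface measures.

## Mesh generation

Meshes are generated from the point-diameter tree by one uniform
construction for all topologies.  The geometry is the union of edge frusta
(flat-capped at terminal tips) and soma spheres; obstacles are coaxial
cylinders subtracted by CSG.  The signed distance field of that solid is
sampled on a cubic lattice of spacing h; cells with center SDF below
-0.1 h are kept (largest debris components below 8 cells are dropped, and
voxel configurations that would pinch the boundary are repaired); each
cell splits into five tetrahedra with checkerboard parity so faces conform
across cells; boundary vertices snap onto the exact zero level set along
the SDF gradient and relax tangentially for two rounds.  A quality guard
blends vertices of any element below the aspect-ratio guideline
(AR_tet = 3 r_in/r_circ >= 0.1) back toward their lattice positions.  The
triangular surface mesh is the oriented boundary of the tetrahedral mesh:
the two are conforming by construction, watertight, genus 0 per closed
component, and inserting an interior obstacle never touches the outer
membrane triangulation (H = 0 is bit-identical to the obstacle-free mesh).

Accuracy trade-offs of this generator: enclosed volume converges with
refinement (errors of a few percent at n_circle = 8 down to well under 1%
by n_circle = 16-24 on a 1 um cylinder), while the *lateral surface area*
of a snapped chord triangulation systematically overshoots by up to ~6%
at fine resolution (the triangle normals zigzag even with all vertices on
the exact surface — the classical inscribed-polyhedron area effect).  The
back-mapping's area-ratio factor absorbs exactly this bias by design, and
the resolution parameter n_circle maps to h = pi r_min / n_circle.

Resolution floors: the lattice must resolve the thinnest feature; an
annular gap around an obstacle needs >= 2-3 cells ((1-H) r / h >= 2), else
the gap seals and the obstacle behaves as a full blockage.

## Discretization and solvers

The 3D problem uses vertex-centered finite volumes realized as a P1
control-volume finite-element scheme: piecewise-linear nodal basis, exact
element stiffness for tensor D, and barycentric dual cells (|T|/4 lumped
per vertex) as control volumes.  The stiffness matrix has zero row sums
(pure Neumann), so total calcium is conserved to solver tolerance with a
sealed membrane; channel fluxes enter as boundary integrals lumped onto
membrane vertices (one third of each incident face area).

Time stepping is implicit Euler (first order, unconditionally stable; the
spatial signal of interest decays over tens of ms, so dt = 0.1 ms keeps
the temporal error far below the spatial error).  The per-step nonlinear
system in (c, b) is solved by a Newton outer loop with a frozen factorized
Jacobian (sparse LU, re-linearized only if convergence stalls) and a
linear-extrapolation predictor; iteration stops when the residual,
measured in concentration units (|r| dt / M_i), drops below 1e-9 uM.  At
desk scale (<= ~3e5 nodes) a cached direct factorization outperforms an
iterative solver and is exactly reproducible; the solver class is
self-contained and replaceable.

The cable equation is advanced by Crank-Nicolson with staggered gates
(gates at half steps, advanced by exact exponential relaxation with rates
frozen at the step-end potential): measured self-convergence order ~2.
Rate-function singularities are evaluated by series limits.  The per-step
tree system is solved directly (dense below 256 compartments, sparse
above).

Spatial self-convergence of the diffusion solver on the snapped meshes is
second order in L2 (fitted order ~2.0-2.3 over h = 0.4/0.2/0.1 um on the
cosine benchmark); the cosine amplitude after 100 ms matches the Fourier
solution to ~1.5% at h = 0.18 um.

Negative concentrations (possible after aggressive flux steps) are
clipped to zero with a counted correction; the reference protocols never
trigger it.

## Parameters and units

Everything internal is um / ms / mV / uM; nA and pA for compartment and
single-channel currents; conductance and capacitance densities are
entered in mS/cm^2 and uF/cm^2 and converted on ingest.  Configuration
accepts the conventional units of each quantity (e.g. diffusion in
um^2/s).

| parameter | default | unit | note |
|---|---|---|---|
| dt | 0.1 | ms | shared 1D/3D step |
| stim amplitude / duration | 0.1 / 10 | nA / ms | soma-midpoint clamp |
| c_m | 1.0 | uF/cm^2 | classical |
| g_Na, g_K, g_L | 120, 36, 0.3 | mS/cm^2 | classical squid set |
| E_Na, E_K, E_L | 50, -77, -54.4 | mV | rest approx. -65 mV |
| R_i | 100 | Ohm*cm | typical dendritic value |
| D (calcium) | 100 (swept 20-100) | um^2/s | experimental range |
| buffer k_on / k_off | 0.09 / 0.24 | 1/(uM ms), 1/ms | K_d ~ 2.67 uM |
| buffer D_B / B_total | 0.043 um^2/ms / 20 uM | | calbindin-scale mobility |
| [Ca]_o / [Ca]_i(0) | 1.6 mM / 0.1 uM | | Nernst ~ +125 mV |
| VGCC density rho | 1000 (swept 200-1000) | 1/um^2 | |
| VGCC V_half (k, l) | -21 / -40 | mV | N-type |
| VGCC K (k, l) | 1.7 / 70 | 1/ms | with tau_0 = 1.7 / 70 ms |
| VGCC z_k / z_l / gamma | 3.4 / +1 / 0 | – | see below |
| p_Ca | 1e-15 | cm^3/s | see below |
| temperature | 300 | K | |

**Activation slope z_k = 3.4.**  With a shallow slope (z_k ~ 2) the
activation gate has a resting open probability of ~3e-2; because the
model has no extrusion mechanism, the resting leak integrated over 100 ms
then exceeds the spike-evoked influx several-fold and the baseline ramps
without bound.  The steep Borg-Graham-style N-type slope (3.4) pushes the
resting open probability to ~3e-3 so the channel is effectively closed at
rest, opens during the spike, and the calcium signal is spike-locked —
the behavior the channel model is meant to produce.  The slope is a
per-gate config field.

**Permeability p_Ca = 1e-15 cm^3/s.**  The permeability sets the absolute
flux scale.  The default is calibrated so that, at the reference density
of 1000 channels/um^2, open-channel currents stay below a picoampere and
the dendritic transient peaks a few hundred nM above the 100 nM baseline
— the scale reported by calcium imaging in fine dendrites.  Larger
literature-quoted permeabilities produce single-channel currents of
nanoampere order at this density, i.e. millimolar-per-millisecond
accumulation, which is outside the regime the buffered diffusion model
(and any real dendrite) can represent.  p_Ca is a plain config field.

**Eq.-10-style back-mapping factor** is applied exactly as defined (mean
times area ratio); see the coupling section for its edge-case behavior.

## Synthetic geometries and what the tests show

The fixtures are a straight cylinder dendrite (10 um x 1 um radius, the
workhorse of the parameter studies), a Y-branch (one bifurcation), and a
sphere-soma with >= 2 dendrites (exercises the soma meshing path).  They
are deterministic given a seed and stand in for reconstructed
morphologies.  They share with real dendrites the governing physics
(cable propagation, surface-to-volume ratio of ~2/r, membrane-localized
influx, buffered diffusion) but not: tapering and tortuosity, spines,
intracellular organelles other than idealized cylindrical obstacles,
inhomogeneous channel maps beyond piecewise-constant windows, or any
extrusion/uptake mechanisms (pumps, exchangers, ER/mitochondria), so
computed baselines drift slowly upward over long windows and absolute
peak values should be read as model-scale, not as predictions for a
specific cell type.  Passing tests demonstrate correctness of the
numerics and mappings and reproduction of the *relative* parameter
dependencies (linearity of peak amplitude in density; linear fit quality
of peak vs diffusivity), not quantitative agreement with any particular
experimental recording.

The reference parameter studies run on the cylinder at lattice spacing
h = 0.16 um (~10^4 mesh vertices, ~50,000 tetrahedra), 100 ms at
dt = 0.1 ms, with peak amplitude read at a membrane-adjacent probe
(0.9 r) on the midpoint cross-section; the diffusion sweep holds
rho = 1000 um^-2, the density sweep holds D = 100 um^2/s.  A probe placed
nearer the axis sees smaller, later, flatter transients; "peak amplitude"
always means max over time minus baseline.  Each sweep of five runs takes
roughly five minutes on one CPU core.

## Known limitations

- Loose (non-iterated) coupling with a one-step lag of I_Ca; adequate at
  dt = 0.1 ms, but stiff two-way feedback (e.g. calcium-activated
  conductances) would need sub-stepping or iteration.
- The surface-area overshoot of snapped chord triangulations (~5%) biases
  total influx by the same factor; relative statements (sweeps, fits) are
  unaffected.
- H = 1 obstacles have no finite effective electrical diameter; the 3D
  domain is sealed but the 1D diameter correction is refused rather than
  guessed.
- The hoc reader covers only the geometry subset (create / connect /
  pt3dadd); it is a geometry carrier, not an interpreter.
- No extracellular space: the exterior is a fixed concentration bath.
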