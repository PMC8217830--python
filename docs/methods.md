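# Methods

## Model

The state variable is oxygen partial pressure P(x, y, z, t) in mmHg on a
box containing a PDMS slab (0 ≤ z ≤ h_pdms, default 25 µm) beneath a block
of skeletal muscle. Dividing the dissolved-oxygen balance by the local
solubility gives the equations the solver integrates:

- tissue: ∂P/∂t = D ∇²P + K(1 − P/P0) − (M0/k) · P/(P + P50)
- PDMS:   ∂P/∂t = D′ ∇²P

The capillary source K(1 − P/P0) models a homogeneous, instantaneously
responsive capillary bed at mean PO2 P0; consumption is Michaelis–Menten
with a ceiling expressed in pressure units as M0/k ≈ 4.04 mmHg/s. The model
is diffusion-only: convective transport by flowing red cells is neglected,
which if anything overestimates how far a challenge spreads. Setting the
reaction to zero in the membrane and changing D, k across the interface is
the whole two-material physics; continuity of P and of flux D·k·∂P/∂n is
imposed by the discretisation below.

Assumptions worth keeping in mind: homogeneous consumption and supply (no
discrete vessels), constant-temperature constants, instantaneous gas
switching at the window, rigid geometry.

## Parameters

All internal units are µm, s, mmHg; diffusivities quoted in cm²/s are
converted once on construction (1 cm²/s = 1e8 µm²/s).

| symbol | meaning | default | units |
|---|---|---|---|
| D | O2 diffusivity, tissue | 2.41e-5 | cm²/s |
| k | O2 solubility, tissue | 3.89e-5 | mL O2/mL/mmHg |
| D′ | O2 diffusivity, PDMS | 3.40e-5 | cm²/s |
| k′ | O2 solubility, PDMS | 1.32e-5 | mL O2/mL/mmHg |
| M0 | max consumption | 1.57e-4 | mL O2/mL/s |
| P50 | consumption half-point | 0.5 | mmHg |
| K | capillary transport rate | 30 | mmHg/s |
| P0 | mean capillary PO2 | 48 | mmHg |

These are standard literature values for resting rat skeletal muscle and
Sylgard-type PDMS. The reaction equilibrium they imply, 41.62 mmHg, is the
far-field tissue PO2; every steady run is checked against it.

Window gas: %O2 converts to boundary PO2 as fraction × 760 mmHg (dry gas,
the default, since the chamber is fed by mass-flow-metered dry mixtures); a
`vapor_correction` flag subtracts 47 mmHg first for humidified lines. The
choice shifts boundary PO2 by ~6%, one of the reasons extent predictions
carry a band of several percent.

## Discretisation and numerics

Vertex-centred grid, isotropic spacing dx; an axis of length L carries
⌊L/dx⌋+1 nodes. h_pdms and the tissue height must be integer multiples of
dx so the material interface is a grid plane. Spatial derivatives are
second-order central differences; zero-flux boundaries use mirror ghosts.
Each vertical face carries the permeability D·k of the single material its
midpoint lies in, and the flux divergence at a node is divided by that
node's solubility. Because the interface is grid-aligned, every face is
single-material and the reaction-free two-layer steady profile is
reproduced exactly (the verification suite checks <1e-4 mmHg); a
harmonic-mean face coefficient would instead displace the effective
interface by dx/2.

Time stepping is the IMEX splitting

P⁺ = [P + dt (D ∇²P + K − (M0/k) P/(P+P50))] / (1 + dt K/P0),

i.e. only the stiff linear relaxation −(K/P0)P is implicit, which is a
pointwise division: the scheme remains matrix-free and costs one sweep per
step. It is first-order accurate in time (verified by the convergence test
against a Runge–Kutta integration of the reaction ODE) and second-order in
space (observed order 1.97 on the linearised 1D column). Stability is
diffusion-limited; dt defaults to 0.9·dx²/(6·max(D, D′)) ≈ 1.1 ms at
dx = 5 µm. Window nodes are reset to the chamber PO2 after every sweep.
Negative or non-finite pressures abort with the offending node and time
rather than being clamped, so instability is loud.

Steady state is declared when max|ΔP|/dt < 1e-3 mmHg/s (sampled every 25
steps); the defaults give settling in ~7–10 s of simulated time for the
challenge scenarios. Protocol runs shrink dt per segment so switches land
exactly on step boundaries.

Degenerate inputs: h_pdms = 0 gives a pure-tissue column (used by the 1D
verification problems); single-node lateral axes drop the lateral stencil;
an empty window layout leaves the whole glass zero-flux.

## Extent metrics

The reach of a challenge ends where the magnitude of the directional
derivative of P drops below θ = e⁻⁴ ≈ 0.0183 mmHg/µm. The locus of
evaluation is a genuine design choice; this package fixes it as follows and
records the choices in every report's metadata:

- penetration depth: along the vertical line through the window centroid,
  the largest z with |∂P/∂z| ≥ θ, reported as depth below the tissue
  surface (z − h_pdms);
- lateral extents: in every horizontal tissue plane, march outward from the
  window-edge midpoint along the window's long (x) and short (y) axes; the
  extent is the distance to the first node with |∂P/∂axis| < θ; the
  headline value is the maximum over planes, and per-plane values are
  available;
- affected area at a plane: window footprint plus twice the lateral extents
  in that plane;
- settle time: first time a probe trace stays within 0.1 mmHg of its final
  value.

All extents are resolved to one grid spacing; the metrics are exact on
synthetic exponential fields (closed forms in the test suite) and
non-increasing in θ by construction.

## Verification

Independent references, none sharing stencil code with the solver:
a piecewise-linear two-layer slab solution; the Krogh-style zero-order
depth √(2DPs/(M0/k)); the cosh profile for consumption linear in P; and a
damped-Newton solution of the complete nonlinear steady system assembled
node-by-node in sparse form (grids ≤ 20³). The `verify` CLI subcommand (or
`oxywindow.verify.run_all()`) prints the comparison table; typical maximum
differences are 1e-7–1e-3 mmHg.

## Canonical scenarios and problem sizes

The production scenario uses a 1200 × 1000 µm footprint with 300 µm of
tissue over 25 µm of PDMS and a single centred 400 × 200 µm window, chosen
so every reported extent stays ≥150 µm from all zero-flux boundaries (the
box does not confine the perturbation; growing the domain or refining the
grid moves extents by under 2%). The acceptance script runs it at dx = 5 µm
(241 × 201 × 66 ≈ 3.2M nodes, a few minutes on one core); the test suite
uses dx = 6.25 µm, the coarsest spacing that keeps the interface
grid-aligned while resolving the extents, and the narrative examples use
12.5 µm. Extents move by roughly one grid cell across these resolutions.

## Known limitations

- The settle-time of the 5% → 2% step is limited by the capillary-supply
  relaxation rate λ ≈ K/P0 = 0.63 /s: driving a ~1 mmHg tail under the
  0.1 mmHg criterion takes ln(tail/0.1)/λ ≈ 3.0–3.7 s across the 25–100 µm
  probes. A looser (e.g. visual-plateau) criterion would report "within
  ~3 s"; the strict criterion used here reports 3.7 s. Both statements are
  about the same transient.
- Homogeneous supply means the model cannot reproduce effects of individual
  vessel geometry; measured perturbations in vivo extend farther than the
  model predicts, consistent with parameter mismatch (notably consumption)
  and discrete vasculature.
- No CO2/N2 transport, no hemoglobin dissociation modelling (SO2 is not a
  state variable), no convection, no implicit diffusion stepping; the
  solver is single-core by design.
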