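# Methods

`tavrom` models, at desk scale, the mechanical and hemodynamic components
of a self-expanding transcatheter aortic valve (TAV) implantation: the
fiber-reinforced hyperelasticity of leaflet and pericardial tissue, a
closed-loop lumped-parameter circulation that loads the valve, a
beam–spring stent frame that is crimped and self-expands, and a 2D
immersed-boundary (IB) fluid–structure solver that demonstrates the
coupling and implicit-contact concepts a full 3D immersed finite
element–difference simulation relies on. This note records the models,
their assumptions, the numerical choices, and what the synthetic data used
for testing can and cannot show.

## Tissue model (`tavrom.hgo`)

Valve leaflets and pericardial tissue are modeled as nearly incompressible
hyperelastic solids with a modified Holzapfel–Gasser–Ogden (HGO) energy,
split into isochoric and volumetric parts, Ψ(F) = W(F̄) + U(J) with
J = det F and F̄ = J^(−1/3) F:

    W(F̄) = C10 {exp[C01 (Ī₁ − 3)] − 1}
           + k1/(2 k2) Σᵢ {exp[k2 (Ī₄ᵢ⋆ − 1)²] − 1},
    U(J)  = β [J ln J − J + 1].

Ī₁ = tr C̄ with C̄ = F̄ᵀF̄, and Ī₄ᵢ⋆ = max(f₀ᵢ·C̄f₀ᵢ, 1) is the
tension-only fourth invariant of fiber family *i*: fibers carry load only
when stretched. Two equally weighted in-plane families at the mean fiber
angle ± θ account for fiber dispersion in a simple way. The first
Piola–Kirchhoff stress P = ∂Ψ/∂F is coded analytically (isochoric
deviatoric projection plus β J ln J F^(−T)) and is verified against
central finite differences of the energy at 1e−6 relative tolerance.

Parameter sets ship for healthy native aortic leaflet tissue
(C10 = 0.1463 kPa, C01 = 26.21, k1 = 0.007072 MPa, k2 = 147.5,
θ = 26.21°, β = 141.0 MPa, mean fiber commissure-to-commissure) and for
glutaraldehyde-fixed porcine pericardium (C10 = 15.14 kPa, C01 = 13.48,
k1 = 0.1526 MPa, k2 = 107.3, θ = 7.81°, β = 5.840 MPa, mean fiber 45° in
the leaflet plane). Two documentation caveats: the native-tissue source
tabulates C01 and θ with the same numeric value (26.21), which we take at
face value; and published descriptions disagree on whether the 45° mean
fiber direction belongs to the prosthetic leaflets or the sealing skirt —
we follow the version that assigns 45° to the leaflets. A stenotic
leaflet variant multiplies C10 by 10³, the conventional way to emulate
severe calcific stiffening. The canonical stress unit is kPa; k1 and β
are quoted in MPa as in the source tables and converted on load.

Exponential arguments are capped at 50 and continued linearly beyond,
with the evaluation flagged; fitting explores extreme k2 values where the
bare exponential overflows double precision. At the shipped parameter
values on the fitting stretch range the cap is never reached.

### Biaxial response and fitting

Planar biaxial tests are emulated under exact incompressibility
(λ₃ = 1/(λ₁λ₂), J = 1) and plane stress (σ₃₃ = 0), the standard membrane
reduction: the hydrostatic multiplier is eliminated analytically and the
volumetric term drops out, which is also why β is *not* identifiable from
biaxial data and is configured rather than fitted. The mean fiber angle is
a protocol property (the specimen is cut at a known orientation) and is
likewise held fixed.

`HGOBiaxialModel.fit()` estimates (C10, C01, k1, k2, θ) by trust-region
least squares in log-parameter space, with residuals weighted by
1/max(|σ|, 0.1 kPa). The relative weighting matters: exponentially
stiffening tissue spans many orders of magnitude of stress over a
[1.0, 1.25] stretch grid, and unweighted residuals would see only the
stiffest corner. A fixed 8-point multi-start schedule, log-spaced over
(k1, k2), guards against the exponential model's local minima and makes
the procedure deterministic. On noise-free synthetic data from either
shipped parameter set the fit recovers all five parameters to machine
precision; with 5% multiplicative noise at 400 stretch states, C10 and k2
return within 10%.

The synthetic generator produces exactly the model's plane-stress response
on a 20×20 stretch grid over the physiologic range [1.0, 1.25] (additive
and/or multiplicative Gaussian noise optional, seeded). It emulates the
*information content* of a planar biaxial test — it does not emulate
experimental artifacts such as tethering effects, shear, fiber-angle
uncertainty, or inter-specimen variability, so successful recovery here
shows identifiability of the estimator, not robustness to real lab data.

## Closed-loop circulation (`tavrom.circulation`)

The left heart is a time-varying elastance model: left atrium (LA) and
left ventricle (LV) have pressures P = E(t)·V̂, where V̂ = C(t)·P is the
volume-like state actually integrated so the balance laws

    d(C_LA P_LA)/dt = Q_vein − Q_MV
    d(C_LV P_LV)/dt = Q_MV − Q_LVOT

hold exactly as written without differentiating C(t). The elastance
waveform is the "two-Hill" product

    E(t) = k·[g₁/(1+g₁)]·[1/(1+g₂)] + Emin,  gᵢ = (t/τᵢ)^mᵢ,

with gain k normalized numerically on a 10⁵-point grid so the waveform
maximum equals Emax exactly; the LA waveform is delayed by 0.85 T
(equivalently advanced by 0.15 T; the sign is a config switch). Venous
return is a constant 5.8 L/min. The mitral valve is an ideal diode with
resistance 0.005 mmHg·s/mL. Downstream, a three-element Windkessel
(Rc = 0.042, Rp = 0.9046 mmHg·s/mL, C = 1.9504 mL/mmHg) gives
P_Ao = P_Wk + Q_Ao·Rc. The period is T = 0.8512 s. All constants ship in
`configs/circulation_default.json`.

The aortic valve is a lumped surrogate standing in for a resolved 3D FSI
valve: a diode in series with a Gorlin-type orifice. When open, the flow
solves

    (Q/(51.6·EOA))² + (R_LVOT + R_c)·Q = P_LV − P_Wk

in closed form (positive quadratic root); 51.6 is the Gorlin constant
linking mL/s, mmHg, and cm². Linear-resistance and ideal-diode kinds are
also available. Both valve states are *lagged*: updated once per time
step from the previous step's pressures, with no event location — the
same simplification used when such reduced-order models drive 3D FSI.

Numerics: classical fixed-step RK4 with dt = 1e−4 s (the step is snapped
to an integer divisor of T so cycles align sample-for-sample), elastance
tabulated at half-step resolution and reused each cycle. Initial
conditions P_Wk = 80, P_LA = 10, P_LV = 8 mmHg. Integration stops when
the cycle-to-cycle maximum aortic-pressure change falls below 0.5 mmHg or
after 20 cycles; metrics always come from the final full cycle. Two runs
with identical inputs are bitwise identical. The slowest transient (the
chamber-volume/afterload balance) decays with a time constant of a few
cycles; at the default tolerance a ~6% volume imbalance remains, so
invariants of the exact periodic orbit (venous inflow volume = stroke
volume to <1%) are verified on a tightly converged run (0.02 mmHg, ≤60
cycles).

Metrics over the final cycle: SV = ∫Q_LVOT dt; CO = SV·60/T (at periodic
steady state this coincides with mean aortic flow, so only one convention
is reported); systole is the set of samples with Q_LVOT > 0; mean
systolic ΔP averages (P_LVOT − P_Ao) over systole; peak diastolic ΔP is
max(P_Ao − P_LVOT) over closed-valve samples; and
EOA = Q_rms,systole/(51.6·√(mean systolic ΔP)), the Gorlin-type reading
of the simplified continuity equation (the Q_rms convention; a
mean-flow-based variant would differ by the flow shape factor).

### Known bias of the inertia-free surrogate

With the shipped parameters and the device's reported 1.50 cm² effective
orifice area, the closed-loop run reproduces SV within ~8%, CO within
~8%, peak diastolic ΔP within ~8%, and returns EOA = 1.50 cm² exactly
(the continuity formula inverts the orifice law). The mean systolic
gradient, however, comes out ~12.4 mmHg against the 9.62 mmHg of the full
3D reference. The cause is structural, not a tuning error: at periodic
steady state the surrogate must eject the full stroke volume within the
ejection window set by the elastance waveform (~0.30 s) and the flow
stops the instant the ventricular pressure drops below the Windkessel
pressure, because the model carries no blood inertia. The resulting
systolic rms flow (~289 mL/s) exceeds the value implied by the 3D
model's own EOA/ΔP pair (~240 mL/s, a longer and flatter ejection
sustained by momentum), and the orifice gradient scales with Q_rms².
Adding an inertance term would flatten the flow and close the gap, but
atrioventricular/valvular inertance is deliberately out of scope for this
surrogate; the bias is reported rather than hidden, and the
corresponding check is expected to fail until an inertance-bearing
surrogate is added.

The prescribed-flow experiment drives any set of valve surrogates with a
common nonnegative flow waveform and reports each valve's gradient
waveform, mean systolic gradient, and continuity EOA. The shipped
synthetic waveform is a single half-sine pulse with stroke volume
45.32 mL at 3.47 L/min (hence T = 0.7836 s), ejection time 0.3 s —
chosen to emulate a severe-stenosis patient waveform by its integral
metrics only; its shape is idealized, so only orderings and scalings
(e.g. gradient ∝ 1/EOA², stenotic > prosthetic > healthy) are meaningful,
not absolute gradients.

## Stent frame (`tavrom.stent`)

The stent is a Lagrangian node set on an idealized cylindrical
diamond-cell lattice (the CT-derived geometry of the real device is not
reproduced): rings of n points, odd rings rotated half a cell, diagonal
struts as linear springs, and discrete beams along the vertical zig-zag
curves penalizing the deviation of the second-difference magnitude from
its rest value — a bending energy invariant under rigid rotation and
translation. Each ring additionally carries circumferential chord
springs, playing the role of the crown connections of a laser-cut frame;
without them the end rings of a pure diamond lattice have a flaring
mechanism (no bending constraint reaches them) and self-expansion settles
a few percent wide. Rest lengths and curvatures are measured from the
generated geometry, so the nominal configuration is an exact equilibrium
and the frame is self-expanding by construction.

Crimping uses a contracting radial barrier: a crimper radius moving
inward at 50.0 cm/s tethering outside nodes back with a stiff spring
constant of 3.0×10⁸ dyne/cm. The barrier realizes the kinematic effect
of a physical crimping cage; in a full FSI setting that contact would be
fluid-mediated, which has no standalone-structural equivalent. Residual
penetration past the barrier is bounded by elastic force / tether
stiffness (~1e−4 cm here). Dynamics are overdamped first-order gradient
flow (only equilibria and quasi-static paths matter), explicit Euler with
stability step damping/(4·k_max); energy blow-up aborts with a suggested
smaller step.

Member stiffnesses are *not* published for the real device: the defaults
(springs 1e5 dyne/cm, beams 1e3, damping 1e4 dyne·s/cm) are chosen so
the crimped frame re-expands on a ~0.1 s timescale and are exposed in
config — absolute stent forces are therefore not meaningful, only
equilibria, diameters, and energy-consistency properties. The shipped
demo crimps the 26 mm frame to 17.25 Fr (5.75 mm; 1 Fr = 1/3 mm),
the delivery-capsule scale, and recovery of the nominal diameter after
release is exact to <0.01%. Diameters are measured about the fixed
z-axis of the generated lattice (no axis refitting).

## 2D immersed-boundary solver (`tavrom.ib2d`)

The fluid is incompressible Navier–Stokes on a uniform periodic MAC grid
(density 1.0 g/cm³, viscosity 3.5 cP by default): explicit centered
advection, Crank–Nicolson viscosity, and an FFT pressure projection that
zeroes the discrete divergence to round-off (≤1e−10 enforced).
Advective CFL above 0.5 aborts with a suggested step. The decaying
Taylor–Green vortex is reproduced within 0.01% in L2 at 64².

Lagrangian coupling uses the classic 4-point regularized delta kernel
(pluggable in principle; the production kernel of large 3D codes varies):
φ(0) = 1/2, φ(±1) = 1/4, support |r| < 2, discrete partition of unity
and zero first moment to 1e−12. Force spreading and velocity
interpolation are exact discrete adjoints up to the mesh-volume factor,
and spreading conserves total force. Structures (point sets with spring,
bending, and tether elasticity — the same force types as the stent
module) move with the interpolated velocity; contact is therefore
implicit: interfaces that close against each other seal against the flow
without any contact model.

Demonstrations, 2D and uniform-grid by design (the adaptive 3D machinery
of production FSI codes is out of scope):

* **Elastic ring** — a pressurized elliptical membrane relaxes to a
  circle in a periodic box; enclosed-area drift ≤1% over 1 s and final
  circularity (radius SD/mean) ≤1% at 64². The equilibrium radius
  converges to the exact area-conserving circle at first order in h.
* **Pressurized leaflets** — a channel built from stiff tether-point
  walls with two elastic leaflets meeting at mid-channel; under a mean
  pressure-gradient body force the closed leaflets carry the load with a
  residual leak <0.1% of the open-channel flux, and the tips never
  interpenetrate. The demo uses viscosity 1.0 g/(cm·s) so the channel
  reaches steady state quickly; the coupling physics being demonstrated
  is viscosity-independent.
* **Poiseuille verification** — tether-point walls displace the
  effective no-slip plane into the channel by a constant fraction of the
  mesh width (≈0.6h, the kernel width), making the open-channel flux
  first-order accurate in h. The flux is therefore Richardson-
  extrapolated from two resolutions (32, 64) before comparison with
  G·H³/(12μ), landing within ~1%; a single resolution would sit ~10%
  low. This is the standard way to verify solvers whose boundary
  treatment is first-order.

## Configuration and I/O (`tavrom.io`, `tavrom.cli`)

JSON configs use unit-suffixed keys throughout; numeric keys without a
recognized suffix (or a whitelisted dimensionless name) are hard errors.
Conversions — 1 mmHg = 1333.22 dyn/cm², 1 Fr = 1/3 mm, 1 MPa = 1000 kPa
— round-trip to 1e−12. Waveforms and histories are CSV at full precision
(round-trip exact); geometry snapshots are VTK legacy ASCII (polydata for
structures, structured points for fields) written by a small built-in
writer; metrics JSON carries convergence flags and the resolved config
hash, and identical runs produce byte-identical outputs. The `tavrom`
CLI exposes each module (`gen-biaxial`, `fit-hgo`, `rom`,
`rom-prescribed`, `crimp`, `expand`, `ib2d-demo`) and writes a manifest
(config hash, version, seed) next to every output.

## Problem sizes

Everything runs on one CPU in minutes: biaxial fits use 400 stretch
states (800 stress observations) and 8 optimizer starts (~0.3 s each);
the circulation integrates ≤20 cycles at dt = 1e−4 s (~3 s); the stent
uses a 72-node lattice (crimp ~0.4 s); IB demos run at 64² (Taylor–Green
0.2 s, ring ~8 s, channel runs ~20–30 s each). These sizes were chosen
as the smallest at which every property above is cleanly exhibited.

## Limitations

No 3D geometry anywhere: patient anatomy, CT-derived stent and leaflet
shapes, and the 3D FSI valve are all replaced by idealized or lumped
stand-ins, so absolute hemodynamic numbers inherit the surrogate biases
described above (most visibly the systolic-gradient overestimate of the
inertia-free orifice). The stent model omits Nitinol's
temperature-dependent superelasticity, sheath dynamics, and
stent–anatomy contact. The tissue model omits viscoelasticity, damage,
and flexural behavior (the pericardial parameter set originates partly
from flexural data that this package does not refit). The 2D IB solver
is periodic and uniform-grid, cannot resolve wall boundary layers or
shear stresses, and its leaflet demo is a closure/contact demonstration,
not a valve simulation.
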