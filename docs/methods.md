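# Methods

## The model

`pyresim` implements a two-state continuum model of the pyrenoid linker
protein EPYC1 in the chloroplast of *Chlamydomonas reinhardtii*.  EPYC1
exists in two interconverting states: unphosphorylated ("sticky"), which
self-attracts and condenses (standing in for the EPYC1–Rubisco network),
and phosphorylated ("non-sticky"), which behaves like solvent.  The
fields are volume fractions φ_s(r,t) and φ_ns(r,t) with solvent
φ_sol = 1 − φ_s − φ_ns.

The free-energy density (units of k_BT per lattice site) is

    f = Σ_i φ_i ln φ_i  −  χ φ_s²
        + ½ (κ̃_s |∇φ_s|² + 2 ∇φ_s·∇φ_ns + κ̃_ns |∇φ_ns|²),

with i ∈ {s, ns, sol}.  Exchange chemical potentials are the variational
derivatives

    μ̃_s  = ln(φ_s /φ_sol) − 2χ φ_s − κ̃_s ∇²φ_s − ∇²φ_ns,
    μ̃_ns = ln(φ_ns/φ_sol)          − ∇²φ_s − κ̃_ns ∇²φ_ns,

and the dynamics are reactive Cahn–Hilliard equations with degenerate
mobilities D̃ φ_i and first-order switching:

    ∂t φ_s  = D̃ ∇·(φ_s  ∇μ̃_s)  − k̃(t) φ_s + φ_ns,
    ∂t φ_ns = D̃ ∇·(φ_ns ∇μ̃_ns) + k̃(t) φ_s − φ_ns.

Lengths are measured in ℓ_κ = √κ′_s-ns and times in the inverse
dephosphorylation rate 1/k_ns→s; k̃ = k_s→ns/k_ns→s is the
kinase/phosphatase activity ratio (the KEY1 dial).

**Sign convention for χ.**  The package stores χ as a *positive
attraction magnitude*; the interaction term in f is −χ φ_s² and μ̃_s
carries −2χ φ_s.  Larger χ therefore always means stickier EPYC1
(χ = 7 is the default, 5.5 models normally sticky EPYC1 with low kinase,
8 models overly sticky EPYC1 with no kinase).  One convention is used
everywhere — free energy, chemical potentials, dispersion relation,
droplet theory — and the free energy/chemical-potential pair is verified
variationally in the tests.  Note the interaction coefficient is −χ (not
−χ/2): this is what makes the pair variationally consistent and matches
the 2χφ_s factor in the transport equations.

The uniform reactive steady state is φ_s,0 = φ_tot/(1+k̃),
φ_ns,0 = φ_tot k̃/(1+k̃).

## Linear stability (`stability`)

Perturbations δφ ~ exp(ω̃t̃ + iq̃x̃) about the uniform state obey a 2×2
eigenvalue problem built from the free-energy Hessian, the
gradient-energy matrix [[κ̃_s, 1], [1, κ̃_ns]] and the reaction matrix
[[−k̃, 1], [k̃, −1]].  ω̃(q̃) is the larger real part of the two
eigenvalues, computed in product form so the k̃ = 0 case (φ_ns,0 = 0)
stays finite.  A second, independent route evaluates the same relation
as an explicit scalar polynomial L(ω̃, q̃); the two agree to ~1e−15 and
any residual above 1e−8 is surfaced as a diagnostic.

Classification: ω̃(0) = 0 always (mass conservation); the curvature
d²ω̃/dq̃² at q̃ = 0 is estimated by Richardson-extrapolated finite
differences at q̃ ∈ {1e−3, 2e−3}.  `stable_uniform` if no mode grows;
`coarsening` if modes grow and the curvature at 0 is non-negative;
`arrested_candidate` if long-wavelength modes are suppressed (negative
curvature) while a finite-q̃ band still grows.  With the default
parameters: k̃ = 0 → coarsening (ω̃_max ≈ 0.42 at q̃ ≈ 0.54), k̃ = 0.14
→ arrested (ω̃_max ≈ 0.002), k̃ ≳ 0.5 → stable uniform.  Arrest proper
is a nonlinear statement and is established by the solver scenarios, not
here.

## Solver (`solver`)

Two geometries:

* **Periodic square** — pseudo-spectral: Laplacians and the divergence
  of the degenerate-mobility flux are evaluated with FFTs; time stepping
  is first-order IMEX with a constant-coefficient biharmonic
  stabilization `A_i = D̃ κ̃_i max φ_i` treated implicitly in Fourier
  space.  Mass is conserved to machine precision (the q = 0 mode is
  untouched by the flux divergence; reactions exchange species
  pointwise).
* **Chloroplast** — ellipse (semiaxes ã = 35, b̃ = 29.17) minus an inner
  disc (r̃ = 16.67) whose centre is displaced along the major axis
  (default δ̃ = 10, configurable), so the disc crosses the ellipse and
  leaves an open cup with two arms, matching the shape of the
  chloroplast around the nucleus.  Discretization is a staircase mask
  with conservative finite-volume face fluxes; no-flux walls (zero face
  flux) plus the anti-wetting contact-angle condition
  ∇φ_i·n = √2/(2κ̃_i) cos(θ)(1−φ_i²) with θ = 5π/6 imposed as a
  ghost-face gradient in the Laplacians of the chemical potential.
  Time stepping is the same stabilized IMEX with a sparse-LU solve of
  (I + Δt A_i L²); L has zero row/column sums, so the implicit solve is
  exactly mass-conserving too (observed drift ~1e−11 relative over 1e4
  steps is LU round-off).

Numerical choices: logarithms are evaluated on fields clipped to
[1e−9, ∞) — the state itself is never clipped, so mass conservation is
exact; mobilities use arithmetic face averages clipped to [0, 1];
default Δt targets ≥ 20 steps per e-folding of the most unstable linear
mode and an explicit second-order stability estimate; on blow-up the
step is halved once and the run restarted, then an error naming the
failing time is raised.  At χ = 7 the dense binodal is ≈ 0.999, so
interfaces are steep (width ≈ 1.5 ℓ_κ); with spacing 0.5 the total
fraction φ_s + φ_ns transiently overshoots 1 by up to ~5% in interface
cells.  This overshoot is a resolution artifact of the sharp-interface
regime, does not grow, and does not affect mass conservation; bound
checks in the tests use this tolerance.

`KinaseSchedule` carries k̃(t) (piecewise linear or constant),
optionally χ(t), and a `reactions` switch: k̃ = 0 still leaves
dephosphorylation running (its rate is the unit of time), so fully
passive runs (both rates zero) use `KinaseSchedule.passive()`.

`measure_interface_fluxes` integrates the conservative transport
divergence over a condensate's node set — by the discrete divergence
theorem this equals the net surface flux exactly — returning the sticky
influx and non-sticky outflux.

## Droplet theory (`droplet`)

The sharp-interface model reduces the mixture to sticky EPYC1 (fraction
φ) in a reactive bath.  In quasi-steady state, 0 = ∇²φ − φ + k̃(1−φ)
with lengths in ℓ = √(D/k_s→ns).  **This module's k̃ is
k_ns→s/k_s→ns — the inverse of the PDE module's ratio** (the two
conventions are both standard for their respective calculations;
`k_tilde_from_pde`/`k_tilde_to_pde` convert).  Closed-form interior and
exterior profiles pinned to the binodal values φ₊/φ₋ at the interface
give the kinematic equation dR̃/dt̃; its stable root (sign change + → −,
located by a log-spaced scan and bisection on R̃ ∈ [1e−3, 1e3]) is the
preferred radius R̃_eq.  A stable root exists iff
k̃ < k̃_c ≃ (φ₊+φ₋)/(2−φ₊−φ₋); the numeric bisection for k̃_c
(tolerance 1e−4) agrees with the closed form to ~0.1%.

The closed-form radius approximation
R_eq ≃ ℓ (3k̃ + √(3k̃(4+3k̃)))/(2√(1+k̃)) follows from equating the
volume-scaling interior conversion with the surface-scaling exterior
flux in the φ₊ → 1, φ₋ → 0 limit.  It is accurate well below the
critical ratio — within ~3% at k̃ = 0.05 and ~10% at k̃ = 0.2 — and
degrades monotonically toward k̃_c (where the exact R̃_eq diverges but
the closed form stays finite): ~16% at k̃ = 0.3 for φ₊ = 0.95.  Tests
assert this accuracy envelope rather than a uniform tolerance.

Without reactions the classic diffusion-limited growth law
R̃ = R̃_init + √(2(φ_∞−φ₋)/(φ₊−φ₋) t̃) applies (exponent ½).  The
droplet model is three-dimensional (spherical symmetry) as is standard;
the PDE simulations are two-dimensional, so quantitative comparisons
between the two are intentionally limited to trends.

## Quantification (`quantify`)

Mirrors a standard confocal pipeline: threshold the condensate channel
inside a cell/chloroplast mask, label connected components
(8-connectivity in 2D, 26 in 3D), report count, sizes, equivalent radii
(disc/sphere equivalent), centroids, condensed volume fraction
V_dense/V_domain, and the largest condensate's share of the cell.
`condensed_fraction` counts *all* super-threshold nodes regardless of
the `min_size` speckle filter (default 4 nodes).  The automatic
threshold is the midpoint of the in-mask range when a clear dense/dilute
gap exists; fields on the volume-fraction scale without a dense plateau
(spread < 0.2) are treated as dissolved — this keeps a slowly diffusing
remnant cloud from being read as a giant condensate.  The threshold is
an explicit argument everywhere, matching practice where it is held
constant within an acquisition.

For noisy stacks, `segment` accepts an optional Gaussian pre-filter
(`smooth_sigma`, off by default; per-axis values supported).  At
signal-to-noise around 5, raw thresholding produces spurious
≥ `min_size` clusters of read noise, so a mild pre-smoothing — the
standard step in confocal pipelines — precedes thresholding there; an
anisotropic sigma (smaller along z) keeps the bias on z-compressed
condensates below the radius tolerance.

Photobleach correction multiplies frame t by total(0)/total(t),
assuming constant protein amount across the acquisition — corrected
totals are exactly constant.  `canonical_position` is the
distance-transform argmax of the domain mask (first raster index on
ties): the interior point farthest from the walls, which for the cup
geometry lies in the wide lobe opposite the inner disc.

## Scenarios and synthetic data (`scenarios`)

Scenario presets reproduce the model's qualitative regimes (see the
module docstring).  The default geometry is a half-linear-scale
chloroplast at spacing 0.5 — chosen so each regime completes in minutes
on one core while keeping ≥ 4 nodes across every interface; `scale=1.0`
restores the full-size domain.  Initial condensates are tanh discs whose
plateau is 98% of the dense binodal φ₊(χ) (common-tangent construction;
the linear part of the interaction does not shift coexistence, so
φ₊ = 1 − φ₋ with ln(φ/(1−φ)) + χ(1−2φ) = 0); the background sits at the
dilute binodal φ₋ unless a scenario specifies a bath level, and φ_ns
starts at the local reaction balance k̃ φ_s.

Scenario-specific choices worth recording:

* **size_control_pair / close_pair** use k̃ = 0.14 (the arrested band).
  Two unequal droplets relax to a common radius; the criterion is the
  final radius ratio.  The repulsion pair is placed with an
  interface-to-interface gap of ~4 ℓ_κ: closer pairs coalesce before
  the active repulsion can act, farther pairs barely interact.
* **off_centre** uses k̃ = 0.12 — below the 0.14 of the size-control
  and repulsion runs, as the regime comparison requires, but high
  enough that the condensate turns its material over in ~1/k̃ ≈ 8 time
  units and drifts measurably within the horizon (at k̃ ≤ 0.05 the
  drift is immeasurable at this scale).  This scenario also runs at
  spacing 0.35 rather than 0.5: the active drift force on a single
  droplet is weak, and on the coarser staircase lattice the droplet
  pins to the grid.  The droplet is placed with ≥ 2 interface widths of
  wall clearance — droplets touching the wall's depletion layer feel a
  passive anti-wetting push that would contaminate the passive
  control — and the bath starts at the dilute binodal.  The passive
  control's only motion is a wall-relaxation transient of the initial
  tanh profile over the first ~0.4 of the horizon; displacement
  comparisons therefore exclude that window (and average snapshot
  endpoints to suppress centroid-quantization jitter).  A droplet in
  net evaporation drifts *toward* the nearest wall (it recedes fastest
  on its open, best-supplied side), the reverse of centring; the
  scenario keeps the droplet in balanced turnover so the influx-biased
  centring drift dominates.
* **ectopic_lowKEY1 / ectopic_noKEY1** place a large main condensate
  and a small ectopic one in an arm.  The discriminating physics is the
  dilute-phase level: φ₋(5.5) ≈ 4e−3 supports ripening of the ectopic
  droplet into the main one within the horizon, while φ₋(8) ≈ 3e−4
  (overly sticky) freezes coarsening, so the ectopic droplet persists.
* **division_cycle** drives k̃(t) through a ramp–plateau–ramp
  (0.01 → hold 0.22 → peak 2.0 → slow quench → 0.01) on a smaller
  domain (scale 0.4).  Each design element maps to one phase of the
  count signature 1 → >1 → 0 → >1 → 1:
  the *up-ramp* ">1" comes from satellite nucleation — the oversized
  condensate shrinks toward the smaller preferred radius of the
  arrested band and its released material pushes the bath past the
  spinodal, which requires droplet mass comparable to the domain's
  capacity and hence the smaller domain (outright droplet division
  also occurs in this model, but only for radii ≳ √(D̃/k̃) ≈ 8–12,
  which do not fit a scaled-down cup);
  the *peak* is k̃ = 2 because droplets survive well beyond the
  linear-stability threshold (≈ 0.5) as metastable objects — the
  droplet theory's critical ratio at φ₊ ≈ 1 maps to a PDE ratio ≈ 1;
  the *down-ramp* is slow (a slow quench nucleates only a few
  condensates, which the first nuclei's growth then suppresses), so
  the re-appearing clusters are few and adjacent and the final ">1 → 1"
  happens by direct coalescence — late-stage Ostwald ripening at χ = 7
  (φ₋ ≈ 1e−3) would need 1e3–1e5 time units and is not a desk-scale
  route.  Small zero-mean seeded noise (amplitude 2e−3·√Δt per step,
  mean-subtracted so mass is untouched) provides the fluctuations for
  both nucleation phases.
* **generate_stacks** emulates two-channel confocal data: channel 0 a
  cup-shaped chloroplast (chlorophyll), channel 1 condensates as
  ellipsoids (anisotropic z) plus a diffuse pool, with exponential
  per-frame bleaching, Gaussian read noise and optional Poisson shot
  noise.  It does not emulate a PSF, z-dependent attenuation, or cell
  crowding/touching cells — recovery tests on these stacks validate
  the segmentation logic, not performance on real microscope data.

## What the desk-scale runs do and do not show

The scaled-down scenarios demonstrate the mechanisms — arrest of
ripening, size equalisation, flux balance, active centring/repulsion,
kinase-controlled dissolution — at half linear scale and over horizons
of 100–300 dimensionless time units.  Real pyrenoid dynamics span
minutes, i.e. ~1e5 time units at the physical rate mapping
(1/k_ns→s ≈ 3.4 ms): slow processes whose rate is set by the dilute
binodal (late-stage Ostwald ripening at χ = 7) complete in the paper's
regime but not within desk-scale horizons.  Where a signature depends
on such slow coarsening it is exercised in a configuration chosen to
keep the relevant timescale inside the horizon (smaller droplets,
shorter distances, χ with a higher φ₋); this is noted per scenario.

## Known limitations

* No hydrodynamic coupling, no Laplace-pressure correction in the PDE,
  no 3D PDE runs; droplet coalescence happens only by interface contact.
* The staircase wall is first-order accurate; condensate centroids can
  pin to the lattice when drift forces are small (droplets ≲ 4 nodes of
  radius are most affected).  Wall normals are exact (analytic), but the
  contact-angle condition is imposed on axis-aligned faces.
* At χ ≥ 7 interfaces are ~3 cells wide at the default spacing, with a
  few-percent overshoot of φ_s + φ_ns at interface cells.
* The dense binodal at χ = 7 is ≈ 0.999: solvent in the dense phase is
  nearly expelled, so the logarithmic terms are stiff; the default time
  step reflects this.
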