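# pyresim

Active phase-separation modelling of pyrenoid condensate regulation by
EPYC1 phosphorylation.

The pyrenoid of *Chlamydomonas reinhardtii* is a biomolecular condensate
that concentrates Rubisco for CO₂ fixation.  Its scaffold, the
multivalent linker protein EPYC1, is "sticky" when unphosphorylated and
"non-sticky" when phosphorylated by a condensate-localized kinase
(KEY1).  `pyresim` implements a continuum model of this system for
researchers studying active (reaction-controlled) condensates: a ternary
Flory–Huggins mixture with reactive Cahn–Hilliard dynamics,

    ∂t φ_s  = D̃ ∇·(φ_s ∇μ̃_s)  − k̃ φ_s + φ_ns
    ∂t φ_ns = D̃ ∇·(φ_ns ∇μ̃_ns) + k̃ φ_s − φ_ns
    μ̃_s  = ln(φ_s/φ_sol) − 2χφ_s − κ̃_s∇²φ_s − ∇²φ_ns
    μ̃_ns = ln(φ_ns/φ_sol) − ∇²φ_s − κ̃_ns∇²φ_ns

where k̃ is the kinase/phosphatase activity ratio and χ the sticky
self-attraction.  Around this core the package provides:

* **`pyresim.stability`** — linear stability of the uniform state:
  dispersion relation ω̃(q̃) and the arrested-coarsening classification
  (negative curvature at q̃ = 0 with a growing finite-q̃ band);
* **`pyresim.solver`** — mass-conserving spectral (periodic square) and
  masked finite-volume (chloroplast cup with anti-wetting no-flux walls,
  contact angle 5π/6) integrators with time-dependent kinase schedules;
* **`pyresim.droplet`** — the sharp-interface theory of a single active
  droplet: quasi-steady profiles, the kinematic radius equation, the
  equilibrium radius, and the critical switching ratio
  k̃_c ≃ (φ₊+φ₋)/(2−φ₊−φ₋);
* **`pyresim.quantify`** — condensate segmentation and metrics (count,
  condensed volume fraction, largest-condensate fraction, centroids,
  photobleach correction) for simulation fields and 3D two-channel
  stacks;
* **`pyresim.scenarios`** — ready-made simulation scenarios for
  kinase-controlled size control, self-centring, inter-condensate
  repulsion, ectopic-cluster dissolution and the division-cycle
  dissolution/re-condensation sequence, plus a generator of synthetic
  confocal stacks with exact ground truth.

## Worked example

Classify the phase behaviour at the default parameters
(φ_tot = 0.1, χ = 7, κ̃_s = 5, κ̃_ns = 1, D̃ = 10) as the kinase dial
k̃ turns:

```python
from pyresim import ModelParams, classify_coarsening

for k in (0.0, 0.14, 1.0):
    cls, diag = classify_coarsening(ModelParams(k_tilde=k))
    print(f"k~={k:4}: {cls:18s} omega_max={diag['omega_max']:.4f} "
          f"lambda_max={diag['lambda_max']:.1f}")
```

prints

```
k~= 0.0: coarsening         omega_max=0.4173 lambda_max=11.7
k~=0.14: arrested_candidate omega_max=0.0022 lambda_max=19.7
k~= 1.0: stable_uniform     omega_max=-0.0000 lambda_max=1697007643.5
```

— without kinase the mixture demixes and ripens without bound; at
intermediate activity long-wavelength modes are suppressed (many small
condensates of a preferred size, wavelength ≈ 20 ℓ_κ); at high activity
the condensed phase dissolves entirely (no unstable mode, so the
reported "wavelength" is the numerical infinity at q̃ → 0).  The same
prediction from the droplet theory:

```python
from pyresim import DropletParams, critical_k, equilibrium_radius

print(critical_k(0.9, 0.01))                                  # 0.8349...
print(equilibrium_radius(DropletParams(0.9, 0.01, 0.1)))      # 0.6997...
```

i.e. for binodal values φ₊ = 0.9, φ₋ = 0.01 a stable droplet radius
exists below k̃_c ≈ 0.83 (droplet convention k̃ = k_ns→s/k_s→ns), and at
k̃ = 0.1 the preferred radius is ≈ 0.70 ℓ.  Run a full scenario from the
shell:

```sh
pyresim simulate size_control_pair --seed 1 --out out/
```

which writes the trajectory (HDF5), per-frame metrics (CSV) and a JSON
report; the report's `ratio` field is the final radius ratio of the two
initially unequal condensates (≈ 1.004: active size control has
equalized them).

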