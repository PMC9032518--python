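# Methods

## Model overview

`atrophysim` simulates the shape changes of an aging brain as the coupling of
two processes on a labeled simplicial mesh:

1. **Biomarker spreading.** A normalized misfolded-protein concentration
   `c(x, t) ∈ [0, 1]` obeys the Fisher–Kolmogorov reaction–diffusion
   equation `∂c/∂t = d Δc + α c (1 − c)` with region-wise diffusivity `d`
   (mm²/yr) and logistic growth rate `α` (1/yr), zero-flux exterior
   boundary, and `d = 0` in fluid regions (ventricles, CSF), which therefore
   exchange no diffusive flux. `α` can equivalently be derived from a
   two-species production/clearance/conversion kinetic model via
   `α = k12 k0 / k1 − k̃1` (`kinetic_alpha`).

2. **Morphoelastic shrinking.** Tissue loses volume through the
   multiplicative split `F = F^e F^a`, `F^a = ϑ^{1/dim} I`, where the atrophy
   factor `ϑ ∈ (0, 1]` is the fraction of local tissue measure retained
   (`ϑ = J^a`). Only the elastic part stores energy
   (compressible neo-Hookean, `Ψ0 = ϑ Ψ(F^e)`), so a uniformly shrunken body
   is stress-free. `ϑ` decays at the gated rate
   `−ϑ̇ = G_h + G_c · H(c − c_crit)` — a constant healthy rate `G_h`
   accelerated by `G_c` once the biomarker crosses `c_crit` — with `H` a
   sigmoid of sharpness `β`. Quasistatic equilibrium `Div P = 0` is solved
   with zero displacement on the outer CSF surface (skull proxy).

Two simulation modes share the machinery: **healthy** (no concentration
problem, gate ≡ 0, linear decay `ϑ(t) = 1 − G_h t`) and **AD** (biomarker
seeded at `c0 = 0.3` in the hippocampus drives the accelerated term).

## Parameters

Region table (kPa for Lamé constants, 1/yr for rates; defaults in
`default_material_table()` and the packaged YAML config):

| region      | λ     | μ     | G_h    | G_c    | c_crit | d  | α    |
|-------------|-------|-------|--------|--------|--------|----|------|
| white matter| 64.67 | 2     | 0.0015 | 0.0035 | 0.5    | 15 | 0.09 |
| gray matter | 32.33 | 1     | 0.001  | 0.002  | 0.5    | 15 | 0.09 |
| hippocampus | 32.33 | 1     | 0.001  | 0.002  | 0.5    | 15 | 0.09 |
| ventricles  | 29.77 | 15.34 | —      | —      | —      | 0  | 0.09 |
| CSF         | 7.22  | 14.43 | —      | —      | —      | 0  | 0.09 |

Units: the diffusivity is read as mm²/yr and the growth rate as 1/yr, giving
an asymptotic front speed `2√(dα) = 2.32` mm/yr; together with 40-year
simulated age spans these are the only readings that make the transport
problem dimensionally coherent at organ scale. `β = 50` (transition width
≈ 0.1 in c) keeps the gate smooth enough for Newton while staying close to a
step; it is configurable. The atrophy factor is floored at 0.5 (logged
clamp) to keep `det F^a` away from zero — never active at the table rates
over 40 years (maximum possible loss 0.2).

### Stress expression

The first Piola–Kirchhoff stress is taken as the exact work conjugate of
the stored energy,
`P = ∂Ψ0/∂F = ϑ^{1−2/dim} μ F + ϑ (λ ln J^e − μ) F^{−T}`,
i.e. the commonly printed shorthand `P = J^a ∂Ψ/∂F^e` completed by the
chain-rule factor `∂F^e/∂F = ϑ^{−1/dim}` and with the inverse-transpose in
the volumetric term. Work conjugacy is enforced by a finite-difference test
(1e3 random states, relative error < 1e-6), which makes the choice
self-verifying. The spatial (Jaumann) tangent used for post-processing is
derived in closed form, `C : d = [ϑ λ tr(d) I + ϑ μ (d b^e + b^e d)]/J`, and
checked against finite differences of the Kirchhoff stress.

### 2D convention

The default phantom is a plane-strain coronal-slice analog with
`F^a = ϑ^{1/2} I₂`, so `det F^a = ϑ` in-plane and ϑ measures the fraction of
*area* retained; the 3D code path (extruded phantoms, tetrahedra) uses
`ϑ^{1/3}` so ϑ is the volume fraction. This keeps "ϑ = fraction of measure
retained" meaningful in both dimensions; closed forms such as
`ϑ_WM(40 yr) = 0.94` hold identically.

## Numerics

* **Space.** P1 simplices, single quadrature point per element; ϑ is stored
  per quadrature point as a state variable and updated from the element-mean
  nodal concentration.
* **Concentration.** Backward Euler with a full Newton solve of the logistic
  term and a row-sum lumped mass matrix. Against the scalar logistic the
  scheme is accurate to 3.5e-5 at dt = 0.01 yr over 40 yr. Nodal values are
  clipped to [0, 1] as a safety net; clipped mass above 1e-6 triggers a
  warning (it indicates too coarse a dt). On Delaunay meshes the lumped
  scheme is monotone, so clipping is normally inactive.
* **Equilibrium.** Full Newton with the analytic first elasticity tensor,
  backtracking line search, and automatic bisection of the ϑ increment on
  divergence. Convergence: residual below 1e-9 (absolute, kPa·mm units) or a
  1e-10 relative drop.
* **Coupling.** One-way staggered per increment (concentration → ϑ →
  mechanics); deformation does not feed back into diffusion, which is solved
  on the reference configuration. Because of the one-way structure,
  equilibrium is solved only at recording times (`output_every` steps);
  intermediate steps advance the concentration and ϑ only. The default
  study cadence is dt = 0.1 yr with mechanics every 0.5–1 yr; the test suite
  uses dt = 0.25 yr with 4-yr recording, which leaves the atrophy closed
  forms exact and changes the final displacement field by well under 1%.
* **Front-speed verification.** Pulled Fisher–Kolmogorov fronts converge to
  `2√(dα)` only like `v(t) ≈ v* − 3/(2λt)`, `λ = √(α/d)` (the slow
  logarithmic transient of pulled fronts), so the travelling-wave check uses
  a 400 mm bar and fits the front trajectory over t ∈ [120, 180] yr, where
  the residual transient is ≈ 3%.

## The phantom

The built-in generator replaces subject-specific imaging-derived meshes with
a parametric, mirror-symmetric 2D slice (optionally extruded to 3D):

* a white-matter core bounded by `r(φ) = R₀ + A cos(n φ)` (n sinusoidal
  folds standing in for gyri);
* a gray-matter ribbon of exactly constant thickness (default 3 mm),
  produced by a normal offset of the WM boundary — mirroring the
  "inflate WM by a constant thickness" construction — with feasibility
  checks that reject self-intersecting pial surfaces and inter-gyral gaps
  below `fold_gap`;
* a solid ultra-stiff-by-default ventricle (elliptical cavity meshed as a
  labeled subdomain, since the material table assigns it moduli) and a
  hippocampal disk placed adjacent to the ventricle (temporal-horn analog;
  its in-slice radius of 7 mm matches the hippocampus:WM proportions of
  segmented adult meshes);
* a CSF layer out to a smooth outer circle at `csf_thickness` (default 5 mm)
  above the gyral crests; the outer circle carries the zero-displacement
  anchor, and the inter-gyral fluid is partitioned into five named sulcal
  pockets by nearest-valley assignment so sulcal widening can be summed per
  sulcus.

Meshing: all five interfaces are sampled at ≈ 0.85 × the target edge length
(2.0–2.3 mm band by default), combined with a jittered hexagonal interior
lattice, and triangulated with a single Delaunay pass over the convex outer
disk — so the mesh is conforming by construction and element labels are
assigned by centroid containment in the exact interface polygons. A lattice
row lies exactly on the symmetry axis and all other points come in mirror
pairs with symmetric jitter, which makes the *connectivity* mirror-symmetric
(any element quad straddling the axis would otherwise have no
symmetry-preserving diagonal). Fixed seed ⇒ bit-identical meshes.

### What the phantom does and does not emulate

It reproduces the topology the measurements need (folded cortical ribbon of
constant thickness, ventricle + adjacent hippocampus, anchored fluid layer,
per-sulcus pockets) and the study's material/kinetic parameters. It does
not reproduce imaging-derived geometry: fold depth/width statistics, a
3D hippocampus, deep gray structures, or the 10⁶-element resolution.
Passing tests therefore validate mechanisms and orderings (cavity expansion
under anchored shrinkage, sulcal widening, healthy-vs-disease divergence),
not subject-specific magnitudes such as absolute displacement maxima,
volume-fraction trajectories, GI level, or thickness ranges.

## Known limitations and honest negative results

* **Disease-mode atrophy depth.** With `c0 = 0.3`, `α = 0.09`/yr and
  `c_crit = 0.5`, the comparison principle bounds every point by the scalar
  logistic, so the earliest possible gate crossing is `ln(7/3)/0.09 ≈ 9.4`
  yr and the minimum reachable atrophy factor over 40 yr is ≥ 0.833 for any
  geometry — and a localized seed smaller than the diffusion length
  `√(d/α) ≈ 12.9` mm first *dilutes*. On the default phantom the maximum
  concentration after 40 yr is ≈ 0.36, the gate stays essentially closed,
  and the minimum atrophy factor is ≈ 0.94. Published values near 0.80
  would require an immediately saturated gate and are not reachable under
  these parameters; the acceptance suite reports the computed value rather
  than asserting an unreachable one.
* **Fluid stiffness trade-off.** With the table-literal fluid moduli
  (CSF stiffer than gray matter) the anchored fluid shell produces
  ventricular enlargement, tissue-volume orderings and sulcal widening, but
  holds the cortex, so the mean thickness rises slightly and the
  gyrification index *increases* by ≈ 0.8% over 40 yr (sulcal widening
  raises the contour/hull ratio on a sinusoidal phantom). The alternative
  `ultrasoft_csf_table()` preset (fluid μ ≪ μ_GM) yields cortical thinning
  and near-free shrinkage, under which the ventricular cavity *contracts*.
  Neither regime reproduces every observed trend at once on this geometry;
  the default remains the literal table, and both presets are exposed.
* **GI response.** Near-similarity shrinkage conserves the gyrification
  index to first order; decreases seen on imaging-derived meshes come from
  skull-anchored unfolding of deep, narrow folds that the sinusoidal
  phantom does not possess.
* No anisotropic (fiber-based) transport, no two-species protein models, no
  contact between gyri (the fold gap is sized to avoid it; a warning-level
  self-intersection check exists), no viscoelasticity or fluid flow.

## Design choices where the design was open

* Zero-flux (not zero-concentration) condition on the outer boundary: the
  skull is impermeable to the biomarker on these time scales.
* Fluid regions keep the reaction term with the tabulated α but start at
  zero concentration, so they stay at zero identically.
* Volume fractions are computed under both denominators ("brain" =
  WM+GM+hippocampus+ventricles; "intracranial" = everything) and optionally
  against a fixed reference configuration; published fraction trajectories
  are mutually consistent only under the fixed-denominator reading, so the
  report emits both, explicitly labeled.
* The slice count of the 3D gyrification profile defaults to 160 (1 mm
  spacing at organ scale) and is a parameter; the 2D phantom is measured on
  its exact polygon without rasterization, while 3D slices are rasterized
  at 0.5 mm pixels.
* Cortical thickness uses the bidirectional nearest-node rule
  `t_c = (d_ij + d_jk)/2` with KD-trees; an O(n²) brute-force twin lives in
  the tests as the oracle.
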