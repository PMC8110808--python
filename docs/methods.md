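# Methods

`woundfield` implements the quantitative chain linking wound tissue
stiffness to hair-placode pattern formation in healing skin wounds:
AFM force-curve analysis, spatial stiffness maps with the 5–15 kPa
morphogenetic band, and a stiffness-coupled Turing model of placode
patterning, all exercised on synthetic data whose generators encode the
measured wound regimes.

## Hertz indentation model (`woundfield.hertz`)

A spherical probe of radius R indenting an elastic half-space obeys

    F(h) = E / (1 − ν²) · (4 √R / 3) · h^{3/2},

with h the indentation beyond the contact point, E the Young's modulus
and ν the Poisson ratio (0.5 for incompressible soft tissue; the glass
bead gives R = 2.5 µm by default). The tip is treated as rigid relative
to the sample.

Fitting estimates (E, h₀) from a measured force–indentation curve by
least squares on F = k·(h − h₀)^{3/2}. For a fixed contact point h₀ the
prefactor k is a linear subproblem solved in closed form, so the fit
reduces to a 1-D search over h₀: a 60-point coarse grid (robust against
the shallow residual landscape of the 3/2-power law) followed by bounded
scalar refinement with a tolerance scaled to the bracket width (an
absolute tolerance would be meaningless at nanometre scales). The
median pre-contact force is subtracted as baseline, and only points at
or below the 5 nN acquisition trigger enter the fit window. Degenerate
curves (flat, or force falling with depth) raise `NoContactError`;
optimizer failure returns `converged=False` rather than raising.
Everything internal is SI; kPa appears only in reporting.

Noiseless round-trips recover E to ~1e-9 relative error; with 5%
multiplicative force noise the mean of 100 fits stays within 1% of
truth (the acceptance suite requires 0.1% and 3% respectively).

## Stiffness maps and the competence band (`woundfield.stiffness_map`)

Sparse stiffness samples (x, y in mm; kPa) are interpolated
piecewise-linearly on their Delaunay triangulation
(`LinearNDInterpolator`), the same family of interpolants as the
spreadsheet-style `griddata` workflows used for wound heatmaps; linear
was chosen over cubic because it is exactly reproducible, monotone on
each simplex, and exact for affine fields (tested). Pixels outside the
convex hull are masked invalid rather than extrapolated; image-editor
contour tracing is replaced by direct pixel counting for determinism.

Area metrics are pixel counts times pixel area (default 0.02 mm for a
~10 mm field, giving area errors well below the 0.1 mm² differences the
analyses care about): `area_below` uses a strict `< threshold`
("under 15 kPa"); `competence_band_area` a closed interval
(default [5, 15] kPa, the placode competence window). The three regions
below / in band / above partition the valid area exactly. Soft area
relates to follicle yield by ordinary least squares; a flat response is
reported as slope 0 with R² = 0 by convention.

## The stiffness-coupled Turing model (`woundfield.turing`)

Three fields on the square [−50, 50]² with zero-flux boundaries:

    ∂u/∂t = ∇²u + α − u + u²v
    ∂v/∂t = D_v ∇²v + E − u²v
    ∂E/∂t = D_E ∇²E + s·S(x, y) − E,   S = exp(−(x/σ)² − (y/σ)²)

Schnakenberg kinetics between activator u and inhibitor v, with the
inhibitor source carried by a diffusible stiffness measure E produced by
soft tissue (Gaussian source of width σ = 20, strength s). Pointwise, E
plays the role of the constant inhibitor source b of classical
Schnakenberg kinetics.

**Linear stability.** For uniform b the steady state is
u\* = α + b, v\* = b/u\*². `dispersion` returns the larger real
eigenvalue part of J − diag(k², D_v k²) in closed form (cross-checked
against dense numerical eigenvalues); `turing_window` brackets the b
interval with a stable k = 0 mode but positive growth at some k > 0,
refining the edges by bisection. For the shipped (α = 0.05, D_v = 40)
the window is b ∈ (0.896, 2.481). The lower edge is bound by k = 0
(Hopf) stability, the upper edge by the Turing marginal condition — the
tests check each endpoint against its own binding condition. With
equal diffusion (D_v = 1) no window exists.

**Numerics.** Cell-centered grid; diffusion (and the decay of E) is
integrated implicitly, diagonalised by the type-II discrete cosine
transform, which realises ghost-node reflection Neumann conditions
exactly — the discrete integral of E balances its source to rounding.
The reaction terms advance by adaptive substepping in which v relaxes
exactly toward E/u² at frozen u (an exponential update that is
unconditionally positive) and u takes forward-Euler steps; the substep
count tracks the stiffest local linearised rate, so the violent spike
transients of small-α Schnakenberg kinetics cannot blow up. With
non-negative starts all fields stay non-negative. An explicit 5-point
scheme with the classical bound dt ≤ Δx²·0.9/(4·max(1, D_v, D_E)) is
kept for cross-checks; the two integrators agree to first order in dt
(tested by step-halving). Steady state is declared when the max
pointwise rate falls below `steady_tol` (1e-6 by default), checked
every 500 steps.

**Defaults and calibration.** The source papers of such models rarely
print kinetic constants, and none were available here; defaults were
fixed by a calibration procedure, before any acceptance measurement was
frozen, to satisfy three structural requirements: (i) a non-empty
Turing window; (ii) at s = 2 the steady central E sits mid-window and
spot peaks exceed the placode threshold u > 3.8; (iii) by s ≥ 6 the
central E exceeds the window top ("too soft"), extinguishing central
spots while an in-window annulus survives peripherally. The shipped set
is α = 0.05, D_v = 40, D_E = 20, n_grid = 128, dt = 0.05, t_end = 500,
ICs uniform in [0.5, 1.5], threshold 3.8 (config-exposed, since its
meaning depends on the kinetics). Smaller D_v (20–30) was rejected
because in-window spot peaks then stay below 3.8; larger D_E smears E
so much that the centre never leaves the window within s ≤ 10.
The steady E for the Gaussian source is solved directly in the DCT
basis, giving a centre value of 0.852·s at D_E = 20.

**Time-step convergence.** Near the window edges the dynamics are
sensitive to dt: at dt = 0.05 spike amplitudes are inflated (u_max ~50
vs ~5 at dt = 0.0125) and spikes can spuriously persist just above
b_max. Halving studies (dt 0.05 → 0.0125, grid 128 → 256) showed the
converged solution decays there, so stability-concordance experiments
run at dt = 0.0125, while pattern-regime runs (spot counting, demos)
keep dt = 0.05, where the qualitative regime is unchanged.

**What agreement with linear theory means here.** Schnakenberg kinetics
in the spike regime are subcritical: finite-amplitude spike branches
extend somewhat beyond the linear window, and below b_min a band of
k = 0 (Hopf) instability can feed spike nucleation. Sweeping 12 uniform
b values across [0.5·b_min, 1.5·b_max] from the standard [0.5, 1.5]
starts, simulation and linear prediction agree on 11/12 points; the one
disagreement is the first point below b_min, where excitability
genuinely sustains patterns. `pattern_present` labels a state patterned
when its relative amplitude exceeds 0.5 and at least five components
rise above the spatial median by min(4 robust SD, 30% of the
median-to-max range) — thresholds chosen to separate tall sparse
spikes, smooth near-marginal patterns, homogeneous states and
synchronised oscillations, not tied to the absolute placode threshold.

**Stiffness-driven simulations.** `simulate_from_measured_stiffness`
rescales an interpolated stiffness map onto the domain (nearest-valid
fill outside the hull) and replaces s·S with a monotone-decreasing map
from stiffness to E-source: rate (15 − K)/3 kPa⁻¹, clipped at 0 and
capped at 3.5. The linear form with zero at 15 kPa encodes the
assumption that tissue stiffer than the competence ceiling produces no
E; the slope places the measured lab-wound centre (10.5 kPa) mid-window
and sub-5 kPa spiny centres above it; the cap keeps the "too-soft"
homogeneous state u ≈ α + E below the 3.8 threshold so over-soft tissue
reads as placode-free rather than as one giant super-threshold region.
This map is a modeling choice — the underlying biology supplies only
the verbal assumption "softer tissue produces more E".

## Spot detection and topology (`woundfield.patterns`)

Spots are connected components of u > 3.8 (strict, per the model's
threshold), 4-connectivity by default (conservative splitting of
near-touching peaks; 8 by flag), centroids area-weighted in domain
coordinates. `detect_spots` itself keeps every component
(`min_area=1`) so it matches a brute-force flood fill exactly; the
pipeline passes `min_area=2` to suppress single-pixel noise.

`classify_topology` compares spot density inside the central disk of
radius σ (the soft-source width) against the rest of the domain:
fewer than 3 spots → `none`; densest annulus interior with both edge
annuli below 25% of it → `ring`; density ratio above 2 →
`center_competent`; below 1/2 → `periphery_competent`; else `uniform`.
The ring test runs before the ratio test because a concentric ring also
depletes the centre. The 2× and 25% cutoffs are reporting conventions,
configurable and documented as such.

A caveat for spot counts at large s: where the tissue is far too soft
(E > 3.75) the homogeneous state itself exceeds u = 3.8, so
thresholding yields one large central component. Central counts
therefore bottom out at 1, not 0, in the strongest-source panels.

## Synthetic data (`woundfield.synthetic`)

Force curves: exact Hertz shape with contact offset, optional additive
(N) and multiplicative (fractional) Gaussian force noise;
`CurveGenConfig.for_max_force` sizes the ramp to end near the 5 nN
trigger as in acquisition. Landscapes: smooth radial fields built from
a cosine smoothstep between centre and margin stiffness over a
transition width; presets encode laboratory PWD14 (10.5 kPa centre,
28 kPa margin), its stiffer PWD21 and Blebbistatin-softened variants
(qualitative values), spiny-mouse wounds (uniformly soft: centre 3 kPa,
margin 12 kPa at PWD14), a stiff field with a soft Gaussian annulus
("ring"), and a uniform control. Sampling mimics an AFM traverse: a
7-station cross transect to 1.4× the wound halfwidth plus a 12-point
margin ring, with Gaussian kPa noise floored at 0.1 kPa. Follicle
datasets draw counts from slope·area + intercept (default slope 12.812
follicles/mm², the control-group value; 1.6828 available for the
perturbed groups) with Gaussian noise, floored at zero and rounded —
except noiseless tables, which stay exactly on the line so the
generating model is recoverable to machine precision.

What the generators deliberately omit: cantilever dynamics, adhesion
and viscoelastic creep in curves; anisotropy, scar texture and
measurement dropout in landscapes; any nonlinearity in the
area–follicle relation. Passing tests therefore demonstrate the
correctness and internal consistency of the analysis chain under the
stated generative models, not its robustness to every artifact of live
AFM data.

## Pipeline and determinism (`woundfield.pipeline`, CLI `woundfield`)

`run_scenario` chains landscape → force curves/fits → heatmap and band
areas → area–count regression → stiffness-driven simulation → spot
detection and topology, persisting each artifact (CSV/JSON, with
config+seed sidecars) and a JSON + text report. All stage seeds derive
from one master seed via `SeedSequence`, so reruns are bit-identical;
the config hash is recorded in the report. Demo scenarios (`lab`,
`spiny`, `bleb`, `ring`) run in well under a minute each at the default
128² grid.

## Known limitations

- The kinetic constants are calibrated, not measured; absolute spot
  counts are therefore not comparable to any in vivo count, only the
  regime structure (central loss with increasing softness, peripheral
  persistence, ring competence) is meaningful.
- Subcriticality makes the pattern/no-pattern boundary fuzzy within
  ~15% of the window edges; statements tied to the linear window carry
  that caveat.
- Linear interpolation of a 4-arm transect renders circular stiffness
  contours as polygons; band areas from sparse sampling are accordingly
  approximate (the tests bound this geometrically).
- The stiffness→source map is a flagged modeling assumption; measured
  stiffness enters the model only through it.
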