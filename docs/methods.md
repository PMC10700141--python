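# Methods

This note documents the models implemented in `physiodiv`, the parameter
and design choices that were genuinely open, and what the synthetic-world
tests do and do not demonstrate about real reconstructions.

## Domain and discretization

The simulation domain is the node set of a subdivided icosahedron projected
onto a sphere of radius 6.371×10⁶ m. Each node owns a spherical-Voronoi
dual cell (areas from `scipy.spatial.SphericalVoronoi`; they partition the
sphere to machine precision). The working resolution is subdivision level 6
— 40,962 nodes, mean node spacing ≈ 1.08° (≈ 120 km) — a deliberate
desk-scale analogue of production runs at kilometre-scale resolution; every
operator takes the mesh as an argument and is resolution-independent, so
levels 3–5 are used freely in tests. A memory guard refuses meshes beyond
3×10⁶ nodes.

Lat-lon rasters are exchanged with the mesh by bilinear interpolation
(raster→mesh, periodic in longitude, clamped at the polar rows) and
inverse-distance weighting from the k = 3 nearest nodes (mesh→raster).
Bilinear/IDW is a pragmatic choice, not a claim about what any production
pipeline uses. Round-trip accuracy is first- to second-order in the grid
spacing; the convergence test refines raster and mesh together because the
mesh→raster leg's error is fixed by the mesh, not the raster.

## Surface evolution

Elevation obeys

∂z/∂t = U + κ∇²z − ε P^d (PA)^m (∇z)^n

with defaults κ = 0.5 m² yr⁻¹, ε = 4.0×10⁻⁷ yr⁻¹, m = 0.5, n = 1,
d = 0.42; P is local runoff (m yr⁻¹, precipitation minus
evapotranspiration clamped at zero) and PA the upstream-accumulated water
flux (m³ yr⁻¹).

**Flow routing.** Every land node routes to all strictly lower neighbors
with weights ∝ (downslope gradient)^p, p = 1 by default. Flat regions
(which arise when depressions fill to a horizontal lake surface) are routed
by breadth-first distance to the flat's outlets, with routing across flats
only toward equal-or-lower nodes — this guarantees an acyclic receiver
graph (a tolerance-equal but slightly higher neighbor could otherwise close
a two-cycle with its own strict-descent receiver). Remaining nodes without
receivers are pits, a legal state. PA solves (I − Wᵀ)q = P·A with a sparse
LU factorization; the factor is cached on the flow solution and reused for
sediment routing and for subsequent steps while the flow is held fixed.
The solve is checked against an explicit topological-order accumulation
oracle in the tests (agreement ≲ 10⁻¹⁵ relative).

**Basins.** Each node is labeled by the terminal of its steepest-descent
path; all paths reaching the ocean share one ocean label, and each interior
pit above sea level defines an endorheic basin. The basin sill is the
minimum over boundary edges of max(z_i, z_j), computed vectorized over the
edge list; the node across the sill is kept for overflow routing.

**Erosion and deposition.** At n = 1 the stream-power term is integrated
implicitly: M z⁺ = z with M = I + Δt·diag(K)(I − W_rec), K = εP^d(PA)^m —
one sparse solve per step, unconditionally stable, and monotone (no node
undercuts its receivers). For n ≠ 1 an explicit, drop-clamped fallback is
provided. Erosion is detachment-limited: eroded volume is routed down the
receiver graph (same LU as the water solve) and deposits only in
depressions. Each endorheic basin fills lake-style — a horizontal surface
rising from the pit, capped at the sill; overflow crosses the sill and is
handed to the next basin (processed in ascending sill order, skipping
through already-full basins; a closed loop of full basins exports through
its lowest outward pass). Sediment reaching ocean nodes leaves the domain.
Every step the volume ledger erosion = ocean + endorheic must close to
10⁻⁶ relative; a violation raises immediately, because with a direct
sparse solve any imbalance is a logic bug, not round-off.

**Hillslope diffusion** uses a symmetric finite-volume Laplacian with edge
conductances κ(a_i + a_j)/(3 L_ij²), exact for regular hexagonal cells and
exactly volume-conserving for any field by antisymmetry of the edge fluxes.
It is stepped explicitly with a CFL guard (the stability limit at study
parameters is ~10¹⁰ yr, so the guard only matters in stress tests). A
zonal Gaussian ridge test against the 1-D heat kernel shows < 2% L2 error.

**Time stepping.** Default Δt = 5,000 yr with flow re-routed every step.
The hypsometry suite and acceptance script use Δt = 10,000 yr with flow
recomputed every 5 steps — at level-6 resolution the 2-Myr unforced runs
are insensitive to this (halving Δt changes equilibrium ocean flux by
< 2%), and it keeps the 20-world suite at ~2–3 minutes on one CPU.

**Calibration.** `calibrate` fits ε so the area-weighted mean land erosion
rate on a prescribed (modern) surface matches a target — 63 m Myr⁻¹ by
default usage — by scalar root bracketing on ε ∈ [10⁻⁹, 10⁻⁴] (the rate is
linear in ε at any n). Mass fluxes convert at 2.7 g cm⁻³ (1 km³ yr⁻¹ =
2.7 Gt yr⁻¹). On coarse meshes the fitted ε falls below the full-resolution
default because per-cell drainage areas, hence (PA)^m, are systematically
larger.

## Assimilation workflow

Each reconstruction epoch is processed independently:

1. **Unforced run**, 2 Myr, U = 0: carves valleys and channels but
   over-erodes the reconstruction.
2. **Correction**: the long-wavelength part of (target − evolved) — the
   equal-weight average of spherical-cap moving means at three nested radii
   (default 2°, 4°, 8°, geometric spacing) — is added back, restoring the
   regional eroded volume while keeping fine carved structure. The retained
   structure is then amplitude-limited: departures from the target beyond 3
   robust standard deviations (1.4826×MAD over land) are clipped. Both
   parts matter — the filter handles high-frequency structure, the clip the
   rare high-amplitude single-cell carvings that would otherwise distort
   the elevation distribution's upper tail. With both, the hypsometric
   curve (100 area quantiles, difference normalized by the target curve's
   range) changes by ≤ 0.45% worst-case over 20 synthetic worlds, against
   a design bound of 0.5%, while typical carved relief (~19 m s.d. on
   land) survives. The windows are a desk-scale choice: at 1.08° spacing
   one cannot reproduce a production setup where sub-degree windows span
   tens of cells.
3. **Tectonic map**: uplift = (target − corrected)/window on land (zero
   over ocean), window = the 2-Myr unforced duration. The map is a
   high-pass of the erosion field by construction.
4. **Forced run** from the corrected surface (not the raw reconstruction,
   so the carved structure persists) with that uplift, until the global
   erosion flux matches the positive-part uplift volume flux within 1%
   (configurable), or a warning flag at max_time. Synthetic worlds, unlike
   near-steady real topographies, may need tens of Myr to converge; the
   per-slice summaries carry the convergence flag.

The hypsometry report compares elevation quantile curves; the alternative
(cumulative-area axis) was rejected because near-vertical CDF segments
(abyssal plains) register metre-level changes as tens of percentage points,
making any bound meaningless.

## Physiography metrics

TPI_i = z_i − mean(z_k) over an annulus neighborhood; the standardized
TPI_S = 100(TPI − mean)/σ (area-weighted, global mean 0, s.d. 100) makes
observation scales comparable. Fine and coarse scales default to 1–3 and
5–10 mesh spacings. Landform classes are equal-frequency (area-weighted
land quantiles, recomputed per slice) with 7 slope, 5 water-flux and 10
TPI_S categories; explicit boundary lists can be supplied when a fixed
published classification is available. P_DIV is the Shannon equitability of
the joint classes within a neighborhood (default radius 5 mesh spacings):
d_SW = −Σ p_k ln p_k over observed joint classes, normalized by ln 3 in
mode `"paper"` (the literal published normalization by the number of
categorical variables — values can then exceed 1, e.g. ln 4/ln 3 ≈ 1.262
for four equally frequent classes, and the tests document this) or by
ln 350 (the joint class count) in mode `"classes"`, which bounds P_DIV to
[0, 1]. P_VAR is the area-weighted interquartile range of P_DIV over land.
S_COV accumulates a per-node deposited column across a slice sequence
(deposition adds, subsequent erosion subtracts, floored at zero); a node
counts as covered above a 1 m threshold, and S_COV is the covered fraction
of land area, starting at zero.

## Sr mass balance

Linear two-endmember mixing with fixed present-day ratios (mantle 0.703,
continental runoff 0.713); inversion Q_M = Q_S(0.713 − r)/(r − 0.703) is
the exact algebraic inverse (round trip < 10⁻¹²) and is monotone
decreasing in the observed ratio. The terrigenous flux is taken
proportional to the modelled net sediment flux to the ocean with unit
constant — the constant cancels in the mass fraction ξ and in ratio
comparisons. Present-day partition r = 0.41/0.59; at those fractions the
forward mixture gives 0.7089, an inference from the stated fractions rather
than a published seawater value.

## Statistics

Series are aligned by linear interpolation onto a target age grid clipped
to the overlap (no extrapolation; dropped ages are counted). Pearson r
uses the t-distribution p-value with n − 2 d.f. The diversity regression
is OLS with intercept on inputs the caller has normalized (min–max to
[0, 1] is the provided helper; the fit itself does not rescale, so
coefficient recovery is exact when the generating scale is inverted);
ANOVA uses sequential (type I) sums of squares, P_VAR before S_COV.
Perfectly collinear predictors are rejected by a rank check.

## Synthetic worlds

Continents are thresholded band-limited spherical-harmonic fields (degrees
2–8, spectrum l^−1.5), the threshold set by area-weighted quantile to the
target land fraction (default 0.3). Orogens are Gaussian-profile ridges
along random great-circle arcs (peak heights 1–5 km, widths 2–3.5°,
half-lengths 10–25°), applied on land. Closed depressions are crater-like:
a rim bump plus a pit whose floor is forced strictly below the lowest
point of its surrounding ring and kept above sea level by a smooth
softplus floor (no artificial flats); centers avoid orogen belts and each
other, so each requested depression yields an endorheic basin. Runoff is a
zonal Hadley-like profile (wet tropics, dry subtropics, wet mid-latitudes,
amplitude ~1.6 m yr⁻¹ peak) plus windward orographic enhancement
(easterlies equatorward of 30°, westerlies poleward; gain 20 m yr⁻¹ per
unit ascent slope) plus weak harmonic noise, clamped non-negative and zero
over the ocean. Successive slices evolve by AR(1) perturbation of the
harmonic coefficients (ρ = 0.99; mean |Δz| between slices < 600 m).
Diversity series follow the linear response intercept + b₁·P_VAR +
b₂·S_COV + N(0, σ), rescaled affinely to a count-like range with the
coefficients and scale recorded in metadata.

What the generator does **not** emulate: plate kinematics and continental
drift, realistic hypsometric detail (shelves, passive margins), sea-level
curves, CO₂-dependent climate states, or any biotic interaction. Passing
tests therefore demonstrate correctness of the operators and the internal
consistency of the pipeline under controlled conditions — not that the
pipeline reproduces Phanerozoic history; that requires the real
reconstruction and fossil inputs.

## Numerical choices and degenerate inputs

- Elevation ties in routing are broken by node index; strict descent plus
  the flat rule above makes the receiver graph provably acyclic.
- Constant elevation: TPI_S is defined as all zeros (with a warning);
  constant classification fields collapse to class 1 (with a warning).
- 0·ln 0 := 0 in the Shannon sum; empty neighborhoods raise.
- Accumulation solves are verified to 10⁻¹⁰ relative residual; ledger
  closure to 10⁻⁶; Sr round trip to 10⁻¹²; TPI_S standardization to 10⁻⁹.
- All randomness flows through explicit `numpy.random.default_rng(seed)`
  arguments; identical seeds give bit-identical outputs.

## Known limitations

- Deposition exists only in closed depressions; no transport-limited
  alluviation, marine deposition, compaction or lithology-dependent
  erodibility.
- Trapped water in endorheic basins is treated as lost (no lake
  evaporation balance); "net sediment flux to the ocean" is erosion minus
  endorheic trapping.
- The forced equilibrium run re-imposes the slice's runoff unchanged while
  elevation evolves.
- Whole-basin overflow chains approximate merged lakes by exporting
  through the lowest outward pass rather than re-flooding.
- At coarse resolution single cells stand in for entire valley systems;
  absolute magnitudes (fluxes, P_DIV levels) are resolution-dependent and
  should be compared across epochs at fixed resolution, not across
  resolutions.
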