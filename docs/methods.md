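# Methods

## The model

`qsense` simulates linearly polarized light reflecting from a turbid slab
and the observable built from it,

    Q' = (I_par - I_perp) / (I_par + I_perp) = Q / I,

the analyzer-normalized Stokes Q of the collected reflectance.  In the
two-component picture the co-polarized channel carries the superficial,
still-polarized reflectance Is plus half of the deep diffuse background
Id, the cross-polarized channel the other half, so Q' = Is/(Is + Id): it
isolates the shallow scattering signal.  Because Is survives at the
centre of the illumination spot, Q' decays with slab thickness to a
nonzero plateau that depends only on the medium's optical properties —
which is what makes a converged Q' reading invertible for the reduced
scattering coefficient mu_s'.

### Transport

Photons are tracked with the meridian-plane Monte Carlo method: each
photon carries a Stokes vector referenced to the plane containing its
direction and the depth axis, together with an explicit orthonormal
transverse frame (e_par, e_perp).  Per event:

1. an exponential free path s = -ln(z)/(mu_a + mu_s) is drawn, with the
   *bulk* mu_s of the suspension — the step never depends on which
   particle size is met;
2. a particle radius is redrawn from the size distribution (polydisperse
   media scatter each event off a different random size);
3. the pair (theta, psi) is rejection-sampled from the polarized phase
   function P(theta, psi) = s11 I + s12 (Q cos 2psi + U sin 2psi), with
   proposals uniform in (cos theta, psi) — the sin(theta) Jacobian lives
   in the proposal measure — and the dominating constant
   1.01 * max(s11 + |s12|) * I, which bounds P for every physical Stokes
   vector since |s12| <= s11 and sqrt(Q^2+U^2) <= I;
4. the Stokes vector is rotated by psi into the scattering plane,
   multiplied by the single-sphere Mueller matrix built from
   (s11, s12, s33, s34) at theta, and rotated into the meridian plane of
   the outgoing direction.  With frame vectors the two rotation angles
   are plain dot products, and the pole degeneracy (|k_z| = 1, meridian
   undefined) has a natural limiting convention: keep the previous
   transverse frame.

After each event the Stokes vector is renormalized to I = 1: the angular
draw already carries the intensity factor, so conditional on the sampled
direction the normalized Stokes state is S/I.  A photon dies when it
leaves the slab, is absorbed (binary draw with probability mu_a/mu_t at
an interaction; a continuous-weight mode with Russian roulette is
available behind a flag), or exceeds the event cap.

Detected photons — top-surface exits inside the collection radius and
acceptance cone — are rotated into the fixed detector frame (analyzer
along lab x, the launch polarization axis) and superposed.  Per-photon
full polarization is preserved exactly through arbitrarily long chains
(measured drift < 1e-13 after 1000 events); depolarization is purely an
ensemble effect of summing rotated Stokes vectors.

### Single scattering

Mie amplitudes S1, S2 are computed with the logarithmic-derivative
downward recurrence and Wiscombe truncation, tabulated on a uniform
1000-point theta grid per radius.  The transport interpolates the
*complex amplitudes* linearly and rebuilds the four scattering elements
from the interpolated Jones pair rather than interpolating the elements
themselves: the accuracy is the same O(h^2), but every per-event Mueller
matrix is then exactly pure (s11^2 = s12^2 + s33^2 + s34^2 to rounding),
so single photons cannot artificially depolarize between grid nodes.
The anisotropy g is computed from the tabulated s11 by Simpson
quadrature; it agrees with the closed-form partial-wave sum to ~1e-10
and moves by < 1e-9 when the grid is doubled.

The single-event algebra (rotation-Mueller-rotation, and the detector
rotation) was verified against an independent lab-frame Jones-calculus
computation, which matches to machine precision angle by angle.

## Media

A medium is (mu_a, mu_s, g, mu_s' = (1-g) mu_s) plus a particle-size
distribution.  Defaults: water host n = 1.33, soybean-oil droplets
n = 1.46, lambda = 632.8 nm, mu_a = 0 (configurable).

* **Size distribution.**  Radii 20-700 nm on a 20 nm grid with
  exponentially decaying number weights (decay length 80 nm), a
  discretized stand-in for the small-droplet-dominated distributions
  measured for lipid emulsions; "size" figures are interpreted as radii
  throughout.  Any two-column (radius_nm, weight) table can replace it.
  A monodisperse mode fixes a single 200 nm radius.
* **Per-event size weighting.**  Number weighting by default; an
  optional cross-section weighting multiplies the weights by each size's
  scattering cross section.  Which convention real emulsions follow is
  genuinely ambiguous, so both are exposed and neither is asserted.
* **Self-consistent anisotropy.**  For a target mu_s' the builder sets
  g to the sampling-weighted mean of the per-size Mie anisotropies —
  exactly the mean single-scattering cosine the transport realizes under
  per-event resampling — and mu_s = mu_s'/(1 - g).  With the default
  distribution g_eff ~= 0.26.  The Intralipid concentration mapping
  (`il_optical_properties`) instead reproduces the published empirical
  fits (g = 1.1 - 0.58 lambda_um; mu_s = 16 c lambda_um^-2.4 per volume
  fraction c of 10% stock) verbatim; the two entry points serve
  different purposes and are documented separately.

## Geometry and detection

Pencil beam at 45 deg from the normal in the x-z meridian, launch Stokes
(1, 1, 0, 0) — "horizontal" is in-plane (p) polarization in this
convention.  The slab is laterally unbounded; boundaries are
index-matched by default, with an optional Fresnel/Snell mode (entry
refraction and specular loss, internal-reflection draws at both
surfaces, real-coefficient polarized Fresnel Mueller factors; total
internal reflection keeps U and V phases, a documented approximation).

The detector collects top-surface exits within 2 mm of the entry point
inside a **30 deg acceptance half-angle** about the normal.  The finite
cone is load-bearing, not cosmetic.  Detected co-polarization depends
strongly on exit obliquity (single-scattered exits near the normal are
almost fully co-polarized; grazing exits are weakly or even negatively
co-polarized).  An open (90 deg) detector therefore sees thin slabs —
which freely leak grazing light — with *depressed* Q', and the
Q'(thickness) curve can invert its expected decay at low mu_s'; a lensed
photodiode above the sample never collects those grazing exits.  The
30 deg default models the lensed instrument; both radius and cone are
configurable.

A genuine consequence of the oblique beam: for *unpolarized*
illumination the detected Q' is not zero at 45 deg incidence
(~ -0.13 for mu_s' = 1.5 at 10 mm) — singly scattered light polarizes
perpendicular to the scattering plane, the skylight effect.  The
no-preferred-axis null is exact only at normal incidence, where the
configuration is rotationally symmetric; the test suite checks it there
(|Q'| < 3 sigma, measured 0.002 +/- 0.007).

## Q-sensing experiments

Each run splits its photons into >= 10 independent batches; standard
errors of Q' and the normalized intensities come from batch-to-batch
variance.  The experiment helpers run one transport per grid cell:
`thickness_sweep` (default test grid {0.6, 1, 2, 5, 10} mm; the full
19-thickness design of 0.6-1.5 mm by 0.1 and 2-10 mm by 1 is provided as
`THICKNESS_GRID_FULL`) and `mus_prime_sweep` over
{0.5, 1, 1.5, 2, 3} mm^-1 at 10 mm.  Tests and the acceptance script use
1e5 photons per cell — trend margins are set by the reported MC errors,
and the kernel covers a 10 mm cell in a few seconds; production runs
scale to 1e7 by the same interface.

## Inversion

`build_calibration` packages the 10 mm sweep into a calibration curve,
refusing curves that are not strictly decreasing beyond MC error and
thicknesses below the convergence threshold (default 10 mm; convergence
is checked empirically by the 10 mm vs 20 mm agreement test rather than
assumed).  The inverse map is a monotone shape-preserving (PCHIP)
interpolant of (Q' -> mu_s').

The reported uncertainty propagates, through the local slope of the
inverse map, three terms added in quadrature:

1. the measurement's standard error,
2. the calibration's local MC error,
3. an a-priori between-knot interpolation error, (h^2/8) |f''| with f''
   estimated from second divided differences of the knots.

Term 3 matters: with knots 0.5 apart the unresolved curvature of
Q'(mu_s') contributes ~0.01 in Q' near mu_s' = 1.25 — larger than the
MC error at 1e5 photons and irreducible by photon budget; checked
against high-budget truth runs, the estimator reproduces that scale.
Intervals are +/- 1.96 combined sigma.  Queries outside the calibrated
Q' range are refused (no extrapolation), and estimates in the flat
regime (|dQ'/dmu_s'| < 0.02 per mm^-1, configurable) carry a
low-confidence flag, since there small Q' noise maps to large mu_s'
excursions.  The curve metadata records that calibration and measurement
must share g and mu_a; a joint (mu_s', g, mu_a) inversion is out of
scope.

## What the synthetic conditions do and do not show

All validation inputs are generated by the package itself under the
study conditions: matched boundaries, zero absorption, a modeled size
distribution, an assumed droplet index, and an idealized
pencil-beam/lens geometry.  Passing tests therefore demonstrate internal
correctness of the polarized transport and the behavior of Q' *within
this model*: they do not calibrate any specific Intralipid batch (whose
size distribution, and hence g_eff, differs from the default in unknown
ways), nor detector-response or polarizer-extinction effects of a real
bench.  The qualitative trends (decay and convergence of Q' with
thickness, inverse ordering and flattening in mu_s', polydisperse vs
monodisperse contrast) are robust to these choices; the absolute Q'
levels are not, which is why mu_s' extraction is calibration-based
rather than absolute.

## Numerical choices and limitations

* theta grid 1000 points; Mie series truncated at the Wiscombe count,
  with explicit failure (never silent truncation) above the term cap.
* Rejection sampler caps proposals (default 1e4) and reports a broken
  envelope as an error; the envelope is provably dominating, including
  between grid nodes (amplitude interpolation cannot exceed nodewise
  bounds, by convexity of |.|^2).
* Event cap 1000 (event-capped photons count as dead and are tallied);
  photon budget, batches, seeds all explicit.  Runs are bit-reproducible
  for a fixed seed; the compiled and interpreted engines share one
  implementation and the same MT19937 stream.
* Circular polarization is tracked but never launched; layered media,
  time resolution, and image-plane Q maps are out of scope.
* The V-component sign convention is internal; only Q is read out, and
  mirror-symmetric conventions give identical Q statistics.
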