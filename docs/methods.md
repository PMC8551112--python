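# Methods

## Scope and model family

`trackevent` implements the computational machinery of nanodosimetric
cell-survival models of the track-event family. The biophysical picture:
a cell is traversed by a Poisson-distributed number of particle tracks;
each track independently produces a nonlethal, sublethal or lethal event
(with per-track probabilities `p0`, `p1`, `p2+`); a cell survives if it
ends up with no lethal event and at most one sublethal event. Sublethal
and lethal events are identified with single and clustered DNA
double-strand breaks (DSBs) in nanometric subcellular targets: basic
interaction volumes (BIVs, spheres of 2–3 nm diameter holding a short
DNA segment, in which an ionization cluster of two or more ionizations
models a DSB) and cluster volumes (CVs, 7.5–18 nm spheres containing
several BIVs, in which two or more lesions constitute a clustered
lesion).

The package covers five layers:

1. **Closed-form survival models** (`trackevent.survival`) — the basic
   form `S = (1 + qD) e^{-(p+q)D}`, its track-probability and RAMN
   (radiation action model based on nanodosimetry) parameterisations,
   the critical-CV variant `(1 + n_t p_SL)^N e^{-N n_t(p_SL+p_CL)}` with
   its large-`N` exponential approximation, and three repair variants.
2. **Count-distribution machinery** (`trackevent.distributions`) —
   exact multinomial conditionals, Poisson mixtures, compound-Poisson
   convolutions, binomial thinning and independence diagnostics.
3. **Fluence geometry** (`trackevent.fluence`) — annulus averaging of
   impact-parameter profiles, track counts per area, conditional lesion
   probabilities.
4. **Lattice scoring** (`trackevent.lattice`) — two-pass Wigner–Seitz
   scoring of ionization clusters in simulated track structures and ROI
   statistics.
5. **Synthetic data** (`trackevent.synthetic`) — seeded generators of
   correlated track-like point clouds, an uncorrelated gas null model
   and parametric impact-parameter profiles.

## Survival models and repair

All survival functions return values in [0, 1] and equal 1 at zero
dose. The three repair variants share the convention that repair acts
on the category counts of the multi-event distribution:

* *Consistent repair*: cells holding exactly one lethal event or
  exactly two sublethal events (and nothing else) are rescued with
  probability `R`, giving
  `S = (1 + qD + R[pD + (qD)^2/2]) e^{-(p+q)D}`. Because repair acts on
  the pooled damage state rather than independently per track, no mixed
  `p·q` terms and no terms quadratic in `R` appear.
* *Four-category repair*: single-track events are split into
  potentially lethal (rate `p'`, repairable) and definitely lethal
  ones; `S = (1 + qD + R[p'D + (qD)^2/2]) e^{-(p+q)D}`, collapsing to
  the consistent form at `p' = p`.
* *Threshold repair*: whenever more than one DSB is present, all damage
  is repaired with probability `R`: `S' = S0 + R(1 - S0)`.

The critical-CV exact form is evaluated as
`exp(N log1p(n_t p_SL) - N n_t (p_SL + p_CL))` so that `N ~ 1e9` does
not overflow; the approximation mode emits a warning when
`N n_t p_SL > 0.5`, where the second-order expansion of the logarithm
becomes dubious. The helper `quadratic_unity_dose(N, q) = sqrt(2N)/q`
locates the dose at which the quadratic correction reaches unity
(≈ 790 Gy for `N = 5e8`, `q = 40 /Gy` — far above any therapeutic
dose, which is why the critical-CV model is effectively a pure
exponential in practice).

## Count distributions

Distributions are finite non-negative mass arrays with an explicit
`tail_mass`; every constructor enforces normalisation to 1 within
1e-9. Poisson supports are truncated where the cumulative weight
reaches `1 - tol` (default 1e-10; the tail is carried, not dropped).
Convolutions in `multi_event_mixture` are exact direct summations
(`scipy.signal.convolve2d`, direct method); no transform shortcuts are
used, so the only error source is the explicit truncation.

Binomial thinning `P*(k1,k2) = sum B(k1|n1,keep1) B(k2|n2,keep2)
P(n1,n2)` is evaluated as a pair of matrix products with binomial
kernels. It implements both repair (`keep = 1 - R`) and the
ionization-cluster to DSB conversion (`keep = p_d`), preserves
independence of the marginals, and maps Poisson marginals to Poisson
marginals with scaled means.

`independence_ratio` masks cells where the product of marginals falls
below a floor (default 1e-6 of the maximum joint mass); the masking
rule is this package's choice, since observed-frequency plots do not
define one. `poisson_reference` defaults to matching the mean of the
zero-truncated distribution (`omit_zero=True`), the convention used
when comparing scored frequency spectra that suppress the empty bin;
both modes are exposed.

## Fluence geometry

Per-annulus integrals of `profile(r) · 2πr dr` use the midpoint rule on
a sub-mesh of ≥ 32 points per annulus; azimuthal symmetry is assumed
(profiles depend on the impact parameter only). The broad-beam fluence
is `φ = D / (S/ρ)` with the mass stopping power in MeV cm²/g converted
internally (2 Gy at 12.45 MeV cm²/g gives 1.0e-5 tracks/nm², i.e.
≈ 772 tracks through a 9.9 µm diameter beam cross-section).

The conditional lesion probabilities for a CV whose chord crosses `n`
BIVs are, with `x = n_t F2`:

* `P_SL = F2 n (1 - x)^(n-1)`,
* `P_CL = P(Binomial(n, x) >= 2) / n_t`.

The binomial-tail formulation is algebraically identical to
`[1 - (1-x)^n]/n_t - P_SL` but numerically stable: the naive difference
cancels catastrophically once `n_t F2` drops below ~1e-7. The
conventional first-order formula `P_CL ≈ n_t n (n-1) F2²` is exposed in
`approx` mode exactly as conventionally printed, but the exact
expansion gives half that value, `(n(n-1)/2) n_t F2²`; the exact mode
is the default and authoritative, and a test pins the factor of two.

`site_multiplicity_probs` offers Poisson (`p1 = μe^{-μ}`) and binomial
alternatives; the binomial needs the number of BIV sites per CV as its
trial count and agrees with Poisson to O(μ/n).

## Lattice scoring

Space is tiled by the Wigner–Seitz cells (rhombic dodecahedra) of a
face-centred cubic lattice whose cell volume matches a sphere of the
target diameter: `a = (2π/3)^{1/3} d ≈ 1.27944 d`. Point-to-cell
assignment uses the exact nearest-site decoder of the D3 (checkerboard)
lattice: round the coordinates in units of `a/2` and, if the index sum
is odd, flip the coordinate with the largest rounding error. The
decoder is exact and O(n); ties (measure-zero) resolve
deterministically through the rounding rule. A KD-tree nearest-
neighbour search serves as an independent oracle in the tests only.

Pass 1 scores ionizations per BIV-sized cell; cells with ≥ 2
ionizations yield an ionization cluster (IC) positioned at the centroid
of its ionizations. Pass 2 scores IC counts per CV-sized cell on an
independent origin-centred lattice (the two passes do not share an
origin; nothing in the procedure requires it). Both lattices are
axis-aligned with the track axis; orientation averaging over the
octahedral fundamental domain would reduce lattice bias but is not
implemented.

ROI tiling: spherical ROIs are centred on the middle of the usable
(trimmed) track length at radial offsets tiling bins of width `R_ROI`
from the axis to `5 R_ROI`, with 8 azimuthal sectors per off-axis bin
(sector counts are a documented choice; the published concept fixes
the geometry but not the counts). Each placement is weighted by its
sector cross-sectional area, which makes the pooled single-event pmf a
deterministic quadrature of the uniform-fluence average; a random-
placement Monte-Carlo oracle confirms convergence in the tests.
Default head/tail trims are 100/50 nm.

The DSB-given-IC conversion assumes each of the `k` ionizations of a
cluster strikes either DNA strand with probability 1/2; summing over
the cumulative size spectrum `F_k = P(size >= k)` gives
`P(DSB|IC) = (1/F2) Σ_{k≥2} F_k / 2^{k-1}`, which lies in [1/2, 1) and
equals the direct strand-assignment enumeration
`Σ_j P_j (1 - 2^{1-j}) / P(size >= 2)` (property-tested). The `F_k`
here are cumulative probabilities — using the pmf instead breaks the
identity.

## Synthetic generators

The track generator is a shape model, not transport physics: primary
ionizations are a Poisson process along the axis; each spawns a
geometric number of secondary branches (memoryless, one parameter);
each branch deposits a Gaussian blob of Poisson-many ionizations at a
radial displacement drawn from an exponential core plus bounded-Pareto
tail (cutoff 500 nm, mirroring the observed penumbra extent of proton
tracks). The expected ionization count is
`L λ (1 + yield · blob mean)`, which the tests verify by Wald's
identity. Two reference parameter sets ship as stand-ins for densely
(low-energy) and sparsely (high-energy) ionizing protons; they are not
calibrated to cross sections, so absolute cluster probabilities are not
comparable to measured nanodosimetric data — only structural findings
(non-Poisson shapes, positive association between single- and
multiple-IC counts, dose-invariant overdispersion) carry over. The gas
null model is a homogeneous Poisson process and reproduces the
closed-form occupied-cell cluster fraction `1 - e^{-μ}(1 + μ)`.

Passing tests on synthetic ensembles therefore demonstrate the
correctness of the scoring and statistics machinery and the direction
of the structural effects, not the absolute values obtained from
condensed-history track-structure simulations of real beams.

## Numerical and design choices

* Poisson truncation tolerance 1e-10 (configurable); distribution
  normalisation asserted to 1e-9; convolution error bounded by the
  truncation tail only.
* Survival evaluation in log space wherever `N` is large.
* Midpoint quadrature with ≥ 32 subdivisions per annulus; refinement
  convergence is property-tested.
* Dose grids for survival curves: inclusive endpoints, uniform spacing.
* Problem sizes in the test suite (1e6-history Monte-Carlo oracles,
  2e6-point volume sampling, ensembles of ~100–300 synthetic tracks or
  gas realisations) were chosen as the smallest sizes at which the
  3-standard-error acceptance bands are meaningful.

## Known limitations

* Uniform (broad-beam) fluence only; position-dependent fluence maps
  and the volume integrals needed for indirectly ionizing radiation are
  out of scope.
* Single lattice orientation (axis-aligned); regular-lattice bias at
  the cell boundaries is not averaged out.
* No fitting of model parameters to experimental survival data, no
  dose-rate/repair kinetics, no chromatin geometry or radical
  chemistry.
* The σ scale factor of the RAMN parameterisation is carried as a
  configuration value; its physical interpretation (geometric cross
  section versus cell-specific effectiveness factor) is left to the
  caller.
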