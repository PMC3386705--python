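# Methods

## Decay model and conventions

All estimators assume an impulse-excited (multi-)exponential decay
`f(t) = Σ_k A_k exp(−t/τ_k) + b` observed on `[0, T)`; the instrument
response is treated as a delta function and no IRF convolution is
performed anywhere.  Amplitudes `A_k` are photon rates at `t = 0`
(photons/ns), lifetimes `τ_k` are in ns, and the background `b` is a
uniform rate on the window — there is no model of afterpulsing, pile-up,
dead time, TDC jitter, or laser-repetition wrap-around.  Time bins are
half-open, zero-based, `[j·h, (j+1)·h)`, so a photon at an edge belongs
to the later bin and photon-to-bin assignment is unambiguous.  The
expected count of bin `j` from one component is `A τ x^j (1 − x)` with
`x = e^{−h/τ}`.

Gate geometry for the two-gate estimators: gate 1 is `[0, h)` and gate 2
is `[S·h, R·h)` with `0 < S ≤ 1 < R`; the gates overlap on `[S·h, h)`
when `S < 1`, and `S = 1, R = 2` is the classical contiguous two-gate
split.  Continuous `S, R` are accepted by the expected-count arithmetic
and by the F-value theory; the integer constraints (`1/S` and `R − S`
integers) are enforced only by the GRLD estimator, whose root equation
needs them.  In `AcquisitionConfig`, `h = T/M` is the gate-1 width and
the gate window is `[0, R·h)` — for gated work one normally constructs
the config with `M = 1, T = h`.

## Estimators: numerical choices

* **GRLD root finding.** `P(x) = x^S (1 − x^{R−S})/(1 − x)` is strictly
  increasing on `(0, 1)` with range `(0, R − S)`, so the gate-ratio
  equation has at most one root.  It is solved by vectorized bisection
  (64 halvings, |Δx| < 1e−16); ratios at or beyond `R − S` are flagged
  invalid.  Bisection was chosen over faster Newton-type schemes because
  the per-pixel call sites are already vectorized and robustness
  dominates.
* **RLD-M.**  The bin coordinates `t_j` entering the log-linear
  least-squares slope are bin *left edges* `j·h`.  Only with left edges
  does the two-bin case reduce algebraically to RLD-2 (`τ = h/ln(N0/N1)`),
  which we treat as the defining consistency requirement; center
  coordinates would shift the intercept only, but the reduction identity
  pins the convention.  Any empty bin invalidates the estimate (log of
  zero) rather than being imputed.
* **IEM.**  Simpson composite weights require an even interval count, so
  the estimator refuses even `M` rather than silently re-weighting; the
  caller rebins.  A constant offset in every bin cancels exactly in the
  `N_0 − N_{M−1}` denominator, which is the source of IEM's background
  tolerance.
* **CMM.**  The centroid uses the half-bin correction
  `τ_cmm = (mean(D) + ½)h` so that a photon population concentrated in
  bin 0 reads `h/2`.  The window-truncation calibration `Ω` inverts
  `g(u) = u − e^{−1/u}/(1 − e^{−1/u})` (`u = τ/T`), tabulated on a
  log-spaced grid of 2048 points over `u ∈ [1e−3, 1e2]` with monotone
  cubic (PCHIP) inversion; round-trip error is < 1e−8 over
  `u ∈ [0.01, 10]`, comfortably inside the stated 1e−3 budget.  `g`
  saturates at ½ (the uniform-distribution limit), so measured centroid
  ratios ≥ ½ are flagged saturated, not extrapolated.  The half-bin
  quantization of the histogram form leaves a residual O((h/τ)²) bias
  that the calibration does not remove; at `M = 256` it is ≲ 0.5%.
* **Binned MLE.**  The count-weighted mean bin index is sufficient for
  the single-exponential multinomial shape, so the MLE is computed by
  bracketed root finding on the monotone mean equation
  `x/(1−x) − M x^M/(1−x^M) = j̄` — machine-precision accurate and free
  of optimizer tolerance artifacts.  Histograms whose centroid is at or
  past the uniform limit `(M−1)/2` have no interior decay solution and
  are flagged invalid.
* **Bi-exponential fit.**  Weighted least squares on a log
  parameterization with *bounded* lifetimes (`[h/10, 10T]`): on sparse
  histograms the slow component of an unbounded fit runs away along a
  near-flat valley.  Multi-start over lifetime spreads; components are
  returned sorted and near-degenerate solutions (`τ2/τ1 < 1.5` or an
  amplitude ratio < 1e−3) are flagged so callers can fall back to a
  single-exponential reading.
* Invalid estimates are returned as flagged values (`valid=False`, NaN
  lifetime) rather than exceptions in all vectorized/image paths, so a
  bad pixel cannot abort a map.

## Photon-economy theory

The figure of merit is `F = √N_c σ_τ/τ` with `N_c` the photon count in
the estimator's own acquisition window (`2h` for RLD-2, `R·h` for the
overlapping gates, `M·h` for binned estimators), background included when
present — F is defined from the measured total, not the decay-only part.

Closed forms:

* RLD-2: `F = (τ/h)(1 + x)/√x = 2 cosh(u/2)/u`, `u = h/τ`.  Its minimum,
  `F = 1.5089` at `u = 2.3994`, is the classical "gate width ≈ 2.4τ"
  operating rule.
* Overlapping gates: `F = (τ/h)·√k(x)/B(x)` with
  `B = (1−S)x^{S+1} + (R−1)x^{R+1} + S x^S − R x^R`,
  `k1 = (1−x)(1−x^R)(x^S−x^R)(1−x+x^S−x^R)` for uncorrelated
  acquisitions and `k2 = k1 − 2(1−x)(1−x^R)(x^S−x)(x^S−x^R)` when both
  gates count one photon stream (the overlap covariance, `Cov(N1,N2) =
  Var(N_ov)`, subtracts).  `k2 ≤ k1` always: correlation can only help.
* RLD-M: `F = [6/(M(M²−1))]·(τ/h)·√((1−x^M)/(1−x)·G(x))` with the
  printed cubic-sum `G`.  The prefactor placement (outside the radical)
  is fixed by exact agreement with the delta-method variance of the
  unweighted log-linear least-squares slope at every `M`, and by the
  identity with RLD-2 at `M = 2` where the prefactor is 1.
* MLE baseline: per-photon Fisher information of the M-bin multinomial
  shape, `F = 1/(τ√I₁)`; it equals the RLD-2 form at `M = 2` (two-bin
  sufficiency) and lower-bounds every estimator above (Cramér–Rao).

Each closed form was cross-validated two ways before being frozen: exact
reduction identities (`f_grld(S=1,R=2) ≡ f_rld_m(M=2) ≡ f_rld2`,
pointwise to 1e−10) and an independent Poisson delta-method derivation,
plus Monte-Carlo agreement (below).

A practical subtlety: the correlated-gate F at `S = 0.2, R = 3.2` is
*bimodal* in `τ/T` — a local minimum of 1.279 near `τ/T = 0.14` and the
global minimum of 1.241 near `τ/T = 0.040`.  Curve minimization therefore
scans a wide log grid before golden-section refinement around the best
grid point; a single bounded 1-D search from arbitrary brackets can land
on the wrong branch.  Setting optimization (e.g. the `R = S + 3` family,
whose best overlap start is `S ≈ 0.50` with min F ≈ 1.184) minimizes the
per-setting global minimum on a grid, then refines.

F-value closed forms for IEM and CMM are not implemented; their photon
economy is characterized only through the Monte-Carlo harness, which
reports both an sd-based F̂ and an RMSE-based variant (the latter folds
in accuracy for biased estimators such as quantization-limited IEM at
small `τ/T`).

## Monte-Carlo harness and photon statistics

Photon arrival times are sampled conditionally on the window — a mixture
of `[0,T)`-truncated exponentials plus a uniform background component
with weights proportional to expected in-window counts — so `N_c` always
means "photons inside the window", consistent with the F definition.
Two total-count laws exist: `fixed` (exactly `N_c` photons; bin/region
counts multinomial) and `poisson`.  The fixed law is the default for
replicate studies.  This is statistically safe because every implemented
histogram estimator and the correlated gate ratio are scale-invariant in
the counts, so conditioning on the total does not change their
asymptotic variance; the theory F derived from independent-Poisson
propagation is reproduced either way.  The *uncorrelated* two-stream
scheme is the exception — its gate ratio is not invariant under
per-stream totals, and fixing them would deflate the variance several
fold — so uncorrelated gate counts are always drawn per-gate Poisson,
matching the physics of two independent snapshots.

`mc_f_estimate` computes `F̂ = √(mean N_c)·sd(τ̂)/τ` over valid
replicates only, reports the invalid fraction (never imputes), and
attaches a bootstrap CI (1.96 × bootstrap sd of the replicate sd, 200
resamples).  The core validation — shipped as tests — checks
RLD-2, UGRLD, CGRLD(0.2/3.2) and RLD-8 at three `τ/T` points each with
`N_c = 1000` and 10⁴ replicates against the closed forms within 3 CI
half-widths.  The RLD-8 points are kept at `τ/T ≤ 0.7`: at `τ/T ≳ 1`
with 10³ photons the log-linear estimator's nonlinearity inflates its
variance a few percent above the first-order theory, which is a property
of the estimator, not a defect of either side of the comparison.

Seeding: every public sampler takes a root seed and derives independent
streams with `numpy.random.SeedSequence([root, key…])`, where the key
encodes replicate or flat pixel index — results are byte-reproducible
and independent of evaluation order.

## Bi-exponential predictors

For a two-component truth, each predictor is by construction the
corresponding estimator applied to the *expected* counts of the mixture
(noise-free composition); the closed forms follow from
`∫ t f` / `∫ f` moments of the mixture.  Window conventions: `h = T/M`
for IEM/CMM and `h = T/(S+R)` for the overlapping gates.  The CMM
predictor uses the continuous first-moment ratio — its `τ²` component
weighting is why CMM (and the even more convex RLD-2 log-ratio) read
long on low-fast-fraction mixtures, while large-M IEM approaches the
amplitude-weighted mean `τ_ave`.  Predictor-estimator consistency to
1e−8 is the module's master test wherever both sides are closed-form;
the CMM pair is compared at the half-bin quantization tolerance instead.

## Synthetic phantom: what it emulates, and what it does not

`default_phantom()` is a 64×64 two-region scene emulating labeled
vasculature in tissue: two broad diagonal "vessel" bands (≈45% of
pixels) and an extra-vascular remainder.  Both regions share one
lifetime pair (0.3 ns / 3.4 ns — values of the order seen for
protein-bound fluorescein contrast agents in vivo) and differ only in
the fast-amplitude fraction: 0.8 inside vessels, 0.2 outside, giving
amplitude-weighted means of 0.92 ns and 2.78 ns.  Default budget is 500
photons per pixel.  The band coverage was set near one half so the two
regions contribute comparably to pooled-sd contrast statistics.

The imaging study conditions used in the contrast analysis: stack window
`T = 7.5 ns` (≈ 2.2 × the slow lifetime — a practical compromise
between two-gate efficiency, which favors short windows, and slow-
component coverage) with `M = 256` pages, chosen so the RLD-2 and
0.2/3.2 gate edges fall exactly on bin boundaries; gate edges that do
not are prorated linearly within the edge bin.  The per-pixel IEM map
uses 25 gates: at 500 counts/pixel a 51-gate rebinning leaves only a few
counts in the `N_0 − N_{M−1}` denominator and the estimate degrades
sharply, while ~25 gates keep the denominator populated without
sacrificing the Simpson integral.  The `τ_ave` map uses global analysis
— one bi-exponential fit of the pooled image histogram fixes the
lifetime pair, then per-pixel non-negative least squares unmixes the two
component amplitudes — the standard low-count alternative to per-pixel
free fits, whose slow component is unstable at this budget.

Passing phantom tests demonstrate correct estimator composition,
ordering and contrast behavior under ideal Poisson statistics.  They do
not probe IRF width, detector dead time or afterpulsing, dark-count
non-uniformity, optical scattering, motion, or spatially varying
backgrounds — all absent from the generator — so real-data contrast will
generally be lower than the phantom's.

## Known limitations

* Single-exponential estimators only (plus the reference bi-exponential
  fitter); no global multi-pixel fitting, phasor, or Bayesian analysis.
* No IRF handling: lifetimes comparable to a real instrument's response
  width will be biased.
* No incomplete-decay (repetition-rate wrap-around) correction.
* IEM/CMM photon-economy curves are empirical (Monte-Carlo) only.
* Vendor TCSPC container formats (.sdt, .ptu) are out of scope; I/O is
  CSV, JSON, and multi-page TIFF.
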