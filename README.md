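# flimkit

Non-iterative lifetime estimation for time-domain fluorescence lifetime
imaging (FLIM), with closed-form photon-economy theory and a Monte-Carlo
photon-acquisition simulator.

## Who this is for

FLIM turns every pixel of a fluorescence image into an exponential decay
rate instead of an intensity.  On SPAD/TCSPC sensor arrays and gated
cameras, iterative least-squares fitting is far too slow for video-rate
imaging, so practitioners use *non-iterative* estimators computed from a
handful of gate counts or simple moments of the photon arrival times.
`flimkit` implements that estimator family, the theory that says how many
photons each estimator wastes, and the simulation machinery to validate
both — for people designing acquisition electronics, choosing gate
settings, or benchmarking lifetime algorithms.

## The model and the estimators

The decay is `f(t) = Σ_k A_k exp(−t/τ_k) + b` observed on a window
`[0, T)` after impulsive excitation (instrument response treated as a
delta).  With bins of width `h` and `x = exp(−h/τ)`:

| estimator | input | formula |
|---|---|---|
| RLD-2 | two equal gates `N1, N2` | `τ = h / ln(N1/N2)` |
| GRLD (overlapping gates) | gate 1 `[0,h)`, gate 2 `[S·h, R·h)` | solve `x^S (1−x^{R−S})/(1−x) = N2/N1` |
| RLD-M | M-bin histogram | inverted least-squares slope of `ln N_j` on `j·h` |
| IEM | M-bin histogram (M odd) | `τ = h·Σ_j C_j N_j / (N_0 − N_{M−1})`, Simpson weights `C = [1/3, 4/3, 2/3, …, 4/3, 1/3]` |
| CMM | photon time codes `D_i` | `τ_cmm = (mean D + ½)h`, then `τ = Ω(τ_cmm/T)·T` with `Ω` the monotone inverse of `g(u) = u − e^{−1/u}/(1 − e^{−1/u})` |

Reference fitters (binned maximum likelihood, bounded bi-exponential
least squares) provide oracles and baselines.

Photon economy is quantified by the F-value `F = √N_c · σ_τ / τ`
(`F = 1` is the shot-noise ideal).  Closed forms are implemented for
RLD-2 (`F = 2 cosh(u/2)/u`, `u = h/τ`), the overlapping-gate estimator in
both its uncorrelated (two independent acquisitions) and correlated
(single photon stream, shared overlap counts) variants, RLD-M, and the
Fisher-information bound of the binned MLE.  For bi-exponential truths,
closed-form predictors give the "average lifetime" each single-exponential
estimator converges to, against the amplitude-weighted mean
`τ_ave = (A1τ1 + A2τ2)/(A1 + A2)`.

## Worked example

```python
import flimkit as fk
from flimkit.simulate import SimSpec, sample_photons

model = fk.DecayModel(amplitudes=[1000.0], lifetimes=[2.5])   # 2.5 ns decay
cfg = fk.AcquisitionConfig(T=10.0, M=51)                      # 10 ns window, 51 bins
spec = SimSpec(model=model, cfg=cfg, n_c=5000, seed=7)
photons = sample_photons(spec)
hist = photons.to_histogram()
for est in (fk.cmm(photons), fk.iem(hist), fk.rld_m(hist), fk.mle_fit(hist)):
    print(f"{est.estimator:>5s}: tau = {est.tau:.3f} ns (valid={est.valid})")
```

prints

```
  cmm: tau = 2.563 ns (valid=True)
  iem: tau = 2.513 ns (valid=True)
rld_m: tau = 2.438 ns (valid=True)
  mle: tau = 2.561 ns (valid=True)
```

— four estimates of the same 2.5 ns decay from 5000 photons; the spread
(±1–3%) is what the F-value theory predicts at this photon budget.  The
theory side:

```python
from flimkit.theory import optimize_setting, f_curve
best, _ = optimize_setting("rld2")
# {'h_over_tau': 2.399, 'min_F': 1.5089}  -> best RLD-2 gate width is 2.4 tau
curve = f_curve("cgrld", {"S": 0.2, "R": 3.2}, grid=2000)
# curve.min_F = 1.2408 at tau/T = 0.040   -> overlapping gates beat RLD-2
```

The same functionality is exposed on the command line (`flim simulate`,
`flim fit`, `flim fcurve`, `flim optimize`, `flim biexp-curve`,
`flim image`, `flim make-fixtures`); lifetime images are written as
32-bit float TIFF with a JSON provenance sidecar.

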