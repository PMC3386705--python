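"""Non-iterative single-exponential lifetime estimators and reference fitters.

All estimators assume an impulse-excited exponential decay sampled on a
finite window with negligible instrument response.  Each returns a
:class:`LifetimeEstimate`; in vectorized/per-pixel contexts invalid inputs
yield a flagged estimate rather than an exception.

Implemented estimators
----------------------
rld2
    Two equal contiguous gates: ``tau = h / ln(N1/N2)``.
grld
    Generalized two-gate geometry with overlapping, unequal gates
    (gate 1 ``[0, h)``, gate 2 ``[S*h, R*h)``); solves the monotone root
    equation ``x**S * (1 - x**(R-S)) / (1 - x) = N2/N1`` for
    ``x = exp(-h/tau)``.
rld_m
    Multi-gate RLD: closed-form least-squares slope of ``ln N_j`` against
    the bin left edges ``t_j = j*h``, inverted.
iem
    Integration-for-extraction: Simpson-weighted bin sum divided by the
    first-minus-last bin difference; insensitive to a constant offset.
cmm
    Center-of-mass: first moment of photon codes with a half-bin
    correction, calibrated for window truncation through a 1-D lookup
    ``Omega`` inverting ``g(u) = u - exp(-1/u)/(1 - exp(-1/u))``.
mle_fit / biexp_fit
    Iterative reference fitters used as precision baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .core import GateCounts, Histogram, PhotonList

__all__ = [
    "LifetimeEstimate",
    "OmegaLUT",
    "rld2",
    "grld",
    "grld_ratio_root",
    "rld_m",
    "iem",
    "simpson_weights",
    "build_omega_lut",
    "cmm",
    "mle_fit",
    "biexp_fit",
    "BiExpFit",
]


@dataclass(frozen=True)
class LifetimeEstimate:
    """A lifetime estimate with validity flag and diagnostic context."""

    tau: float
    estimator: str
    valid: bool = True
    diagnostic: str = ""

    def __post_init__(self):
        if self.valid and not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError("a valid estimate requires finite tau > 0")


def _invalid(name: str, why: str) -> LifetimeEstimate:
    return LifetimeEstimate(tau=float("nan"), estimator=name, valid=False,
                            diagnostic=why)


# ---------------------------------------------------------------------------
# Gated estimators


def rld2(gc: GateCounts) -> LifetimeEstimate:
    """Two-gate RLD on equal contiguous gates: ``tau = h / ln(N1/N2)``.

    Requires ``S = 1, R = 2`` geometry (gate 2 immediately follows gate 1,
    same width), so the window is ``T = 2h`` and ``tau = 0.5*T/ln(N1/N2)``.
    """
    if not (gc.S == 1 and gc.R == 2):
        raise ValueError("rld2 requires S=1, R=2 gate geometry")
    if gc.n2 <= 0:
        return _invalid("rld2", "N2 <= 0: log divergence")
    if gc.n1 <= gc.n2:
        return _invalid("rld2", "N1 <= N2: non-decaying counts")
    return LifetimeEstimate(gc.h / np.log(gc.n1 / gc.n2), "rld2")


def _check_grld_geometry(S: float, R: float) -> int:
    """Validate the integer constraints 1/S and R-S integral; return R-S."""
    inv_s = 1.0 / S
    d = R - S
    if abs(inv_s - round(inv_s)) > 1e-9 or abs(d - round(d)) > 1e-9:
        raise ValueError("grld requires both 1/S and R-S to be integers")
    if not (0 < S <= 1 < R):
        raise ValueError("grld requires 0 < S <= 1 < R")
    return int(round(d))


def _grld_poly(x: np.ndarray, S: float, d: int) -> np.ndarray:
    """P(x) = x**S * (1 + x + ... + x**(d-1)), strictly increasing on (0,1)."""
    x = np.asarray(x, dtype=float)
    geom = np.zeros_like(x)
    for i in range(d):
        geom = geom + np.power(x, i)
    return np.power(x, S) * geom


def grld_ratio_root(ratio, S: float, R: float, *, tol: float = 1e-14):
    """Solve ``P(x) = ratio`` for ``x`` in (0,1) by vectorized bisection.

    ``P`` is strictly increasing with ``P(0+) = 0`` and ``P(1-) = R - S``,
    so ratios outside ``(0, R-S)`` have no root and return NaN.
    """
    d = _check_grld_geometry(S, R)
    ratio = np.asarray(ratio, dtype=float)
    lo = np.full(ratio.shape, 1e-300)
    hi = np.full(ratio.shape, 1.0 - 1e-16)
    bad = ~((ratio > 0) & (ratio < d))
    # ~60 bisection steps give |dx| < 1e-16 absolute
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        go_up = _grld_poly(mid, S, d) < ratio
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    x = 0.5 * (lo + hi)
    return np.where(bad, np.nan, x)


def grld(gc: GateCounts) -> LifetimeEstimate:
    """Generalized (overlapping-gate) RLD.

    Solves ``x**S (1 - x**(R-S)) / (1 - x) = N2/N1`` for ``x = exp(-h/tau)``
    and returns ``tau = -h / ln(x)``.  Geometry must satisfy the integer
    constraints (``1/S`` and ``R-S`` integers).  Reduces exactly to
    :func:`rld2` at ``S=1, R=2`` where ``P(x) = x``.
    """
    d = _check_grld_geometry(gc.S, gc.R)
    if gc.n1 <= 0 or gc.n2 <= 0:
        return _invalid("grld", "non-positive gate count")
    ratio = gc.n2 / gc.n1
    if ratio >= d:
        return _invalid("grld", f"N2/N1 = {ratio:.4g} >= R-S = {d}: no root")
    x = float(grld_ratio_root(ratio, gc.S, gc.R))
    if not (0 < x < 1):
        return _invalid("grld", "root outside (0,1)")
    return LifetimeEstimate(-gc.h / np.log(x), "grld",
                            diagnostic=f"x={x:.12g}")


def rld_m(hist: Histogram) -> LifetimeEstimate:
    """Multi-gate RLD: inverted least-squares slope of ``ln N_j`` on ``t_j = j*h``.

    ``tau = [(sum t)^2 - M sum t^2] / [M sum(t ln N) - sum t * sum ln N]``.
    With ``M = 2`` this is algebraically identical to :func:`rld2`.
    All bins must be strictly positive.
    """
    n = hist.counts
    if np.any(n <= 0):
        return _invalid("rld_m", "zero or negative bin: log undefined")
    m = hist.M
    if m < 2:
        return _invalid("rld_m", "need at least 2 bins")
    t = np.arange(m) * hist.h
    ln = np.log(n)
    num = t.sum() ** 2 - m * (t * t).sum()
    den = m * (t * ln).sum() - t.sum() * ln.sum()
    if den >= 0:
        return _invalid("rld_m", "non-decaying log-slope")
    return LifetimeEstimate(num / den, "rld_m")


# ---------------------------------------------------------------------------
# IEM


def simpson_weights(M: int) -> np.ndarray:
    """Simpson composite weights ``[1/3, 4/3, 2/3, ..., 4/3, 1/3]``; M odd."""
    if M < 3 or M % 2 == 0:
        raise ValueError("Simpson weights require odd M >= 3")
    w = np.full(M, 2.0 / 3.0)
    w[0] = w[-1] = 1.0 / 3.0
    w[1::2] = 4.0 / 3.0
    return w


def iem(hist: Histogram) -> LifetimeEstimate:
    """Integration-for-extraction method.

    ``tau = h * sum_j C_j N_j / (N_0 - N_{M-1})`` with Simpson weights
    ``C``.  A constant offset added to every bin cancels in the
    denominator, which makes the estimator background-tolerant.  ``M``
    must be odd (even interval count); an even-``M`` histogram is refused
    rather than silently re-weighted.
    """
    n = hist.counts
    w = simpson_weights(hist.M)  # raises on even M: configuration error
    den = n[0] - n[-1]
    if den <= 0:
        return _invalid("iem", "N_0 <= N_{M-1}: non-decaying counts")
    return LifetimeEstimate(hist.h * float(np.dot(w, n)) / float(den), "iem")


# ---------------------------------------------------------------------------
# CMM


def _truncated_centroid(u):
    """g(u) = u - exp(-1/u)/(1 - exp(-1/u)): normalized first moment of a
    single-exponential decay truncated to [0, T), with u = tau/T."""
    u = np.asarray(u, dtype=float)
    e = np.exp(-1.0 / u)
    return u - e / (1.0 - e)


@dataclass(frozen=True)
class OmegaLUT:
    """Monotone lookup inverting the truncated-window centroid map.

    Maps the measured normalized centroid ``g = tau_cmm / T`` (in
    ``(0, 1/2)``) back to ``tau / T``.  Built on a log-spaced grid of
    ``u = tau/T`` with monotone-cubic (PCHIP) interpolation of the inverse.
    """

    grid_u: np.ndarray
    grid_g: np.ndarray
    _inv: PchipInterpolator = field(repr=False)

    @property
    def g_min(self) -> float:
        return float(self.grid_g[0])

    @property
    def g_max(self) -> float:
        return float(self.grid_g[-1])

    def __call__(self, g):
        """Invert: return u = tau/T for measured centroid ratio(s) g.

        Inputs at or beyond the saturation limit (g -> 1/2 as tau/T -> inf)
        map to NaN.
        """
        g = np.asarray(g, dtype=float)
        out = self._inv(np.clip(g, self.g_min, self.g_max))
        out = np.where((g >= self.g_max) | (g <= 0) | ~np.isfinite(g),
                       np.nan, out)
        return out if out.ndim else float(out)


def build_omega_lut(grid_size: int = 2048,
                    u_range: tuple[float, float] = (1e-3, 1e2)) -> OmegaLUT:
    """Tabulate ``g(u)`` on a log-spaced grid and return its monotone inverse."""
    if grid_size < 256:
        raise ValueError("grid_size must be >= 256")
    u = np.logspace(np.log10(u_range[0]), np.log10(u_range[1]), grid_size)
    g = _truncated_centroid(u)
    return OmegaLUT(grid_u=u, grid_g=g, _inv=PchipInterpolator(g, u))


_DEFAULT_LUT: OmegaLUT | None = None


def default_omega_lut() -> OmegaLUT:
    global _DEFAULT_LUT
    if _DEFAULT_LUT is None:
        _DEFAULT_LUT = build_omega_lut()
    return _DEFAULT_LUT


def cmm(data: PhotonList | Histogram,
        lut: OmegaLUT | None = None) -> LifetimeEstimate:
    """Center-of-mass lifetime with truncation calibration.

    Raw centroid ``tau_cmm = (mean(D_i) + 1/2) * h`` (photon list) or the
    identical histogram form ``(sum j N_j / sum N_j + 1/2) * h``; then
    ``tau = Omega(tau_cmm / T) * T``.  Centroids at or beyond ``T/2``
    (uniform-distribution limit) are flagged saturated.
    """
    lut = lut or default_omega_lut()
    if isinstance(data, PhotonList):
        if data.n_photons == 0:
            return _invalid("cmm", "empty photon list")
        mean_code = float(data.codes.mean())
        M, h = data.M, data.h
    else:
        tot = data.total
        if tot <= 0:
            return _invalid("cmm", "empty histogram")
        mean_code = float(np.dot(np.arange(data.M), data.counts) / tot)
        M, h = data.M, data.h
    tau_cmm = (mean_code + 0.5) * h
    ratio = tau_cmm / (M * h)
    if ratio >= 0.5:
        return _invalid("cmm", f"centroid ratio {ratio:.4g} >= 1/2: saturated")
    u = lut(ratio)
    if not np.isfinite(u):
        return _invalid("cmm", "centroid outside calibration range")
    return LifetimeEstimate(float(u) * M * h, "cmm",
                            diagnostic=f"tau_cmm={tau_cmm:.6g}")


def cmm_centroid_ratio(counts: np.ndarray) -> np.ndarray:
    """Vectorized raw centroid ratio ``tau_cmm/T`` for histograms in rows."""
    counts = np.asarray(counts, dtype=float)
    M = counts.shape[-1]
    j = np.arange(M)
    tot = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_code = counts @ j / tot
    return (mean_code + 0.5) / M


# ---------------------------------------------------------------------------
# Reference fitters


def _single_exp_probs(x: float, M: int) -> np.ndarray:
    j = np.arange(M)
    return np.power(x, j) * (1.0 - x) / (1.0 - x**M)


def mle_fit(hist: Histogram) -> LifetimeEstimate:
    """Single-exponential maximum-likelihood fit of the binned decay.

    Maximizes the multinomial log-likelihood ``sum_j N_j ln p_j`` with
    ``p_j = x**j (1-x)/(1-x**M)``, ``x = exp(-h/tau)``.  The count-weighted
    mean bin index is sufficient, and the score vanishes where the model
    mean ``m(x) = x/(1-x) - M x**M/(1-x**M)`` (strictly increasing, range
    ``(0, (M-1)/2)``) equals it, so the MLE is found by safeguarded 1-D
    root bracketing on that monotone equation.
    """
    n = hist.counts
    tot = n.sum()
    if tot < 1:
        return _invalid("mle", "needs at least one count")
    M = hist.M
    jbar = float(np.dot(np.arange(M), n) / tot)
    if jbar <= 0:
        # all photons in bin 0: tau -> 0 boundary; still defined via limit
        return _invalid("mle", "all counts in first bin: tau at boundary")
    if jbar >= M - 1:
        return _invalid("mle", "all counts in last bin")
    if jbar >= (M - 1) / 2:
        return _invalid("mle", "centroid past uniform limit: no interior MLE")

    def score(x: float) -> float:
        return x / (1.0 - x) - M * x**M / (1.0 - x**M) - jbar

    from scipy.optimize import brentq

    x = brentq(score, 1e-14, 1.0 - 1e-12, xtol=1e-300, rtol=1e-15)
    if not (0 < x < 1):
        return _invalid("mle", "score root at boundary")
    return LifetimeEstimate(-hist.h / np.log(x), "mle",
                            diagnostic=f"jbar={jbar:.6g}")


def mle_fit_codes(counts: np.ndarray, h: float) -> np.ndarray:
    """Vectorized MLE over histograms in rows; NaN where undefined."""
    counts = np.asarray(counts, dtype=float)
    M = counts.shape[-1]
    out = np.full(counts.shape[0], np.nan)
    for i in range(counts.shape[0]):
        est = mle_fit(Histogram(counts[i], h))
        if est.valid:
            out[i] = est.tau
    return out


@dataclass(frozen=True)
class BiExpFit:
    """Bi-exponential fit result, components sorted tau1 < tau2."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    valid: bool
    degenerate: bool = False
    diagnostic: str = ""

    @property
    def tau_ave(self) -> float:
        """Amplitude-weighted mean lifetime of the fitted components."""
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / (self.a1 + self.a2)


def _biexp_expected(theta, h, M):
    """Expected bin counts for log-parameterized bi-exp (no background)."""
    la1, lt1, la2, lt2 = theta
    j = np.arange(M)
    out = np.zeros(M)
    for la, lt in ((la1, lt1), (la2, lt2)):
        a, tau = np.exp(la), np.exp(lt)
        x = np.exp(-h / tau)
        out = out + a * tau * np.power(x, j) * (1.0 - x)
    return out


def biexp_fit(hist: Histogram, n_starts: int = 4) -> BiExpFit:
    """Weighted least-squares bi-exponential fit of a binned decay.

    Weighted residuals ``(N_j - mu_j)/sqrt(N_j + 1)`` on a
    log-parameterization (amplitudes and lifetimes positive by
    construction), with multiple starts spreading the two lifetimes over
    decades around the histogram centroid.  Lifetimes are constrained to
    ``[h/10, 10*T]`` and amplitudes to physically sensible decades — on
    sparse histograms the unconstrained slow component can run away to
    arbitrarily long lifetimes with near-zero curvature in the objective.
    Components are returned sorted ``tau1 < tau2``; near-equal lifetimes
    or a vanishing amplitude are flagged degenerate
    (single-exponential-compatible data).
    """
    n = hist.counts
    if hist.M < 8:
        raise ValueError("biexp_fit needs M >= 8 bins")
    if n.sum() < 100:
        return BiExpFit(np.nan, np.nan, np.nan, np.nan, valid=False,
                        diagnostic="fewer than 100 counts")
    h, M = hist.h, hist.M
    tot = n.sum()
    # moment-based scale: calibrated centroid if available, else T/4
    est0 = cmm(hist)
    tau0 = est0.tau if est0.valid else 0.25 * M * h
    tau0 = min(max(tau0, 0.05 * M * h), 2.0 * M * h)
    a0 = tot / (2 * tau0)

    w = 1.0 / np.sqrt(n + 1.0)

    def resid(theta):
        return (_biexp_expected(theta, h, M) - n) * w

    t_lo, t_hi = np.log(h / 10.0), np.log(10.0 * M * h)
    a_lo, a_hi = np.log(a0) - 14.0, np.log(a0) + 7.0
    lower = np.array([a_lo, t_lo, a_lo, t_lo])
    upper = np.array([a_hi, t_hi, a_hi, t_hi])

    best = None
    spreads = [3.0, 6.0, 10.0, 1.5][:n_starts]
    for spread in spreads:
        theta0 = np.log([a0, tau0 / np.sqrt(spread), a0, tau0 * np.sqrt(spread)])
        theta0 = np.clip(theta0, lower + 1e-6, upper - 1e-6)
        try:
            res = least_squares(resid, theta0, method="trf",
                                bounds=(lower, upper), max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BiExpFit(np.nan, np.nan, np.nan, np.nan, valid=False,
                        diagnostic="no converged start")
    la1, lt1, la2, lt2 = best.x
    a = np.exp([la1, la2])
    t = np.exp([lt1, lt2])
    order = np.argsort(t)
    a, t = a[order], t[order]
    degenerate = bool(t[1] / t[0] < 1.5 or min(a) / max(a) < 1e-3)
    return BiExpFit(a1=float(a[0]), tau1=float(t[0]),
                    a2=float(a[1]), tau2=float(t[1]),
                    valid=True, degenerate=degenerate,
                    diagnostic=f"cost={best.cost:.4g} nfev={best.nfev}")
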