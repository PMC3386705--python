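"""What single-exponential estimators report on bi-exponential decays.

When the true decay is ``f(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2)``, each
non-iterative estimator converges (noise-free) to a different "average
lifetime".  The reference is the amplitude-weighted mean

    tau_ave = (A1 tau1 + A2 tau2) / (A1 + A2),

and this module gives the closed-form noise-free readout of IEM, two-gate
RLD, CMM and the correlated overlapping-gate RLD, obtained by composing
each estimator with the expected counts of the mixture.  These power the
average-lifetime-versus-fraction curves and the phantom contrast analysis;
stochastic spread comes from the simulator, not from here.

Window conventions follow the estimators: ``h = T/M`` for IEM/CMM and
``h = T/(S+R)`` for the overlapping gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionConfig, DecayModel, expected_bin_counts
from .estimators import OmegaLUT, default_omega_lut, grld_ratio_root, iem

__all__ = [
    "BiExpSetting",
    "tau_ave",
    "tau_iem_pred",
    "tau_iem_pred_approx",
    "tau_rld2_pred",
    "tau_cmm_pred",
    "tau_cgrld_pred",
    "predictor_table",
]


@dataclass(frozen=True)
class BiExpSetting:
    """Bi-exponential mixture plus the measurement window it is viewed in."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    T: float

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("lifetimes must be > 0")
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 <= 0:
            raise ValueError("amplitudes must be >= 0 with positive sum")
        if self.T <= 0:
            raise ValueError("window T must be > 0")

    @property
    def model(self) -> DecayModel:
        return DecayModel(amplitudes=(self.a1, self.a2),
                          lifetimes=(self.tau1, self.tau2))

    @classmethod
    def from_fraction(cls, fraction_fast: float, tau1: float, tau2: float,
                      T: float) -> "BiExpSetting":
        """Mixture with ``A1/(A1+A2) = fraction_fast`` and unit total amplitude."""
        return cls(a1=fraction_fast, tau1=tau1, a2=1.0 - fraction_fast,
                   tau2=tau2, T=T)


def tau_ave(s: BiExpSetting) -> float:
    """Amplitude-weighted mean lifetime ``(A1 tau1 + A2 tau2)/(A1 + A2)``."""
    return (s.a1 * s.tau1 + s.a2 * s.tau2) / (s.a1 + s.a2)


def _moment(s: BiExpSetting, fn) -> float:
    return fn(s.a1, s.tau1) + fn(s.a2, s.tau2)


def tau_iem_pred(s: BiExpSetting, M: int) -> float:
    """Noise-free IEM readout: Simpson-weighted estimator applied to the
    expected bin counts of the mixture (exact form; M odd)."""
    cfg = AcquisitionConfig(T=s.T, M=M)
    est = iem(expected_bin_counts(s.model, cfg))
    if not est.valid:
        raise ArithmeticError(f"IEM undefined here: {est.diagnostic}")
    return est.tau


def tau_iem_pred_approx(s: BiExpSetting, M: int) -> float:
    """Large-M IEM approximation:
    ``int_0^{(M-1)h} f / (f(0) - f((M-1)h))`` in closed form."""
    h = s.T / M
    tail = (M - 1) * h

    num = _moment(s, lambda a, tau: a * tau * (1.0 - np.exp(-tail / tau)))
    den = _moment(s, lambda a, tau: a * (1.0 - np.exp(-tail / tau)))
    return num / den


def tau_rld2_pred(s: BiExpSetting) -> float:
    """Noise-free two-gate RLD readout with half-window gates:
    ``0.5 T / ln(int_0^{T/2} f / int_{T/2}^T f)``."""
    half = 0.5 * s.T
    n1 = _moment(s, lambda a, tau: a * tau * (1.0 - np.exp(-half / tau)))
    n2 = _moment(s, lambda a, tau: a * tau * (np.exp(-half / tau)
                                              - np.exp(-s.T / tau)))
    return half / np.log(n1 / n2)


def tau_cmm_pred(s: BiExpSetting, lut: OmegaLUT | None = None) -> float:
    """Noise-free CMM readout: window-truncated first-moment ratio of the
    mixture pushed through the calibration lookup.

    ``E[t]/T = sum_k A_k tau_k^2 (1 - e^{-T/tau_k} - (T/tau_k) e^{-T/tau_k})
    / (T sum_k A_k tau_k (1 - e^{-T/tau_k}))``; the slow component enters
    with a ``tau_2^2`` weight, which is why low-A1 mixtures read long.
    """
    lut = lut or default_omega_lut()
    T = s.T
    num = _moment(s, lambda a, tau: a * tau**2 * (1.0 - np.exp(-T / tau)
                                                 - (T / tau) * np.exp(-T / tau)))
    den = T * _moment(s, lambda a, tau: a * tau * (1.0 - np.exp(-T / tau)))
    u = lut(num / den)
    if not np.isfinite(u):
        raise ArithmeticError("CMM centroid saturated for this mixture")
    return float(u) * T


def tau_cgrld_pred(s: BiExpSetting, S: float = 0.2, R: float = 3.2,
                   h: float | None = None) -> float:
    """Noise-free overlapping-gate RLD readout.

    Forms the expected gate-count ratio of the mixture (gate 1 ``[0, h)``,
    gate 2 ``[S*h, R*h)``) and solves the single-exponential root equation
    for it.  Default bin width follows the ``h = T/(S+R)`` convention.
    """
    if h is None:
        h = s.T / (S + R)
    n1 = _moment(s, lambda a, tau: a * tau * (1.0 - np.exp(-h / tau)))
    n2 = _moment(s, lambda a, tau: a * tau * (np.exp(-S * h / tau)
                                              - np.exp(-R * h / tau)))
    x = float(grld_ratio_root(n2 / n1, S, R))
    if not (0 < x < 1):
        raise ArithmeticError("gate ratio outside the solvable range")
    return -h / np.log(x)


def predictor_table(fractions, tau1: float, tau2: float, T: float, *,
                    M_iem: int = 7, S: float = 0.2, R: float = 3.2,
                    lut: OmegaLUT | None = None) -> dict[str, np.ndarray]:
    """All five average-lifetime curves versus fast-amplitude fraction.

    Returns arrays keyed ``fraction, tau_ave, tau_iem, tau_rld2, tau_cmm,
    tau_cgrld`` for plotting average-lifetime-versus-fraction figures.
    """
    lut = lut or default_omega_lut()
    fr = np.asarray(fractions, dtype=float)
    cols = {k: np.empty(fr.size) for k in
            ("tau_ave", "tau_iem", "tau_rld2", "tau_cmm", "tau_cgrld")}
    for i, f in enumerate(fr):
        s = BiExpSetting.from_fraction(f, tau1, tau2, T)
        cols["tau_ave"][i] = tau_ave(s)
        cols["tau_iem"][i] = tau_iem_pred(s, M_iem)
        cols["tau_rld2"][i] = tau_rld2_pred(s)
        cols["tau_cmm"][i] = tau_cmm_pred(s, lut)
        cols["tau_cgrld"][i] = tau_cgrld_pred(s, S, R)
    return {"fraction": fr, **cols}
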