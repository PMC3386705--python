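"""Decay models, acquisition geometry, and closed-form expected counts.

Everything downstream — estimators, photon-economy theory, Monte-Carlo
simulation — consumes the types defined here.  The physical model is a
multi-exponential fluorescence decay observed over a finite window after an
impulsive excitation (the instrument response is treated as a delta):

    f(t) = sum_k A_k exp(-t / tau_k) + b,    0 <= t < T,

with amplitudes ``A_k`` (photons per unit time at t=0), lifetimes ``tau_k``
(ns), and a uniform background rate ``b``.  Time bins are half-open
``[j*h, (j+1)*h)``, zero-based; the expected count in bin ``j`` from one
exponential component is ``A*tau*x**j*(1-x)`` with ``x = exp(-h/tau)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DecayModel",
    "AcquisitionConfig",
    "Histogram",
    "PhotonList",
    "GateCounts",
    "expected_bin_counts",
    "expected_total",
    "expected_gate_counts",
]

SCHEMES = ("sequential", "correlated-gates", "uncorrelated-gates", "tcspc")


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential decay with uniform background.

    Parameters
    ----------
    amplitudes : sequence of float
        Initial photon rates ``A_k`` (photons/ns), all >= 0, at least one > 0.
    lifetimes : sequence of float
        Lifetimes ``tau_k`` (ns), all > 0, same length as ``amplitudes``.
    background : float, default 0
        Uniform background rate ``b`` (photons/ns) on ``[0, T)``.
    """

    amplitudes: tuple[float, ...]
    lifetimes: tuple[float, ...]
    background: float = 0.0

    def __init__(self, amplitudes: Sequence[float], lifetimes: Sequence[float],
                 background: float = 0.0):
        amplitudes = tuple(float(a) for a in np.atleast_1d(amplitudes))
        lifetimes = tuple(float(t) for t in np.atleast_1d(lifetimes))
        if len(amplitudes) != len(lifetimes) or not amplitudes:
            raise ValueError("amplitudes and lifetimes must be non-empty and "
                             "of equal length")
        if any(t <= 0 for t in lifetimes):
            raise ValueError("all lifetimes must be > 0")
        if any(a < 0 for a in amplitudes) or not any(a > 0 for a in amplitudes):
            raise ValueError("amplitudes must be >= 0 with at least one > 0")
        if background < 0:
            raise ValueError("background must be >= 0")
        object.__setattr__(self, "amplitudes", amplitudes)
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "background", float(background))

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)

    def to_json(self) -> dict:
        return {"amplitudes": list(self.amplitudes),
                "lifetimes": list(self.lifetimes),
                "background": self.background}

    @classmethod
    def from_json(cls, doc: dict) -> "DecayModel":
        return cls(doc["amplitudes"], doc["lifetimes"], doc.get("background", 0.0))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Measurement window, binning, and optional two-gate geometry.

    The window is ``T = M*h``.  When a gate pair is configured, gate 1 is
    ``[0, h)`` and gate 2 is ``[S*h, R*h)`` with ``0 < S < 1 < R`` — the
    gates overlap on ``[S*h, h)``.  ``scheme`` names how photons are routed
    to counters: ``sequential`` / ``uncorrelated-gates`` record the two
    gates from independent photon streams, ``correlated-gates`` from the
    same stream, ``tcspc`` records a full per-photon time code.
    """

    T: float
    M: int
    S: float | None = None
    R: float | None = None
    scheme: str = "tcspc"

    def __post_init__(self):
        if self.M < 1 or self.T <= 0:
            raise ValueError("need M >= 1 and T > 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if (self.S is None) != (self.R is None):
            raise ValueError("S and R must be given together")
        if self.S is not None:
            # S = 1 is the degenerate no-overlap case (plain RLD-2 geometry)
            if not (0 < self.S <= 1 < self.R):
                raise ValueError("gate geometry requires 0 < S <= 1 < R")

    @property
    def h(self) -> float:
        """Bin width ``T / M`` (ns)."""
        return self.T / self.M

    @property
    def has_gates(self) -> bool:
        return self.S is not None

    def to_json(self) -> dict:
        return {"T": self.T, "M": self.M, "h": self.h,
                "S": self.S, "R": self.R, "scheme": self.scheme}

    @classmethod
    def from_json(cls, doc: dict) -> "AcquisitionConfig":
        return cls(T=doc["T"], M=int(doc["M"]), S=doc.get("S"),
                   R=doc.get("R"), scheme=doc.get("scheme", "tcspc"))


def save_json(obj, path) -> None:
    """Serialize a DecayModel and/or AcquisitionConfig to one flat JSON file."""
    doc = {}
    for o in (obj if isinstance(obj, (list, tuple)) else [obj]):
        doc.update(o.to_json())
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model_json(path) -> DecayModel:
    with open(path) as fh:
        return DecayModel.from_json(json.load(fh))


def load_config_json(path) -> AcquisitionConfig:
    with open(path) as fh:
        return AcquisitionConfig.from_json(json.load(fh))


@dataclass(frozen=True)
class Histogram:
    """Binned decay: counts ``N_j`` over ``M`` bins of width ``h`` (ns)."""

    counts: np.ndarray
    h: float

    def __init__(self, counts, h: float):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a 1-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if h <= 0:
            raise ValueError("h must be > 0")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "h", float(h))

    @property
    def M(self) -> int:
        return self.counts.size

    @property
    def T(self) -> float:
        return self.M * self.h

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PhotonList:
    """Per-photon TDC codes ``D_i`` (bin indices in ``[0, M)``)."""

    codes: np.ndarray
    M: int
    h: float

    def __init__(self, codes, M: int, h: float):
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 1:
            raise ValueError("codes must be 1-D")
        if codes.size and (codes.min() < 0 or codes.max() >= M):
            raise ValueError("codes must lie in [0, M)")
        if h <= 0 or M < 1:
            raise ValueError("need h > 0 and M >= 1")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "M", int(M))
        object.__setattr__(self, "h", float(h))

    @property
    def n_photons(self) -> int:
        return self.codes.size

    def to_histogram(self) -> Histogram:
        return Histogram(np.bincount(self.codes, minlength=self.M)[: self.M], self.h)


@dataclass(frozen=True)
class GateCounts:
    """Counts from the generalized two-gate geometry.

    ``n1`` is the count of gate 1 ``[0, h)``, ``n2`` of gate 2
    ``[S*h, R*h)``.  ``correlated`` records whether the overlap region
    ``[S*h, h)`` was counted from the same photon stream by both gates.
    """

    n1: float
    n2: float
    S: float
    R: float
    h: float
    correlated: bool = True

    def __post_init__(self):
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.S <= 1 < self.R) or self.h <= 0:
            raise ValueError("gate geometry requires 0 < S <= 1 < R and h > 0")


# ---------------------------------------------------------------------------
# Expected-count arithmetic


def _window_integral(model: DecayModel, t0, t1) -> float:
    """Expected decay+background count on [t0, t1), closed form."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    out = model.background * (t1 - t0)
    for a, tau in zip(model.amplitudes, model.lifetimes):
        out = out + a * tau * (np.exp(-t0 / tau) - np.exp(-t1 / tau))
    return out


def expected_bin_counts(model: DecayModel, cfg: AcquisitionConfig) -> Histogram:
    """Expected (real-valued) bin counts of the binned decay.

    ``N_j = sum_k A_k tau_k x_k**j (1 - x_k) + b*h`` with ``x_k = exp(-h/tau_k)``.
    """
    h = cfg.h
    j = np.arange(cfg.M)
    counts = np.full(cfg.M, model.background * h)
    for a, tau in zip(model.amplitudes, model.lifetimes):
        x = np.exp(-h / tau)
        counts = counts + a * tau * np.power(x, j) * (1.0 - x)
    return Histogram(counts, h)


def expected_total(model: DecayModel, T: float) -> float:
    """Expected total count on ``[0, T)``: ``sum_k A_k tau_k (1 - e^{-T/tau_k}) + b*T``."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return float(_window_integral(model, 0.0, T))


def expected_gate_counts(model: DecayModel, cfg: AcquisitionConfig) -> GateCounts:
    """Expected (real-valued) counts of the two configured gates.

    Returns a :class:`GateCounts` whose ``n1``/``n2`` are the expected counts
    of ``[0, h)`` and ``[S*h, R*h)``.  Continuous (non-integer-constrained)
    ``S``, ``R`` are accepted here; the GRLD *estimator* enforces the
    integer-geometry constraints it needs.
    """
    if not cfg.has_gates:
        raise ValueError("cfg has no gate geometry")
    h, S, R = cfg.h, cfg.S, cfg.R
    n1 = float(_window_integral(model, 0.0, h))
    n2 = float(_window_integral(model, S * h, R * h))
    return GateCounts(n1=n1, n2=n2, S=S, R=R, h=h,
                      correlated=(cfg.scheme == "correlated-gates"))


def expected_overlap_count(model: DecayModel, cfg: AcquisitionConfig) -> float:
    """Expected count of the gate-overlap region ``[S*h, h)``."""
    if not cfg.has_gates:
        raise ValueError("cfg has no gate geometry")
    return float(_window_integral(model, cfg.S * cfg.h, cfg.h))
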