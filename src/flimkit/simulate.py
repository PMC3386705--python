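"""Monte-Carlo photon acquisition: photon lists, gate counts, image stacks.

Photon arrival times are drawn conditionally on the measurement window,
i.e. from the truncated density ``f(t) / int_0^T f`` — a mixture of
window-truncated exponentials plus a uniform background component, with
mixture weights proportional to each component's expected in-window count.
``N_c`` therefore always means "counts inside [0, T)".

Two total-count laws are supported: ``fixed`` (exactly ``n_c`` photons per
replicate; bin counts are multinomial) and ``poisson`` (replicate totals
Poisson with mean ``n_c``; bin counts are then independent Poissons).

Reproducibility: every operation takes a root seed; per-replicate and
per-pixel streams are derived with ``numpy.random.SeedSequence(root, key)``
counter-style spawning, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (AcquisitionConfig, DecayModel, GateCounts, PhotonList,
                   expected_bin_counts)

__all__ = [
    "SimSpec",
    "Phantom",
    "sample_photons",
    "sample_histogram_counts",
    "sample_gate_counts",
    "sample_gate_count_arrays",
    "simulate_image_stack",
    "default_phantom",
]


@dataclass(frozen=True)
class SimSpec:
    """One simulated acquisition: model, geometry, count law, seed."""

    model: DecayModel
    cfg: AcquisitionConfig
    n_c: float
    count_law: str = "fixed"  # "fixed" | "poisson"
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.count_law not in ("fixed", "poisson"):
            raise ValueError("count_law must be 'fixed' or 'poisson'")


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _mixture_weights(model: DecayModel, T: float):
    """In-window expected count per component (exponentials..., background)."""
    w = [a * tau * (1.0 - np.exp(-T / tau))
         for a, tau in zip(model.amplitudes, model.lifetimes)]
    w.append(model.background * T)
    return np.asarray(w)


def _sample_times(model: DecayModel, T: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw n arrival times from the window-truncated density f(t)/int_0^T f."""
    w = _mixture_weights(model, T)
    comp = rng.choice(w.size, size=n, p=w / w.sum())
    u = rng.random(n)
    t = np.empty(n)
    for k, tau in enumerate(model.lifetimes):
        m = comp == k
        if m.any():
            # inverse CDF of exponential truncated to [0, T)
            t[m] = -tau * np.log1p(-u[m] * (1.0 - np.exp(-T / tau)))
        # guard against roundoff landing exactly on T
    m = comp == len(model.lifetimes)
    if m.any():
        t[m] = u[m] * T
    return np.minimum(t, np.nextafter(T, 0.0))


def _draw_total(spec: SimSpec, rng: np.random.Generator) -> int:
    if spec.count_law == "fixed":
        return int(round(spec.n_c))
    return int(rng.poisson(spec.n_c))


def sample_photons(spec: SimSpec, replicate: int = 0) -> PhotonList:
    """Draw one replicate of time-tagged photons; codes are ``floor(t/h)``."""
    rng = _rng(spec.seed, replicate)
    n = _draw_total(spec, rng)
    t = _sample_times(spec.model, spec.cfg.T, n, rng)
    codes = np.minimum((t / spec.cfg.h).astype(np.int64), spec.cfg.M - 1)
    return PhotonList(codes, M=spec.cfg.M, h=spec.cfg.h)


def sample_histogram_counts(spec: SimSpec) -> np.ndarray:
    """All replicates' bin counts at once, shape (replicates, M).

    Distributionally identical to histogramming :func:`sample_photons`
    draws: multinomial over bins for the fixed law, independent Poissons
    for the poisson law.  Used by the Monte-Carlo F harness where only bin
    counts matter.
    """
    rng = _rng(spec.seed, 1_000_003)
    p = expected_bin_counts(spec.model, spec.cfg).counts
    p = p / p.sum()
    if spec.count_law == "fixed":
        return rng.multinomial(int(round(spec.n_c)), p,
                               size=spec.replicates).astype(float)
    mu = spec.n_c * p
    return rng.poisson(mu, size=(spec.replicates, p.size)).astype(float)


def _gate_region_probs(model: DecayModel, cfg: AcquisitionConfig):
    """Expected counts of the partition [0,Sh), [Sh,h), [h,Rh) of [0,Rh)."""
    from .core import _window_integral

    h, S, R = cfg.h, cfg.S, cfg.R
    bounds = [0.0, S * h, h, R * h]
    return np.array([_window_integral(model, bounds[i], bounds[i + 1])
                     for i in range(3)])


def sample_gate_counts(spec: SimSpec, replicate: int = 0) -> GateCounts:
    """Draw one replicate of two-gate counts under the configured scheme."""
    n1, n2, nov, _ = sample_gate_count_arrays(replace(spec, replicates=1),
                                              base_replicate=replicate)
    return GateCounts(n1=float(n1[0]), n2=float(n2[0]), S=spec.cfg.S,
                      R=spec.cfg.R, h=spec.cfg.h,
                      correlated=spec.cfg.scheme == "correlated-gates")


def sample_gate_count_arrays(spec: SimSpec, base_replicate: int = 0):
    """Vectorized gate-count replicates: arrays (n1, n2, n_ov, n_window).

    correlated-gates
        One photon stream over ``[0, R*h)``; the overlap region increments
        both counters, so region counts are a 3-cell multinomial (fixed
        law) or independent Poissons (poisson law) and
        ``n1 = n_[0,Sh) + n_ov``, ``n2 = n_ov + n_[h,Rh)``.
    uncorrelated-gates
        Two independent acquisitions of equal expected intensity; each
        gate's count is Poisson regardless of the count law (each snapshot
        sees its own photon stream, whose in-gate count is Poisson).
        ``n_ov`` is reported as 0: no shared events exist.

    ``n_window`` is the per-replicate photon count attributed to one
    acquisition window ``[0, R*h)``, the normalization entering F-values.
    """
    cfg = spec.cfg
    if not cfg.has_gates:
        raise ValueError("spec.cfg has no gate geometry")
    if cfg.scheme not in ("correlated-gates", "uncorrelated-gates"):
        raise ValueError("gate sampling requires a gated scheme")
    rng = _rng(spec.seed, 2_000_003, base_replicate)
    mu = _gate_region_probs(spec.model, cfg)  # [0,Sh), [Sh,h), [h,Rh)
    reps = spec.replicates
    if cfg.scheme == "correlated-gates":
        if spec.count_law == "fixed":
            counts = rng.multinomial(int(round(spec.n_c)), mu / mu.sum(),
                                     size=reps).astype(float)
        else:
            scale = spec.n_c / mu.sum()
            counts = rng.poisson(mu * scale, size=(reps, 3)).astype(float)
        n_pre, n_ov, n_post = counts[:, 0], counts[:, 1], counts[:, 2]
        n1 = n_pre + n_ov
        n2 = n_ov + n_post
        n_window = counts.sum(axis=1)
        return n1, n2, n_ov, n_window
    # uncorrelated: per-gate Poisson from two independent streams
    scale = spec.n_c / mu.sum()
    n1 = rng.poisson((mu[0] + mu[1]) * scale, size=reps).astype(float)
    n2 = rng.poisson((mu[1] + mu[2]) * scale, size=reps).astype(float)
    n_window = np.full(reps, spec.n_c, dtype=float)
    return n1, n2, np.zeros(reps), n_window


# ---------------------------------------------------------------------------
# Synthetic FLIM scenes


@dataclass(frozen=True)
class Phantom:
    """A labeled 2-D scene with one decay model per label.

    ``labels`` is an integer image; ``models[lbl]`` gives the decay shape
    for that label and ``expected_counts`` the per-pixel expected total
    photon count (amplitude scaling is irrelevant: per-pixel histograms are
    drawn with the label's *shape* and the pixel's expected total).
    """

    labels: np.ndarray
    models: dict[int, DecayModel]
    expected_counts: np.ndarray

    def __post_init__(self):
        if self.labels.shape != self.expected_counts.shape:
            raise ValueError("labels and expected_counts must share extent")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.models):
            raise ValueError("every label needs a model")
        if np.any(self.expected_counts < 0):
            raise ValueError("expected counts must be >= 0")


def default_phantom(shape: tuple[int, int] = (64, 64),
                    n_c: float = 500.0,
                    vessel_fraction_fast: float = 0.8,
                    background_fraction_fast: float = 0.2,
                    tau_fast: float = 0.3,
                    tau_slow: float = 3.4) -> Phantom:
    """Two-region vascular phantom with a shared bi-exponential lifetime pair.

    Emulates a vessel network (label 1) embedded in extra-vascular tissue
    (label 0).  Both regions decay with the same two lifetimes (defaults
    0.3 ns and 3.4 ns); they differ only in the amplitude fraction of the
    fast component — high inside vessels, low outside — so the
    amplitude-weighted mean lifetime is short in the vessels and long
    outside.  Geometry: two broad diagonal vessel bands covering ~45% of
    the field, so the two regions carry comparable pixel counts in
    contrast statistics.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros(shape, dtype=np.int64)
    # two diagonal vessels crossing the field
    d1 = (xx + yy - int(0.9 * nx)) / np.sqrt(2.0)
    d2 = (xx - yy + int(0.25 * nx)) / np.sqrt(2.0)
    half_width = 0.11 * nx
    labels[np.abs(d1) < half_width] = 1
    labels[np.abs(d2) < half_width] = 1

    def region_model(frac_fast: float) -> DecayModel:
        # amplitudes normalized so A1 + A2 = 1 (shape only)
        return DecayModel(amplitudes=(frac_fast, 1.0 - frac_fast),
                          lifetimes=(tau_fast, tau_slow))

    models = {0: region_model(background_fraction_fast),
              1: region_model(vessel_fraction_fast)}
    return Phantom(labels=labels, models=models,
                   expected_counts=np.full(shape, float(n_c)))


def simulate_image_stack(phantom: Phantom, cfg: AcquisitionConfig,
                         seed: int = 0, count_law: str = "fixed") -> np.ndarray:
    """Per-pixel histogram stack, shape ``(M, ny, nx)`` (one page per bin).

    Each pixel is sampled independently with its label's decay shape and
    its own expected total count; the per-pixel random stream is derived
    from ``(seed, pixel_flat_index)`` so the result is independent of
    evaluation order.  Pixels with zero expected count get all-zero
    histograms.
    """
    ny, nx = phantom.labels.shape
    stack = np.zeros((cfg.M, ny, nx), dtype=np.uint32)
    # per-label bin probabilities
    probs = {}
    for lbl, model in phantom.models.items():
        p = expected_bin_counts(model, cfg).counts
        probs[lbl] = p / p.sum()
    flat_labels = phantom.labels.ravel()
    flat_nc = phantom.expected_counts.ravel()
    for idx in range(flat_labels.size):
        nc = flat_nc[idx]
        if nc <= 0:
            continue
        rng = _rng(seed, 3_000_017, idx)
        n = int(round(nc)) if count_law == "fixed" else int(rng.poisson(nc))
        if n == 0:
            continue
        counts = rng.multinomial(n, probs[flat_labels[idx]])
        stack[:, idx // nx, idx % nx] = counts
    return stack


def stack_sidecar(phantom: Phantom, cfg: AcquisitionConfig, seed: int) -> dict:
    """JSON-serializable provenance for a simulated stack."""
    return {
        "h_ns": cfg.h,
        "M": cfg.M,
        "T_ns": cfg.T,
        "seed": int(seed),
        "phantom": {
            "shape": list(phantom.labels.shape),
            "labels": sorted(int(k) for k in phantom.models),
            "models": {str(k): m.to_json() for k, m in phantom.models.items()},
        },
    }
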