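"""Per-pixel lifetime mapping of histogram image stacks.

A stack is a 3-D count array ``(M, ny, nx)`` — one page per time bin —
with metadata ``h`` (bin width, ns).  Any scalar estimator is applied
independently per pixel; pixels with too few counts or estimator-invalid
results are masked (NaN in the lifetime map), never imputed.

Gate counts are derived from the binned stack by summing bins, prorating
linearly inside a bin when a gate edge does not land on a bin boundary;
rebinned (coarser) histograms for IEM are formed the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .estimators import (biexp_fit, cmm_centroid_ratio, default_omega_lut,
                         grld_ratio_root, simpson_weights)
from .core import Histogram

__all__ = [
    "LifetimeImage",
    "map_estimator",
    "region_stats",
    "contrast_report",
    "fractional_rebin",
    "gate_sums",
    "write_stack",
    "read_stack",
    "write_lifetime_image",
]


@dataclass(frozen=True)
class LifetimeImage:
    """Per-pixel lifetime map with intensity and validity companions."""

    tau: np.ndarray        # 2-D, ns; NaN where invalid
    intensity: np.ndarray  # 2-D, total counts per pixel
    valid: np.ndarray      # 2-D bool
    estimator: str
    settings: dict

    def __post_init__(self):
        if not (self.tau.shape == self.intensity.shape == self.valid.shape):
            raise ValueError("maps must share extent")

    def masked_tau(self) -> np.ndarray:
        return np.where(self.valid, self.tau, np.nan)


def fractional_rebin(stack: np.ndarray, m_out: int) -> np.ndarray:
    """Rebin the time axis to ``m_out`` equal bins, prorating edge bins.

    Exact (pure aggregation) when ``M % m_out == 0``; otherwise counts in
    a bin straddling an output edge are split linearly by overlap length.
    """
    M = stack.shape[0]
    if m_out == M:
        return stack.astype(float)
    edges = np.linspace(0.0, M, m_out + 1)
    out = np.empty((m_out,) + stack.shape[1:], dtype=float)
    cum = np.concatenate([np.zeros((1,) + stack.shape[1:]),
                          np.cumsum(stack, axis=0)], axis=0)

    def cum_at(pos: float):
        i = int(np.floor(pos))
        if i >= M:
            return cum[M]
        frac = pos - i
        return cum[i] + frac * (cum[i + 1] - cum[i])

    lo = cum_at(edges[0])
    for k in range(m_out):
        hi = cum_at(edges[k + 1])
        out[k] = hi - lo
        lo = hi
    return out


def gate_sums(stack: np.ndarray, h: float, S: float, R: float):
    """Per-pixel two-gate counts (n1, n2) with gate width equal to the
    stack window divided by R: gate 1 ``[0, hg)``, gate 2 ``[S*hg, R*hg)``."""
    M = stack.shape[0]
    hg_bins = M / R  # gate width in stack bins so that R*hg = T
    cum = np.concatenate([np.zeros((1,) + stack.shape[1:]),
                          np.cumsum(stack, axis=0)], axis=0)

    def cum_at(pos: float):
        i = int(np.floor(pos))
        if i >= M:
            return cum[M]
        return cum[i] + (pos - i) * (cum[i + 1] - cum[i])

    n1 = cum_at(hg_bins) - cum_at(0.0)
    n2 = cum_at(R * hg_bins) - cum_at(S * hg_bins)
    return n1, n2, hg_bins * h


def map_estimator(stack: np.ndarray, h: float, estimator: str, *,
                  settings: dict | None = None,
                  min_counts: float = 50.0) -> LifetimeImage:
    """Apply an estimator per pixel to a histogram stack.

    Parameters
    ----------
    stack : (M, ny, nx) array of counts
    h : bin width in ns
    estimator : one of ``rld2, grld, iem, cmm, rld_m, tau_ave``
        ``tau_ave`` maps the amplitude-weighted mean lifetime via global
        analysis: a pooled-histogram bi-exponential fit fixes the
        lifetime pair, per-pixel NNLS unmixes the component amplitudes.
    settings : estimator settings (``S``, ``R`` for grld; ``M`` for a
        rebinned IEM; ``lut`` for cmm; ``M_fit`` rebin factor for tau_ave)
    min_counts : pixels with fewer total counts are masked.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (M, ny, nx)")
    settings = dict(settings or {})
    est = estimator.lower()
    M = stack.shape[0]
    intensity = stack.sum(axis=0).astype(float)
    enough = intensity >= min_counts
    flat = stack.reshape(M, -1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        if est == "rld2":
            n1, n2, hg = gate_sums(stack, h, 1.0, 2.0)
            tau = np.where((n1 > n2) & (n2 > 0), hg / np.log(n1 / n2), np.nan)
        elif est in ("grld", "cgrld", "ugrld"):
            S, R = settings.get("S", 0.2), settings.get("R", 3.2)
            n1, n2, hg = gate_sums(stack, h, S, R)
            ratio = np.where(n1 > 0, n2 / np.maximum(n1, 1e-300), np.nan)
            x = grld_ratio_root(ratio, S, R)
            tau = -hg / np.log(x)
        elif est == "iem":
            m_iem = settings.get("M", M if M % 2 == 1 else None)
            if m_iem is None or m_iem % 2 == 0:
                raise ValueError("iem needs an odd bin count; pass settings={'M': odd}")
            sub = fractional_rebin(stack, m_iem).reshape(m_iem, -1)
            w = simpson_weights(m_iem)
            den = sub[0] - sub[-1]
            h_iem = h * M / m_iem
            tau = np.where(den > 0, h_iem * (w @ sub) / den, np.nan)
            tau = tau.reshape(stack.shape[1:])
        elif est == "cmm":
            lut = settings.get("lut") or default_omega_lut()
            ratio = cmm_centroid_ratio(flat.T)
            u = lut(np.where(ratio < 0.5, ratio, np.nan))
            tau = (np.asarray(u) * M * h).reshape(stack.shape[1:])
        elif est in ("rld_m", "rldm"):
            m = M
            t = np.arange(m) * h
            ok = np.all(flat > 0, axis=0)
            ln = np.log(np.maximum(flat, 1e-300))
            num = t.sum() ** 2 - m * (t * t).sum()
            den = m * (t @ ln) - t.sum() * ln.sum(axis=0)
            tau = np.where(ok & (den < 0), num / den, np.nan)
            tau = tau.reshape(stack.shape[1:])
        elif est == "tau_ave":
            # global analysis: one bi-exponential fit on the pooled image
            # histogram fixes the lifetime pair; per-pixel non-negative
            # linear unmixing of the two component shapes then gives the
            # amplitudes entering the weighted mean.  Per-pixel free
            # bi-exponential fits are far noisier at typical pixel counts.
            m_fit = min(settings.get("M_fit", 64), M)
            sub = fractional_rebin(stack, m_fit).reshape(m_fit, -1)
            h_fit = h * M / m_fit
            pooled = biexp_fit(Histogram(sub.sum(axis=1), h_fit))
            if not pooled.valid:
                raise ArithmeticError("pooled bi-exponential fit failed: "
                                      + pooled.diagnostic)
            taus_c = np.array([pooled.tau1, pooled.tau2])
            j = np.arange(m_fit)[:, None]
            x_c = np.exp(-h_fit / taus_c)[None, :]
            design = taus_c[None, :] * x_c**j * (1.0 - x_c)  # counts per unit A
            from scipy.optimize import nnls

            tau = np.full(sub.shape[1], np.nan)
            for i in range(sub.shape[1]):
                if sub[:, i].sum() < min_counts:
                    continue
                amps, _ = nnls(design, sub[:, i])
                if amps.sum() > 0:
                    tau[i] = float(amps @ taus_c / amps.sum())
            tau = tau.reshape(stack.shape[1:])
            settings = {**settings, "tau1": pooled.tau1, "tau2": pooled.tau2}
        else:
            raise ValueError(f"unknown estimator {estimator!r}")

    tau = np.asarray(tau, dtype=float).reshape(stack.shape[1:])
    valid = enough & np.isfinite(tau) & (tau > 0)
    tau = np.where(valid, tau, np.nan)
    public_settings = {k: v for k, v in settings.items() if k != "lut"}
    return LifetimeImage(tau=tau, intensity=intensity, valid=valid,
                         estimator=estimator, settings=public_settings)


def region_stats(img: LifetimeImage, labels: np.ndarray,
                 hist_bins: int = 40) -> dict[int, dict]:
    """Per-label mean/sd/count and a lifetime histogram over valid pixels.

    Histogram range is the 1st-99th percentile of each label's valid
    lifetimes, fixed-width bins.  Empty labels yield an empty summary.
    """
    if labels.shape != img.tau.shape:
        raise ValueError("labels must match image extent")
    out = {}
    for lbl in np.unique(labels):
        sel = (labels == lbl) & img.valid
        vals = img.tau[sel]
        if vals.size == 0:
            out[int(lbl)] = {"n": 0, "mean": np.nan, "sd": np.nan,
                             "hist": (np.array([]), np.array([]))}
            continue
        lo, hi = np.percentile(vals, [1, 99])
        if hi <= lo:
            hi = lo + 1e-9
        counts, edges = np.histogram(vals, bins=hist_bins, range=(lo, hi))
        out[int(lbl)] = {"n": int(vals.size), "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "hist": (counts, edges)}
    return out


def contrast_report(imgs: list[LifetimeImage], labels: np.ndarray,
                    region_a: int = 1, region_b: int = 0) -> dict:
    """Inter-region contrast per method and pixelwise cross-method agreement.

    Contrast is ``|mean_b - mean_a| / pooled sd`` over valid pixels.  For
    every method pair the report includes the Pearson correlation and the
    least-squares slope of method-j lifetimes regressed on method-i
    lifetimes over the pixels valid in both.
    """
    if len(imgs) < 2:
        raise ValueError("need at least two images")
    per_method = {}
    for img in imgs:
        stats = region_stats(img, labels)
        sa, sb = stats[region_a], stats[region_b]
        na, nb = sa["n"], sb["n"]
        pooled = np.sqrt(((na - 1) * sa["sd"] ** 2 + (nb - 1) * sb["sd"] ** 2)
                         / max(na + nb - 2, 1))
        per_method[img.estimator] = {
            "mean_a": sa["mean"], "mean_b": sb["mean"],
            "pooled_sd": float(pooled),
            "contrast": float(abs(sb["mean"] - sa["mean"]) / pooled)
            if pooled > 0 else np.inf,
        }
    pairs = {}
    for i, a in enumerate(imgs):
        for b in imgs[i + 1:]:
            both = a.valid & b.valid
            xa, xb = a.tau[both], b.tau[both]
            slope = float(np.polyfit(xa, xb, 1)[0])
            r = float(np.corrcoef(xa, xb)[0, 1])
            pairs[(a.estimator, b.estimator)] = {"slope": slope, "corr": r,
                                                 "n": int(both.sum())}
    return {"methods": per_method, "pairs": pairs}


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O


def write_stack(path, stack: np.ndarray, sidecar: dict) -> None:
    """Multi-page TIFF (page = time bin, uint32) plus a JSON sidecar."""
    import tifffile

    tifffile.imwrite(path, stack.astype(np.uint32))
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_stack(path) -> tuple[np.ndarray, dict]:
    import tifffile

    stack = tifffile.imread(path)
    try:
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"stack sidecar {path}.json with h_ns/M metadata is required") from exc
    return np.asarray(stack), sidecar


def write_lifetime_image(path, img: LifetimeImage, extra_meta: dict | None = None) -> None:
    """32-bit float TIFF with NaN sentinel + JSON sidecar of settings."""
    import tifffile

    tifffile.imwrite(path, img.masked_tau().astype(np.float32))
    meta = {"estimator": img.estimator, "settings": img.settings}
    meta.update(extra_meta or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
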