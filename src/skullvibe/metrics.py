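"""FRF similarity metrics and robust cross-sensor aggregation.

Three scaled metrics compare a pair of complex FRFs on a shared
frequency grid, each mapping to [0, 1] (1 = perfect agreement):

* **CSAC** (cross-signature assurance criterion) — shape correlation,
  the squared normalized inner product of the two spectra.  Sensitive
  to resonance locations, blind to global scale and phase rotation.
* **CSSF2** (cross-signature scale factor, magnitude variant) —
  amplitude agreement from the magnitudes alone, independent of CSAC:
  2 sum|H1||H2| / (sum|H1|^2 + sum|H2|^2).  Equals 1 iff the magnitude
  spectra are identical; a uniform scale factor alpha gives
  2 alpha / (1 + alpha^2).
* **FRFSM** — overall dB-scale similarity: the per-bin dB error is
  weighted by a Gaussian of width sigma0 (default 6 dB) and averaged.

Scores across a sensor array are summarized robustly by the median and
the scaled median absolute deviation (MAD, consistency constant
b = 1.4826 for normally distributed scores), reported as the pair
(median, 2 * MAD).

The published sources for these metrics leave some freedom (the CSSF2
variant and the FRFSM sigma0 in particular); the operational
definitions above are this package's frozen contract, and sigma0 is
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .frf import FRFSet

#: MAD consistency constant for normally distributed data,
#: 1 / Phi^{-1}(3/4).
MAD_CONSISTENCY = 1.4826

#: Relative magnitude floor applied before taking logs in FRFSM.
FRFSM_FLOOR = 1e-30


def _check_pair(H1, H2):
    H1 = np.asarray(H1, complex).ravel()
    H2 = np.asarray(H2, complex).ravel()
    if H1.shape != H2.shape or H1.size == 0:
        raise ValueError("spectra must be nonempty and on the same grid")
    return H1, H2


def csac(H1, H2) -> float:
    """Shape correlation |<H1, H2>|^2 / (||H1||^2 ||H2||^2)."""
    H1, H2 = _check_pair(H1, H2)
    n1 = np.sum(np.abs(H1) ** 2)
    n2 = np.sum(np.abs(H2) ** 2)
    if n1 == 0 or n2 == 0:
        raise ValueError("CSAC undefined for a zero spectrum")
    return float(np.abs(np.vdot(H1, H2)) ** 2 / (n1 * n2))


def cssf2(H1, H2) -> float:
    """Magnitude-only scale similarity 2 sum|H1||H2| / (sum|H1|^2 + sum|H2|^2)."""
    H1, H2 = _check_pair(H1, H2)
    a1, a2 = np.abs(H1), np.abs(H2)
    denom = np.sum(a1**2) + np.sum(a2**2)
    if denom == 0:
        raise ValueError("CSSF2 undefined for two zero spectra")
    return float(2.0 * np.sum(a1 * a2) / denom)


def frfsm(H1, H2, sigma0: float = 6.0) -> float:
    """Gaussian-weighted dB-error similarity.

    eps_k = | 20 log10|H1_k| - 20 log10|H2_k| |,
    score = mean_k exp( -eps_k^2 / (2 sigma0^2) ).
    Magnitudes are floored at FRFSM_FLOOR times the pair maximum so
    zero bins stay finite (and score 0 against nonzero bins).
    """
    if sigma0 <= 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    H1, H2 = _check_pair(H1, H2)
    a1, a2 = np.abs(H1), np.abs(H2)
    floor = FRFSM_FLOOR * max(a1.max(), a2.max())
    if floor == 0:
        return 1.0  # two identically zero spectra are identical
    eps = 20.0 * np.abs(np.log10(np.maximum(a1, floor))
                        - np.log10(np.maximum(a2, floor)))
    return float(np.mean(np.exp(-(eps**2) / (2.0 * sigma0**2))))


METRICS = {"CSAC": csac, "CSSF2": cssf2, "FRFSM": frfsm}


def robust_summary(scores, b: float = MAD_CONSISTENCY):
    """Median and scaled MAD of per-sensor scores.

    Returns (median, 2 * b * median|s - median|), the reporting
    convention used throughout: the half-width 2*MAD plays the role of
    a robust confidence interval.
    """
    s = np.asarray(scores, float).ravel()
    if s.size == 0:
        raise ValueError("robust_summary requires at least one score")
    if b <= 0:
        raise ValueError(f"consistency constant must be positive, got {b}")
    med = float(np.median(s))
    mad = b * float(np.median(np.abs(s - med)))
    return med, 2.0 * mad


def smooth_frf(H: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average on log-magnitude and unwrapped phase.

    Window must be odd; window 1 is the identity.  Ends use shrinking
    (reflected) windows so the grid length is preserved.
    """
    H = np.asarray(H, complex).ravel()
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > H.size:
        raise ValueError(f"window {window} exceeds grid length {H.size}")
    if window == 1:
        return H.copy()
    mag = np.abs(H)
    floor = FRFSM_FLOOR * mag.max()
    logmag = np.log(np.maximum(mag, floor))
    phase = np.unwrap(np.angle(H))
    kernel = np.ones(window) / window
    pad = window // 2

    def smooth(x):
        xp = np.pad(x, pad, mode="reflect")
        return np.convolve(xp, kernel, mode="valid")

    return np.exp(smooth(logmag)) * np.exp(1j * smooth(phase))


@dataclass
class SimilarityReport:
    """Per-channel metric scores with robust (median, 2*MAD) summaries."""

    per_channel: dict  # metric name -> {channel: score}
    summary: dict  # metric name -> (median, 2*mad)
    freq_range: tuple
    smoothing_window: int = 1
    frfsm_sigma0: float = 6.0

    def to_json(self, path=None) -> str:
        doc = {
            "frequency_range_hz": list(self.freq_range),
            "smoothing_window": self.smoothing_window,
            "frfsm_sigma0_db": self.frfsm_sigma0,
            "per_channel": self.per_channel,
            "summary": {k: {"median": v[0], "two_mad": v[1]}
                        for k, v in self.summary.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    def __str__(self) -> str:
        lines = [f"FRF similarity over {self.freq_range[0]:g}-"
                 f"{self.freq_range[1]:g} Hz"]
        channels = list(next(iter(self.per_channel.values())))
        for metric, scores in self.per_channel.items():
            med, tm = self.summary[metric]
            lines.append(f"  {metric}: ({med:.3f}, {tm:.3f})")
            lines.append("    " + ", ".join(f"{ch}: {scores[ch]:.3f}"
                                            for ch in channels))
        return "\n".join(lines)


def compare_frf_sets(reference: FRFSet, model: FRFSet,
                     fmin: float = 170.0, fmax: float = 1000.0,
                     smoothing_window: int = 1,
                     frfsm_sigma0: float = 6.0) -> SimilarityReport:
    """Score every shared channel with all three metrics and summarize.

    Both sets are restricted to the common band [fmin, fmax]; grids
    must agree there.  Optional smoothing is applied to both inputs.
    """
    ref = reference.restrict(fmin, fmax)
    mod = model.restrict(fmin, fmax)
    if ref.freq.shape != mod.freq.shape or not np.allclose(ref.freq, mod.freq):
        raise ValueError("reference and model frequency grids differ on "
                         f"[{fmin}, {fmax}] Hz; resample first")
    shared = [c for c in ref.names if c in mod.channels]
    if not shared:
        raise ValueError("no shared channels between the two FRF sets")
    per_channel = {}
    summary = {}
    for name, fn in METRICS.items():
        scores = {}
        for ch in shared:
            h1, h2 = ref[ch], mod[ch]
            if smoothing_window > 1:
                h1 = smooth_frf(h1, smoothing_window)
                h2 = smooth_frf(h2, smoothing_window)
            scores[ch] = (fn(h1, h2, frfsm_sigma0) if name == "FRFSM"
                          else fn(h1, h2))
        per_channel[name] = scores
        summary[name] = robust_summary(list(scores.values()))
    return SimilarityReport(per_channel, summary, (float(ref.freq[0]),
                                                   float(ref.freq[-1])),
                            smoothing_window, frfsm_sigma0)
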