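"""Simulation-based phase classification of motif parameter points.

Reproduces the protocol used to shade the phase diagrams: integrate an
ensemble of constant-history initial conditions, then label the parameter
point from the late-time behavior of every member.

Autoregulation protocol: ``n_ic`` initial conditions spread
logarithmically on [1e-4, 2 eta], integrated to T_end = 100 (gamma + 1).
A point is *stable* when the largest absolute discrete derivative over the
last three-quarters of the run stays below 0.1 for every member; stable
points are *bistable* when the histogram of final values has more than one
peak.  A point is *oscillatory* when the ensemble-averaged amplitude
spectrum of the last three-quarters has at least one peak above the
amplitude threshold, and *spiral* (damped oscillation) when that condition
holds for the first quarter of the run only.

The spectrum protocol is fixed for reproducibility: each window is
resampled onto 8192 uniform points, the mean is removed, the unnormalized
discrete-Fourier magnitude is averaged across members, and strict local
maxima above the threshold count as peaks.  Histogram peaks use 20
equal-width bins over the observed range of final values; a peak is a bin
strictly above both neighbors holding more than 2% of the ensemble (basins
of a genuine second state can be small under the prescribed
initial-condition spread, so the floor only guards against stragglers).

Loop protocol: initial conditions range over 0..max(eta1, eta2) in equal
(X = Y) and apposing (X high/Y low and mirrored) arrangements; bistable
points are annotated correlated (both-high/both-low) or anti-correlated
using the low-state cutoff 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .loops import LoopParams
from .models import build_motif
from .solver import integrate, resample_uniform

__all__ = [
    "ClassifierConfig",
    "ClassificationResult",
    "classify_autoreg_sim",
    "classify_loop_sim",
    "oscillation_features",
]


@dataclass(frozen=True)
class ClassifierConfig:
    n_ic: int = 100
    ic_low: float = 1e-4
    t_end_factor: float = 100.0  # T_end = factor * (gamma + 1)
    deriv_threshold: float = 0.1
    fft_amplitude_threshold: float = 100.0
    low_cutoff: float = 0.05
    histogram_bins: int = 20
    histogram_min_frac: float = 0.02
    n_fft: int = 8192
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_ic < 2:
            raise ValueError("need at least 2 initial conditions")
        if min(self.deriv_threshold, self.fft_amplitude_threshold, self.low_cutoff) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    final_values: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _spectrum_peaks(window: np.ndarray, threshold: float) -> int:
    """Strict local maxima above threshold in the ensemble-mean spectrum.

    ``window`` has shape (n_samples, n_ens); the unnormalized rFFT
    magnitude of each mean-removed member is averaged across the ensemble.
    """
    w = window - window.mean(axis=0, keepdims=True)
    mag = np.abs(np.fft.rfft(w, axis=0)).mean(axis=1)
    # start at bin 2: bin 1 borders the zeroed DC bin, so any monotone
    # (non-oscillatory) relaxation would register a spurious "peak" there
    inner = mag[2:-1]
    peaks = (inner > mag[1:-2]) & (inner > mag[3:]) & (inner > threshold)
    return int(np.count_nonzero(peaks))


def _histogram_peaks(finals: np.ndarray, bins: int, min_frac: float) -> int:
    lo, hi = float(finals.min()), float(finals.max())
    # distinct steady states are separated on the concentration scale; a
    # collapsed range is a single state up to solver tolerance
    if hi - lo < 1e-2 * max(1.0, abs(hi)):
        return 1
    counts, _ = np.histogram(finals, bins=bins, range=(lo, hi))
    padded = np.concatenate([[-1], counts, [-1]])
    inner = padded[1:-1]
    is_peak = (inner > padded[:-2]) & (inner > padded[2:]) & (inner > min_frac * finals.size)
    return int(np.count_nonzero(is_peak))


def _window_samples(traj, t0: float, t1: float, n: int) -> np.ndarray:
    ts = np.linspace(t0, t1, n)
    vals = traj(ts)  # (n, n_nodes, n_ens)
    return vals


def classify_autoreg_sim(
    eta: float, gamma: float, n: float, cfg: ClassifierConfig | None = None
) -> ClassificationResult:
    """Label one autoregulation parameter point by ensemble simulation."""
    cfg = cfg or ClassifierConfig()
    if eta <= 0 or gamma < 0:
        raise ValueError("need eta > 0 and gamma >= 0")
    system = build_motif("autoregulation", eta=eta, n=n, gamma=gamma)
    t_end = cfg.t_end_factor * (gamma + 1.0)
    ics = np.geomspace(cfg.ic_low, 2.0 * eta, cfg.n_ic)
    traj = integrate(system, ics[None, :], t_end, rtol=cfg.rtol, atol=cfg.atol)

    tail = _window_samples(traj, 0.25 * t_end, t_end, cfg.n_fft)[:, 0, :]
    head = _window_samples(traj, 0.0, 0.25 * t_end, cfg.n_fft)[:, 0, :]
    dt_tail = 0.75 * t_end / (cfg.n_fft - 1)
    max_deriv = float(np.max(np.abs(np.diff(tail, axis=0) / dt_tail)))
    finals = tail[-1]

    tail_peaks = _spectrum_peaks(tail, cfg.fft_amplitude_threshold)
    head_peaks = _spectrum_peaks(head, cfg.fft_amplitude_threshold)

    diagnostics = {
        "max_deriv": max_deriv,
        "tail_peaks": tail_peaks,
        "head_peaks": head_peaks,
        "t_end": t_end,
    }
    if tail_peaks >= 1:
        label = "oscillatory"
    elif max_deriv < cfg.deriv_threshold:
        hist_peaks = _histogram_peaks(finals, cfg.histogram_bins, cfg.histogram_min_frac)
        diagnostics["hist_peaks"] = hist_peaks
        if hist_peaks > 1:
            label = "bistable"
        elif head_peaks >= 1:
            label = "monostable_spiral"
        else:
            label = "monostable"
    else:
        # not settled and no sustained spectral peak: call it oscillatory
        # only on spectral evidence; otherwise report as unresolved
        label = "unresolved"
    return ClassificationResult(label=label, final_values=finals, diagnostics=diagnostics)


def classify_loop_sim(p: LoopParams, cfg: ClassifierConfig | None = None) -> ClassificationResult:
    """Label a two-component loop point; bistable points get a mode annotation."""
    cfg = cfg or ClassifierConfig()
    system = build_motif(
        "loop",
        eta1=p.eta1,
        eta2=p.eta2,
        n1=p.n1,
        n2=p.n2,
        gamma1=p.gamma1,
        gamma2=p.gamma2,
    )
    t_end = cfg.t_end_factor * (p.mean_delay + 1.0)
    half = cfg.n_ic // 2
    top = max(p.eta1, p.eta2)
    lev = np.linspace(cfg.ic_low, top, half)
    # equal and apposing X/Y arrangements
    x0 = np.concatenate([lev, lev, lev[::-1]])
    y0 = np.concatenate([lev, lev[::-1], lev])
    traj = integrate(system, np.vstack([x0, y0]), t_end, rtol=cfg.rtol, atol=cfg.atol)

    tail = _window_samples(traj, 0.25 * t_end, t_end, cfg.n_fft)
    dt_tail = 0.75 * t_end / (cfg.n_fft - 1)
    max_deriv = float(np.max(np.abs(np.diff(tail, axis=0) / dt_tail)))
    finals_x = tail[-1, 0, :]
    finals_y = tail[-1, 1, :]
    tail_peaks = _spectrum_peaks(tail[:, 0, :], cfg.fft_amplitude_threshold)

    diagnostics = {"max_deriv": max_deriv, "tail_peaks": tail_peaks, "t_end": t_end}
    if tail_peaks >= 1:
        label = "oscillatory"
    elif max_deriv < cfg.deriv_threshold:
        both = np.concatenate([finals_x, finals_y])
        hist_peaks = _histogram_peaks(both, cfg.histogram_bins, cfg.histogram_min_frac)
        diagnostics["hist_peaks"] = hist_peaks
        if hist_peaks > 1:
            # split each member's final (X, Y) into low/high with the cutoff
            # taken relative to the observed state range (floor 0.05)
            thr = max(cfg.low_cutoff, 0.5 * (float(both.min()) + float(both.max())))
            x_low = finals_x < thr
            y_low = finals_y < thr
            anti = np.count_nonzero(x_low != y_low)
            corr = np.count_nonzero(x_low == y_low)
            mode = "anti_correlated" if anti > corr else "correlated"
            diagnostics["bistable_mode"] = mode
            label = f"bistable_{mode}"
        else:
            label = "monostable"
    else:
        label = "unresolved"
    return ClassificationResult(
        label=label, final_values=np.vstack([finals_x, finals_y]), diagnostics=diagnostics
    )


def oscillation_features(series: np.ndarray, dt: float, threshold: float = 100.0) -> dict:
    """Peak count, dominant period and amplitude of a uniform series."""
    series = np.asarray(series, dtype=float)
    if series.size < 16:
        raise ValueError("need at least 16 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = series - series.mean()
    mag = np.abs(np.fft.rfft(v))
    freqs = np.fft.rfftfreq(series.size, d=dt)
    inner = mag[1:-1]
    peak_mask = (inner > mag[:-2]) & (inner > mag[2:]) & (inner > threshold)
    n_peaks = int(np.count_nonzero(peak_mask))
    k = int(np.argmax(mag[1:])) + 1
    period = 1.0 / freqs[k] if freqs[k] > 0 else math.inf
    amplitude = 2.0 * mag[k] / series.size
    return {"peak_count": n_peaks, "dominant_period": float(period), "amplitude": float(amplitude)}
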