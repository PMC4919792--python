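"""Spike detection via Cepstrum of Bispectrum (CoB) inverse filtering.

The channel voltage is modelled as a skewed impulse process driven through
a linear filter (the spike waveform) plus Gaussian noise.  The bispectrum
of the voltage factorises over the filter's frequency response,

    B_v(n, m) = xi * F(n) F(m) F*(n + m),

while the bispectrum of Gaussian noise vanishes, so the transfer function
F can be reconstructed from B alone: its log-magnitude from a slice of the
bicepstrum (the 2-D inverse Fourier transform of log|B|) and its phase
from the recursion implied by the B(1, n) slice.  Inverse filtering the
voltage through a regularised 1/F then concentrates each spike back into
a sharp pulse at its peak sample, which survives thresholding even at low
SNR.  The filtered trace is denoised with an undecimated coiflet wavelet
transform before peak picking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats as sstats

from selsort.synthgen import Recording, DEFAULT_REFRACTORY


@dataclass
class CobConfig:
    """Controls for bispectrum estimation, denoising and thresholding."""

    segment_length: int = 1024
    overlap_fraction: float = 0.5
    taper: str = "hann"
    skewness_xi: float | None = None  # scale only; estimated when None
    swt_level: int = 4
    wavelet_order: int = 3  # coiflet order for the SWT denoiser
    threshold_k: float = 4.0
    inverse_epsilon: float = 0.05  # Tikhonov floor relative to max|F|
    relative_floor: float = 0.15  # threshold floor as a fraction of the top peak
    silent_ratio: float = 200.0  # peak/MAD ratio marking a silent background
    max_segments: int = 256  # cap on segments averaged into B
    min_event_gap: int = 3  # samples between distinct events
    refine_radius: int = 3  # snap events to the raw-trace peak
    raw_check_k: float = 2.5  # events must clear this many raw-noise SDs

    def __post_init__(self):
        L = self.segment_length
        if L < 64 or (L & (L - 1)) != 0:
            raise ValueError("segment_length must be a power of two >= 64")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def wavelet(self) -> str:
        return f"coif{self.wavelet_order}"


@dataclass
class EventIndex:
    """Sorted unique sample positions of detected events."""

    indices: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class WaveformMatrix:
    """Peak-aligned spike snippets, one row per retained event."""

    waveforms: np.ndarray  # (M, window)
    align_index: int
    event_indices: np.ndarray
    interp_factor: int = 1
    n_edge_dropped: int = 0

    def __post_init__(self):
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=np.float64))
        self.event_indices = np.asarray(self.event_indices, dtype=np.int64)

    @property
    def n_waveforms(self) -> int:
        return self.waveforms.shape[0]


def _segments(x: np.ndarray, cfg: CobConfig) -> np.ndarray:
    L = cfg.segment_length
    step = max(1, int(round(L * (1.0 - cfg.overlap_fraction))))
    starts = np.arange(0, x.size - L + 1, step)
    if starts.size > cfg.max_segments:
        sel = np.linspace(0, starts.size - 1, cfg.max_segments).round().astype(int)
        starts = starts[np.unique(sel)]
    return np.stack([x[s:s + L] for s in starts])


def estimate_bispectrum(rec: Recording, cfg: CobConfig) -> np.ndarray:
    """Average third-order spectral moment over tapered segments.

    Returns the full L x L complex matrix B(n, m) = <V(n) V(m) V*(n+m)>
    on the FFT grid (frequency indices wrap modulo L).  Symmetric in its
    two arguments by construction.
    """
    x = np.asarray(rec.samples, dtype=np.float64)
    L = cfg.segment_length
    if x.size < L:
        raise ValueError(
            f"trace length {x.size} shorter than one segment ({L})"
        )
    x = x - x.mean()
    segs = _segments(x, cfg)
    win = sps.get_window(cfg.taper, L, fftbins=True)
    V = np.fft.fft(segs * win, axis=1)
    idx = (np.arange(L)[:, None] + np.arange(L)[None, :]) % L
    B = np.zeros((L, L), dtype=np.complex128)
    outer = np.empty((L, L), dtype=np.complex128)
    conj_sum = np.empty((L, L), dtype=np.complex128)
    for v in V:
        np.multiply(v[:, None], v[None, :], out=outer)
        np.take(np.conj(v), idx, out=conj_sum)
        outer *= conj_sum
        B += outer
    B /= V.shape[0]
    return B


class CobFilter(NamedTuple):
    """Inverse filter and its application to the trace."""

    f_inv: np.ndarray  # FIR kernel, zero lag at the centre tap
    filtered: np.ndarray  # trace convolved with f_inv, same length
    f_est: np.ndarray  # reconstructed transfer function f(t), peak at 0


def _reconstruct_transfer(B: np.ndarray) -> np.ndarray:
    """Recover f(t) from the bispectrum, peak rolled to sample 0.

    Log-magnitude comes from the q=0 slice of the bicepstrum of log|B|.
    The phase uses the factorisation arg B(k, s-k) = phi(k) + phi(s-k)
    - phi(s): every split k of frequency s gives an estimate of phi(s),
    and the estimates are averaged circularly with |B| weights, which
    keeps the recursion stable when single slices are noisy.  The
    remaining linear-phase/scale ambiguities are fixed by rolling the
    impulse response so its dominant peak sits at lag 0, matching the
    peak-marking time convention.
    """
    L = B.shape[0]
    mag = np.abs(B)
    logmag = np.log(mag + mag.max() * 1e-15 + 1e-300)
    bicep = np.real(np.fft.ifft2(logmag))
    c = bicep[:, 0].copy()
    c[0] = 0.0
    c = 0.5 * (c + np.roll(c[::-1], 1))  # enforce even real cepstrum
    logF = np.real(np.fft.fft(c))
    logF = np.clip(logF, -40.0, 40.0)
    Fmag = np.exp(logF)

    phi = np.zeros(L)
    angB = np.angle(B)
    for s in range(2, L // 2 + 1):
        k = np.arange(1, s)
        est = phi[k] + phi[s - k] - angB[k, s - k]
        wgt = mag[k, s - k]
        phi[s] = np.angle(np.sum(wgt * np.exp(1j * est)))
    F = Fmag.astype(np.complex128)
    half = np.arange(1, L // 2)
    F[half] = Fmag[half] * np.exp(1j * phi[half])
    F[L - half] = np.conj(F[half])
    F[L // 2] = Fmag[L // 2] * np.cos(phi[L // 2])

    f = np.real(np.fft.ifft(F))
    f = np.roll(f, -int(np.argmax(np.abs(f))))
    if f[0] < 0:
        f = -f
    return f


def cob_inverse_filter(rec: Recording, cfg: CobConfig,
                       transfer: np.ndarray | None = None) -> CobFilter:
    """Build the regularised inverse of the CoB transfer estimate and
    apply it to the trace.

    The filtered output has the input's length; each spike collapses to a
    pulse at (near) its template-peak sample.  Detection positions are
    invariant to amplitude scaling and DC offset of the input.  A known
    ``transfer`` (length ``segment_length``, peak at sample 0) bypasses
    the bispectral estimate — handy for diagnostics against ground truth.
    """
    x = np.asarray(rec.samples, dtype=np.float64)
    x = x - x.mean()
    L = cfg.segment_length
    if not np.any(x):
        warnings.warn("all-zero trace: falling back to a flat (identity) filter")
        f_inv = np.zeros(L)
        f_inv[L // 2] = 1.0
        f_est = np.zeros(L)
        f_est[0] = 1.0
        return CobFilter(f_inv=f_inv, filtered=x.copy(), f_est=f_est)

    if transfer is not None:
        f = np.asarray(transfer, dtype=np.float64)
        if f.size != L:
            raise ValueError("transfer must have segment_length samples")
    else:
        B = estimate_bispectrum(rec, cfg)
        f = _reconstruct_transfer(B)
    F = np.fft.fft(f)
    lam = (cfg.inverse_epsilon * np.abs(F).max()) ** 2
    Finv = np.conj(F) / (np.abs(F) ** 2 + lam)
    h = np.real(np.fft.ifft(Finv))
    h_lin = np.roll(h, L // 2)  # zero-lag tap at index L//2
    filtered = sps.fftconvolve(x, h_lin, mode="full")[L // 2: L // 2 + x.size]
    return CobFilter(f_inv=h_lin, filtered=filtered, f_est=f)


def swt_denoise(x: np.ndarray, cfg: CobConfig) -> np.ndarray:
    """Undecimated coiflet-wavelet denoising with a universal soft threshold.

    The trace is padded to a multiple of 2**level, transformed with the
    stationary wavelet transform, detail coefficients soft-thresholded at
    sigma * sqrt(2 log T) (sigma from the MAD of the finest details), and
    inverted.  Output length equals input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.any(x):
        return x.copy()
    level = cfg.swt_level
    n = x.size
    max_level = max(1, int(np.floor(np.log2(max(n, 2)))) - 1)
    if level > max_level:
        warnings.warn(f"SWT level {level} too deep for length {n}; using {max_level}")
        level = max_level
    block = 1 << level
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="symmetric") if pad else x
    coeffs = pywt.swt(xp, cfg.wavelet, level=level, norm=True, trim_approx=True)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(xp.size, 2)))
    if thr <= 0:  # noise-free input: nothing to shrink
        return x.copy()
    den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    y = pywt.iswt(den, cfg.wavelet, norm=True)
    return np.asarray(y[:n], dtype=np.float64)


def threshold_events(x: np.ndarray, cfg: CobConfig) -> EventIndex:
    """Pick local maxima above k robust (MAD-based) standard deviations.

    When the background is (near-)silent the MAD collapses to the
    deconvolution-ripple scale and the rule degenerates; in that regime
    (peak-to-MAD ratio beyond ``silent_ratio``) the threshold is floored
    at ``relative_floor`` times the largest sample.  Peaks closer than
    ``min_event_gap`` samples are pruned keeping the larger one (ties
    keep the earlier index).  May return empty.
    """
    x = np.asarray(x, dtype=np.float64)
    robust_sd = sstats.median_abs_deviation(x, scale="normal")
    thr = cfg.threshold_k * robust_sd
    if robust_sd == 0 or x.max() > cfg.silent_ratio * robust_sd:
        thr = max(thr, cfg.relative_floor * x.max())
    if thr <= 0:
        thr = np.finfo(float).tiny
    peaks, _ = sps.find_peaks(x, height=thr, distance=max(1, cfg.min_event_gap))
    return EventIndex(indices=peaks, source="cob")


def _refine_on_raw(raw: np.ndarray, indices: np.ndarray, radius: int) -> np.ndarray:
    """Snap each event to the raw-trace local maximum within +/- radius."""
    if radius <= 0 or indices.size == 0:
        return indices
    out = []
    for t in indices:
        a, b = max(0, t - radius), min(raw.size, t + radius + 1)
        cand = a + int(np.argmax(raw[a:b]))
        out.append(cand)
    out = np.asarray(out, dtype=np.int64)
    # never merge two distinct events by snapping onto the same sample
    keep = np.ones(out.size, dtype=bool)
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = indices[i]
    return np.unique(out)


def detect_spikes(rec: Recording, cfg: CobConfig | None = None) -> EventIndex:
    """Full CoB detection: inverse filter, SWT denoise, threshold, refine.

    The final refinement snaps each event to the local maximum of the raw
    trace within ``refine_radius`` samples, since a spike time marks the
    template's peak sample, and discards events whose raw amplitude sits
    below ``raw_check_k`` robust noise SDs — the regularised inverse
    filter rings slightly around strong spikes, and those echoes have no
    raw-trace support.  Deterministic for fixed input.
    """
    cfg = cfg or CobConfig()
    x = np.asarray(rec.samples, dtype=np.float64)
    if not np.any(x - x.mean()):
        return EventIndex(indices=np.empty(0, dtype=np.int64), source="cob")
    cob = cob_inverse_filter(rec, cfg)
    den = swt_denoise(cob.filtered, cfg)
    ev = threshold_events(den, cfg)
    xc = x - x.mean()
    refined = _refine_on_raw(xc, ev.indices, cfg.refine_radius)
    if cfg.raw_check_k > 0 and refined.size:
        raw_sd = sstats.median_abs_deviation(xc, scale="normal")
        refined = refined[xc[refined] >= cfg.raw_check_k * raw_sd]
    return EventIndex(indices=refined, source="cob")


_BASELINE_STATS = ("noise_sd", "rms", "channel_sd")


def baseline_detect(rec: Recording, method: str, k: float,
                    min_gap: int = 3) -> EventIndex:
    """Conventional hard-threshold detectors used for comparison.

    ``noise_sd`` thresholds at k times the robust (median-based) estimate
    of the background-noise SD, ``rms`` at k times the root mean square of
    the channel, ``channel_sd`` at k times the channel's SD.  Peak picking
    uses the same minimum-gap rule as the CoB detector.
    """
    if method not in _BASELINE_STATS:
        raise ValueError(f"unknown baseline method {method!r}")
    x = np.asarray(rec.samples, dtype=np.float64)
    x = x - x.mean()
    if method == "noise_sd":
        stat = sstats.median_abs_deviation(x, scale="normal")
    elif method == "rms":
        stat = float(np.sqrt(np.mean(x**2)))
    else:
        stat = float(np.std(x))
    thr = k * stat
    if thr <= 0:
        thr = np.finfo(float).tiny
    peaks, _ = sps.find_peaks(x, height=thr, distance=max(1, min_gap))
    return EventIndex(indices=peaks, source=method)


def extract_waveforms(rec: Recording, events: EventIndex, window: int = 61,
                      align_index: int = 20, interp_factor: int = 1) -> WaveformMatrix:
    """Extract one peak-aligned snippet per retained event.

    Windows are half-open ``[t - align_index, t - align_index + window)``.
    Events whose window would cross a trace edge are dropped (counted);
    events falling inside an already-extracted window are treated as
    secondary peaks and do not spawn extra rows (the larger peak wins).
    Each row is re-centred so its maximum sits exactly at ``align_index``;
    ``interp_factor > 1`` refines the peak on a cubic-spline upsampled
    grid before decimating back.
    """
    if window < 8:
        raise ValueError("window must be at least 8 samples")
    if not 0 <= align_index < window:
        raise ValueError("align_index must lie inside the window")
    x = np.asarray(rec.samples, dtype=np.float64)
    T = x.size

    # secondary-peak suppression: keep the largest peak among events
    # packed closer than half a window
    retained: list[int] = []
    for t in np.asarray(events.indices, dtype=np.int64):
        if retained and t - retained[-1] < window // 2:
            if x[t] > x[retained[-1]]:
                retained[-1] = int(t)
            continue
        retained.append(int(t))

    rows, kept, dropped = [], [], 0
    for t in retained:
        t_al = _align_event(x, t, window, align_index)
        if t_al is None:
            dropped += 1
            continue
        a = t_al - align_index
        row = x[a:a + window].copy()
        if interp_factor > 1:
            row = _subsample_align(x, t_al, window, align_index, interp_factor)
            if row is None:
                dropped += 1
                continue
        rows.append(row)
        kept.append(t_al)
    wf = np.asarray(rows) if rows else np.empty((0, window))
    return WaveformMatrix(
        waveforms=wf,
        align_index=align_index,
        event_indices=np.asarray(kept, dtype=np.int64),
        interp_factor=interp_factor,
        n_edge_dropped=dropped,
    )


def _align_event(x, t, window, align_index, max_iter=4):
    """Walk the event to the window's local maximum; None if near an edge."""
    for _ in range(max_iter):
        a = t - align_index
        if a < 0 or a + window > x.size:
            return None
        p = int(np.argmax(x[a:a + window]))
        if p == align_index:
            return t
        t = a + p
    a = t - align_index
    if a < 0 or a + window > x.size:
        return None
    return t


def _subsample_align(x, t, window, align_index, factor):
    """Cubic-spline sub-sample alignment: re-grid so the interpolated
    peak lands exactly on the align index, then decimate."""
    from scipy.interpolate import CubicSpline

    a = t - align_index
    lo, hi = a - 2, a + window + 2
    if lo < 0 or hi > x.size:
        return None
    cs = CubicSpline(np.arange(lo, hi), x[lo:hi])
    fine = np.arange(t - 1, t + 1, 1.0 / (4 * factor))
    t_fine = fine[int(np.argmax(cs(fine)))]
    grid = (np.arange(window) - align_index) + t_fine
    row = cs(np.clip(grid, lo, hi - 1))
    if int(np.argmax(row)) != align_index:  # flat peak fallback
        row = x[a:a + window].copy()
    return row
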