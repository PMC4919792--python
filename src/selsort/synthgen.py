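"""Generative model for single-channel extracellular voltage.

The channel voltage is modelled as a sum over neurons of a binary impulse
train convolved with that neuron's characteristic spike waveform, plus
low-amplitude activity from distant "neighbour" neurons and additive
Gaussian noise:

    v(t) = sum_n (delta_n * w_n)(t) + neighbour(t) + eta(t)

A spike time marks the sample at which the template's (positive) peak is
placed; all indices are 0-based.  The module also reads and writes the
MAT-file dialect of the public simulated spike-sorting benchmark
(C_Difficult1_noise(XX)-style files: a raw trace, a spike-time vector and
a class-label vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.io as sio

from selsort.io import FileFormatError

DEFAULT_SAMPLING_RATE = 24000.0
#: template span: ~2.5 ms at 24 kHz
DEFAULT_TAU = 60
DEFAULT_REFRACTORY = 60


@dataclass
class Recording:
    """A single-channel voltage trace."""

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("recording must be a non-empty 1-D trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class GroundTruth:
    """True per-neuron spike times, templates and noise level."""

    spike_times: list  # per-neuron sorted sample indices
    templates: np.ndarray | None  # (N, tau) or None when unknown
    noise_sigma: float = 0.0
    refractory: int = DEFAULT_REFRACTORY

    def __post_init__(self):
        self.spike_times = [
            np.asarray(st, dtype=np.int64) for st in self.spike_times
        ]
        for st in self.spike_times:
            if st.size > 1:
                gaps = np.diff(st)
                if np.any(gaps <= 0):
                    raise ValueError("spike times must be strictly increasing")
                if np.any(gaps < self.refractory):
                    raise ValueError("inter-spike interval below refractory")
        if self.templates is not None:
            self.templates = np.asarray(self.templates, dtype=np.float64)
            if self.templates.ndim != 2:
                raise ValueError("templates must be an (N, tau) matrix")
            if self.templates.shape[0] != len(self.spike_times):
                raise ValueError("one template per neuron required")

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def tau(self) -> int:
        return 0 if self.templates is None else self.templates.shape[1]

    def total_spikes(self) -> int:
        return int(sum(st.size for st in self.spike_times))


@dataclass
class SimConfig:
    """Parameters of the generative model.

    ``firing_rates`` are per-sample spike probabilities (e.g. 0.0008 per
    sample at 24 kHz is about 19 spikes/s).  ``noise_level`` and
    ``neighbour_amplitude`` are fractions of the unit template peak.
    ``overlap_rate`` forces near-coincident cross-neuron spike pairs to
    exercise overlap resolution.
    """

    duration: int = 24000 * 60
    firing_rates: Sequence[float] = (0.0008, 0.0008, 0.0008)
    noise_level: float = 0.1
    neighbour_amplitude: float = 0.0
    seed: int = 0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    tau: int = DEFAULT_TAU
    refractory: int = DEFAULT_REFRACTORY
    overlap_rate: float = 0.0
    n_neighbours: int = 2
    neighbour_rate: float = 0.002

    def __post_init__(self):
        if any(r < 0 for r in self.firing_rates):
            raise ValueError("firing rates must be non-negative")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


def _biphasic(tau: int, peak: int, rise: float, trough_delay: float,
              trough_width: float, trough_depth: float,
              predip_depth: float) -> np.ndarray:
    """Sum-of-Gaussians biphasic waveform with positive peak at ``peak``."""
    x = np.arange(tau, dtype=np.float64)
    w = np.exp(-((x - peak) ** 2) / (2 * rise**2))
    w -= trough_depth * np.exp(
        -((x - peak - trough_delay) ** 2) / (2 * trough_width**2)
    )
    w -= predip_depth * np.exp(-((x - peak + 2.5 * rise) ** 2) / (2 * rise**2))
    w /= w.max()
    return w


def make_templates(n: int, tau: int = DEFAULT_TAU, seed: int = 0) -> list:
    """Generate ``n`` distinct unit-peak biphasic spike templates.

    Templates are sum-of-Gaussians waveforms of length ``tau`` with the
    positive peak at sample ``tau // 3`` and pairwise correlation below
    0.99.  ``n = 0`` returns an empty list; ``tau < 8`` is rejected.
    """
    if n == 0:
        return []
    if n < 0:
        raise ValueError("n must be non-negative")
    if tau < 8:
        raise ValueError("tau must be at least 8 samples")
    rng = np.random.default_rng(seed)
    peak = tau // 3
    templates: list[np.ndarray] = []
    # spread base shapes deterministically, jitter within each slot;
    # widths stay in a narrow band so classes have comparable energy,
    # as in recorded spike classes — distinctness comes from the
    # repolarisation trough and the pre-depolarisation dip instead
    for i in range(n):
        for _attempt in range(200):
            u = rng.random(4)
            rise = 2.0 + 0.35 * (i % 3) + 0.5 * u[0]
            trough_delay = 0.06 * tau + 0.14 * tau * u[1] + 0.04 * tau * (i % 3)
            trough_width = rise * (1.0 + 1.2 * u[2])
            trough_depth = 0.35 + 0.5 * u[3]
            predip = 0.22 * ((i + 1) % 3) / 2
            w = _biphasic(tau, peak, rise, trough_delay, trough_width,
                          trough_depth, predip)
            if int(np.argmax(w)) != peak:
                continue
            # distinct single units on one channel: keep pairwise shape
            # correlation moderate (well under the 0.99 hard bound)
            if all(
                abs(np.corrcoef(w, t)[0, 1]) < 0.92 for t in templates
            ):
                templates.append(w)
                break
        else:  # pragma: no cover - parameter space is wide enough
            raise RuntimeError("could not draw a sufficiently distinct template")
    return templates


def _bernoulli_train(rng, duration: int, rate: float, refractory: int,
                     lo: int, hi: int) -> np.ndarray:
    """Bernoulli-per-sample spiking thinned by an absolute refractory period."""
    if rate <= 0 or duration <= 0:
        return np.empty(0, dtype=np.int64)
    if rate * refractory >= 1.0:
        warnings.warn("firing rate incompatible with refractory period; clipping")
        rate = 0.5 / max(refractory, 1)
    hits = np.flatnonzero(rng.random(duration) < rate)
    kept = []
    last = -np.inf
    for t in hits:
        if t - last >= refractory and lo <= t < hi:
            kept.append(t)
            last = t
    return np.asarray(kept, dtype=np.int64)


def generate_ground_truth(config: SimConfig, templates: Sequence[np.ndarray]) -> GroundTruth:
    """Draw per-neuron impulse trains with refractory enforcement.

    Each neuron spikes as an independent Bernoulli process at its
    configured per-sample rate, thinned so no inter-spike interval falls
    below the refractory span.  With ``overlap_rate > 0`` a fraction of
    spikes additionally trigger a near-coincident spike (within half a
    template length) from another neuron, creating overlap events.
    """
    tmpl = np.asarray(templates, dtype=np.float64)
    if tmpl.size and config.duration <= tmpl.shape[1]:
        raise ValueError("duration must exceed template length")
    n = tmpl.shape[0] if tmpl.size else len(templates)
    rates = list(config.firing_rates)[:n]
    while len(rates) < n:
        rates.append(rates[-1] if rates else 0.0)
    tau = tmpl.shape[1] if tmpl.size else config.tau
    peak = tau // 3
    lo, hi = peak, config.duration - (tau - peak)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    trains = [
        _bernoulli_train(rng, config.duration, r, config.refractory, lo, hi)
        for r in rates
    ]
    if config.overlap_rate > 0 and n >= 2:
        trains = _force_overlaps(rng, trains, tau, config)
    return GroundTruth(
        spike_times=trains,
        templates=tmpl if tmpl.size else None,
        noise_sigma=config.noise_level * (np.abs(tmpl).max() if tmpl.size else 1.0),
        refractory=config.refractory,
    )


def _force_overlaps(rng, trains, tau, config):
    """Inject cross-neuron coincidences: partner spike within tau/2 samples."""
    n = len(trains)
    out = [list(t) for t in trains]
    for i, st in enumerate(trains):
        for t in st:
            if rng.random() >= config.overlap_rate:
                continue
            j = int(rng.integers(n - 1))
            j = j if j < i else j + 1
            lag = int(rng.integers(3, max(4, tau // 2)))
            if rng.random() < 0.5:
                lag = -lag
            cand = t + lag
            existing = np.asarray(out[j])
            if existing.size and np.min(np.abs(existing - cand)) < config.refractory:
                continue
            if 0 <= cand < config.duration:
                out[j].append(cand)
    return [np.asarray(sorted(t), dtype=np.int64) for t in out]


@dataclass
class RenderParts:
    """Additive components of a rendered channel (for audits and oracles)."""

    clean: np.ndarray
    neighbour: np.ndarray
    noise: np.ndarray


def place_templates(duration: int, spike_times, template: np.ndarray,
                    out: np.ndarray | None = None) -> np.ndarray:
    """Add ``template`` at each spike time (peak-aligned) into a trace."""
    if out is None:
        out = np.zeros(duration, dtype=np.float64)
    tau = template.size
    peak = int(np.argmax(np.abs(template)))
    for t in np.asarray(spike_times, dtype=np.int64):
        a = int(t) - peak
        b = a + tau
        ta, tb = max(a, 0), min(b, duration)
        if ta < tb:
            out[ta:tb] += template[ta - a: tb - a]
    return out


def render_channel(truth: GroundTruth, config: SimConfig,
                   with_parts: bool = False):
    """Render the voltage trace for a ground truth under ``config``.

    Deterministic given ``config.seed``; the noise and neighbour streams
    are drawn from fixed sub-seeds so a re-render reproduces the exact
    same components.
    """
    T = config.duration
    clean = np.zeros(T, dtype=np.float64)
    if truth.templates is not None:
        for st, w in zip(truth.spike_times, truth.templates):
            place_templates(T, st, w, out=clean)
    peak_amp = (
        float(np.abs(truth.templates).max()) if truth.templates is not None else 1.0
    )

    neighbour = np.zeros(T, dtype=np.float64)
    if config.neighbour_amplitude > 0 and config.n_neighbours > 0:
        n_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
        n_tmpl = make_templates(config.n_neighbours, config.tau,
                                seed=config.seed + 7919)
        for w in n_tmpl:
            st = _bernoulli_train(n_rng, T, config.neighbour_rate,
                                  config.refractory, 0, T)
            place_templates(T, st, config.neighbour_amplitude * peak_amp * w,
                            out=neighbour)

    e_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    noise = e_rng.normal(0.0, config.noise_level * peak_amp, size=T)

    rec = Recording(
        samples=clean + neighbour + noise,
        sampling_rate=config.sampling_rate,
        id=f"sim-seed{config.seed}",
    )
    if with_parts:
        return rec, RenderParts(clean=clean, neighbour=neighbour, noise=noise)
    return rec


def simulate(config: SimConfig, n_neurons: int = 3):
    """Convenience wrapper: templates + ground truth + rendered channel."""
    templates = make_templates(n_neurons, config.tau, seed=config.seed)
    truth = generate_ground_truth(config, templates)
    rec = render_channel(truth, config)
    return rec, truth


# ---------------------------------------------------------------------------
# Benchmark MAT dialect
# ---------------------------------------------------------------------------

def _as_1d(a):
    return np.asarray(a).reshape(-1)


def read_benchmark(path):
    """Read a benchmark MAT-file into ``(Recording, GroundTruth)``.

    Expects the public simulated benchmark's conventions: ``data`` (the
    raw trace), ``spike_times`` and ``spike_class`` (either one cell with
    a pooled time/label pair, or one cell per neuron), and optionally
    ``samplingInterval`` in milliseconds.  Times are returned as 0-based
    sample indices.
    """
    mat = sio.loadmat(path, squeeze_me=True)
    for var in ("data", "spike_times", "spike_class"):
        if var not in mat:
            raise FileFormatError(f"{path}: missing variable '{var}'")
    data = _as_1d(mat["data"]).astype(np.float64)
    interval_ms = float(mat.get("samplingInterval", 1000.0 / DEFAULT_SAMPLING_RATE))
    rate = 1000.0 / interval_ms

    st_raw, cl_raw = mat["spike_times"], mat["spike_class"]
    if isinstance(st_raw, np.ndarray) and st_raw.dtype == object:
        cells = [_as_1d(c).astype(np.int64) for c in st_raw]
        label_cells = [_as_1d(c).astype(np.int64) for c in np.atleast_1d(cl_raw)]
        if len(cells) == 1:
            times, labels = cells[0], label_cells[0]
            classes = np.unique(labels)
            trains = [np.sort(times[labels == c]) for c in classes]
        else:
            trains = [np.sort(c) for c in cells]
    else:
        times = _as_1d(st_raw).astype(np.int64)
        labels = _as_1d(cl_raw).astype(np.int64)
        classes = np.unique(labels)
        trains = [np.sort(times[labels == c]) for c in classes]

    templates = mat.get("templates")
    if templates is not None:
        templates = np.atleast_2d(np.asarray(templates, dtype=np.float64))
    truth = GroundTruth(
        spike_times=trains,
        templates=templates,
        noise_sigma=float(mat.get("noise_sigma", 0.0)),
        refractory=int(mat.get("refractory", 0)),
    )
    rec_id = str(mat.get("rec_id", ""))
    return Recording(samples=data, sampling_rate=rate, id=rec_id), truth


def write_dataset(rec: Recording, truth: GroundTruth, path) -> None:
    """Write a recording + ground truth in the benchmark MAT dialect.

    Lossless round-trip with :func:`read_benchmark` (pooled spike-time /
    class-label layout, class ids 1..N).
    """
    if truth.n_neurons:
        times = np.concatenate(truth.spike_times)
        labels = np.concatenate(
            [np.full(st.size, i + 1, dtype=np.int64)
             for i, st in enumerate(truth.spike_times)]
        )
        order = np.argsort(times, kind="stable")
        times, labels = times[order], labels[order]
    else:
        times = np.empty(0, dtype=np.int64)
        labels = np.empty(0, dtype=np.int64)
    out = {
        "data": rec.samples.reshape(1, -1),
        "spike_times": times.reshape(1, -1),
        "spike_class": labels.reshape(1, -1),
        "samplingInterval": 1000.0 / rec.sampling_rate,
        "noise_sigma": truth.noise_sigma,
        "refractory": truth.refractory,
        "rec_id": rec.id,
    }
    if truth.templates is not None:
        out["templates"] = truth.templates
    sio.savemat(path, out)
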