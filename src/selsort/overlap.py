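"""Statistical estimation: putative templates, noise modelling and
likelihood-based resolution of unclustered (including overlapping) spikes.

Given initial per-neuron impulse trains from clustering, each neuron's
putative template w_n is the least-squares solution of

    v(t)  ~  sum_n sum_u w_n(u) delta_n(t - u),   u = -L..+L,

whose normal equations are block-Toeplitz in the trains' auto- and
cross-correlations (solved with a pseudo-inverse).  Subtracting the
fitted templates leaves a residual carrying noise plus the unclustered
spikes; the centre column of the Toeplitz matrix of its autocovariance
defines a symmetric coiflet-like filter that, convolved with the voltage,
accentuates spike-shaped structure.  Each detected-but-unclustered index
is then scored per neuron with a matched-filter log-likelihood plus a
Bernoulli log-odds prior from the neuron's spike rate,

    L_n = w_n . v_window - ||w_n||^2 / 2 + log(p_n / (1 - p_n)),

the winner (if L > 0) is accepted, its template subtracted, and the
window re-scored — so a second neuron can claim the remainder of an
overlap event.  Per-neuron refractory intervals are enforced throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps
from statsmodels.tsa.stattools import acovf

from selsort.synthgen import Recording, GroundTruth, DEFAULT_REFRACTORY
from selsort.detect import (
    CobConfig,
    EventIndex,
    WaveformMatrix,
    detect_spikes,
    extract_waveforms,
)
from selsort.features import build_features
from selsort.cluster import ClusterAssignment, SpcConfig, spc_cluster, optics_cluster


@dataclass
class TemplateSet:
    """Putative templates on a lag axis -L..+L with the peak at lag 0."""

    templates: np.ndarray  # (N, 2L+1)
    spike_rates: np.ndarray  # per-neuron spikes per sample
    lag: int
    filtered_templates: np.ndarray | None = None  # re-estimated on whitened trace

    def __post_init__(self):
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=np.float64))
        self.spike_rates = np.asarray(self.spike_rates, dtype=np.float64)
        if self.templates.shape[1] != 2 * self.lag + 1:
            raise ValueError("template length must equal 2*lag + 1")
        if np.any(self.spike_rates < 0) or np.any(self.spike_rates >= 1):
            raise ValueError("spike rates must lie in [0, 1)")

    @property
    def n_neurons(self) -> int:
        return self.templates.shape[0]


@dataclass
class NoiseModel:
    """Residual trace, its autocovariance and the derived filter."""

    residual: np.ndarray
    autocov: np.ndarray  # lags 0..m-1
    filter: np.ndarray  # odd length, symmetric, unit L2 norm

    def __post_init__(self):
        self.autocov = np.asarray(self.autocov, dtype=np.float64)
        self.filter = np.asarray(self.filter, dtype=np.float64)
        if self.filter.size % 2 == 0:
            raise ValueError("noise filter length must be odd")
        if self.autocov.size and np.any(
            np.abs(self.autocov[1:]) > abs(self.autocov[0]) + 1e-9
        ):
            raise ValueError("autocovariance must peak at lag 0")


@dataclass
class SortResult:
    """Final per-neuron spike trains plus the matching audit trail."""

    spike_trains: list  # per-neuron sorted sample indices
    likelihoods: np.ndarray  # (n_targets, N) first-pass L_n per target
    decisions: list  # per target: tuple of accepted neuron ids (may be empty)
    target_indices: np.ndarray
    stages: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.spike_trains)

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_trains))


def build_impulse_trains(assign: ClusterAssignment, event_indices,
                         T: int):
    """Split row events into per-cluster binary trains and an unassigned pool.

    ``event_indices`` are the waveform-row event positions aligned with
    ``assign.labels``.  Returns ``(trains, unassigned)`` where each train
    is the sorted support of delta_n(t) for cluster n and ``unassigned``
    holds the label-0 events (putative overlaps and outliers).
    """
    ev = np.asarray(event_indices, dtype=np.int64)
    if ev.size != assign.labels.size:
        raise ValueError("one label per event required")
    if np.any(ev >= T) or np.any(ev < 0):
        raise ValueError("event index outside the trace")
    trains = [
        np.sort(ev[assign.labels == c]) for c in range(1, assign.n_clusters + 1)
    ]
    unassigned = np.sort(ev[assign.labels == 0])
    return trains, unassigned


def _train_crosscorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """c(d) = #{(s in a, s' in b): s' - s = d} for d in -max_lag..max_lag."""
    c = np.zeros(2 * max_lag + 1, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        return c
    for s in a:
        lo = np.searchsorted(b, s - max_lag)
        hi = np.searchsorted(b, s + max_lag, side="right")
        for sp in b[lo:hi]:
            c[sp - s + max_lag] += 1
    return c


def estimate_templates(rec: Recording, trains, lags: int = 30,
                       rcond: float = 1e-10) -> TemplateSet:
    """Joint block-Toeplitz least-squares template estimation.

    Solves the normal equations G w = b where G stacks the Toeplitz
    blocks of train auto-/cross-correlations and b the cross-correlation
    of each train with the voltage, using a pseudo-inverse (equivalent to
    the dense least-squares fit of the convolution model).  Singular
    systems fall back to the minimum-norm solution with a warning.
    """
    v = np.asarray(rec.samples, dtype=np.float64)
    T = v.size
    trains = [np.asarray(t, dtype=np.int64) for t in trains]
    if any(t.size == 0 for t in trains):
        raise ValueError("every train needs at least one spike")
    N = len(trains)
    taps = 2 * lags + 1
    u = np.arange(-lags, lags + 1)

    b = np.zeros(N * taps)
    vp = np.pad(v, (lags, lags))
    for n, tr in enumerate(trains):
        # b[(n,u)] = sum_{s in train} v(s + u)
        b[n * taps:(n + 1) * taps] = vp[(tr[:, None] + u[None, :]) + lags].sum(axis=0)

    G = np.zeros((N * taps, N * taps))
    for n in range(N):
        for m in range(n, N):
            c = _train_crosscorr(trains[n], trains[m], 2 * lags)
            # G[(n,u),(m,r)] = #{s_m - s_n = u - r} = c_{nm}(u - r)
            blk = np.empty((taps, taps))
            for iu in range(taps):
                for ir in range(taps):
                    blk[iu, ir] = c[(iu - ir) + 2 * lags]
            G[n * taps:(n + 1) * taps, m * taps:(m + 1) * taps] = blk
            if m != n:
                G[m * taps:(m + 1) * taps, n * taps:(n + 1) * taps] = blk.T

    rank = np.linalg.matrix_rank(G, tol=rcond * np.abs(G).max() * G.shape[0])
    if rank < G.shape[0]:
        warnings.warn("singular train correlation matrix; minimum-norm solve")
    w = np.linalg.pinv(G, rcond=rcond) @ b
    templates = w.reshape(N, taps)
    rates = np.array([t.size / T for t in trains])
    return TemplateSet(templates=templates, spike_rates=rates, lag=lags)


def place_lag_templates(T: int, trains, templates: np.ndarray,
                        lag: int, out=None, sign: float = 1.0) -> np.ndarray:
    """Add lag-axis templates (peak at lag 0) at each spike time."""
    if out is None:
        out = np.zeros(T, dtype=np.float64)
    taps = 2 * lag + 1
    for tr, w in zip(trains, templates):
        for s in np.asarray(tr, dtype=np.int64):
            a, b = s - lag, s + lag + 1
            ta, tb = max(a, 0), min(b, T)
            if ta < tb:
                out[ta:tb] += sign * w[ta - a: tb - a]
    return out


def compute_noise_residual(rec: Recording, tset: TemplateSet, trains) -> np.ndarray:
    """Channel voltage minus each fitted template at its clustered indices.

    The residual carries system noise, the unclustered spikes (which stay
    visible as local peaks) and per-spike fit error.
    """
    v = np.asarray(rec.samples, dtype=np.float64).copy()
    return place_lag_templates(v.size, trains, tset.templates, tset.lag,
                               out=v, sign=-1.0)


def noise_autocovariance(v_delta: np.ndarray, m: int) -> np.ndarray:
    """Biased sample autocovariance of the residual at lags 0..m-1."""
    x = np.asarray(v_delta, dtype=np.float64)
    if m < 1 or m > x.size:
        raise ValueError("need 1 <= m <= len(residual)")
    return acovf(x, nlag=m - 1, adjusted=False, fft=True)


def coiflet_filter_from_cov(autocov: np.ndarray, m: int | None = None) -> np.ndarray:
    """Centre column of the residual-covariance Toeplitz matrix,
    normalised to unit L2 norm.

    Because the residual retains spike-shaped structure, this column is a
    symmetric wavelet-like kernel matched to it (white residual gives a
    unit impulse).  ``m`` must be odd.
    """
    ac = np.asarray(autocov, dtype=np.float64)
    if m is None:
        m = ac.size if ac.size % 2 == 1 else ac.size - 1
    if m % 2 == 0:
        raise ValueError("filter length m must be odd")
    if m > ac.size:
        raise ValueError("m exceeds the available autocovariance lags")
    toe = sla.toeplitz(ac[:m])
    f = toe[:, m // 2].copy()
    norm = np.linalg.norm(f)
    return f / norm if norm > 0 else f


def whiten(rec: Recording | np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Zero-phase convolution of the voltage with the noise-derived filter
    (the kernel is symmetric, so 'same'-mode convolution adds no delay)."""
    v = rec.samples if isinstance(rec, Recording) else np.asarray(rec, dtype=np.float64)
    return sps.fftconvolve(v, np.asarray(filt, dtype=np.float64), mode="same")


def match_unclustered(v_f: np.ndarray, tset: TemplateSet, targets,
                      refractory: int = DEFAULT_REFRACTORY,
                      initial_trains=None,
                      accept_threshold: float = 0.0,
                      lag_search: int = 3,
                      max_per_event: int = 2,
                      noise_var: float | None = None) -> SortResult:
    """Prediction-and-elimination over the detected-but-unclustered indices.

    At each target the Gaussian matched-filter log-likelihood ratio

        L_n = (w_n . v_window - ||w_n||^2 / 2) / sigma^2 + log(p_n/(1-p_n))

    is evaluated per neuron over a small lag search; ``sigma^2`` is the
    background-noise variance (robust MAD-based estimate of ``v_f`` when
    not given) which sets the likelihood's scale against the Bernoulli
    rate prior.  Acceptance is globally greedy across targets: the best
    (target, neuron) match anywhere wins, its template is subtracted from
    the working trace, and the targets its window touches are re-scored —
    iterative elimination that lets a second neuron claim the remainder
    of an overlap event.  Wins violating a neuron's refractory interval
    are rejected; each neuron claims a target at most once and each
    target accepts at most ``max_per_event`` neurons.  Accepted indices
    are recorded at target positions, so final trains are subsets of
    detected events.
    """
    v = np.asarray(v_f, dtype=np.float64).copy()
    targets = np.asarray(targets, dtype=np.int64)
    N = tset.n_neurons
    W = tset.filtered_templates if tset.filtered_templates is not None else tset.templates
    W = np.atleast_2d(W)
    L_half = tset.lag
    if noise_var is None:
        mad = np.median(np.abs(v - np.median(v))) / 0.6745
        noise_var = float(mad**2)
    noise_var = max(noise_var, 1e-12)
    norms2 = 0.5 * np.sum(W**2, axis=1)
    p = np.clip(tset.spike_rates, 1e-12, 1 - 1e-12)
    log_odds = np.log(p / (1 - p))

    trains = [list(np.asarray(t, dtype=np.int64)) for t in (initial_trains or [[] for _ in range(N)])]
    while len(trains) < N:
        trains.append([])
    likelihoods = np.full((targets.size, N), -np.inf)
    decisions = []

    if N == 0 or W.size == 0:
        return SortResult(
            spike_trains=[np.asarray(t) for t in trains],
            likelihoods=likelihoods, decisions=[() for _ in targets],
            target_indices=targets,
        )

    lagset = np.arange(-lag_search, lag_search + 1)
    T = v.size

    def score(t, n):
        """Best (L, lag) for neuron n at target t on the working trace."""
        Ln_best, lag_best = -np.inf, 0
        for d in lagset:
            a, bnd = t + d - L_half, t + d + L_half + 1
            if a < 0 or bnd > T:
                continue
            Ln = (float(W[n] @ v[a:bnd]) - norms2[n]) / noise_var \
                + log_odds[n]
            if Ln > Ln_best:
                Ln_best, lag_best = Ln, d
        return Ln_best, lag_best

    L_cur = np.full((targets.size, N), -np.inf)
    lag_cur = np.zeros((targets.size, N), dtype=np.int64)
    for it, t in enumerate(targets):
        for n in range(N):
            L_cur[it, n], lag_cur[it, n] = score(int(t), n)
    likelihoods[:] = L_cur

    taps = 2 * L_half + 1
    xcorr = np.empty((N, N, 2 * taps - 1))
    for n in range(N):
        for m in range(N):
            xcorr[n, m] = np.correlate(W[n], W[m], mode="full")

    def cross_term(n, m, s):
        """sum_t w_n(t - p1) w_m(t - p2) for s = p2 - p1."""
        idx = (taps - 1) - s
        if 0 <= idx < 2 * taps - 1:
            return xcorr[m, n, idx]
        return 0.0

    def single_score(n, pos):
        a, bnd = pos - L_half, pos + L_half + 1
        if a < 0 or bnd > T:
            return -np.inf
        return (float(W[n] @ v[a:bnd]) - norms2[n]) / noise_var + log_odds[n]

    def best_joint_pair(it, n):
        """Best two-template placement anchored near target ``it``.

        A single-template match on an overlap mixture can prefer a
        compromise position between the two true spikes; jointly scoring
        template pairs over the nearby candidate positions resolves the
        ambiguity (elimination depth 2).
        """
        t = int(targets[it])
        near = [kt for kt in range(targets.size)
                if abs(int(targets[kt]) - t) <= 2 * L_half]
        P = sorted({int(targets[kt]) + int(d) for kt in near for d in lagset})
        best = (-np.inf, None)
        singles = {(m, p): single_score(m, p) for m in range(N) for p in P}
        for a_n in range(N):
            for b_n in range(N):
                if a_n == b_n:
                    continue
                for p1 in P:
                    s1 = singles[(a_n, p1)]
                    if not np.isfinite(s1):
                        continue
                    for p2 in P:
                        if p2 <= p1:
                            continue
                        s2 = singles[(b_n, p2)]
                        if not np.isfinite(s2):
                            continue
                        Lp = s1 + s2 - cross_term(a_n, b_n, p2 - p1) / noise_var
                        if Lp > best[0]:
                            best = (Lp, ((a_n, p1), (b_n, p2)))
        return best

    def try_commit(n, pos):
        """Record neuron n at the target nearest ``pos`` if the claim and
        refractory rules allow it; subtract the template either way the
        commit succeeds."""
        jt = int(np.argmin(np.abs(targets - pos)))
        tj = int(targets[jt])
        if len(accepted_at[jt]) >= max_per_event or n in accepted_at[jt]:
            return False
        existing = np.asarray(trains[n], dtype=np.int64)
        if existing.size and np.min(np.abs(existing - tj)) < refractory:
            return False
        trains[n].append(tj)
        accepted_at[jt].append(n)
        a, bnd = pos - L_half, pos + L_half + 1
        ta, tb = max(a, 0), min(bnd, T)
        v[ta:tb] -= W[n][ta - a: tb - a]
        L_cur[jt, n] = -np.inf
        open_pairs.discard((jt, n))
        return True

    accepted_at: list[list[int]] = [[] for _ in targets]
    open_pairs = {(it, n) for it in range(targets.size) for n in range(N)}
    while open_pairs:
        it, n = max(open_pairs, key=lambda p: (L_cur[p], -p[0], -p[1]))
        if not np.isfinite(L_cur[it, n]) or L_cur[it, n] <= accept_threshold:
            break
        open_pairs.discard((it, n))
        t = int(targets[it])
        pos = t + int(lag_cur[it, n])
        L_pair, placement = best_joint_pair(it, n)
        committed_near = []
        if placement is not None and L_pair > L_cur[it, n]:
            for m, p in placement:
                if try_commit(m, p):
                    committed_near.append(p)
        if not committed_near:
            if try_commit(n, pos):
                committed_near.append(pos)
            else:
                L_cur[it, n] = -np.inf
                continue
        L_cur[it, n] = -np.inf
        # re-score every still-open pair whose window overlaps the change
        reach = 2 * L_half + 2 * lag_search
        for jt2, m2 in list(open_pairs):
            if any(abs(int(targets[jt2]) - p) <= reach for p in committed_near):
                L_cur[jt2, m2], lag_cur[jt2, m2] = score(int(targets[jt2]), m2)

    decisions = [tuple(acc) for acc in accepted_at]
    final = [np.asarray(sorted(tr), dtype=np.int64) for tr in trains]
    return SortResult(
        spike_trains=final, likelihoods=likelihoods,
        decisions=decisions, target_indices=targets,
    )


def templates_from_waveforms(waveforms: np.ndarray, spike_rates,
                             lag: int, peak_index: int | None = None) -> TemplateSet:
    """Re-house fixed-window templates on the symmetric lag axis -L..+L."""
    Wf = np.atleast_2d(np.asarray(waveforms, dtype=np.float64))
    out = np.zeros((Wf.shape[0], 2 * lag + 1))
    for i, w in enumerate(Wf):
        p = int(np.argmax(np.abs(w))) if peak_index is None else peak_index
        for u in range(-lag, lag + 1):
            j = p + u
            if 0 <= j < w.size:
                out[i, u + lag] = w[j]
    return TemplateSet(templates=out, spike_rates=np.asarray(spike_rates, dtype=np.float64), lag=lag)


@dataclass
class SortConfig:
    """End-to-end pipeline parameters."""

    cob: CobConfig = field(default_factory=CobConfig)
    spc: SpcConfig = field(default_factory=SpcConfig)
    window: int = 61
    align_index: int = 20
    interp_factor: int = 2
    n_features: int = 10
    lags: int = 30
    refractory: int = DEFAULT_REFRACTORY
    cluster_method: str = "spc"  # or "optics"
    optics_min_samples: int = 11
    optics_eps: float | None = None
    noise_lags: int = 31
    accept_threshold: float = 0.0
    lag_search: int = 3


def sort_channel(rec: Recording, cfg: SortConfig | None = None) -> SortResult:
    """Run the full selective-sorting pipeline on one channel.

    detect -> extract -> features -> cluster -> templates -> residual
    noise -> coiflet-type filter -> re-estimate -> match unclustered.
    All stage outputs are retained in ``result.stages`` for audit.
    """
    cfg = cfg or SortConfig()
    events = detect_spikes(rec, cfg.cob)
    wf = extract_waveforms(rec, events, window=cfg.window,
                           align_index=cfg.align_index,
                           interp_factor=cfg.interp_factor)
    if wf.n_waveforms < max(10, cfg.spc.min_cluster_size or 0):
        raise ValueError("too few detected waveforms to sort this channel")
    fm = build_features(wf, d=cfg.n_features)
    if cfg.cluster_method == "spc":
        assign, diag = spc_cluster(fm.values, cfg.spc)
    else:
        assign = optics_cluster(wf.waveforms, cfg.optics_min_samples, cfg.optics_eps)
        diag = None
    trains, unassigned = build_impulse_trains(assign, wf.event_indices, len(rec))
    trains = [t for t in trains if t.size > 0]
    if not trains:
        raise ValueError("clustering produced no usable clusters")

    tset = estimate_templates(rec, trains, lags=cfg.lags)
    residual = compute_noise_residual(rec, tset, trains)
    ac = noise_autocovariance(residual, cfg.noise_lags)
    m = cfg.noise_lags if cfg.noise_lags % 2 == 1 else cfg.noise_lags - 1
    filt = coiflet_filter_from_cov(ac, m)
    v_f = whiten(rec, filt)
    tset.filtered_templates = estimate_templates(
        Recording(v_f, rec.sampling_rate, rec.id), trains, lags=cfg.lags
    ).templates

    # targets: every detected index not claimed by a cluster
    clustered = np.concatenate(trains) if trains else np.empty(0, dtype=np.int64)
    mask = ~np.isin(events.indices, clustered)
    targets = events.indices[mask]
    # the clustered spikes are already explained: eliminate their (filtered)
    # contribution so a target cannot score against a neighbour's spike
    v_match = place_lag_templates(
        len(rec), trains, tset.filtered_templates, cfg.lags,
        out=v_f.copy(), sign=-1.0,
    )
    result = match_unclustered(
        v_match, tset, targets, refractory=cfg.refractory,
        initial_trains=trains, accept_threshold=cfg.accept_threshold,
        lag_search=cfg.lag_search,
    )
    result.stages = {
        "events": events,
        "waveforms": wf,
        "features": fm,
        "assignment": assign,
        "cluster_diagnostics": diag,
        "templates": tset,
        "noise_model": NoiseModel(residual=residual, autocov=ac, filter=filt),
        "residual": residual,
        "autocov": ac,
        "filter": filt,
        "whitened": v_f,
        "unassigned": unassigned,
    }
    return result
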