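"""Clustering feature set: Haar wavelet coefficients ranked by
deviation from normality.

Every extracted waveform is decomposed with a full multi-level orthonormal
Haar transform.  A coefficient whose distribution over all waveforms is a
mixture (several spike classes) deviates from a Gaussian, while a
noise-only coefficient does not — so coefficients are ranked by the
Kolmogorov–Smirnov distance between their standardised empirical
distribution and the standard normal CDF, and the top ``d`` (10 by
default) form the feature matrix.  Kernel density curves per feature let
the selection be cross-checked: well-chosen features are multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats as sstats

from selsort.detect import WaveformMatrix


@dataclass
class FeatureMatrix:
    """Selected wavelet features, columns ordered by descending KS score."""

    values: np.ndarray  # (M, d)
    coeff_ids: np.ndarray  # selected coefficient positions
    ks_scores: np.ndarray  # per-selected-coefficient KS distances

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.coeff_ids = np.asarray(self.coeff_ids, dtype=np.int64)
        self.ks_scores = np.asarray(self.ks_scores, dtype=np.float64)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def haar_decompose(wf: WaveformMatrix | np.ndarray) -> np.ndarray:
    """Full multi-level Haar coefficient vector per waveform.

    Rows shorter than a power of two are symmetrically extended; the
    transform uses periodised orthonormal Haar filters, so for
    power-of-two rows the coefficient vector conserves the row's L2 norm
    (Parseval) and the column count equals the (padded) row length.
    """
    X = wf.waveforms if isinstance(wf, WaveformMatrix) else np.atleast_2d(wf)
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[1]
    if n < 4:
        raise ValueError("waveform length must be at least 4 samples")
    n_pad = 1 << int(np.ceil(np.log2(n)))
    if n_pad != n:
        X = np.pad(X, ((0, 0), (0, n_pad - n)), mode="symmetric")
    level = int(np.log2(n_pad))
    coeffs = pywt.wavedec(X, "haar", mode="periodization", level=level, axis=1)
    return np.concatenate(coeffs, axis=1)


def ks_deviation_scores(coeffs: np.ndarray, trim_sd: float | None = 3.0) -> np.ndarray:
    """KS distance from normality per coefficient position.

    Each column is standardised by its own mean and SD (a Lilliefors-style
    statistic, since the null parameters are estimated from the data) and
    compared against the standard normal CDF.  Values beyond ``trim_sd``
    standard deviations are discarded first — outlier-heavy coefficients
    (contaminated by overlaps or neighbour activity) would otherwise score
    high purely through their tails, crowding out the genuinely multimodal
    coefficients that separate spike classes.  Zero-variance columns
    score 0.
    """
    C = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    M = C.shape[0]
    if M < 2:
        raise ValueError("need at least two waveforms to score features")
    scores = np.zeros(C.shape[1])
    for j in range(C.shape[1]):
        x = C[:, j]
        if x.std(ddof=1) == 0:
            continue
        if trim_sd is not None:
            x = x[np.abs(x - x.mean()) <= trim_sd * x.std(ddof=1)]
            if x.size < 2 or x.std(ddof=1) == 0:
                continue
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        n = z.size
        cdf = sstats.norm.cdf(z)
        scores[j] = max(
            np.max(np.arange(1, n + 1) / n - cdf),
            np.max(cdf - np.arange(0, n) / n),
        )
    return scores


def select_features(coeffs: np.ndarray, scores: np.ndarray,
                    d: int = 10) -> FeatureMatrix:
    """Keep the ``d`` coefficients with the largest deviation scores.

    Ties are broken toward the lower coefficient index; columns of the
    result are ordered by descending score.
    """
    C = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    scores = np.asarray(scores, dtype=np.float64)
    d = min(d, C.shape[1])
    order = np.lexsort((np.arange(scores.size), -scores))[:d]
    return FeatureMatrix(
        values=C[:, order], coeff_ids=order, ks_scores=scores[order]
    )


def build_features(wf: WaveformMatrix, d: int = 10) -> FeatureMatrix:
    """Haar decomposition, KS ranking and top-``d`` selection in one step."""
    coeffs = haar_decompose(wf)
    scores = ks_deviation_scores(coeffs)
    return select_features(coeffs, scores, d=d)


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    n_modes: int
    degenerate: bool = False


def feature_pdf(fm: FeatureMatrix, n_grid: int = 512) -> list[DensityCurve]:
    """Gaussian kernel density per selected feature.

    Bandwidth scales with the per-feature SD (Silverman's factor
    sigma * (4 / 3M)^(1/5)); each curve integrates to 1 within 1e-3 on
    its grid.  The local-maxima count makes the visual multimodality
    check automatic: a feature that separates spike classes shows more
    than one mode.  Zero-variance features are flagged degenerate.
    """
    M = fm.values.shape[0]
    if M < 2:
        raise ValueError("need at least two waveforms for density estimation")
    curves = []
    for j in range(fm.n_features):
        x = fm.values[:, j]
        sd = x.std(ddof=1)
        if sd == 0:
            g = np.linspace(x[0] - 1, x[0] + 1, n_grid)
            dens = np.zeros(n_grid)
            curves.append(DensityCurve(g, dens, n_modes=0, degenerate=True))
            continue
        h = sd * (4.0 / (3.0 * M)) ** 0.2
        g = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
        dens = np.exp(-0.5 * ((g[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
        dens /= M * h * np.sqrt(2 * np.pi)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        prominence = dens[1:-1] > 0.05 * dens.max()
        n_modes = int(np.count_nonzero(interior & prominence))
        curves.append(DensityCurve(g, dens, n_modes=n_modes))
    return curves
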