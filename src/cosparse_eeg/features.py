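"""Statistical descriptors of (sparse-represented) EEG segments.

Fifteen scalar descriptors per segment: mean, population variance, skewness,
kurtosis (non-excess), sample entropy, approximate entropy, Shannon entropy
(histogram, bits), Hurst exponent (rescaled range), largest Lyapunov exponent
(Rosenstein), Higuchi fractal dimension, recurrence rate (RQA), normalized
4th-order cumulant, Lempel-Ziv complexity (LZ76 phrase count on a
median-binarized sequence), Kolmogorov complexity (compression-ratio proxy)
and the Hjorth complexity parameter.

All estimators are deterministic given the input and a :class:`FeatureConfig`.
Degenerate inputs (constant segments) return the defined degenerate values
(0 where the definition forces it) with a warning rather than NaN.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

def _is_constant(x: np.ndarray) -> bool:
    return float(np.ptp(x)) == 0.0


FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "sample_entropy",
    "approximate_entropy",
    "shannon_entropy",
    "hurst_exponent",
    "largest_lyapunov",
    "fractal_dimension",
    "rqa_recurrence_rate",
    "higher_order_cumulant",
    "lempel_ziv",
    "kolmogorov_complexity",
    "hjorth",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Deterministic estimator parameters.

    ``entropy_m`` / ``entropy_r``: embedding dimension and tolerance (as a
    fraction of the segment std) for sample/approximate entropy.
    ``shannon_bins``: histogram bins for Shannon entropy (bits).
    ``rqa_radius`` (fraction of std) and ``rqa_embedding`` for the recurrence
    rate.  ``higuchi_kmax`` for the fractal dimension; ``lyap_dim`` /
    ``lyap_delay`` for the Rosenstein largest-Lyapunov estimator.
    """

    entropy_m: int = 2
    entropy_r: float = 0.2
    shannon_bins: int = 256
    rqa_radius: float = 0.2
    rqa_embedding: int = 3
    higuchi_kmax: int = 10
    lyap_dim: int = 5
    lyap_delay: int = 1

    def __post_init__(self) -> None:
        if self.entropy_m < 1:
            raise ValueError("entropy_m must be >= 1")
        if not self.entropy_r > 0:
            raise ValueError("entropy_r must be > 0")
        if self.shannon_bins < 2:
            raise ValueError("shannon_bins must be >= 2")


def _embed(x: np.ndarray, dim: int, delay: int = 1) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n <= 0:
        return np.empty((0, dim))
    return np.lib.stride_tricks.sliding_window_view(x, (dim - 1) * delay + 1)[
        :, :: delay]


def _chebyshev_counts(emb: np.ndarray, r: float) -> np.ndarray:
    """Per-template counts of templates within Chebyshev distance r (incl. self)."""
    d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    return np.count_nonzero(d <= r, axis=1)


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r): -log of the conditional recurrence ratio.

    Self-matches are excluded. Returns 0 for constant (all templates match)
    and for signals with no recurrences at all (defined degenerate value).
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        warnings.warn("sample_entropy of a constant signal is 0", UserWarning,
                      stacklevel=2)
        return 0.0
    sd = x.std()
    r = r_frac * sd
    em = _embed(x, m)
    em1 = _embed(x, m + 1)
    # align template counts: use the first len(em1) m-templates for fairness
    B = float(np.sum(_chebyshev_counts(em, r) - 1))
    A = float(np.sum(_chebyshev_counts(em1, r) - 1))
    if A == 0 or B == 0:
        return 0.0
    return float(-np.log(A / B))


def approximate_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """ApEn(m, r) = Phi(m) - Phi(m+1) with self-matches included."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        warnings.warn("approximate_entropy of a constant signal is 0",
                      UserWarning, stacklevel=2)
        return 0.0
    sd = x.std()
    r = r_frac * sd

    def phi(dim: int) -> float:
        emb = _embed(x, dim)
        counts = _chebyshev_counts(emb, r)
        return float(np.mean(np.log(counts / len(emb))))

    return phi(m) - phi(m + 1)


def shannon_entropy(x: np.ndarray, bins: int = 256) -> float:
    """Histogram entropy in bits; 0 for a constant signal."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    hist, _ = np.histogram(x, bins=bins)
    p = hist[hist > 0] / hist.sum()
    return float(-np.sum(p * np.log2(p)))


def hurst_exponent(x: np.ndarray) -> float:
    """Rescaled-range (R/S) estimate of the Hurst exponent.

    Windows are dyadic from 8 up to n/2; the exponent is the slope of
    log(R/S) against log(window).  White noise gives ~0.5, persistent
    signals > 0.5.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if _is_constant(x) or n < 16:
        warnings.warn("hurst_exponent undefined for constant/short input; 0",
                      UserWarning, stacklevel=2)
        return 0.0
    sizes = []
    w = 8
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    if not sizes:
        sizes = [max(n // 2, 2)]
    log_rs, log_w = [], []
    for w in sizes:
        k = n // w
        segs = x[: k * w].reshape(k, w)
        mean = segs.mean(axis=1, keepdims=True)
        dev = np.cumsum(segs - mean, axis=1)
        R = dev.max(axis=1) - dev.min(axis=1)
        S = segs.std(axis=1)
        ok = S > 0
        if not np.any(ok):
            continue
        log_rs.append(np.log(np.mean(R[ok] / S[ok])))
        log_w.append(np.log(w))
    if len(log_w) < 2:
        return 0.5
    slope, _ = np.polyfit(log_w, log_rs, 1)
    return float(slope)


def largest_lyapunov(x: np.ndarray, dim: int = 5, delay: int = 1,
                     fs: float = 1.0) -> float:
    """Rosenstein's largest Lyapunov exponent estimate.

    Nearest neighbours are sought outside a mean-period Theiler window; the
    exponent is the least-squares slope of the mean log-divergence curve.
    Returns 0 for constant signals.
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        warnings.warn("largest_lyapunov of a constant signal is 0",
                      UserWarning, stacklevel=2)
        return 0.0
    emb = _embed(x, dim, delay)
    m = len(emb)
    if m < 10:
        return 0.0
    # Theiler window from the mean period (dominant FFT frequency)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    spec[0] = 0.0
    kdom = int(np.argmax(spec))
    mean_period = len(x) / kdom if kdom > 0 else len(x)
    window = max(int(mean_period), 1)
    d = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=2)
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) <= window
    d[mask] = np.inf
    nn = np.argmin(d, axis=1)
    valid = np.isfinite(d[idx, nn])
    if not np.any(valid):
        return 0.0
    max_t = min(m // 4, int(10 * mean_period), m - 1)
    max_t = max(max_t, 2)
    div = []
    for t in range(max_t):
        i = idx[valid]
        j = nn[valid]
        keep = (i + t < m) & (j + t < m)
        if keep.sum() < 2:
            break
        dist = np.linalg.norm(emb[i[keep] + t] - emb[j[keep] + t], axis=1)
        dist = dist[dist > 0]
        if dist.size < 2:
            div.append(-np.inf)
            continue
        div.append(np.mean(np.log(dist)))
    div = np.asarray(div)
    ok = np.isfinite(div)
    if ok.sum() < 2:
        return 0.0
    t_ax = np.arange(len(div))[ok] / fs
    slope, _ = np.polyfit(t_ax, div[ok], 1)
    return float(slope)


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension (between 1 and 2 for waveforms)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if _is_constant(x) or n < kmax + 2:
        warnings.warn("higuchi_fd undefined for constant/short input; 0",
                      UserWarning, stacklevel=2)
        return 0.0
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            diff = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(diff * norm / k)
        if lengths:
            lk.append(np.log(np.mean(lengths)))
            ks.append(np.log(1.0 / k))
    if len(ks) < 2:
        return 0.0
    slope, _ = np.polyfit(ks, lk, 1)
    return float(slope)


def recurrence_rate(x: np.ndarray, radius_frac: float = 0.2,
                    embedding: int = 3) -> float:
    """Fraction of embedded state pairs closer than radius (RQA RR in [0,1])."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 1.0
    sd = x.std()
    emb = _embed(x, embedding)
    m = len(emb)
    if m < 2:
        return 0.0
    d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    rec = np.count_nonzero(d <= radius_frac * sd)
    return float(rec) / (m * m)


def higher_order_cumulant(x: np.ndarray) -> float:
    """4th-order cumulant normalized by variance^2 (excess-kurtosis form)."""
    x = np.asarray(x, dtype=float)
    var = x.var()
    if _is_constant(x) or var == 0:
        return 0.0
    c = x - x.mean()
    k4 = np.mean(c ** 4) - 3.0 * var ** 2
    return float(k4 / var ** 2)


def _binarize(x: np.ndarray) -> np.ndarray:
    """Median binarization; ties (== median) map to 0."""
    med = np.median(x)
    return (x > med).astype(np.uint8)


def lempel_ziv(x: np.ndarray) -> float:
    """LZ76 phrase count of the median-binarized sequence (raw count)."""
    s = _binarize(np.asarray(x, dtype=float))
    n = len(s)
    if n == 0:
        return 0.0
    # classic LZ76 parsing (Lempel & Ziv 1976 exhaustive history)
    i, k, l = 0, 1, 1
    complexity = 1
    k_max = 1
    while True:
        if l + k > n:
            complexity += 1
            break
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                complexity += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                complexity += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return float(complexity)


def kolmogorov_complexity(x: np.ndarray) -> float:
    """Compression-ratio proxy: deflate length over raw length of the
    median-binarized '0'/'1' byte sequence (smaller = more regular)."""
    bits = _binarize(np.asarray(x, dtype=float))
    raw = bits.tobytes()
    if not raw:
        return 0.0
    comp = zlib.compress(raw, level=9)
    return float(len(comp)) / len(raw)


def hjorth_complexity(x: np.ndarray) -> float:
    """Hjorth complexity: mobility of the derivative over mobility.

    ~1 for a pure sinusoid, larger for broader-band signals; 0 for constants.
    """
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return 0.0
    d1 = np.diff(x)
    if d1.var() == 0:
        return 0.0
    d2 = np.diff(d1)
    mob = np.sqrt(d1.var() / x.var())
    mob_d = np.sqrt(d2.var() / d1.var())
    return float(mob_d / mob)


def compute_features(x: np.ndarray, config: FeatureConfig | None = None,
                     fs: float = 1.0) -> dict[str, float]:
    """All fifteen descriptors of one segment, keyed by FEATURE_NAMES."""
    config = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    if len(x) < 32:
        warnings.warn(f"segment length {len(x)} < 32; nonlinear estimators "
                      "are unreliable", UserWarning, stacklevel=2)
    constant = _is_constant(x)
    with warnings.catch_warnings():
        if constant:
            warnings.simplefilter("ignore", UserWarning)
        out = {
            "mean": float(x.mean()),
            "variance": float(x.var()),
            "skewness": 0.0 if constant else float(sstats.skew(x, bias=False)),
            "kurtosis": 0.0 if constant else float(
                sstats.kurtosis(x, fisher=False, bias=False)),
            "sample_entropy": sample_entropy(x, config.entropy_m,
                                             config.entropy_r),
            "approximate_entropy": approximate_entropy(x, config.entropy_m,
                                                       config.entropy_r),
            "shannon_entropy": shannon_entropy(x, config.shannon_bins),
            "hurst_exponent": hurst_exponent(x),
            "largest_lyapunov": largest_lyapunov(x, config.lyap_dim,
                                                 config.lyap_delay, fs),
            "fractal_dimension": higuchi_fd(x, config.higuchi_kmax),
            "rqa_recurrence_rate": recurrence_rate(x, config.rqa_radius,
                                                   config.rqa_embedding),
            "higher_order_cumulant": higher_order_cumulant(x),
            "lempel_ziv": lempel_ziv(x),
            "kolmogorov_complexity": kolmogorov_complexity(x),
            "hjorth": hjorth_complexity(x),
        }
    if constant:
        warnings.warn("constant segment: entropy/Hurst/Lyapunov descriptors "
                      "returned as their defined degenerate values",
                      UserWarning, stacklevel=2)
    return out


def feature_table(dataset, config: FeatureConfig | None = None):
    """Per-class mean of every descriptor (rows = descriptors, cols = classes)."""
    import pandas as pd

    if dataset.n_segments == 0:
        raise ValueError("dataset is empty")
    classes = sorted(set(dataset.labels.tolist()))
    columns = {}
    for cls in classes:
        rows = dataset.segments[dataset.labels == cls]
        if rows.shape[0] == 0:
            raise ValueError(f"class {cls!r} has zero segments")
        vecs = [compute_features(r, config, dataset.fs) for r in rows]
        columns[cls] = {name: float(np.mean([v[name] for v in vecs]))
                        for name in FEATURE_NAMES}
    return pd.DataFrame(columns, index=list(FEATURE_NAMES))
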