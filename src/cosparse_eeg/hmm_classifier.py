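"""Per-family hidden Markov models with Jaccard emissions.

One model per feature family (here: per class).  The hidden chain is
deterministic and left-to-right — state l transitions to l+1 with probability
one, the chain starts in state 1 — so the forward probability collapses to the
product of the per-state emissions.  The emission at state l is a Jaccard
overlap computed from training data: with association tolerance delta_l, a
training value w' is *associated* with a value a when |w' - a| <= delta_l.
Writing A for the training values associated with the observation w_l and B
for those associated with the state value V_l,

    P(w_l | V_l) = H11 / (H11 + H10 + H01),
    H11 = |A ∩ B|,  H01 = |A \\ B|,  H10 = |B \\ A|.

The emission therefore depends on the observation through A; a model scores an
observation vector highly when each component falls inside the same cloud of
training values as the tuned state value V_l.  State values and tolerances
(V_l, delta_l) are the parameters later fitted by the swarm optimizers.

"Terms": each sample's sparse code is partitioned into ``h`` contiguous
sub-segments, each scored by ``n`` cheap feature extractors, giving the h x n
term-feature matrix whose column means form the observation vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats

logger = logging.getLogger(__name__)


def _term_mean(v: np.ndarray) -> float:
    return float(np.mean(v))


def _term_variance(v: np.ndarray) -> float:
    return float(np.var(v))


def _term_skewness(v: np.ndarray) -> float:
    if np.std(v) == 0:
        return 0.0
    return float(sstats.skew(v))


def _term_kurtosis(v: np.ndarray) -> float:
    if np.std(v) == 0:
        return 0.0
    return float(sstats.kurtosis(v, fisher=False))


def _term_log_variance(v: np.ndarray) -> float:
    return float(np.log(np.var(v) + 1e-9))


def _term_log_energy(v: np.ndarray) -> float:
    return float(np.log(np.mean(v ** 2) + 1e-9))


def _term_mean_abs(v: np.ndarray) -> float:
    return float(np.mean(np.abs(v)))


def _term_max_abs(v: np.ndarray) -> float:
    return float(np.max(np.abs(v)))


#: Available per-term extractors (cheap, deterministic scalar summaries).
TERM_EXTRACTORS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": _term_mean,
    "variance": _term_variance,
    "log_variance": _term_log_variance,
    "skewness": _term_skewness,
    "kurtosis": _term_kurtosis,
    "log_energy": _term_log_energy,
    "mean_abs": _term_mean_abs,
    "max_abs": _term_max_abs,
}

#: Default bank: six families (mixing location, spread-on-log-scale and
#: amplitude summaries of the code sub-segments).
DEFAULT_EXTRACTORS = ("mean", "log_variance", "skewness", "log_energy",
                      "mean_abs", "max_abs")


@dataclass(frozen=True)
class TermFeatureMatrix:
    """h x n matrix: entry (j, l) = feature l of term (sub-segment) j."""

    M: np.ndarray
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        object.__setattr__(self, "M", M)
        if M.shape[0] < 1:
            raise ValueError("term-feature matrix needs h >= 1 rows")
        if not np.all(np.isfinite(M)):
            raise ValueError("term-feature matrix must be finite")


@dataclass(frozen=True)
class ObservationVector:
    """Per-family summary values w_1..w_n for one sample."""

    w: np.ndarray
    family: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if not np.all(np.isfinite(w)):
            raise ValueError("observation vector must be finite")


def build_observation_vector(M: TermFeatureMatrix,
                             family: str = "") -> ObservationVector:
    """Column means of the term-feature matrix: w_l = sum_j z_jl / h."""
    if M.M.shape[0] == 0:
        raise ValueError("empty term-feature matrix")
    return ObservationVector(w=M.M.mean(axis=0), family=family)


def terms_from_code(code: np.ndarray, h: int,
                    extractors: Sequence[str] | None = None) -> TermFeatureMatrix:
    """Partition a sparse-code vector into h contiguous terms and score each.

    Trailing remainder entries go to the last term so nothing is lost.
    """
    code = np.asarray(code, dtype=float).ravel()
    if h < 1 or h > len(code):
        raise ValueError(f"h must be in [1, {len(code)}], got {h}")
    names = tuple(extractors) if extractors else DEFAULT_EXTRACTORS
    funcs = []
    for name in names:
        if name not in TERM_EXTRACTORS:
            raise ValueError(f"unknown extractor {name!r}; "
                             f"valid: {tuple(TERM_EXTRACTORS)}")
        funcs.append(TERM_EXTRACTORS[name])
    base = len(code) // h
    rows = []
    for j in range(h):
        start = j * base
        stop = (j + 1) * base if j < h - 1 else len(code)
        seg = code[start:stop]
        rows.append([f(seg) for f in funcs])
    return TermFeatureMatrix(M=np.asarray(rows), terms=names)


_VECTOR_EXTRACTORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda S: S.mean(axis=0),
    "variance": lambda S: S.var(axis=0),
    "log_variance": lambda S: np.log(S.var(axis=0) + 1e-9),
    "skewness": lambda S: _safe_stat(sstats.skew, S),
    "kurtosis": lambda S: _safe_stat(
        lambda v, axis: sstats.kurtosis(v, axis=axis, fisher=False), S),
    "log_energy": lambda S: np.log(np.mean(S ** 2, axis=0) + 1e-9),
    "mean_abs": lambda S: np.mean(np.abs(S), axis=0),
    "max_abs": lambda S: np.max(np.abs(S), axis=0),
}


def _safe_stat(fn, S: np.ndarray) -> np.ndarray:
    out = np.asarray(fn(S, axis=0), dtype=float)
    out[S.std(axis=0) == 0] = 0.0
    return out


def observation_matrix(codes: np.ndarray, h: int,
                       extractors: Sequence[str] | None = None) -> np.ndarray:
    """Observation vectors for many samples (codes: n_atoms x N) -> (N, n).

    Column-vectorized but numerically identical to applying
    :func:`terms_from_code` + :func:`build_observation_vector` per sample.
    """
    codes = np.asarray(codes, dtype=float)
    names = tuple(extractors) if extractors else DEFAULT_EXTRACTORS
    for name in names:
        if name not in _VECTOR_EXTRACTORS:
            raise ValueError(f"unknown extractor {name!r}; "
                             f"valid: {tuple(TERM_EXTRACTORS)}")
    n_atoms, N = codes.shape
    base = n_atoms // h
    term_rows = []
    for j in range(h):
        start = j * base
        stop = (j + 1) * base if j < h - 1 else n_atoms
        block = codes[start:stop]           # (block, N)
        term_rows.append(np.stack(
            [_VECTOR_EXTRACTORS[name](block) for name in names], axis=1))
    return np.mean(term_rows, axis=0)       # (N, n)


def transition_prob(p: int, m: int, n_states: int) -> float:
    """Deterministic left-to-right chain: 1 iff p == m + 1 (1-based states)."""
    if not (1 <= p <= n_states and 1 <= m <= n_states):
        raise ValueError(f"state indices must be in [1, {n_states}]")
    return 1.0 if p == m + 1 else 0.0


def is_associated(w_train: float, w_l: float, V_l: float,
                  delta_l: float) -> bool:
    """Association test: |w' - w_l| <= delta or |w' - V_l| <= delta."""
    if delta_l < 0:
        raise ValueError("delta must be >= 0")
    return abs(w_train - w_l) <= delta_l or abs(w_train - V_l) <= delta_l


@dataclass
class FeatureHMM:
    """One per-family model: state values, tolerances and training values."""

    family: str
    V: np.ndarray                  # (n,) state values
    delta: np.ndarray              # (n,) association tolerances, >= 0
    train_values: np.ndarray | None = None   # (n_train, n) training w' values
    counts: np.ndarray | None = None         # (n, 3) H11, H10, H01
    trained: bool = False

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.V.shape != self.delta.shape or self.V.ndim != 1:
            raise ValueError("V and delta must be 1-D of equal length")
        if np.any(self.delta < 0):
            raise ValueError("delta must be >= 0")

    @property
    def n_states(self) -> int:
        return int(self.V.size)

    def set_params(self, delta: np.ndarray, V: np.ndarray) -> None:
        delta = np.asarray(delta, dtype=float)
        if np.any(delta < 0):
            logger.info("negative delta components clipped to 0")
            delta = np.maximum(delta, 0.0)
        self.delta = delta
        self.V = np.asarray(V, dtype=float)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "V": self.V.tolist(),
            "delta": self.delta.tolist(),
            "counts": None if self.counts is None else self.counts.tolist(),
            "trained": self.trained,
        }


def initialize_model(family: str, train_obs: np.ndarray,
                     delta_scale: float = 1.5) -> FeatureHMM:
    """V_l = training mean of w_l; delta_l = delta_scale * training std.

    The tolerance must cover most of the class cloud or the product of
    per-state emissions vanishes for typical in-class observations; 1.5
    standard deviations keeps roughly the central 87%% of a Gaussian cloud
    associated with the state value while still rejecting far-out values.
    """
    train_obs = np.atleast_2d(np.asarray(train_obs, dtype=float))
    V = train_obs.mean(axis=0)
    delta = delta_scale * train_obs.std(axis=0)
    model = FeatureHMM(family=family, V=V, delta=delta)
    return fit_model(model, train_obs)


def _count_triples(train_vals: np.ndarray, w: np.ndarray, V: np.ndarray,
                   delta: np.ndarray) -> np.ndarray:
    """(n, 3) association counts H11, H10, H01 for reference observation w."""
    A = np.abs(train_vals - w[None, :]) <= delta[None, :]
    B = np.abs(train_vals - V[None, :]) <= delta[None, :]
    H11 = np.count_nonzero(A & B, axis=0)
    H01 = np.count_nonzero(A & ~B, axis=0)
    H10 = np.count_nonzero(B & ~A, axis=0)
    return np.stack([H11, H10, H01], axis=1)


def fit_model(model: FeatureHMM, train_obs: np.ndarray,
              reference: np.ndarray | None = None) -> FeatureHMM:
    """Accumulate the per-state count tables from training observations.

    ``reference`` is the observation vector the counts are taken against;
    by default the family's training mean.  The raw training values are kept
    so emissions for new observations can be re-counted at scoring time.
    """
    train_obs = np.atleast_2d(np.asarray(train_obs, dtype=float))
    if train_obs.shape[0] == 0:
        raise ValueError("empty training set")
    if train_obs.shape[1] != model.n_states:
        raise ValueError("training observation width != number of states")
    if reference is None:
        reference = train_obs.mean(axis=0)
    model.train_values = train_obs
    model.counts = _count_triples(train_obs, np.asarray(reference, float),
                                  model.V, model.delta)
    model.trained = True
    if np.all(model.counts.sum(axis=1) == 0):
        logger.warning("model %s: no training sample associated with any "
                       "state; scoring will be degenerate", model.family)
    return model


def emission_prob(model: FeatureHMM, l: int) -> float:
    """Jaccard emission H11/(H11+H10+H01) at state l (1-based), from the
    count table frozen at fit time."""
    if not model.trained or model.counts is None:
        raise ValueError("model is not trained")
    if not 1 <= l <= model.n_states:
        raise ValueError(f"state index must be in [1, {model.n_states}]")
    h11, h10, h01 = model.counts[l - 1]
    denom = h11 + h10 + h01
    if denom == 0:
        raise ZeroDivisionError(
            f"Jaccard emission undefined at state {l}: no associated "
            f"training samples")
    return float(h11) / float(denom)


def _emissions_for(model: FeatureHMM, w: np.ndarray) -> np.ndarray:
    """Observation-conditional emissions e_l(w_l) for every state."""
    counts = _count_triples(model.train_values, w, model.V, model.delta)
    denom = counts.sum(axis=1)
    em = np.zeros(model.n_states)
    ok = denom > 0
    em[ok] = counts[ok, 0] / denom[ok]
    return em


def forward_probability(model: FeatureHMM, obs: ObservationVector) -> float:
    """P(w_1..w_n | model) by the forward algorithm.

    With the deterministic left-to-right chain started in state 1 the
    recursion reduces to the product of per-state emissions; log-space
    accumulation is used, exact zeros propagate as 0.
    """
    if not model.trained or model.train_values is None:
        raise ValueError("model is not trained")
    w = np.asarray(obs.w, dtype=float)
    if w.size != model.n_states:
        raise ValueError("observation length != number of states")
    if obs.family and obs.family != model.family:
        logger.debug("scoring observation of family %s against model %s",
                     obs.family, model.family)
    em = _emissions_for(model, w)
    if np.any(em == 0):
        return 0.0
    return float(np.exp(np.sum(np.log(em))))


def classify(models: Sequence[FeatureHMM], obs: ObservationVector,
             fallback: str | None = None) -> str:
    """Family of maximal forward probability; lexicographic tie-break.

    If every model assigns probability zero, the configured fallback label
    (default: lexicographically first family) is returned with a warning.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to classify")
    for m in models:
        if not m.trained:
            raise ValueError(f"model {m.family} is not trained")
    probs = {m.family: forward_probability(m, obs) for m in models}
    families = sorted(probs)
    best = max(probs.values())
    if best == 0.0:
        label = fallback if fallback is not None else families[0]
        logger.warning("all forward probabilities zero; fallback %r", label)
        return label
    winners = [f for f in families if probs[f] == best]
    if len(winners) > 1:
        logger.info("tie between %s; lexicographically first chosen", winners)
    return winners[0]


def classify_batch(models: Sequence[FeatureHMM], obs_matrix: np.ndarray,
                   fallback: str | None = None) -> np.ndarray:
    """Vectorized argmax classification of many observation vectors.

    Equivalent to calling :func:`classify` row by row but computes every
    model's per-state emissions for all observations at once.
    """
    obs_matrix = np.atleast_2d(np.asarray(obs_matrix, dtype=float))
    families = sorted(m.family for m in models)
    order = {m.family: m for m in models}
    log_probs = np.empty((obs_matrix.shape[0], len(families)))
    for k, fam in enumerate(families):
        model = order[fam]
        lp = np.zeros(obs_matrix.shape[0])
        for l in range(model.n_states):
            t = model.train_values[:, l]
            V = model.V[l]
            d = model.delta[l]
            A = np.abs(t[:, None] - obs_matrix[None, :, l]) <= d
            B = np.abs(t - V) <= d
            h11 = B.astype(np.float64) @ A
            sA = A.sum(axis=0)
            sB = B.sum()
            denom = sA + sB - h11
            em = np.where(denom > 0, h11 / np.maximum(denom, 1), 0.0)
            with np.errstate(divide="ignore"):
                lp += np.where(em > 0, np.log(np.maximum(em, 1e-300)), -np.inf)
        log_probs[:, k] = lp
    all_zero = np.all(np.isneginf(log_probs), axis=1)
    winners = np.argmax(log_probs, axis=1)  # argmax takes first max: lexicographic
    labels = np.asarray(families, dtype=object)[winners]
    if np.any(all_zero):
        fb = fallback if fallback is not None else families[0]
        labels[all_zero] = fb
    return labels.astype(str)


def forward_probability_batch(models: Sequence[FeatureHMM],
                              obs_matrix: np.ndarray) -> np.ndarray:
    """(N, K) matrix of forward probabilities, columns in sorted family order."""
    obs_matrix = np.atleast_2d(np.asarray(obs_matrix, dtype=float))
    families = sorted(m.family for m in models)
    order = {m.family: m for m in models}
    out = np.empty((obs_matrix.shape[0], len(families)))
    for k, fam in enumerate(families):
        model = order[fam]
        probs = np.ones(obs_matrix.shape[0])
        for l in range(model.n_states):
            t = model.train_values[:, l]
            A = np.abs(t[:, None] - obs_matrix[None, :, l]) <= model.delta[l]
            B = np.abs(t - model.V[l]) <= model.delta[l]
            h11 = B.astype(np.float64) @ A
            denom = A.sum(axis=0) + B.sum() - h11
            em = np.where(denom > 0, h11 / np.maximum(denom, 1), 0.0)
            probs *= em
        out[:, k] = probs
    return out
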