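"""Population metaheuristics (PSO, DE, WOA, BSA) maximizing a fitness.

All four optimizers share the same contract: maximize ``fitness(x)`` over a
box, seed-reproducible, best-so-far never decreasing.  Non-finite fitness
values are treated as -inf (logged).  Bound handling: PSO/DE/WOA clip to the
box; BSA regenerates out-of-bounds trial entries uniformly inside the box, as
its own scheme prescribes.

Defaults follow the printed settings where they exist: PSO inertia 0.5 and
both acceleration constants 4; DE strategy rand/1; BSA mutation scale 5.
Unprinted knobs (DE scale 0.5 / CR 0.9, WOA spiral constant 1, BSA mixrate 1,
population 30, 200 iterations) use standard literature values and are all
exposed on :class:`SwarmConfig`.

In the classifier pipeline the decision vector encodes, per class block, the
association tolerances delta_1..delta_n and the hidden-state values V_1..V_n
of that class's model; the fitness is the validation F1 of the installed
parameters (see :func:`fitness_f1` and :func:`blockwise_search`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from cosparse_eeg.hmm_classifier import FeatureHMM, classify_batch, fit_model

logger = logging.getLogger(__name__)

DE_STRATEGIES = ("rand/1", "best/1", "rand/2", "best/2",
                 "current-to-best/1", "rand-to-best/1")
_DE_NEEDED = {"rand/1": 3, "best/1": 2, "rand/2": 5, "best/2": 4,
              "current-to-best/1": 3, "rand-to-best/1": 2}

ALGORITHMS = ("pso", "de", "woa", "bsa")


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if np.any(lo >= up):
            raise ValueError("every lower bound must be < its upper bound")

    @property
    def dim(self) -> int:
        return int(self.lower.size)

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lower + rng.uniform(size=(n, self.dim)) * (
            self.upper - self.lower)


@dataclass(frozen=True)
class Candidate:
    x: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))


@dataclass(frozen=True)
class SwarmConfig:
    algorithm: str = "de"
    population: int = 30
    iterations: int = 200
    seed: int = 0
    # PSO
    inertia: float = 0.5
    ac1: float = 4.0
    ac2: float = 4.0
    v_max_frac: float = 0.2
    # DE
    de_strategy: str = "rand/1"
    de_scale: float = 0.5
    de_cr: float = 0.9
    # WOA
    woa_spiral: float = 1.0
    # BSA
    bsa_scale: float = 5.0
    bsa_mixrate: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.de_strategy not in DE_STRATEGIES:
            raise ValueError(
                f"unknown DE strategy {self.de_strategy!r}; "
                f"valid: {DE_STRATEGIES}")
        min_pop = _DE_NEEDED[self.de_strategy] + 1 if self.algorithm == "de" else 2
        if self.population < max(2, min_pop):
            raise ValueError(
                f"population {self.population} too small for "
                f"{self.algorithm}/{self.de_strategy}")


def _safe_eval(fitness, X: np.ndarray) -> np.ndarray:
    vals = np.empty(X.shape[0])
    for i, x in enumerate(X):
        v = float(fitness(x))
        if not np.isfinite(v):
            logger.warning("non-finite fitness for candidate %d; set to -inf", i)
            v = -np.inf
        vals[i] = v
    return vals


def pso_optimize(fitness, bounds: Bounds, config: SwarmConfig,
                 seed: int | None = None,
                 x0: np.ndarray | None = None) -> Candidate:
    """Global-best particle swarm with per-dimension random accelerations.

    ``x0`` (optional) replaces the first particle of the initial swarm —
    warm-starting from an incumbent solution.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, D = config.population, bounds.dim
    X = bounds.sample(rng, S)
    if x0 is not None:
        X[0] = bounds.clip(np.asarray(x0, dtype=float))
    span = bounds.upper - bounds.lower
    v_max = config.v_max_frac * span
    V = rng.uniform(-1.0, 1.0, size=(S, D)) * v_max
    fit = _safe_eval(fitness, X)
    pbest, pbest_fit = X.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest, gbest_fit = X[g].copy(), float(fit[g])
    for _ in range(config.iterations):
        r = rng.uniform(size=(S, D))
        R = rng.uniform(size=(S, D))
        V = (config.inertia * V
             + config.ac1 * r * (pbest - X)
             + config.ac2 * R * (gbest[None, :] - X))
        V = np.clip(V, -v_max, v_max)
        X = bounds.clip(X + V)
        fit = _safe_eval(fitness, X)
        better = fit > pbest_fit
        pbest[better] = X[better]
        pbest_fit[better] = fit[better]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    return Candidate(x=gbest, fitness=gbest_fit)


def de_mutation(population: np.ndarray, best: np.ndarray, i: int,
                strategy: str, C: float, rng: np.random.Generator) -> np.ndarray:
    """Mutant vector for target i under the chosen strategy.

    Distinct donor indices are drawn without replacement excluding i.
    """
    if strategy not in DE_STRATEGIES:
        raise ValueError(f"unknown DE strategy {strategy!r}; "
                         f"valid: {DE_STRATEGIES}")
    S = population.shape[0]
    need = _DE_NEEDED[strategy]
    pool = np.delete(np.arange(S), i)
    if pool.size < need:
        raise ValueError(f"population too small for {strategy}")
    r = rng.choice(pool, size=need, replace=False)
    z = population
    if strategy == "rand/1":
        return z[r[0]] + C * (z[r[1]] - z[r[2]])
    if strategy == "best/1":
        return best + C * (z[r[0]] - z[r[1]])
    if strategy == "rand/2":
        return z[r[0]] + C * (z[r[1]] - z[r[2]]) + C * (z[r[3]] - z[r[4]])
    if strategy == "best/2":
        return best + C * (z[r[0]] - z[r[1]]) + C * (z[r[2]] - z[r[3]])
    if strategy == "current-to-best/1":
        return z[i] + C * (z[r[0]] - z[i]) + C * (z[r[1]] - z[r[2]])
    # rand-to-best/1
    return z[i] + C * (best - z[i]) + C * (z[r[0]] - z[r[1]])


def de_optimize(fitness, bounds: Bounds, config: SwarmConfig,
                seed: int | None = None,
                x0: np.ndarray | None = None) -> Candidate:
    """Differential evolution: mutation, binomial crossover, greedy selection."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, D = config.population, bounds.dim
    X = bounds.sample(rng, S)
    if x0 is not None:
        X[0] = bounds.clip(np.asarray(x0, dtype=float))
    fit = _safe_eval(fitness, X)
    for _ in range(config.iterations):
        best = X[int(np.argmax(fit))]
        newX = X.copy()
        newfit = fit.copy()
        for i in range(S):
            m = de_mutation(X, best, i, config.de_strategy, config.de_scale,
                            rng)
            cross = rng.uniform(size=D) <= config.de_cr
            cross[rng.integers(D)] = True        # forced j_rand dimension
            trial = np.where(cross, m, X[i])
            trial = bounds.clip(trial)
            tf = float(fitness(trial))
            if not np.isfinite(tf):
                logger.warning("non-finite trial fitness; set to -inf")
                tf = -np.inf
            if tf > fit[i]:                      # greedy selection
                newX[i], newfit[i] = trial, tf
        X, fit = newX, newfit
    g = int(np.argmax(fit))
    return Candidate(x=X[g].copy(), fitness=float(fit[g]))


def woa_optimize(fitness, bounds: Bounds, config: SwarmConfig,
                 seed: int | None = None,
                 x0: np.ndarray | None = None) -> Candidate:
    """Whale optimization: shrinking encircling, spiral update, random search.

    Per whale per iteration: draw k in [0,1]; k >= 0.5 takes the logarithmic
    spiral toward the best solution, otherwise the encircling move — around
    the best whale when |M| < 1, around a random whale when |M| >= 1.  The
    control scalar m decreases linearly from 2 to 0 over the run.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, D = config.population, bounds.dim
    X = bounds.sample(rng, S)
    if x0 is not None:
        X[0] = bounds.clip(np.asarray(x0, dtype=float))
    fit = _safe_eval(fitness, X)
    g = int(np.argmax(fit))
    best, best_fit = X[g].copy(), float(fit[g])
    T = config.iterations
    for t in range(T):
        m = 2.0 - 2.0 * t / max(T, 1)
        for i in range(S):
            k = rng.uniform()
            if k >= 0.5:
                dis = np.abs(best - X[i])
                q = rng.uniform(-1.0, 1.0)
                X[i] = dis * np.exp(config.woa_spiral * q) * np.cos(
                    2.0 * np.pi * q) + best
            else:
                r = rng.uniform(size=D)
                M = 2.0 * m * r - m
                N = 2.0 * rng.uniform(size=D)
                if np.max(np.abs(M)) < 1.0:
                    dis = np.abs(N * best - X[i])
                    X[i] = best - M * dis
                else:
                    j = int(rng.integers(S))
                    dis = np.abs(N * X[j] - X[i])
                    X[i] = X[j] - M * dis
            X[i] = bounds.clip(X[i])
        fit = _safe_eval(fitness, X)
        g = int(np.argmax(fit))
        if fit[g] > best_fit:
            best, best_fit = X[g].copy(), float(fit[g])
    return Candidate(x=best, fitness=best_fit)


def bsa_optimize(fitness, bounds: Bounds, config: SwarmConfig,
                 seed: int | None = None,
                 x0: np.ndarray | None = None) -> Candidate:
    """Backtracking search: historical population, map crossover, greedy pick."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, D = config.population, bounds.dim
    A = bounds.sample(rng, S)
    if x0 is not None:
        A[0] = bounds.clip(np.asarray(x0, dtype=float))
    oldA = bounds.sample(rng, S)
    fit = _safe_eval(fitness, A)
    g = int(np.argmax(fit))
    best, best_fit = A[g].copy(), float(fit[g])
    for _ in range(config.iterations):
        # Selection-I: maybe snapshot current population, then permute history
        p, q = rng.uniform(), rng.uniform()
        if p < q:
            oldA = A.copy()
        oldA = oldA[rng.permutation(S)]
        M = A + config.bsa_scale * (oldA - A)
        # binary map: row i exchanges ceil(mixrate * rand * D) dimensions
        # (at least one) with the mutant, the classic partial crossover
        mask = np.zeros((S, D), dtype=bool)
        for i in range(S):
            n_cross = max(int(np.ceil(config.bsa_mixrate * rng.uniform() * D)),
                          1)
            mask[i, rng.choice(D, size=n_cross, replace=False)] = True
        Tp = np.where(mask, M, A)
        # regenerate out-of-bounds entries uniformly inside the box
        oob = (Tp < bounds.lower) | (Tp > bounds.upper)
        if np.any(oob):
            regen = bounds.sample(rng, S)
            Tp = np.where(oob, regen, Tp)
        tfit = _safe_eval(fitness, Tp)
        better = tfit > fit
        A[better] = Tp[better]
        fit[better] = tfit[better]
        g = int(np.argmax(fit))
        if fit[g] > best_fit:
            best, best_fit = A[g].copy(), float(fit[g])
    return Candidate(x=best, fitness=best_fit)


_DISPATCH = {"pso": pso_optimize, "de": de_optimize, "woa": woa_optimize,
             "bsa": bsa_optimize}


def optimize(fitness, bounds: Bounds, config: SwarmConfig,
             seed: int | None = None,
             x0: np.ndarray | None = None) -> Candidate:
    """Run the optimizer named in ``config.algorithm``."""
    return _DISPATCH[config.algorithm](fitness, bounds, config, seed, x0)


# ---------------------------------------------------------------------------
# HMM-parameter fitness and blockwise search


def f1_score_binary(y_true: np.ndarray, y_pred: np.ndarray,
                    positive: str) -> float:
    """F1 = 2 TP / (2 TP + FP + FN) of the designated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    denom = 2 * tp + fp + fn
    return 2.0 * tp / denom if denom > 0 else 0.0


def fitness_f1(params: np.ndarray, models: dict[str, FeatureHMM],
               family: str, train_obs: dict[str, np.ndarray],
               val_obs: np.ndarray, val_labels: np.ndarray,
               positive: str) -> float:
    """Install (delta, V) for one family's block, refit, score validation F1.

    ``params`` concatenates delta_1..delta_n and V_1..V_n for ``family``;
    negative deltas are clipped to zero.  Other families keep their current
    parameters.
    """
    if not np.any(np.asarray(val_labels) == positive):
        raise ValueError("validation pool contains no positive samples")
    model = models[family]
    n = model.n_states
    params = np.asarray(params, dtype=float)
    model.set_params(params[:n], params[n:2 * n])
    fit_model(model, train_obs[family])
    preds = classify_batch(list(models.values()), val_obs)
    return f1_score_binary(val_labels, preds, positive)


def parameter_bounds(train_obs: np.ndarray) -> Bounds:
    """Box for one family block: delta in [0, 2 std(w_l)], V in [min, max]."""
    train_obs = np.atleast_2d(np.asarray(train_obs, dtype=float))
    std = train_obs.std(axis=0)
    std = np.where(std > 0, std, 1e-6)
    lo_v = train_obs.min(axis=0)
    hi_v = train_obs.max(axis=0)
    degenerate = hi_v - lo_v <= 0
    hi_v = np.where(degenerate, lo_v + 1e-6, hi_v)
    lower = np.concatenate([np.zeros_like(std) - 1e-12, lo_v])
    upper = np.concatenate([2.0 * std, hi_v])
    return Bounds(lower=lower, upper=upper)


def _log_forward(model: FeatureHMM, obs_matrix: np.ndarray) -> np.ndarray:
    """Log forward probability of each observation row under one model."""
    lp = np.zeros(obs_matrix.shape[0])
    for l in range(model.n_states):
        t = model.train_values[:, l]
        A = np.abs(t[:, None] - obs_matrix[None, :, l]) <= model.delta[l]
        B = np.abs(t - model.V[l]) <= model.delta[l]
        h11 = B.astype(np.float64) @ A
        denom = A.sum(axis=0) + B.sum() - h11
        em = np.where(denom > 0, h11 / np.maximum(denom, 1), 0.0)
        with np.errstate(divide="ignore"):
            lp += np.where(em > 0, np.log(np.maximum(em, 1e-300)), -np.inf)
    return lp


def blockwise_search(models: dict[str, FeatureHMM],
                     train_obs: dict[str, np.ndarray],
                     val_obs: np.ndarray, val_labels: np.ndarray,
                     positive: str, config: SwarmConfig,
                     ) -> tuple[dict[str, FeatureHMM], dict[str, float]]:
    """Optimize each family's (delta, V) block with the others frozen.

    Families are visited in sorted order; returns the fitted models and the
    per-block best fitness.  With ``config.iterations == 0`` the models keep
    their initialization values (the block search is a no-op) and the trace
    records the fitness of those initial parameters.

    While one family's block is searched, the frozen families' validation
    log-probabilities are cached — the result is identical to re-scoring
    every model per fitness call, just cheaper.
    """
    trace: dict[str, float] = {}
    val_obs = np.atleast_2d(np.asarray(val_obs, dtype=float))
    val_labels = np.asarray(val_labels)
    families = sorted(models)
    for k, family in enumerate(families):
        def fit_fn(x, fam=family):
            return fitness_f1(x, models, fam, train_obs, val_obs,
                              val_labels, positive)

        model = models[family]
        if config.iterations == 0:
            trace[family] = fit_fn(
                np.concatenate([model.delta, model.V]))
            continue
        # frozen families' log-probabilities on the validation pool
        other_lp = np.column_stack([
            _log_forward(models[f], val_obs) for f in families
        ])
        fam_col = families.index(family)
        fam_labels = np.asarray(families, dtype=object)
        n = model.n_states
        # per-state |train value - validation value| matrices are independent
        # of (delta, V): cache them once per block
        t_vals = np.asarray(train_obs[family], dtype=np.float32)
        v_vals = np.asarray(val_obs, dtype=np.float32)
        absdiff = [np.abs(t_vals[:, l][:, None] - v_vals[None, :, l])
                   for l in range(n)]

        def fast_fit_fn(x, fam=family, col=fam_col):
            # identical scoring to fitness_f1 (count tables only matter for
            # emission_prob reporting, not for forward scoring), cheaper
            x = np.asarray(x, dtype=float)
            delta = np.maximum(x[:n], 0.0)
            V = x[n:2 * n]
            lp_fam = np.zeros(v_vals.shape[0])
            for l in range(n):
                A = absdiff[l] <= delta[l]
                B = np.abs(t_vals[:, l] - V[l]) <= delta[l]
                h11 = (B[:, None] & A).sum(axis=0)
                denom = A.sum(axis=0) + B.sum() - h11
                em = np.where(denom > 0, h11 / np.maximum(denom, 1), 0.0)
                with np.errstate(divide="ignore"):
                    lp_fam += np.where(em > 0,
                                       np.log(np.maximum(em, 1e-300)),
                                       -np.inf)
            lp = other_lp.copy()
            lp[:, col] = lp_fam
            all_zero = np.all(np.isneginf(lp), axis=1)
            preds = fam_labels[np.argmax(lp, axis=1)].astype(str)
            preds[all_zero] = families[0]
            return f1_score_binary(val_labels, preds, positive)

        bounds = parameter_bounds(train_obs[family])
        best = optimize(fast_fit_fn, bounds, config,
                        seed=(config.seed * 1009 + k) % (2 ** 31),
                        x0=np.concatenate([model.delta, model.V]))
        # re-install the winning block
        fit_fn(best.x)
        trace[family] = best.fitness
    return models, trace
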