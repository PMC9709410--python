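"""Entropy-based active learning over the pool of unlabelled samples.

Each round: refit all per-class models on the labelled pool D with the chosen
metaheuristic, score every pool sample by the Shannon entropy of its
normalized per-class forward probabilities, and move the B_s most uncertain
samples (their held-back true labels revealed on selection — the standard
active-learning simulation) from the pool N into D.  The loop stops after a
configured number of rounds or when N is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cosparse_eeg.hmm_classifier import (
    FeatureHMM,
    forward_probability_batch,
    initialize_model,
)
from cosparse_eeg.swarm_optimizers import SwarmConfig, blockwise_search

logger = logging.getLogger(__name__)


@dataclass
class DataPools:
    """Labelled training pool D and unlabelled query pool N.

    Pool membership is by row; ``pool_labels`` are the held-back ground-truth
    labels revealed when a sample is selected.
    """

    train_obs: np.ndarray
    train_labels: np.ndarray
    pool_obs: np.ndarray
    pool_labels: np.ndarray
    batch_size: int = 1

    def __post_init__(self) -> None:
        self.train_obs = np.atleast_2d(np.asarray(self.train_obs, float))
        self.pool_obs = np.atleast_2d(np.asarray(self.pool_obs, float))
        self.train_labels = np.asarray(self.train_labels)
        self.pool_labels = np.asarray(self.pool_labels)
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.train_obs.shape[0] != self.train_labels.shape[0]:
            raise ValueError("training pool labels/rows mismatch")
        if self.pool_obs.shape[0] != self.pool_labels.shape[0]:
            raise ValueError("query pool labels/rows mismatch")

    @property
    def n_train(self) -> int:
        return int(self.train_obs.shape[0])

    @property
    def n_pool(self) -> int:
        return int(self.pool_obs.shape[0])


def posterior_over_families(models, obs_w: np.ndarray) -> np.ndarray:
    """Forward probabilities normalized to a posterior over families.

    All-zero forward probabilities yield the uniform posterior with a warning.
    """
    probs = forward_probability_batch(models, np.atleast_2d(obs_w))[0]
    total = probs.sum()
    if total == 0:
        logger.warning("all forward probabilities zero; uniform posterior")
        return np.full(probs.size, 1.0 / probs.size)
    return probs / total


def entropy_score(posterior: np.ndarray) -> float:
    """phi(S) = -sum_i p_i ln p_i, with 0 ln 0 := 0; in [0, ln k]."""
    p = np.asarray(posterior, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("posterior must be non-negative and sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _pool_entropies(models, pool_obs: np.ndarray) -> np.ndarray:
    probs = forward_probability_batch(models, pool_obs)
    totals = probs.sum(axis=1, keepdims=True)
    k = probs.shape[1]
    post = np.where(totals > 0, probs / np.maximum(totals, 1e-300),
                    1.0 / k)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(post > 0, np.log(np.maximum(post, 1e-300)), 0.0)
    return -np.sum(post * logp, axis=1)


@dataclass
class FeedbackRound:
    round_index: int
    selected_indices: list[int]
    selected_entropies: list[float]
    max_remaining_entropy: float
    n_train: int
    n_pool: int


def feedback_loop(pools: DataPools, optimizer: SwarmConfig,
                  rounds: int = 5, positive: str | None = None,
                  ) -> tuple[DataPools, dict[str, FeatureHMM],
                             list[FeedbackRound]]:
    """Run the retrain-select-move loop; returns pools, models and a log.

    Models are refit from scratch on the current D each round (fresh-start;
    pass ``optimizer.iterations == 0`` to skip metaheuristic tuning and keep
    moment-initialized models).  |D| + |N| is conserved; each selected
    sample's entropy is >= every entropy left in the pool that round.
    """
    if pools.n_pool == 0:
        raise ValueError("query pool is empty")
    classes = sorted(set(pools.train_labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in the training pool")
    if positive is None:
        positive = classes[-1]
    total = pools.n_train + pools.n_pool
    log: list[FeedbackRound] = []
    models: dict[str, FeatureHMM] = {}
    for rnd in range(rounds):
        if pools.n_pool == 0:
            logger.info("feedback loop stopped: pool exhausted after %d "
                        "rounds", rnd)
            break
        models = {
            c: initialize_model(c, pools.train_obs[pools.train_labels == c])
            for c in classes
        }
        if optimizer.iterations > 0:
            train_by_class = {c: pools.train_obs[pools.train_labels == c]
                              for c in classes}
            blockwise_search(models, train_by_class, pools.train_obs,
                             pools.train_labels, positive,
                             optimizer)
        phi = _pool_entropies(list(models.values()), pools.pool_obs)
        bs = min(pools.batch_size, pools.n_pool)
        # descending entropy; ties broken by pool position (stable sort on
        # the negated scores keeps earlier samples first)
        order = np.argsort(-phi, kind="stable")
        chosen = order[:bs]
        remaining = order[bs:]
        log.append(FeedbackRound(
            round_index=rnd,
            selected_indices=[int(i) for i in chosen],
            selected_entropies=[float(phi[i]) for i in chosen],
            max_remaining_entropy=float(phi[remaining].max())
            if remaining.size else 0.0,
            n_train=pools.n_train + bs,
            n_pool=pools.n_pool - bs,
        ))
        pools = DataPools(
            train_obs=np.vstack([pools.train_obs, pools.pool_obs[chosen]]),
            train_labels=np.concatenate([pools.train_labels,
                                         pools.pool_labels[chosen]]),
            pool_obs=pools.pool_obs[remaining],
            pool_labels=pools.pool_labels[remaining],
            batch_size=pools.batch_size,
        )
        assert pools.n_train + pools.n_pool == total
    return pools, models, log
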