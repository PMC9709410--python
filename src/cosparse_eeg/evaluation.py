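"""Confusion-matrix metrics, grouped k-fold CV and the end-to-end pipeline.

The pipeline follows the method's flow: segment the records, learn the
analysis dictionary on the segment matrix (sparse modeling precedes the fold
split), derive per-segment observation vectors from the sparse codes, then
per fold either fit the per-class pliable HMMs with a metaheuristic and
classify by maximum forward probability, or train the 1D CNN on the raw
segments.  Folds are grouped by source record by default so chunks of one
recording never straddle the train/test boundary; ``grouped=False``
reproduces the chunk-level split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from cosparse_eeg import signal_data as sd
from cosparse_eeg import sparse_model as sm
from cosparse_eeg import hmm_classifier as hc
from cosparse_eeg import swarm_optimizers as so
from cosparse_eeg import cnn_model as cm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("empty confusion matrix")

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_pred == positive) & (y_true == positive))),
            FP=int(np.sum((y_pred == positive) & (y_true != positive))),
            TN=int(np.sum((y_pred != positive) & (y_true != positive))),
            FN=int(np.sum((y_pred != positive) & (y_true == positive))),
        )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy (percent) and F1 (fraction).

    A metric with a zero denominator is reported as None with a warning.
    """
    out: dict[str, float | None] = {}
    if c.TP + c.FN > 0:
        out["sensitivity"] = 100.0 * c.TP / (c.TP + c.FN)
    else:
        warnings.warn("sensitivity undefined: no positive ground truth",
                      UserWarning, stacklevel=2)
        out["sensitivity"] = None
    if c.TN + c.FP > 0:
        out["specificity"] = 100.0 * c.TN / (c.TN + c.FP)
    else:
        warnings.warn("specificity undefined: no negative ground truth",
                      UserWarning, stacklevel=2)
        out["specificity"] = None
    total = c.TP + c.FP + c.TN + c.FN
    out["accuracy"] = 100.0 * (c.TP + c.TN) / total
    denom = 2 * c.TP + c.FP + c.FN
    out["f1"] = 2.0 * c.TP / denom if denom > 0 else None
    if out["f1"] is None:
        warnings.warn("F1 undefined: no positive samples or predictions",
                      UserWarning, stacklevel=2)
    return out


@dataclass(frozen=True)
class FoldPlan:
    """Fold index per segment; folds partition the data, sizes within 1
    (within 1 group for grouped plans)."""

    assignments: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(n: int, k: int, seed: int,
               groups: np.ndarray | None = None) -> FoldPlan:
    """Random near-equal split into k folds, optionally grouped.

    With ``groups`` (e.g. source record ids) whole groups are assigned to
    folds so no group spans the train/test boundary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if groups is None:
        if n < k:
            raise ValueError(f"cannot split {n} items into {k} folds")
        order = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(order, k)):
            assignments[chunk] = fold
    else:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups length must equal n")
        uniq = np.asarray(sorted(set(groups.tolist())), dtype=object)
        if len(uniq) < k:
            raise ValueError(
                f"cannot split {len(uniq)} groups into {k} folds")
        order = rng.permutation(len(uniq))
        fold_of_group = {}
        for fold, chunk in enumerate(np.array_split(order, k)):
            for gi in chunk:
                fold_of_group[uniq[gi]] = fold
        assignments = np.asarray([fold_of_group[g] for g in groups])
    return FoldPlan(assignments=assignments, k=k, seed=seed)


# ---------------------------------------------------------------------------
# pipeline stages


def default_synthetic_spec(seed: int = 0, **overrides) -> sd.SyntheticSpec:
    return sd.SyntheticSpec(seed=seed, **overrides)


def segments_to_codes(dataset: sd.SegmentedDataset,
                      adla_config: sm.ADLAConfig) -> tuple[sm.AnalysisModel,
                                                           np.ndarray]:
    """Learn the analysis dictionary on all segments; return per-segment codes.

    Sparse modeling precedes the fold split; it is unsupervised, so labels
    never leak.  Codes of any segment are the proximal code update applied to
    its analysis coefficients.
    """
    T = dataset.segments.T                 # (p, N)
    model = sm.adla_fit(T, adla_config)
    codes = sm.update_code(model.Omega, T, adla_config.measure,
                           adla_config.beta, adla_config.zero_tol)
    return model, codes


def codes_to_observations(codes: np.ndarray, h: int = 4,
                          extractors=None) -> np.ndarray:
    """Observation matrix (N, n_features) from sparse codes (n_atoms, N)."""
    return hc.observation_matrix(codes, h, extractors)


def _internal_split(labels: np.ndarray, frac: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split (validation fraction frac)."""
    labels = np.asarray(labels)
    val = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(int(round(frac * idx.size)), 1)
        val.append(idx[:n_val])
    val = np.concatenate(val)
    mask = np.ones(labels.size, dtype=bool)
    mask[val] = False
    return np.flatnonzero(mask), val


def fit_hmm_fold(obs: np.ndarray, labels: np.ndarray, positive: str,
                 optimizer: so.SwarmConfig, val_frac: float = 0.25,
                 ) -> dict[str, hc.FeatureHMM]:
    """Fit per-class models on one training fold, tuning (delta, V) by the
    configured metaheuristic against an internal stratified validation split."""
    rng = np.random.default_rng(optimizer.seed)
    classes = sorted(set(labels.tolist()))
    tr_idx, val_idx = _internal_split(labels, val_frac, rng)
    tr_obs, tr_lab = obs[tr_idx], labels[tr_idx]
    models = {c: hc.initialize_model(c, tr_obs[tr_lab == c]) for c in classes}
    train_by_class = {c: tr_obs[tr_lab == c] for c in classes}
    so.blockwise_search(models, train_by_class, obs[val_idx], labels[val_idx],
                        positive, optimizer)
    return models


def run_hmm_cv(dataset: sd.SegmentedDataset, adla_config: sm.ADLAConfig,
               optimizer: so.SwarmConfig, positive: str, k: int = 10,
               grouped: bool = True, seed: int = 0, h: int = 4,
               extractors=None, n_eval_folds: int | None = None) -> dict:
    """Full swarm-HMM cross-validation; returns per-fold and mean metrics."""
    _, codes = segments_to_codes(dataset, adla_config)
    obs = codes_to_observations(codes, h, extractors)
    labels = dataset.labels
    groups = dataset.record_ids if grouped else None
    plan = make_folds(dataset.n_segments, k, seed, groups)
    folds = range(k if n_eval_folds is None else min(n_eval_folds, k))
    per_fold = []
    preds_all, true_all = [], []
    for fold in folds:
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        opt = so.SwarmConfig(**{**_swarm_dict(optimizer),
                                "seed": (seed * 7919 + fold) % (2 ** 31)})
        models = fit_hmm_fold(obs[tr], labels[tr], positive, opt)
        preds = hc.classify_batch(list(models.values()), obs[te])
        counts = ConfusionCounts.from_predictions(labels[te], preds, positive)
        per_fold.append(metrics(counts))
        preds_all.append(preds)
        true_all.append(labels[te])
    return _summarize(per_fold, preds_all, true_all, positive)


def run_cnn_cv(dataset: sd.SegmentedDataset, train_config: cm.TrainConfig,
               positive: str, k: int = 10, grouped: bool = True,
               seed: int = 0, arch: cm.CNNArchitecture | None = None,
               n_eval_folds: int | None = None) -> dict:
    """CNN cross-validation on the raw segments."""
    arch = arch or cm.CNNArchitecture()
    labels = dataset.labels
    groups = dataset.record_ids if grouped else None
    plan = make_folds(dataset.n_segments, k, seed, groups)
    folds = range(k if n_eval_folds is None else min(n_eval_folds, k))
    per_fold = []
    preds_all, true_all = [], []
    seg_len = dataset.segments.shape[1]
    for fold in folds:
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        net = cm.build_network(arch, seg_len,
                               seed=(seed * 104729 + fold) % (2 ** 31))
        cfg = cm.TrainConfig(**{**_train_dict(train_config),
                                "seed": (seed * 15485863 + fold) % (2 ** 31)})
        net, _trace = cm.train(net, dataset.segments[tr], labels[tr], cfg)
        preds, _proba = cm.predict(net, dataset.segments[te])
        counts = ConfusionCounts.from_predictions(labels[te], preds, positive)
        per_fold.append(metrics(counts))
        preds_all.append(preds)
        true_all.append(labels[te])
    return _summarize(per_fold, preds_all, true_all, positive)


def _swarm_dict(c: so.SwarmConfig) -> dict:
    from dataclasses import asdict
    return asdict(c)


def _train_dict(c: cm.TrainConfig) -> dict:
    from dataclasses import asdict
    return asdict(c)


def _summarize(per_fold, preds_all, true_all, positive) -> dict:
    keys = ("sensitivity", "specificity", "accuracy", "f1")
    mean = {}
    std = {}
    for key in keys:
        vals = [m[key] for m in per_fold if m[key] is not None]
        mean[key] = float(np.mean(vals)) if vals else None
        std[key] = float(np.std(vals)) if vals else None
    pooled = ConfusionCounts.from_predictions(
        np.concatenate(true_all), np.concatenate(preds_all), positive)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pooled_metrics = metrics(pooled)
    return {"per_fold": per_fold, "mean": mean, "std": std,
            "pooled": pooled_metrics,
            "n_test_total": int(sum(len(t) for t in true_all))}


# ---------------------------------------------------------------------------
# config-driven entry point


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "classifier": "si-hmm",          # or "cnn"
    "positive": "ictal",
    "data": {},                       # SyntheticSpec overrides
    "segmentation": {"n_chunks": sd.BONN_N_CHUNKS},
    "adla": {"n_atoms": 64, "lam": 1.0, "beta": 2.0, "measure": "l1",
             "max_iter": 8, "tol": 1e-4},
    "hmm": {"h": 4, "extractors": None},
    "optimizer": {"algorithm": "de", "population": 10, "iterations": 12},
    "cv": {"k": 10, "grouped": True, "n_eval_folds": None},
    "cnn": {"epochs": 30, "batch_size": 200, "learning_rate": 1e-4},
    "repeats": 1,
}


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured end-to-end experiment.

    ``repeats`` re-runs the whole experiment with derived seeds and averages
    the reported means.  The report carries every stage's configuration and
    all seeds used, so identical configs reproduce identical reports.
    """
    cfg = _merged(config)
    reports = []
    for rep in range(int(cfg["repeats"])):
        seed = (int(cfg["seed"]) + 977 * rep) % (2 ** 31)
        spec = sd.SyntheticSpec(seed=seed, **cfg["data"])
        records = sd.generate_synthetic(spec)
        dataset = sd.segment_records(records, cfg["segmentation"]["n_chunks"])
        stage = "classification"
        try:
            if cfg["classifier"] == "si-hmm":
                adla = sm.ADLAConfig(seed=seed, **cfg["adla"])
                opt = so.SwarmConfig(seed=seed, **cfg["optimizer"])
                rep_out = run_hmm_cv(
                    dataset, adla, opt, cfg["positive"],
                    k=cfg["cv"]["k"], grouped=cfg["cv"]["grouped"],
                    seed=seed, h=cfg["hmm"]["h"],
                    extractors=cfg["hmm"]["extractors"],
                    n_eval_folds=cfg["cv"]["n_eval_folds"])
            elif cfg["classifier"] == "cnn":
                tc = cm.TrainConfig(seed=seed, **cfg["cnn"])
                rep_out = run_cnn_cv(
                    dataset, tc, cfg["positive"], k=cfg["cv"]["k"],
                    grouped=cfg["cv"]["grouped"], seed=seed,
                    n_eval_folds=cfg["cv"]["n_eval_folds"])
            else:
                raise ValueError(
                    f"classifier must be 'si-hmm' or 'cnn', got "
                    f"{cfg['classifier']!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        rep_out["seed"] = seed
        reports.append(rep_out)
    keys = ("sensitivity", "specificity", "accuracy", "f1")
    mean_of_means = {}
    for key in keys:
        vals = [r["mean"][key] for r in reports if r["mean"][key] is not None]
        mean_of_means[key] = float(np.mean(vals)) if vals else None
    return {"config": cfg, "repeats": reports, "mean": mean_of_means}
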