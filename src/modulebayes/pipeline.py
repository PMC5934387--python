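"""End-to-end training, cross-validation and majority-vote prediction.

The deployable classifier is an odd-sized ensemble of consensus Bayesian
networks sharing one eigengene model and one discretizer. Samples are
partitioned into k stratified folds; model i is trained on all folds except
fold i (subsampling without replacement, which also makes the k models the
exact cross-validation models). A new sample is classified by projecting
the trained eigengenes, replaying the discretization, reading each model's
Effect posterior, and taking the majority vote.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import (
    BNModel,
    DiscreteData,
    DiscretizationModel,
    bootstrap_structures,
    consensus_network,
    fit_parameters,
    hartemink_discretize,
)
from .coexpression import (
    ModuleAssignment,
    adjacency,
    detect_modules,
    merge_close_modules,
    pick_soft_threshold,
    topological_overlap,
)
from .config import BNConfig, RunConfig
from .eigengenes import EigengeneModel, compute_eigengenes, project_eigengenes

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleModel",
    "PerformanceReport",
    "stratified_folds",
    "train_ensemble",
    "train_from_expression",
    "predict",
    "predict_from_eigengenes",
    "cross_validate",
    "performance",
]

EFFECT = "Effect"


@dataclass
class PerformanceReport:
    """Confusion counts, threshold metrics, and the ROC summary."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "auc": self.auc,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


@dataclass
class EnsembleModel:
    """k consensus Bayesian networks over one shared eigengene space."""

    eigengene_model: EigengeneModel | None
    discretizer: DiscretizationModel
    bn_models: list[BNModel]
    fold_assignment: list[int]
    seed: int
    config: dict = field(default_factory=dict)
    module_labels: dict[str, int] | None = None

    @property
    def k(self) -> int:
        return len(self.bn_models)

    def to_dict(self) -> dict:
        return {
            "type": "ensemble",
            "eigengene_model": (
                self.eigengene_model.to_dict() if self.eigengene_model else None
            ),
            "discretizer": self.discretizer.to_dict(),
            "bn_models": [m.to_dict() for m in self.bn_models],
            "fold_assignment": [int(f) for f in self.fold_assignment],
            "seed": int(self.seed),
            "config": self.config,
            "module_labels": self.module_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            eigengene_model=(
                EigengeneModel.from_dict(d["eigengene_model"])
                if d.get("eigengene_model")
                else None
            ),
            discretizer=DiscretizationModel.from_dict(d["discretizer"]),
            bn_models=[BNModel.from_dict(m) for m in d["bn_models"]],
            fold_assignment=[int(f) for f in d["fold_assignment"]],
            seed=int(d["seed"]),
            config=d.get("config", {}),
            module_labels=d.get("module_labels"),
        )


def stratified_folds(labels: pd.Series, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random stratified partition into k folds of near-equal size.

    Within each class, shuffled members are dealt round-robin through a
    running counter, so overall fold sizes differ by at most one and every
    fold contains both classes whenever each class has >= k members.
    """
    n = len(labels)
    folds = np.empty(n, dtype=int)
    counter = 0
    lab = labels.to_numpy()
    for c in np.unique(lab):
        members = np.flatnonzero(lab == c)
        rng.shuffle(members)
        for pos in members:
            folds[pos] = counter % k
            counter += 1
    return folds


def _fit_fold_model(
    data: DiscreteData,
    blacklist: set[tuple[str, str]],
    cfg: BNConfig,
    seed: int,
) -> BNModel:
    boot = bootstrap_structures(
        data, R=cfg.R, blacklist=blacklist, iss=cfg.iss, tol=cfg.tol,
        restarts=cfg.restarts, seed=seed,
    )
    dag, _ = consensus_network(
        boot, top_fraction=cfg.top_fraction,
        strength_threshold=cfg.strength_threshold, blacklist=blacklist,
    )
    return fit_parameters(dag, data, iss=cfg.iss, effect=EFFECT)


def train_ensemble(
    eigen: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    seed: int = 0,
    config: BNConfig | None = None,
    eigengene_model: EigengeneModel | None = None,
) -> EnsembleModel:
    """Train the k-model subsampled ensemble on an eigengene matrix.

    One Hartemink discretizer is learned on the full matrix and shared;
    model i is then trained (bootstrap + consensus + CPT fit) on every
    fold except fold i. ``k`` must be odd so the majority vote cannot tie
    (k = 1 degenerates to a single model on all data). Deterministic given
    ``seed``.
    """
    if k != 1 and k % 2 == 0:
        raise ValueError("k must be odd")
    cfg = config or BNConfig()
    cfg.validate()
    lab = labels.reindex(eigen.index)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    rng = np.random.default_rng(seed)
    disc_model, disc = hartemink_discretize(
        eigen, levels=cfg.levels, ibreaks=cfg.ibreaks,
        extra=pd.DataFrame({EFFECT: lab.astype(int)}),
    )
    frame = disc.copy()
    frame[EFFECT] = lab.astype(int).to_numpy()
    arities = {v: cfg.levels for v in disc.columns}
    arities[EFFECT] = 2
    blacklist = {(EFFECT, str(v)) for v in disc.columns}
    folds = (
        stratified_folds(lab, k, rng) if k > 1 else np.zeros(len(lab), dtype=int) - 1
    )
    model_seeds = rng.integers(0, 2**31, size=k)
    bns = []
    for i in range(k):
        mask = folds != i
        sub_lab = lab.to_numpy()[mask]
        if len(np.unique(sub_lab)) < 2:
            raise ValueError(f"training subsample {i} contains a single class")
        data = DiscreteData(frame.loc[mask], arities)
        bns.append(_fit_fold_model(data, blacklist, cfg, int(model_seeds[i])))
    return EnsembleModel(
        eigengene_model=eigengene_model,
        discretizer=disc_model,
        bn_models=bns,
        fold_assignment=[int(f) for f in folds],
        seed=int(seed),
        config={
            "k": k, "R": cfg.R, "top_fraction": cfg.top_fraction,
            "strength_threshold": cfg.strength_threshold, "iss": cfg.iss,
            "levels": cfg.levels, "ibreaks": cfg.ibreaks,
        },
    )


def train_from_expression(
    x: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig | None = None,
) -> tuple[EnsembleModel, ModuleAssignment, pd.DataFrame]:
    """Full training pipeline from a gene-level expression matrix.

    Builds the coexpression network on the positive-class samples, detects
    and merges modules, computes class-balanced eigengenes on all samples,
    and trains the subsampled ensemble. Returns (ensemble, module
    assignment, training eigengene matrix).
    """
    cfg = config or RunConfig()
    cfg.validate()
    lab = labels.reindex(x.columns)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    net_samples = x.columns[lab == cfg.network_class]
    if len(net_samples) < 3:
        raise ValueError("need >= 3 samples in the network-building class")
    x_net = x[net_samples]
    scan = pick_soft_threshold(
        x_net, powers=cfg.powers, rsq_cut=cfg.rsq_cut, n_bins=cfg.n_bins
    )
    if scan.converged:
        beta = scan.chosen_beta
    else:
        # no power reached the scale-free cut; use the conventional default
        # power for unsigned networks rather than an extreme argmax
        beta = cfg.fallback_beta
        logger.warning("scale-free scan did not converge; using beta=%d", beta)
    logger.info("soft threshold beta=%d (max fit %.3f, converged=%s)",
                beta, max(scan.fit_indices), scan.converged)
    adj = adjacency(x_net, beta)
    tom = topological_overlap(adj)
    modules = detect_modules(
        tom, min_module_size=cfg.min_module_size, cut_height=cfg.cut_height
    )
    modules = merge_close_modules(x_net, modules, merge_cut=cfg.merge_cut)
    if not modules.module_ids:
        raise ValueError("no modules detected")
    logger.info("detected %d modules (sizes %s)", len(modules.module_ids),
                modules.sizes)
    eigen_model, eigen = compute_eigengenes(x, modules, labels=lab, f_ref=cfg.f_ref)
    ensemble = train_ensemble(
        eigen, lab, k=cfg.k, seed=cfg.seed, config=cfg.bn,
        eigengene_model=eigen_model,
    )
    ensemble.module_labels = {g: int(m) for g, m in modules.labels.items()}
    ensemble.config["run"] = cfg.to_dict()
    return ensemble, modules, eigen


def predict_from_eigengenes(ensemble: EnsembleModel, eigen: pd.DataFrame) -> pd.DataFrame:
    """Per-model Effect votes, majority class and mean posterior P(Effect=1)."""
    disc = ensemble.discretizer.transform(eigen)
    votes = np.zeros((len(disc), ensemble.k), dtype=int)
    post1 = np.zeros((len(disc), ensemble.k), dtype=float)
    records = disc.to_dict("records")
    n_ties = 0
    for j, bn in enumerate(ensemble.bn_models):
        for i, row in enumerate(records):
            evidence = {v: int(row[v]) for v in disc.columns}
            cls, post = bn.predict_effect_exact(evidence, warn_on_tie=False)
            n_ties += post[0] == post[1]
            votes[i, j] = cls
            post1[i, j] = post[1]
    if n_ties:
        logger.warning(
            "%d tied Effect posteriors resolved to class 0 "
            "(unseen parent configurations)", n_ties,
        )
    majority = (votes.sum(axis=1) * 2 > ensemble.k).astype(int)
    out = pd.DataFrame(
        votes, index=eigen.index,
        columns=[f"vote_{j + 1}" for j in range(ensemble.k)],
    )
    out["majority"] = majority
    out["posterior"] = post1.mean(axis=1)
    return out


def predict(ensemble: EnsembleModel, x_new: pd.DataFrame) -> pd.DataFrame:
    """Classify new expression samples (possibly from another platform)."""
    if ensemble.eigengene_model is None:
        raise ValueError("ensemble has no eigengene model; use predict_from_eigengenes")
    eigen = project_eigengenes(ensemble.eigengene_model, x_new)
    return predict_from_eigengenes(ensemble, eigen)


def cross_validate(
    eigen: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    seed: int = 0,
    config: BNConfig | None = None,
) -> tuple[EnsembleModel, list[PerformanceReport]]:
    """k-fold cross-validation at the Bayesian-network stage.

    The k trained models are exactly the ensemble's models (shared
    stratified partition): model i, trained without fold i, predicts the
    held-out fold i.
    """
    ensemble = train_ensemble(eigen, labels, k=k, seed=seed, config=config)
    lab = labels.reindex(eigen.index).astype(int)
    folds = np.asarray(ensemble.fold_assignment)
    disc = ensemble.discretizer.transform(eigen)
    reports = []
    for i in range(ensemble.k):
        mask = folds == i
        bn = ensemble.bn_models[i]
        preds, scores = [], []
        for _, row in disc.loc[mask].iterrows():
            evidence = {v: int(row[v]) for v in disc.columns}
            cls, post = bn.predict_effect_exact(evidence, warn_on_tie=False)
            preds.append(cls)
            scores.append(post[1])
        reports.append(
            performance(np.array(preds), lab.to_numpy()[mask], scores=np.array(scores))
        )
    return ensemble, reports


def _roc_curve(scores: np.ndarray, truth: np.ndarray, positive_class: int):
    pos = truth == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    points = [(0.0, 0.0)]
    if n_pos == 0 or n_neg == 0:
        points.append((1.0, 1.0))
        return points, float("nan")
    for t in sorted(np.unique(scores), reverse=True):
        called = scores >= t
        tpr = float((called & pos).sum()) / n_pos
        fpr = float((called & ~pos).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def performance(
    predicted: np.ndarray,
    truth: np.ndarray,
    scores: np.ndarray | None = None,
    positive_class: int = 1,
) -> PerformanceReport:
    """Confusion counts, accuracy/precision/recall, and trapezoid-rule AUC.

    ``scores`` (e.g. the ensemble mean posterior) drive the ROC sweep; with
    no scores the AUC is NaN. Undefined ratios (no positives in truth, or
    no positive calls) are reported as NaN with a warning.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == positive_class
    called = predicted == positive_class
    tp = int((called & pos).sum())
    fp = int((called & ~pos).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & ~pos).sum())
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else float("nan")
    if tp + fp == 0:
        logger.warning("no positive calls; precision undefined")
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no positives in truth; recall undefined")
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    if scores is not None:
        points, auc = _roc_curve(np.asarray(scores, dtype=float), truth, positive_class)
    else:
        points, auc = [], float("nan")
    return PerformanceReport(
        tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
        precision=precision, recall=recall, auc=auc, roc_points=points,
    )
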