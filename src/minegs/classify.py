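"""Leakage-free cross-validated AUC evaluation of a gene-selection model.

The sample set is partitioned into stratified folds; within each fold the
gene-selection model is run on the *training* samples only, the top-J genes
feed a classifier, and the held-out fold is scored.  Held-out scores are
pooled across folds within a repeat before the AUC is computed, and the
whole cross-validation is repeated (default 20 times) with fresh partitions
to average out partitioning noise.  Because edge-sign filtering and edge
correlations depend on expression, the network filter and all diffusion/NFP
structures are recomputed inside every training fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import filter_negative_edges
from .ranking import run_model
from .types import BindingMatrix, ExpressionDataset, GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["CVConfig", "ClassifierSpec", "make_folds", "auc", "cross_validated_auc"]


@dataclass
class CVConfig:
    """Cross-validation protocol: 6 stratified folds, 20 repeats, J = 1..30."""

    n_folds: int = 6
    n_repeats: int = 20
    J_grid: tuple[int, ...] = tuple(range(1, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if any(j < 1 for j in self.J_grid):
            raise ValueError("J values must be >= 1")


@dataclass
class ClassifierSpec:
    """Pluggable classifier behind a fit/score contract.

    Built-in kinds: ``"nn"`` — a single-hidden-layer neural network with
    floor(sqrt(J)) hidden units for J input genes; ``"svm"`` — an RBF-kernel
    support vector machine (library-default regularisation and kernel width,
    recorded here as the artifact's choice); ``"custom"`` — a
    ``factory(J, seed)`` returning an object with ``fit(X, y)`` and
    ``score_samples(X) -> real scores``.
    """

    kind: str = "svm"
    params: dict = field(default_factory=dict)
    factory: Callable | None = None

    def build(self, J: int, seed: int):
        if self.kind == "nn":
            hidden = max(1, int(math.isqrt(J)))
            est = make_pipeline(
                StandardScaler(),
                MLPClassifier(
                    hidden_layer_sizes=(hidden,),
                    max_iter=2000,
                    random_state=seed,
                    **self.params,
                ),
            )
            return _SklearnScorer(est, use_proba=True)
        if self.kind == "svm":
            est = make_pipeline(StandardScaler(), SVC(kernel="rbf", **self.params))
            return _SklearnScorer(est, use_proba=False)
        if self.kind == "custom":
            if self.factory is None:
                raise ValueError("custom classifier requires a factory")
            return self.factory(J, seed)
        raise ValueError(f"unknown classifier kind {self.kind!r}")


class _SklearnScorer:
    """Adapts an sklearn estimator to the fit/score contract used here."""

    def __init__(self, est, use_proba: bool) -> None:
        self.est = est
        self.use_proba = use_proba

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnScorer":
        self.est.fit(X, y)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        if self.use_proba:
            proba = self.est.predict_proba(X)
            return proba[:, 1]
        return self.est.decision_function(X)


def make_folds(labels: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (one fold index per sample), deterministic under seed."""
    labels = np.asarray(labels)
    n = labels.size
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} samples")
    counts = [int(np.sum(labels == c)) for c in np.unique(labels)]
    if n_folds > min(counts):
        logger.warning(
            "n_folds=%d exceeds the smallest class count %d; some folds will miss a class",
            n_folds,
            min(counts),
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = f
    return assignment


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based (Mann–Whitney) AUC; ties contribute 1/2 of a concordant pair.

    The second of the two label values in sorted order is taken as the
    positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("AUC requires both classes present")
    pos = labels == classes[1]
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cross_validated_auc(
    dataset: ExpressionDataset,
    binding: BindingMatrix,
    network: GeneNetwork,
    model: str | Callable,
    classifier_spec: ClassifierSpec,
    cv_config: CVConfig,
    k: int = 3,
    t: int = 1,
    bins: int = 10,
) -> dict[int, float]:
    """Mean held-out AUC per gene-subset size J, averaged over repeats.

    ``model`` is a variant name (``classic``/``MiGS``/``NeGS``/``MiNeGS``) or
    a callable ``model(train_dataset, binding, train_network) -> GeneRanking``
    that sees *only* the training partition — the interface itself enforces
    the no-leakage contract.  Folds where a classifier fails are skipped with
    a warning.
    """
    labels = np.asarray(dataset.labels)
    aucs: dict[int, list[float]] = {J: [] for J in cv_config.J_grid}
    for rep in range(cv_config.n_repeats):
        rep_seed = cv_config.seed + rep
        assignment = make_folds(labels, cv_config.n_folds, seed=rep_seed)
        pooled: dict[int, tuple[list[float], list]] = {J: ([], []) for J in cv_config.J_grid}
        for f in range(cv_config.n_folds):
            train_idx = np.flatnonzero(assignment != f)
            test_idx = np.flatnonzero(assignment == f)
            train_ds = dataset.subset_samples(train_idx)
            # the edge-sign filter depends on (training) expression: recompute per fold
            train_net, _ = filter_negative_edges(network, train_ds)
            if callable(model):
                ranking = model(train_ds, binding, train_net)
            else:
                ranking, _ = run_model(
                    train_ds, binding, train_net, model=model, k=k, t=t, bins=bins
                )
            gidx = dataset.gene_index()
            for J in cv_config.J_grid:
                if J > len(ranking.order):
                    raise ValueError(f"J={J} exceeds the {len(ranking.order)} ranked genes")
                genes = ranking.top(J)
                rows = [gidx[g] for g in genes]
                X_train = dataset.values[np.ix_(rows, train_idx)].T
                X_test = dataset.values[np.ix_(rows, test_idx)].T
                clf = classifier_spec.build(J, seed=rep_seed)
                try:
                    clf.fit(X_train, labels[train_idx])
                    scores = np.asarray(clf.score_samples(X_test), dtype=float)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("classifier failed on fold %d (J=%d): %s", f, J, exc)
                    continue
                pooled[J][0].extend(scores.tolist())
                pooled[J][1].extend(labels[test_idx].tolist())
        for J in cv_config.J_grid:
            sc, lb = pooled[J]
            if sc and len(set(lb)) == 2:
                aucs[J].append(auc(sc, lb))
    return {J: float(np.mean(v)) if v else float("nan") for J, v in aucs.items()}
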