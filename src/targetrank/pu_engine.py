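"""Stochastic semi-supervised positive-unlabelled (PU) ensemble.

The whole gene universe is repeatedly split into balanced partitions, each
pairing the full positive (seed) set with a disjoint chunk of unlabelled genes
of roughly ``rho * |P|`` genes. Within every partition a stratified k-fold
cross-validation is run: a classifier is fitted on the training folds and
probabilities are predicted for the held-out fold, so every partition member
receives exactly one out-of-bag (OOB) prediction per partition. The procedure
repeats for L stochastic iterations with fresh random chunks; a gene's final
druggability score is the plain mean of all its logged OOB probabilities
(L predictions for an unlabelled gene, one per partition per iteration for a
positive gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .datamodel import (
    GB_DEFAULTS,
    GB_INHERITED,
    ClassifierSpec,
    GeneFeatureTable,
    InputError,
    LabelSet,
    RunConfig,
    ScoreTable,
    substream,
)

logger = logging.getLogger("targetrank")

OOB_COLUMNS = ["iteration", "partition", "fold", "gene", "prob", "label"]


@dataclass(frozen=True)
class Partition:
    """Full positive set paired with one disjoint chunk of unlabelled genes."""

    positives: tuple
    unlabelled_chunk: tuple


# ---------------------------------------------------------------------------
# classifier registry
# ---------------------------------------------------------------------------

class _SklearnModel:
    """Adapter exposing fit / predict_probability over sklearn estimators."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, features, labels):
        self.estimator.fit(np.asarray(features), np.asarray(labels))
        return self

    def predict_probability(self, features) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(features))
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, pos_col]


def _build_gradient_boosting(params, random_state):
    merged = {**GB_DEFAULTS, **params}
    return GradientBoostingClassifier(random_state=random_state, **merged)


def _build_random_forest(params, random_state):
    merged = {"n_estimators": 100, **params}
    return RandomForestClassifier(random_state=random_state, n_jobs=1, **merged)


def _build_extra_trees(params, random_state):
    merged = {"n_estimators": 100, **params}
    return ExtraTreesClassifier(random_state=random_state, n_jobs=1, **merged)


def _build_svc(params, random_state):
    # the ensemble contract requires predict_proba; wrap the margin classifier
    # in Platt-style calibration
    merged = {"gamma": "scale", **params}
    return CalibratedClassifierCV(
        SVC(random_state=random_state, **merged), ensemble=False
    )


def _build_naive_bayes(params, random_state):
    return GaussianNB(**params)


_REGISTRY: dict[str, Callable] = {
    "gradient_boosting": _build_gradient_boosting,
    "random_forest": _build_random_forest,
    "extra_trees": _build_extra_trees,
    "svc": _build_svc,
    "naive_bayes": _build_naive_bayes,
}


def register_classifier(name: str, builder: Callable) -> None:
    """Register a classifier builder(hyperparameters, random_state) -> estimator
    exposing sklearn's fit/predict_proba interface."""
    _REGISTRY[name] = builder


def classifier_registry(
    spec: ClassifierSpec, random_state: int | None = None
) -> _SklearnModel:
    """Instantiate a registry classifier from its spec.

    The returned model exposes ``fit(features, labels)`` and
    ``predict_probability(features)`` with probabilities in [0, 1].
    """
    if spec.name not in _REGISTRY:
        raise InputError(
            f"unknown classifier {spec.name!r}; registered: {sorted(_REGISTRY)}"
        )
    est = _REGISTRY[spec.name](dict(spec.hyperparameters), random_state)
    return _SklearnModel(est)


def registered_classifiers() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# balanced partitioning
# ---------------------------------------------------------------------------

def make_balanced_partitions(
    P, U: Sequence, rho: float, rng: np.random.Generator, k: int = 2
) -> list[Partition]:
    """Shuffle U and cut it into disjoint chunks of ~rho*|P| genes, each
    paired with the full positive set.

    A final chunk smaller than half the nominal size is merged into the
    previous chunk, so the chunks always cover U exactly.
    """
    pos = tuple(sorted(P.genes if isinstance(P, LabelSet) else P))
    unlabelled = sorted(U)
    if not unlabelled:
        raise InputError("unlabelled set is empty")
    if set(pos) & set(unlabelled):
        raise InputError("positive and unlabelled sets overlap")
    nominal = rho * len(pos)
    if nominal < k:
        raise InputError(
            f"rho*|P| = {nominal:.1f} < k = {k}: folds would lack unlabelled members"
        )
    size = max(int(round(nominal)), 1)
    shuffled = [unlabelled[i] for i in rng.permutation(len(unlabelled))]
    chunks = [shuffled[i : i + size] for i in range(0, len(shuffled), size)]
    if len(chunks) > 1 and len(chunks[-1]) < max(size / 2, k):
        chunks[-2].extend(chunks.pop())
    return [Partition(pos, tuple(c)) for c in chunks]


# ---------------------------------------------------------------------------
# stochastic ensemble
# ---------------------------------------------------------------------------

def run_stochastic_ensemble(
    X: GeneFeatureTable,
    P: LabelSet,
    spec: ClassifierSpec | None = None,
    cfg: RunConfig | None = None,
) -> tuple[ScoreTable, pd.DataFrame]:
    """Run the full PU ensemble and return (ScoreTable, OOB log).

    The OOB log holds one record per (iteration, partition, fold, gene) with
    the predicted probability and the gene's in-partition label; final scores
    are the per-gene mean over all records, and ``n_oob`` counts them.
    """
    cfg = cfg or RunConfig()
    spec = spec or cfg.classifier_spec
    if X.n_missing:
        raise InputError("feature table must be preprocessed (no missing cells)")
    genes = set(X.gene_ids)
    if not P.genes <= genes:
        extra = sorted(P.genes - genes)[:5]
        raise InputError(f"positive genes absent from feature table: {extra}")
    if len(P) < cfg.k:
        raise InputError(f"|P| = {len(P)} < k = {cfg.k}: stratified folds degenerate")
    unlabelled = sorted(genes - P.genes)

    records: list[tuple] = []
    for it in range(cfg.L):
        rng = substream(cfg.seed, "pu_engine", it)
        for attempt in range(10):
            partitions = make_balanced_partitions(
                P, unlabelled, cfg.rho, rng, k=cfg.k
            )
            ok = all(
                len(p.unlabelled_chunk) >= cfg.k for p in partitions
            )
            if ok:
                break
            logger.warning("iteration %d: degenerate partition, re-drawing", it)
        else:
            raise InputError("could not draw non-degenerate partitions")
        for pi, part in enumerate(partitions):
            members = list(part.positives) + list(part.unlabelled_chunk)
            y = np.array([1] * len(part.positives) + [0] * len(part.unlabelled_chunk))
            Xp = X.values.loc[members].to_numpy(dtype=float)
            skf = StratifiedKFold(
                n_splits=cfg.k,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            for fi, (train, test) in enumerate(skf.split(Xp, y)):
                if len(np.unique(y[train])) < 2:
                    raise InputError("training fold lost a class")  # pragma: no cover
                model = classifier_registry(
                    spec, random_state=int(rng.integers(2**31 - 1))
                )
                try:
                    model.fit(Xp[train], y[train])
                    probs = model.predict_probability(Xp[test])
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(
                        f"classifier {spec.name!r} failed on iteration {it}, "
                        f"partition {pi}, fold {fi}: {exc}"
                    ) from exc
                for idx, p in zip(test, probs):
                    records.append((it, pi, fi, members[idx], float(p), int(y[idx])))

    log = pd.DataFrame(records, columns=OOB_COLUMNS)
    agg = log.groupby("gene")["prob"].agg(["mean", "count"])
    table = pd.DataFrame(
        {
            "gene": agg.index,
            "score": agg["mean"].to_numpy(),
            "n_oob": agg["count"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    scores = percentile_rank(ScoreTable(table))
    return scores, log


def percentile_rank(scores: ScoreTable) -> ScoreTable:
    """Attach percentile = 100 * (ascending average rank) / n."""
    t = scores.table.copy()
    if (t["n_oob"] <= 0).any():
        raise InputError("percentile_rank requires a score for every gene")
    ranks = rankdata(t["score"].to_numpy(), method="average")
    t["percentile"] = 100.0 * ranks / len(t)
    t = t.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    return ScoreTable(t)


# ---------------------------------------------------------------------------
# gradient-boosting grid search
# ---------------------------------------------------------------------------

def _cv_auc(Xp, y, params, k, rng) -> float:
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    aucs = []
    for train, test in skf.split(Xp, y):
        model = _SklearnModel(
            _build_gradient_boosting(params, int(rng.integers(2**31 - 1)))
        )
        model.fit(Xp[train], y[train])
        aucs.append(roc_auc_score(y[test], model.predict_probability(Xp[test])))
    return float(np.mean(aucs))


def grid_search_gb(
    X: GeneFeatureTable,
    P: LabelSet,
    depth_grid: Sequence[int] = (1, 2, 3, 5),
    estimator_grid: Sequence[int] = (10, 50, 100, 200, 300, 400, 500),
    lr_grid: Sequence[float] = (0.001, 0.01, 0.1, 1),
    cfg: RunConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Two-stage gradient-boosting hyperparameter search.

    Stage 1 scans max_depth with the remaining hyperparameters fixed at the
    inherited values; stage 2 jointly scans n_estimators x learning_rate at
    the chosen depth. Selection is by highest mean CV AUC; exact AUC ties are
    broken toward fewer estimators (the plateau rule).
    """
    if not (len(depth_grid) and len(estimator_grid) and len(lr_grid)):
        raise InputError("grids must be non-empty")
    cfg = cfg or RunConfig()
    rng = substream(cfg.seed, "grid_search")
    genes = set(X.gene_ids)
    unlabelled = sorted(genes - P.genes)
    chunk = make_balanced_partitions(P, unlabelled, cfg.rho, rng, k=cfg.k)[0]
    members = list(chunk.positives) + list(chunk.unlabelled_chunk)
    y = np.array([1] * len(chunk.positives) + [0] * len(chunk.unlabelled_chunk))
    Xp = X.values.loc[members].to_numpy(dtype=float)

    rows = []
    for d in depth_grid:
        params = {**GB_INHERITED, "max_depth": d}
        auc = _cv_auc(Xp, y, params, cfg.k, rng)
        rows.append(("depth", d, params["n_estimators"], params["learning_rate"], auc))
    stage1 = [r for r in rows if r[0] == "depth"]
    best_depth = max(stage1, key=lambda r: r[4])[1]

    for n in estimator_grid:
        for lr in lr_grid:
            params = {
                **GB_INHERITED,
                "max_depth": best_depth,
                "n_estimators": n,
                "learning_rate": lr,
            }
            auc = _cv_auc(Xp, y, params, cfg.k, rng)
            rows.append(("joint", best_depth, n, lr, auc))
    stage2 = [r for r in rows if r[0] == "joint"]
    best_auc = max(r[4] for r in stage2)
    winners = [r for r in stage2 if r[4] == best_auc]
    best = min(winners, key=lambda r: r[2])  # fewest estimators on ties
    surface = pd.DataFrame(
        rows, columns=["stage", "max_depth", "n_estimators", "learning_rate", "mean_auc"]
    )
    best_params = {
        "max_depth": int(best_depth),
        "n_estimators": int(best[2]),
        "learning_rate": float(best[3]),
    }
    return best_params, surface
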