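"""End-to-end study orchestration and k-fold cross-validated evaluation.

A study takes the five raw inputs (ontology, annotations, domains, PPI
edges, positive/unlabeled gene lists), builds feature vectors, selects
discriminating features, partitions the unlabeled set, trains the
multi-level weighted SVM and scores the unlabeled genes.  The CV harness
re-runs feature selection, the PPI neighbourhood features, the similarity
network and the penalty search inside each training fold, so held-out
positives never influence any training-side quantity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from . import __version__
from .classifier import (
    PenaltyProfile,
    TrainedModel,
    predict,
    select_penalties,
    train_weighted_svm,
)
from .evaluate import Metrics, f_measure, precision_recall
from .features import (
    FeatureSpace,
    GeneRecord,
    build_feature_matrix,
    fit_ppi_scaler,
    read_annotations,
    read_domains,
    read_gene_list,
    read_ppi,
)
from .ontology import load_obo
from .partition import PartitionResult, partition_genes
from .selection import score_features, select_top_n

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """All inputs and tunables of one study run."""

    obo_path: str = ""
    annotation_path: str = ""
    domain_path: str = ""
    ppi_path: str = ""
    positive_path: str = ""
    unlabeled_path: str = ""

    n_top_features: int = 1000
    q_neighbors: int = 10
    alpha: float = 0.8
    epsilon: float = 1e-6
    max_iter: int = 1000
    sigma: float | None = None
    kernel: str = "linear"
    penalty: PenaltyProfile = field(default_factory=PenaltyProfile)
    penalty_search: bool = False
    folds: int = 10
    balance: bool = False
    min_nonzero_fraction: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        penalty = data.pop("penalty", None)
        cfg = cls(**data)
        if penalty:
            cfg.penalty = PenaltyProfile(**penalty)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class StudyData:
    """Loaded and resolved study inputs."""

    records: dict[str, GeneRecord]
    dags: dict
    net: object
    positives: list[str]
    unlabeled: list[str]


@dataclass
class PipelineResult:
    partition: PartitionResult
    model: TrainedModel
    predictions: pd.DataFrame  # gene_id, label, score, probability
    space: FeatureSpace
    manifest: dict


def load_study(config: StudyConfig) -> StudyData:
    """Read all five inputs; optionally balance U to |P| = |U| (seeded) and
    drop sparsely annotated positives."""
    dags = load_obo(config.obo_path)
    records = read_annotations(config.annotation_path)
    read_domains(config.domain_path, records)
    net = read_ppi(config.ppi_path)
    positives = read_gene_list(config.positive_path)
    unlabeled = read_gene_list(config.unlabeled_path)

    overlap = set(positives) & set(unlabeled)
    if overlap:
        logger.warning("%d genes in both P and U; removed from U", len(overlap))
        unlabeled = [g for g in unlabeled if g not in overlap]

    if config.min_nonzero_fraction is not None:
        space = FeatureSpace.from_data(records, dags)
        scaler = fit_ppi_scaler(net, positives + unlabeled, set(positives))
        kept = []
        for g in positives:
            x = build_feature_matrix(records, [g], space, dags, net,
                                     set(positives), scaler)[0]
            if np.count_nonzero(x) / x.size >= config.min_nonzero_fraction:
                kept.append(g)
        logger.info("nonzero-fraction filter kept %d/%d positives",
                    len(kept), len(positives))
        positives = kept

    if config.balance and len(unlabeled) > len(positives):
        rng = np.random.default_rng(config.seed)
        idx = sorted(rng.choice(len(unlabeled), size=len(positives), replace=False))
        unlabeled = [unlabeled[i] for i in idx]
        logger.info("balanced U down to |U| = |P| = %d", len(unlabeled))

    return StudyData(records, dags, net, positives, unlabeled)


def _featurize(
    data: StudyData,
    config: StudyConfig,
    train_positives: list[str],
    train_unlabeled: list[str],
) -> tuple[FeatureSpace, object, callable]:
    """Fit the feature pipeline on training genes only.

    Returns the selected feature space, the PPI scaler, and a closure
    mapping a gene-id list to a feature matrix.  The known-positive set
    used by the 1N/2N neighbourhood features is restricted to the training
    positives (leakage guard).
    """
    known_pos = set(train_positives)
    space_full = FeatureSpace.from_data(
        data.records, data.dags, train_positives + train_unlabeled
    )
    scores = score_features(
        data.records, train_positives, train_unlabeled, space_full, data.dags
    )
    space = select_top_n(scores, space_full, config.n_top_features)
    scaler = fit_ppi_scaler(data.net, train_positives + train_unlabeled, known_pos)

    def featurize(gene_ids: list[str]) -> np.ndarray:
        return build_feature_matrix(
            data.records, gene_ids, space, data.dags, data.net, known_pos, scaler
        )

    return space, scaler, featurize


def _partition_and_train(
    config: StudyConfig,
    p_ids: list[str],
    u_ids: list[str],
    x_p: np.ndarray,
    x_u: np.ndarray,
) -> tuple[PartitionResult, TrainedModel]:
    part = partition_genes(
        p_ids, u_ids, x_p, x_u,
        q=config.q_neighbors, alpha=config.alpha,
        epsilon=config.epsilon, max_iter=config.max_iter, sigma=config.sigma,
    )
    u_index = {g: i for i, g in enumerate(u_ids)}
    sets = {"P": x_p}
    for name, members in (
        ("RN", part.reliable_negative),
        ("LP", part.likely_positive),
        ("LN", part.likely_negative),
        ("WN", part.weak_negative),
    ):
        if members:
            sets[name] = x_u[[u_index[g] for g in sorted(members)]]
    profile = config.penalty
    if config.penalty_search:
        profile = select_penalties(
            sets, folds=min(config.folds, 10), seed=config.seed, kernel=config.kernel
        )
    model = train_weighted_svm(sets, profile, config.kernel, seed=config.seed)
    return part, model


def run_pipeline(config: StudyConfig, out_dir: str | None = None) -> PipelineResult:
    """Execute the full study: featurize, partition, train, score U."""
    t0 = time.time()
    data = load_study(config)
    space, _, featurize = _featurize(data, config, data.positives, data.unlabeled)
    x_p = featurize(data.positives)
    x_u = featurize(data.unlabeled)
    part, model = _partition_and_train(config, data.positives, data.unlabeled, x_p, x_u)

    labels, scores, probs = predict(model, x_u)
    predictions = pd.DataFrame({
        "gene_id": data.unlabeled,
        "label": np.where(labels > 0, "disease", "non-disease"),
        "score": scores,
        "probability": probs,
    })

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "pudi_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_positives": len(data.positives),
        "n_unlabeled": len(data.unlabeled),
        "n_features": len(space),
        "partition_sizes": {k: len(v) for k, v in part.as_dict().items()},
        "runtime_s": round(time.time() - t0, 3),
    }
    result = PipelineResult(part, model, predictions, space, manifest)
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for name, members in result.partition.as_dict().items():
        for g in sorted(members):
            rows.append((g, name, result.partition.scores.get(g, 1.0)))
    pd.DataFrame(rows, columns=["gene_id", "set", "score"]).to_csv(
        os.path.join(out_dir, "partition.tsv"), sep="\t", index=False
    )
    result.predictions.to_csv(
        os.path.join(out_dir, "predictions.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def naive_pu_baseline(
    x_p: np.ndarray, x_u: np.ndarray, kernel: str = "linear"
) -> np.ndarray:
    """Control classifier that treats all of U as negatives: a plain
    soft-margin SVM on P vs U.  Returns decision scores over U."""
    x = np.vstack([x_p, x_u])
    y = np.concatenate([np.ones(len(x_p)), -np.ones(len(x_u))])
    svm = SVC(kernel=kernel, C=1.0, gamma="scale")
    svm.fit(x, y)
    return svm.decision_function(x_u)


def kfold_evaluate(config: StudyConfig, data: StudyData | None = None) -> Metrics:
    """k-fold cross-validated precision/recall/F of the full method.

    Folds are drawn separately over P and U (seeded).  Each training fold
    re-runs feature selection, PPI scaling, 1N/2N with training positives
    only, partitioning, and training; the held-out fold is scored with
    P-membership as ground truth.  Folds whose test side lacks positives
    are skipped with a warning.
    """
    if config.folds < 2:
        raise ValueError("k-fold evaluation needs k >= 2")
    if data is None:
        data = load_study(config)
    p_ids = list(data.positives)
    u_ids = list(data.unlabeled)
    kf_p = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    kf_u = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed + 1)
    p_splits = list(kf_p.split(p_ids))
    u_splits = list(kf_u.split(u_ids))

    fold_metrics = []
    all_truth, all_scores = [], []
    for fold, ((p_tr, p_te), (u_tr, u_te)) in enumerate(zip(p_splits, u_splits)):
        if len(p_te) == 0:
            logger.warning("fold %d has no held-out positives; skipped", fold)
            continue
        train_p = [p_ids[i] for i in p_tr]
        train_u = [u_ids[i] for i in u_tr]
        test_ids = [p_ids[i] for i in p_te] + [u_ids[i] for i in u_te]
        y_true = np.array([True] * len(p_te) + [False] * len(u_te))

        _, _, featurize = _featurize(data, config, train_p, train_u)
        x_p = featurize(train_p)
        x_u = featurize(train_u)
        _, model = _partition_and_train(config, train_p, train_u, x_p, x_u)

        labels, _, probs = predict(model, featurize(test_ids))
        p, r = precision_recall(y_true, labels > 0)
        fold_metrics.append((p, r, f_measure(p, r)))
        all_truth.append(y_true)
        all_scores.append(probs)

    if not fold_metrics:
        raise ValueError("no evaluable folds")
    return Metrics.from_folds(
        fold_metrics, np.concatenate(all_truth), np.concatenate(all_scores)
    )
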