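"""Self-contained benchmark experiments on synthetic studies.

Two experiments quantify the method end to end without any external data:

* **Hidden-positive recovery** — generate a contaminated study, run the
  full pipeline, and measure (i) the ranking AUC of the SVM decision
  scores for hidden positives versus true negatives inside U, and (ii)
  the F-measure on a balanced held-out test set (all hidden positives
  against an equal-size random sample of true negatives), for both the
  multi-level classifier and a naive P-vs-U SVM control that treats every
  unlabeled gene as negative.
* **Null control** — the same pipeline on a study generated with no
  planted signal (enrichment odds 1, no PPI attachment bias); the
  recovery AUC should sit at chance level.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np

from .classifier import predict
from .evaluate import f_measure, precision_recall, ranking_auc
from .pipeline import (
    StudyConfig,
    _featurize,
    _partition_and_train,
    load_study,
    naive_pu_baseline,
)
from .simulate import SyntheticParams, generate_synthetic_study


@dataclass
class RecoveryResult:
    """One seed's outcome of the hidden-positive recovery experiment."""

    auc: float
    pudi_f: float
    baseline_f: float
    pudi_precision: float
    pudi_recall: float
    baseline_precision: float
    baseline_recall: float
    n_hidden: int
    n_unlabeled: int


def study_config_for(study, seed: int, **overrides) -> StudyConfig:
    cfg = StudyConfig(
        obo_path=study.obo_path,
        annotation_path=study.annotation_path,
        domain_path=study.domain_path,
        ppi_path=study.ppi_path,
        positive_path=study.positive_path,
        unlabeled_path=study.unlabeled_path,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def _balanced_test(
    unlabeled: list[str], hidden: set[str], rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """All hidden positives plus an equal-size sample of true negatives."""
    negatives = [g for g in unlabeled if g not in hidden]
    k = min(len(hidden), len(negatives))
    idx = sorted(rng.choice(len(negatives), size=k, replace=False))
    test_ids = sorted(hidden) + [negatives[i] for i in idx]
    truth = np.array([True] * len(hidden) + [False] * k)
    return test_ids, truth


def run_recovery_experiment(
    seed: int,
    params: SyntheticParams | None = None,
    work_dir: str | None = None,
) -> RecoveryResult:
    """Generate a study at *seed*, run PUDI and the naive control, measure
    hidden-positive recovery."""
    params = params or SyntheticParams()
    own_tmp = work_dir is None
    tmp = tempfile.TemporaryDirectory() if own_tmp else None
    out_dir = tmp.name if own_tmp else work_dir
    try:
        study = generate_synthetic_study(params, seed, out_dir)
        cfg = study_config_for(study, seed)
        data = load_study(cfg)
        _, _, featurize = _featurize(data, cfg, data.positives, data.unlabeled)
        x_p = featurize(data.positives)
        x_u = featurize(data.unlabeled)
        _, model = _partition_and_train(cfg, data.positives, data.unlabeled, x_p, x_u)

        hidden = set(study.hidden_positives)
        u_index = {g: i for i, g in enumerate(data.unlabeled)}
        truth_u = np.array([g in hidden for g in data.unlabeled])
        _, scores_u, _ = predict(model, x_u)
        auc = ranking_auc(truth_u, scores_u) if hidden else float("nan")

        baseline_scores_u = naive_pu_baseline(x_p, x_u, kernel=cfg.kernel)

        rng = np.random.default_rng(seed + 1)
        test_ids, truth = _balanced_test(data.unlabeled, hidden, rng)
        rows = [u_index[g] for g in test_ids]
        pudi_pred = scores_u[rows] > 0
        base_pred = baseline_scores_u[rows] > 0
        p1, r1 = precision_recall(truth, pudi_pred)
        p2, r2 = precision_recall(truth, base_pred)
        return RecoveryResult(
            auc=auc,
            pudi_f=f_measure(p1, r1),
            baseline_f=f_measure(p2, r2),
            pudi_precision=p1,
            pudi_recall=r1,
            baseline_precision=p2,
            baseline_recall=r2,
            n_hidden=len(hidden),
            n_unlabeled=len(data.unlabeled),
        )
    finally:
        if tmp is not None:
            tmp.cleanup()


def run_null_experiment(
    seed: int, params: SyntheticParams | None = None
) -> float:
    """Recovery AUC on a study with no planted signal (chance level)."""
    base = params or SyntheticParams()
    null_params = SyntheticParams(
        **{
            **{f: getattr(base, f) for f in base.__dataclass_fields__},
            "enrichment_odds": 1.0,
            "ppi_positive_bias": 0.0,
        }
    )
    return run_recovery_experiment(seed, null_params).auc


def summarize_recovery(
    seeds: list[int], params: SyntheticParams | None = None
) -> dict[str, float]:
    results = [run_recovery_experiment(s, params) for s in seeds]
    return {
        "auc": float(np.mean([r.auc for r in results])),
        "pudi_f": float(np.mean([r.pudi_f for r in results])),
        "baseline_f": float(np.mean([r.baseline_f for r in results])),
        "pudi_precision": float(np.mean([r.pudi_precision for r in results])),
        "pudi_recall": float(np.mean([r.pudi_recall for r in results])),
        "baseline_precision": float(np.mean([r.baseline_precision for r in results])),
        "baseline_recall": float(np.mean([r.baseline_recall for r in results])),
    }
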