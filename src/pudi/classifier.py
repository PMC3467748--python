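"""Multi-level weighted soft-margin SVM over the five graded training sets.

The classifier treats P and LP as the positive class and RN, LN, WN as
the negative class, but penalises a misclassified example according to
the confidence of its set: the soft-margin objective is
``1/2 ||w||^2 + sum_i C_set(i) * xi_i`` where ``C_set`` is a per-set
penalty factor with ``C_P >= C_LP`` and ``C_RN >= C_LN >= C_WN``.
Decision scores are mapped to probabilities by a monotone sigmoid fitted
on out-of-fold scores of P (positive) versus RN (negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluate import f_measure

logger = logging.getLogger(__name__)

SET_NAMES = ("P", "LP", "RN", "LN", "WN")
POSITIVE_SETS = {"P", "LP"}


@dataclass(frozen=True)
class PenaltyProfile:
    """Per-set misclassification penalty factors.

    The orderings ``C_P >= C_LP`` and ``C_RN >= C_LN >= C_WN`` encode that
    confirmed labels are trusted more than propagated ones.  Equality is
    allowed so collapsed profiles reduce to a plain two-class SVM.
    """

    c_p: float = 1.0
    c_lp: float = 0.5
    c_rn: float = 1.0
    c_ln: float = 0.5
    c_wn: float = 0.25

    def __post_init__(self) -> None:
        values = asdict(self)
        if any(v <= 0 for v in values.values()):
            raise ValueError("penalty factors must be positive")
        if self.c_p < self.c_lp:
            raise ValueError("requires C_P >= C_LP")
        if not (self.c_rn >= self.c_ln >= self.c_wn):
            raise ValueError("requires C_RN >= C_LN >= C_WN")

    def weight_of(self, set_name: str) -> float:
        return {
            "P": self.c_p, "LP": self.c_lp,
            "RN": self.c_rn, "LN": self.c_ln, "WN": self.c_wn,
        }[set_name]

    @property
    def total(self) -> float:
        return self.c_p + self.c_lp + self.c_rn + self.c_ln + self.c_wn


@dataclass
class TrainedModel:
    """Fitted weighted SVM plus the monotone probability calibration."""

    svm: SVC
    profile: PenaltyProfile
    n_features: int
    calibration: tuple[float, float] = (1.0, 0.0)  # p = sigmoid(a*s + b), a > 0

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature length mismatch: expected {self.n_features}, got {x.shape[1]}"
            )
        return self.svm.decision_function(x)

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        a, b = self.calibration
        s = self.decision_scores(x)
        return 1.0 / (1.0 + np.exp(-(a * s + b)))


def _stack_sets(
    sets: dict[str, tuple[np.ndarray, ...]], profile: PenaltyProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, ys, ws = [], [], []
    for name in SET_NAMES:
        entry = sets.get(name)
        if entry is None:
            continue
        x = np.atleast_2d(np.asarray(entry, dtype=float))
        if x.shape[0] == 0:
            continue
        label = 1.0 if name in POSITIVE_SETS else -1.0
        xs.append(x)
        ys.append(np.full(x.shape[0], label))
        ws.append(np.full(x.shape[0], profile.weight_of(name)))
    if not xs:
        raise ValueError("no training data")
    return np.vstack(xs), np.concatenate(ys), np.concatenate(ws)


def train_weighted_svm(
    sets: dict[str, np.ndarray],
    profile: PenaltyProfile | None = None,
    kernel: str = "linear",
    calibrate: bool = True,
    seed: int = 0,
) -> TrainedModel:
    """Fit the multi-level SVM on per-set feature matrices.

    ``sets`` maps set names (P, LP, RN, LN, WN; P and RN mandatory) to
    feature matrices sharing one feature space.  Per-example penalties are
    implemented as sample weights multiplying a unit base C.
    """
    profile = profile or PenaltyProfile()
    if "P" not in sets or "RN" not in sets:
        raise ValueError("training requires non-empty P and RN sets")
    x, y, w = _stack_sets(sets, profile)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training input")

    svm = SVC(kernel=kernel, C=1.0, gamma="scale")
    svm.fit(x, y, sample_weight=w)
    model = TrainedModel(svm=svm, profile=profile, n_features=x.shape[1])
    if calibrate:
        model.calibration = _platt_calibration(sets, profile, kernel, seed)
    return model


def _platt_calibration(
    sets: dict[str, np.ndarray],
    profile: PenaltyProfile,
    kernel: str,
    seed: int,
    folds: int = 3,
) -> tuple[float, float]:
    """Sigmoid fit on out-of-fold decision scores, P positive vs RN negative.

    The slope is constrained positive so the probability map is monotone
    non-decreasing in the decision score.
    """
    x_p = np.atleast_2d(np.asarray(sets["P"], dtype=float))
    x_rn = np.atleast_2d(np.asarray(sets["RN"], dtype=float))
    n_splits = min(folds, x_p.shape[0], x_rn.shape[0])
    scores, labels = [], []
    if n_splits >= 2:
        x_cal = np.vstack([x_p, x_rn])
        y_cal = np.concatenate([np.ones(x_p.shape[0]), np.zeros(x_rn.shape[0])])
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(x_cal, y_cal):
            fold_sets = dict(sets)
            fold_sets["P"] = x_cal[train_idx][y_cal[train_idx] == 1]
            fold_sets["RN"] = x_cal[train_idx][y_cal[train_idx] == 0]
            try:
                fold_model = train_weighted_svm(
                    fold_sets, profile, kernel, calibrate=False
                )
            except ValueError:
                continue
            scores.append(fold_model.decision_scores(x_cal[test_idx]))
            labels.append(y_cal[test_idx])
    if not scores:
        return (1.0, 0.0)
    s = np.concatenate(scores)
    t = np.concatenate(labels)

    # Platt's regularised targets, fitted by Newton steps on log-loss
    n_pos, n_neg = t.sum(), len(t) - t.sum()
    targets = np.where(t == 1, (n_pos + 1) / (n_pos + 2), 1 / (n_neg + 2))
    a, b = 1.0, 0.0
    for _ in range(100):
        z = a * s + b
        p = 1.0 / (1.0 + np.exp(-z))
        grad_a = np.dot(p - targets, s)
        grad_b = np.sum(p - targets)
        w = np.clip(p * (1 - p), 1e-12, None)
        h_aa = np.dot(w, s * s) + 1e-9
        h_bb = np.sum(w) + 1e-9
        h_ab = np.dot(w, s)
        det = h_aa * h_bb - h_ab**2
        if abs(det) < 1e-18:
            break
        da = (h_bb * grad_a - h_ab * grad_b) / det
        db = (h_aa * grad_b - h_ab * grad_a) / det
        a, b = a - da, b - db
        if abs(da) + abs(db) < 1e-10:
            break
    if a <= 0:  # keep the probability map monotone in the score
        logger.warning("calibration slope non-positive; falling back to identity")
        return (1.0, 0.0)
    return (float(a), float(b))


def predict(model: TrainedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels (+1 disease / -1 non-disease), decision scores and calibrated
    probabilities for a batch of gene vectors.

    A score of exactly zero is labeled non-disease; ranking by probability
    equals ranking by score because the calibration map is monotone.
    """
    scores = model.decision_scores(x)
    labels = np.where(scores > 0, 1, -1)
    return labels, scores, model.probabilities(x)


def default_penalty_grid() -> list[PenaltyProfile]:
    """Small feasible grid over the per-set penalty factors."""
    grid = []
    for c_p in (1.0, 2.0):
        for c_lp in (0.25, 0.5, 1.0):
            for c_rn in (1.0, 2.0):
                for c_ln in (0.25, 0.5):
                    for c_wn in (0.1, 0.25):
                        try:
                            grid.append(PenaltyProfile(c_p, c_lp, c_rn, c_ln, c_wn))
                        except ValueError:
                            continue
    return grid


def select_penalties(
    sets: dict[str, np.ndarray],
    grid: list[PenaltyProfile] | None = None,
    folds: int = 10,
    seed: int = 0,
    kernel: str = "linear",
) -> PenaltyProfile:
    """Choose the penalty profile maximising mean F-measure under k-fold CV.

    Folds are drawn over P (held out as positives) and RN (held out as
    negatives); LP/LN/WN always stay in the training side.  Profiles
    violating the ordering constraints are filtered out before the search;
    ties break toward smaller total penalties.  Deterministic for a fixed
    seed.
    """
    candidates = []
    for prof in default_penalty_grid() if grid is None else grid:
        try:
            PenaltyProfile(prof.c_p, prof.c_lp, prof.c_rn, prof.c_ln, prof.c_wn)
        except ValueError:
            continue
        candidates.append(prof)
    if not candidates:
        raise ValueError("no feasible penalty profile in the grid")
    candidates.sort(key=lambda pr: (pr.total, pr.c_p, pr.c_lp, pr.c_rn, pr.c_ln, pr.c_wn))

    x_p = np.atleast_2d(np.asarray(sets["P"], dtype=float))
    x_rn = np.atleast_2d(np.asarray(sets["RN"], dtype=float))
    n_splits = min(folds, x_p.shape[0], x_rn.shape[0])
    if n_splits < 2:
        return candidates[0]
    x_cal = np.vstack([x_p, x_rn])
    y_cal = np.concatenate([np.ones(x_p.shape[0]), np.zeros(x_rn.shape[0])])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(x_cal, y_cal))

    best_prof, best_f = None, -1.0
    for prof in candidates:
        f_vals = []
        for train_idx, test_idx in splits:
            fold_sets = dict(sets)
            fold_sets["P"] = x_cal[train_idx][y_cal[train_idx] == 1]
            fold_sets["RN"] = x_cal[train_idx][y_cal[train_idx] == 0]
            try:
                model = train_weighted_svm(fold_sets, prof, kernel, calibrate=False)
            except ValueError:
                continue
            pred = model.decision_scores(x_cal[test_idx]) > 0
            truth = y_cal[test_idx] == 1
            tp = np.sum(pred & truth)
            p = tp / pred.sum() if pred.sum() else 0.0
            r = tp / truth.sum() if truth.sum() else 0.0
            f_vals.append(f_measure(p, r))
        mean_f = float(np.mean(f_vals)) if f_vals else 0.0
        if mean_f > best_f + 1e-12:
            best_f, best_prof = mean_f, prof
    return best_prof if best_prof is not None else candidates[0]
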