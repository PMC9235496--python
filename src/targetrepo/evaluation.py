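"""ROC/AUC evaluation and cross-validation of the prediction methods.

Predictions are ranked scores over (target, disease) pairs; performance is
the area under the ROC curve against the gold-standard binary labels, with
tied scores given half credit (the Mann-Whitney convention).  The
trans-disease model is evaluated by k-fold cross-validation at the pair
level: pairs are partitioned into folds, the test fold's positives are
masked to 0 in the training label matrix (targets stay in X so they remain
scoreable), the model is refitted, and the test pairs are scored.
Per-cell-line evaluation mirrors the main benchmark: each cell line's
signatures form an independent dataset and contribute one AUC per method.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .graph import DiseaseGraph
from .model import TrainConfig, TransDiseaseLogistic, LabelMatrix

__all__ = ["RocCurve", "EvaluationError", "roc_auc", "cross_validate",
           "CrossValidationReport", "evaluate_per_cell_line"]


class EvaluationError(ValueError):
    """Raised when labels contain a single class or folds cannot be formed."""


@dataclass
class RocCurve:
    """ROC curve points and the trapezoidal area under them."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC of scores against binary labels (ties: half credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    npos = int(labels.sum())
    if npos == 0 or npos == len(labels):
        raise EvaluationError("need at least one positive and one negative label")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_skm.roc_auc_score(labels, scores)))


@dataclass
class CrossValidationReport:
    """Per-fold AUCs, their mean, and the pooled test-pair score table."""

    fold_aucs: list[float]
    mean_auc: float
    pooled: pd.DataFrame  # columns: fold, target_index, disease_index, score, label

    def pooled_auc(self) -> float:
        return roc_auc(self.pooled["score"].to_numpy(),
                       self.pooled["label"].to_numpy()).auc


def _make_folds(n_pairs: int, k: int, rng: np.random.Generator) -> np.ndarray:
    assignment = np.repeat(np.arange(k), int(np.ceil(n_pairs / k)))[:n_pairs]
    rng.shuffle(assignment)
    return assignment


def cross_validate(X, Y, graph: DiseaseGraph | np.ndarray | None,
                   config: TrainConfig | None = None, k: int = 5,
                   seed: int = 0) -> CrossValidationReport:
    """k-fold pair-level cross-validation of the trans-disease model.

    Folds that land without both classes trigger a refold with a new seed,
    up to 10 attempts.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(Y, LabelMatrix):
        Ymat, obs = Y.Y, Y.observed
    else:
        Ymat, obs = np.asarray(Y, dtype=float), None
    N, M = Ymat.shape
    flat_y = Ymat.reshape(-1)
    flat_obs = (np.ones(N * M) if obs is None else obs.reshape(-1)).astype(bool)
    obs_idx = np.flatnonzero(flat_obs)
    y_obs = flat_y[obs_idx]
    if y_obs.sum() == 0 or y_obs.sum() == y_obs.size:
        raise EvaluationError("gold standard contains a single class")
    config = config or TrainConfig()
    # folds smaller than two pairs (or with fewer positives than folds) can
    # never hold both classes; then per-fold AUCs are skipped and the pooled
    # AUC over all test pairs stands in (the leave-one-pair-out regime)
    feasible = len(obs_idx) >= 2 * k and y_obs.sum() >= k and \
        (y_obs.size - y_obs.sum()) >= k
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        folds = _make_folds(len(obs_idx), k, rng)
        ok = all(0 < y_obs[folds == f].sum() < (folds == f).sum() for f in range(k))
        if ok:
            break
    else:
        if feasible:
            raise EvaluationError(
                "could not build folds with both classes in each test set")
    fold_aucs, rows = [], []
    for f in range(k):
        test = obs_idx[folds == f]
        Y_train = flat_y.copy()
        Y_train[test] = 0.0  # mask test positives; targets stay in X
        labels = LabelMatrix(Y=Y_train.reshape(N, M),
                             target_ids=[f"target_{i}" for i in range(N)],
                             disease_ids=[f"disease_{m}" for m in range(M)],
                             observed=None if obs is None else obs)
        model = TransDiseaseLogistic(X, labels, graph)
        res = model.fit(config)
        scores = res.predict(X).reshape(-1)
        if 0 < flat_y[test].sum() < len(test):
            fold_aucs.append(roc_auc(scores[test], flat_y[test]).auc)
        ti, di = np.unravel_index(test, (N, M))
        rows.append(pd.DataFrame({"fold": f, "target_index": ti, "disease_index": di,
                                  "score": scores[test], "label": flat_y[test]}))
    pooled = pd.concat(rows, ignore_index=True)
    report = CrossValidationReport(fold_aucs=fold_aucs, mean_auc=np.nan,
                                   pooled=pooled)
    report.mean_auc = float(np.mean(fold_aucs)) if fold_aucs else report.pooled_auc()
    return report


def evaluate_per_cell_line(datasets: dict, method: str = "trans_disease",
                           config: TrainConfig | None = None, k: int = 5,
                           seed: int = 0) -> pd.DataFrame:
    """One AUC per cell line for the chosen method.

    ``datasets`` maps cell line -> dict with keys ``X``, ``Y``, ``graph``
    (trans_disease), or ``aligned``, ``Y`` (inverse), or ``scores``, ``Y``
    (snp: precomputed pair scores).  Cell lines whose gold standard has a
    single class are skipped with a warning row (auc = NaN).
    """
    from .inverse import rank_inverse_candidates

    rows = []
    for cell, data in sorted(datasets.items()):
        Ymat = data["Y"].Y if isinstance(data["Y"], LabelMatrix) else np.asarray(data["Y"], float)
        flat_y = Ymat.reshape(-1)
        if flat_y.sum() in (0, flat_y.size):
            rows.append((cell, method, np.nan, "single-class gold standard"))
            continue
        if method == "trans_disease":
            report = cross_validate(data["X"], Ymat, data.get("graph"),
                                    config, k=k, seed=seed)
            auc = report.mean_auc
        elif method == "inverse":
            aligned = data["aligned"]
            table = rank_inverse_candidates(aligned, data.get("mode", "knockdown"), cell)
            tix = {t: i for i, t in enumerate(aligned.target_ids)}
            dix = {d: j for j, d in enumerate(aligned.disease_ids)}
            scores = np.array([s for s in table["score"]])
            labels = np.array([Ymat[tix[t], dix[d]] for t, d in
                               zip(table["target_gene"], table["disease_id"])])
            auc = roc_auc(scores, labels).auc
        elif method == "snp":
            auc = roc_auc(np.asarray(data["scores"], float).reshape(-1), flat_y).auc
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((cell, method, auc, ""))
    return pd.DataFrame(rows, columns=["cell_line", "method", "auc", "note"])
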