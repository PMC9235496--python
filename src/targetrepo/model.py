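"""Trans-disease multi-label logistic regression with a disease-graph penalty.

The learner scores every (target, disease) pair jointly across all M
diseases.  Target i carries a d-dimensional perturbation signature x_i and a
binary label y_mi per disease m.  Each disease has a linear score
f_m(x) = w_m^T x, and the d x M weight matrix W = [w_1 ... w_M] minimizes

    sum_m sum_i log(1 + exp(-yt_mi w_m^T x_i))
        + lambda_r * (1/2) Tr(W W^T)
        + lambda_s * (1/2) Tr(W Ls W^T)

with yt = 2y - 1 the +-1 labels, Ls the symmetric normalized Laplacian of
the disease cosine-similarity graph.  The Laplacian term equals
(1/4) sum_lm S_lm || w_l/sqrt(K_ll) - w_m/sqrt(K_mm) ||^2: similar diseases
are pulled toward proportional weight vectors, which transfers label
information to diseases with few or no known targets.

The objective is convex; it is minimized by full-batch gradient descent
with backtracking (step halved whenever a step would increase the
objective), so the recorded objective trace is non-increasing.

Usage follows the Model/Results convention::

    model = TransDiseaseLogistic(X, Y, graph)
    res = model.fit(TrainConfig(lambda_s=0.1, lambda_r=0.1))
    scores = res.predict(X_new)        # N' x M matrix in (0, 1)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph import DiseaseGraph

__all__ = [
    "LabelMatrix", "TrainConfig", "OptimizationError",
    "TransDiseaseLogistic", "TransDiseaseResults",
    "logistic_loss", "ridge_penalty", "laplacian_penalty",
    "select_hyperparameters", "HyperparameterSelectionError",
]


class OptimizationError(RuntimeError):
    """Raised when gradient descent produces a non-finite objective."""


class HyperparameterSelectionError(RuntimeError):
    """Raised when no hyperparameter grid point yields a valid score."""


@dataclass
class LabelMatrix:
    """Binary N x M target-by-disease association labels.

    ``observed`` optionally marks which pairs belong to the learning set
    (1 = observed).  Unobserved pairs contribute neither to the loss nor to
    evaluation folds; by default every pair is observed, which is the
    situation with a real curated gold standard (unknown pairs are
    negatives).
    """

    Y: np.ndarray
    target_ids: list[str]
    disease_ids: list[str]
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.target_ids), len(self.disease_ids)):
            raise ValueError("Y shape inconsistent with id lists")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=float)
            if self.observed.shape != self.Y.shape:
                raise ValueError("observed mask shape differs from Y")
            if not np.isin(self.observed, (0.0, 1.0)).all():
                raise ValueError("observed mask must be binary")
            if np.any((self.Y == 1.0) & (self.observed == 0.0)):
                raise ValueError("positive labels must be observed")

    @classmethod
    def from_associations(cls, assoc: pd.DataFrame, target_ids: Sequence[str],
                          disease_ids: Sequence[str], mode: str) -> "LabelMatrix":
        """Build labels from a (target_gene, disease_id, mode) association table.

        Pairs absent from the table are negatives; associations whose target
        or disease is not in the given id lists are dropped.
        """
        tix = {t: i for i, t in enumerate(target_ids)}
        dix = {d: j for j, d in enumerate(disease_ids)}
        Y = np.zeros((len(target_ids), len(disease_ids)))
        sel = assoc[assoc["mode"] == mode]
        for t, dis in zip(sel["target_gene"], sel["disease_id"]):
            if t in tix and dis in dix:
                Y[tix[t], dix[dis]] = 1.0
        return cls(Y=Y, target_ids=list(target_ids), disease_ids=list(disease_ids))

    def diseases_without_positives(self) -> list[str]:
        return [d for j, d in enumerate(self.disease_ids) if self.Y[:, j].sum() == 0]


@dataclass
class TrainConfig:
    """Gradient-descent settings and regularization strengths.

    lambda_s scales the disease-graph (Laplacian) penalty, lambda_r the
    ridge penalty; learning_rate is the initial step, halved on any step
    that would increase the objective; tol is the relative objective-change
    stopping threshold.
    """

    lambda_s: float = 0.1
    lambda_r: float = 0.1
    learning_rate: float = 0.05
    max_iters: int = 5000
    tol: float = 1e-7
    seed: int = 0
    init: str = "zeros"  # "zeros" or "small_random"

    def __post_init__(self) -> None:
        if self.lambda_s < 0 or self.lambda_r < 0:
            raise ValueError("regularization strengths must be nonnegative")
        if self.learning_rate <= 0 or self.max_iters <= 0 or self.tol <= 0:
            raise ValueError("learning_rate, max_iters and tol must be positive")
        if self.init not in ("zeros", "small_random"):
            raise ValueError(f"unknown init {self.init!r}")


# -- objective pieces (module-level so they can be tested in isolation) -----

def logistic_loss(W: np.ndarray, X: np.ndarray, Y: np.ndarray,
                  observed: np.ndarray | None = None) -> float:
    """Sum over diseases and targets of log(1 + exp(-yt f)), yt = 2y - 1.

    Evaluated with log1p/softplus stability, finite even for |f| ~ 1e3.
    ``observed`` (0/1, same shape as Y) restricts the sum to the learning
    pairs; omitted, every pair contributes.
    """
    W, X, Y = (np.asarray(a, dtype=float) for a in (W, X, Y))
    if X.shape[1] != W.shape[0] or Y.shape != (X.shape[0], W.shape[1]):
        raise ValueError("dimension mismatch between W, X and Y")
    margins = (2.0 * Y - 1.0) * (X @ W)
    terms = np.logaddexp(0.0, -margins)
    if observed is not None:
        terms = terms * np.asarray(observed, dtype=float)
    return float(terms.sum())


def ridge_penalty(W: np.ndarray) -> float:
    """(1/2) Tr(W W^T) = half the squared Frobenius norm."""
    W = np.asarray(W, dtype=float)
    return 0.5 * float((W * W).sum())


def laplacian_penalty(W: np.ndarray, graph: DiseaseGraph | np.ndarray) -> float:
    """(1/2) Tr(W Ls W^T); equals the pairwise normalized-difference sum form."""
    Ls = graph.Ls if isinstance(graph, DiseaseGraph) else np.asarray(graph, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape[1] != Ls.shape[0]:
        raise ValueError("W columns do not match graph diseases")
    return 0.5 * float(np.einsum("dl,lm,dm->", W, Ls, W))


def laplacian_penalty_sum_form(W: np.ndarray, S: np.ndarray, K: np.ndarray) -> float:
    """Explicit (1/4) sum_lm S_lm ||w_l/sqrt(K_ll) - w_m/sqrt(K_mm)||^2.

    Redundant with :func:`laplacian_penalty`; kept as a built-in cross-check
    of the trace identity.
    """
    Wn = np.asarray(W, dtype=float) / np.sqrt(np.diag(K))[None, :]
    M = S.shape[0]
    total = 0.0
    for l in range(M):
        diff = Wn[:, l][:, None] - Wn
        total += float(np.maximum(S, 0.0)[l] @ (diff * diff).sum(axis=0))
    return 0.25 * total


class TransDiseaseLogistic:
    """Joint logistic model over diseases, coupled by a disease-similarity graph.

    Parameters
    ----------
    X : (N, d) array
        Perturbation signatures, one row per target gene.
    Y : (N, M) binary array or LabelMatrix
        Known target-disease associations; unknown pairs are negatives.
    graph : DiseaseGraph or (M, M) Laplacian array, optional
        Disease-similarity Laplacian.  Omitted -> lambda_s term inert
        (equivalent to Ls = 0).
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray | LabelMatrix,
                 graph: DiseaseGraph | np.ndarray | None = None, *,
                 target_ids: Sequence[str] | None = None,
                 disease_ids: Sequence[str] | None = None,
                 gene_list: Sequence[str] | None = None):
        self.X = np.asarray(X, dtype=float)
        if isinstance(Y, LabelMatrix):
            self.labels = Y
        else:
            Y = np.asarray(Y, dtype=float)
            self.labels = LabelMatrix(
                Y=Y,
                target_ids=list(target_ids) if target_ids is not None
                else [f"target_{i}" for i in range(Y.shape[0])],
                disease_ids=list(disease_ids) if disease_ids is not None
                else [f"disease_{m}" for m in range(Y.shape[1])],
            )
        if self.X.shape[0] != self.labels.Y.shape[0]:
            raise ValueError("X and Y disagree on the number of targets")
        if isinstance(graph, DiseaseGraph):
            if graph.n_diseases != self.labels.Y.shape[1]:
                raise ValueError("graph and Y disagree on the number of diseases")
            if graph.disease_ids != self.labels.disease_ids and disease_ids is None \
                    and not all(d.startswith("disease_") for d in self.labels.disease_ids):
                raise ValueError("graph disease ordering differs from label ordering")
            self.Ls = graph.Ls
        elif graph is None:
            self.Ls = np.zeros((self.labels.Y.shape[1],) * 2)
        else:
            self.Ls = np.asarray(graph, dtype=float)
        self.graph = graph if isinstance(graph, DiseaseGraph) else None
        self.gene_list = list(gene_list) if gene_list is not None else None

    # -- dimensions ---------------------------------------------------------
    @property
    def n_targets(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_diseases(self) -> int:
        return self.labels.Y.shape[1]

    # -- objective ----------------------------------------------------------
    def objective(self, W: np.ndarray, config: TrainConfig) -> float:
        """R(W) + lambda_s * Omega_s(W) + lambda_r * Omega_r(W)."""
        return (logistic_loss(W, self.X, self.labels.Y, self.labels.observed)
                + config.lambda_s * laplacian_penalty(W, self.Ls)
                + config.lambda_r * ridge_penalty(W))

    def objective_gradient(self, W: np.ndarray, config: TrainConfig) -> np.ndarray:
        """Closed-form gradient: X^T(sigma(XW) - Y) + lambda_r W + lambda_s W Ls."""
        W = np.asarray(W, dtype=float)
        resid = expit(self.X @ W) - self.labels.Y
        if self.labels.observed is not None:
            resid = resid * self.labels.observed
        return (self.X.T @ resid
                + config.lambda_r * W
                + config.lambda_s * (W @ self.Ls))

    # -- fitting ------------------------------------------------------------
    def fit(self, config: TrainConfig | None = None) -> "TransDiseaseResults":
        """Minimize the objective by backtracking gradient descent."""
        config = config or TrainConfig()
        d, M = self.n_genes, self.n_diseases
        if config.init == "zeros":
            W = np.zeros((d, M))
        else:
            rng = np.random.default_rng(config.seed)
            W = 0.01 * rng.standard_normal((d, M))
        eta = config.learning_rate
        obj = self.objective(W, config)
        trace = [obj]
        converged = False
        for it in range(config.max_iters):
            grad = self.objective_gradient(W, config)
            accepted = False
            for _ in range(60):
                W_new = W - eta * grad
                obj_new = self.objective(W_new, config)
                if not np.isfinite(obj_new):
                    raise OptimizationError(
                        f"objective became non-finite at iteration {it}")
                if obj_new <= obj:
                    accepted = True
                    break
                eta *= 0.5
            if not accepted:
                converged = True  # no descent possible at float precision
                break
            rel_change = (obj - obj_new) / max(abs(obj), 1.0)
            W, obj = W_new, obj_new
            trace.append(obj)
            if rel_change < config.tol:
                converged = True
                break
        return TransDiseaseResults(model=self, W=W, config=config,
                                   objective_trace=np.array(trace),
                                   converged=converged)

    @classmethod
    def from_aligned(cls, aligned, labels: LabelMatrix,
                     graph: DiseaseGraph | None = None) -> "TransDiseaseLogistic":
        """Build from an AlignedDataset plus a LabelMatrix on matching ids."""
        if labels.target_ids != aligned.target_ids:
            raise ValueError("label target ordering differs from aligned dataset")
        return cls(aligned.X, labels, graph, gene_list=aligned.gene_list)


@dataclass
class TransDiseaseResults:
    """Fitted weights, convergence trace and prediction interface."""

    model: TransDiseaseLogistic
    W: np.ndarray
    config: TrainConfig
    objective_trace: np.ndarray
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.objective_trace) - 1

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Targetability scores sigma(w_m^T x) in (0,1), shape (N', M)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[-1]} genes, model was trained on "
                f"{self.W.shape[0]}")
        return expit(X_new @ self.W)

    def predict_frame(self, X_new: np.ndarray,
                      target_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Long-format score table with per-disease ranks (1 = best)."""
        scores = self.predict(X_new)
        if target_ids is None:
            target_ids = [f"target_{i}" for i in range(scores.shape[0])]
        rows = []
        for j, dis in enumerate(self.model.labels.disease_ids):
            order = pd.Series(scores[:, j], index=list(target_ids))
            ranks = order.rank(ascending=False, method="first")
            for t in target_ids:
                rows.append((t, dis, order[t], int(ranks[t])))
        return pd.DataFrame(rows, columns=["target_gene", "disease_id", "score", "rank"])

    def summary(self) -> str:
        m = self.model
        lines = [
            "Trans-disease logistic regression",
            "=" * 44,
            f"targets (N):          {m.n_targets}",
            f"genes (d):            {m.n_genes}",
            f"diseases (M):         {m.n_diseases}",
            f"positives:            {int(m.labels.Y.sum())}",
            f"lambda_s / lambda_r:  {self.config.lambda_s} / {self.config.lambda_r}",
            f"iterations:           {self.n_iterations}"
            + (" (converged)" if self.converged else " (max_iters reached)"),
            f"final objective:      {self.final_objective:.6f}",
            f"||W||_F:              {np.linalg.norm(self.W):.6f}",
        ]
        orphan = m.labels.diseases_without_positives()
        if orphan:
            lines.append(f"diseases w/o positives: {len(orphan)} "
                         f"(coupled only through the graph)")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, weights_path, sidecar_path) -> None:
        """TSV weight matrix (genes x diseases) + JSON sidecar with config/trace."""
        genes = self.model.gene_list or [f"g{k}" for k in range(self.W.shape[0])]
        pd.DataFrame(self.W, index=genes,
                     columns=self.model.labels.disease_ids).to_csv(
            weights_path, sep="\t", float_format="%.12g")
        sidecar = {
            "config": asdict(self.config),
            "gene_list": genes,
            "disease_ids": self.model.labels.disease_ids,
            "converged": self.converged,
            "objective_trace": [float(v) for v in self.objective_trace],
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=1)


def select_hyperparameters(X, Y, graph, grid: Sequence[tuple[float, float]],
                           k: int = 3, seed: int = 0,
                           config: TrainConfig | None = None) -> tuple[float, float]:
    """Pick (lambda_s, lambda_r) maximizing mean inner-k-fold validation AUC.

    Ties break toward the earliest grid point, so the result is
    deterministic given the seed.
    """
    from .evaluation import cross_validate, EvaluationError

    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    base = config or TrainConfig()
    best, best_auc = None, -np.inf
    any_valid = False
    for lam_s, lam_r in grid:
        cfg = TrainConfig(lambda_s=lam_s, lambda_r=lam_r,
                          learning_rate=base.learning_rate,
                          max_iters=base.max_iters, tol=base.tol,
                          seed=base.seed, init=base.init)
        try:
            report = cross_validate(X, Y, graph, cfg, k=k, seed=seed)
        except EvaluationError:
            continue
        any_valid = True
        if report.mean_auc > best_auc:
            best, best_auc = (lam_s, lam_r), report.mean_auc
    if not any_valid:
        raise HyperparameterSelectionError(
            "no grid point produced a scoreable validation fold")
    return best
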