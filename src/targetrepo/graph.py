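"""Disease similarity graph and its symmetric normalized Laplacian.

Diseases are compared by the cosine similarity of their full-gene
differential-expression signatures.  The similarity matrix S feeds a
symmetric normalized Laplacian Ls = K^{-1/2} (K - S) K^{-1/2}, where K is
diagonal with K_ll = sum_m S_lm (self-similarity included).  Ls couples the
per-disease weight vectors of the trans-disease model: similar diseases are
pushed toward proportional weights.

Disease signatures are signed, so raw cosines can be negative and K^{-1/2}
would be ill-defined; negative entries are clamped to zero before K and Ls
are formed (the raw matrix is kept for reporting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DiseaseSignature

__all__ = ["DiseaseGraph", "DegenerateGraphError", "cosine_similarity_matrix",
           "graph_laplacian", "build_disease_graph"]

logger = logging.getLogger(__name__)


class DegenerateGraphError(ValueError):
    """Raised when a disease row has nonpositive total similarity."""


@dataclass
class DiseaseGraph:
    """Cosine similarity S (raw and nonnegative-adjusted), degrees K, Laplacian Ls."""

    disease_ids: list[str]
    S: np.ndarray            # raw cosine similarity, entries in [-1, 1]
    S_adjusted: np.ndarray   # clamped at 0, used for K and Ls
    K: np.ndarray            # diagonal degree matrix
    Ls: np.ndarray           # symmetric normalized Laplacian, PSD

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def to_frame(self, which: str = "S") -> pd.DataFrame:
        mat = {"S": self.S, "S_adjusted": self.S_adjusted, "K": self.K,
               "Ls": self.Ls}[which]
        return pd.DataFrame(mat, index=self.disease_ids, columns=self.disease_ids)


def cosine_similarity_matrix(disease_sigs: Sequence[DiseaseSignature]) -> np.ndarray:
    """Pairwise cosine similarity of disease signatures (shared gene list).

    A zero signature gets similarity 0 to every other disease and 1 to
    itself, with a logged warning.
    """
    if not disease_sigs:
        raise ValueError("no disease signatures given")
    genes = list(disease_sigs[0].values.index)
    Z = np.array([s.values.reindex(genes).to_numpy(dtype=float) for s in disease_sigs])
    if Z.shape[1] != len(genes) or any(len(s.values) != len(genes) for s in disease_sigs):
        raise ValueError("disease signatures must share one gene list")
    norms = np.linalg.norm(Z, axis=1)
    zero = norms == 0
    if np.all(zero):
        raise ValueError("all disease signatures are zero vectors")
    if np.any(zero):
        ids = [disease_sigs[i].disease_id for i in np.flatnonzero(zero)]
        logger.warning("zero disease signature(s): %s; similarities set to 0", ids)
    safe = np.where(zero, 1.0, norms)
    Zn = Z / safe[:, None]
    S = Zn @ Zn.T
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    S[np.flatnonzero(zero), np.flatnonzero(zero)] = 1.0
    return S


def graph_laplacian(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and symmetric normalized Laplacian of a similarity matrix.

    Negative entries of ``S`` are clamped to zero first.  Returns ``(K, Ls)``
    with K_ll = sum_m max(S,0)_lm and Ls = K^{-1/2} (K - S) K^{-1/2}.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    S0 = np.maximum(S, 0.0)
    deg = S0.sum(axis=1)
    bad = np.flatnonzero(deg <= 0)
    if bad.size:
        raise DegenerateGraphError(
            f"nonpositive similarity row sum for disease index(es) {bad.tolist()}"
        )
    K = np.diag(deg)
    inv_sqrt = 1.0 / np.sqrt(deg)
    Ls = (K - S0) * np.outer(inv_sqrt, inv_sqrt)
    Ls = (Ls + Ls.T) / 2.0
    return K, Ls


def build_disease_graph(disease_sigs: Sequence[DiseaseSignature]) -> DiseaseGraph:
    """Full pipeline: cosine similarity -> clamp -> degrees -> normalized Laplacian."""
    S = cosine_similarity_matrix(disease_sigs)
    K, Ls = graph_laplacian(S)
    return DiseaseGraph(
        disease_ids=[s.disease_id for s in disease_sigs],
        S=S, S_adjusted=np.maximum(S, 0.0), K=K, Ls=Ls,
    )
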