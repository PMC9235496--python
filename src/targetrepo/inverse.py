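"""Inverse-signature scoring of target-disease pairs.

A knockdown signature approximates inhibiting the protein, an
overexpression signature approximates activating it.  If perturbing the
target reverses the disease expression pattern — Pearson correlation
between the perturbation signature and the disease signature strongly
negative — the target is a candidate for treating that disease.  Candidates
are ranked ascending in r (most negative first); the score exported for
ROC evaluation is -r.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import AlignedDataset, PerturbationMode

__all__ = ["UndefinedCorrelationError", "pearson_correlation", "rank_inverse_candidates"]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when an input vector has zero variance."""


def pearson_correlation(x: np.ndarray, z: np.ndarray) -> float:
    """Pearson correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` on zero variance rather than
    silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape or x.ndim != 1:
        raise ValueError("x and z must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least two genes")
    xc = x - x.mean()
    zc = z - z.mean()
    denom = np.sqrt((xc @ xc) * (zc @ zc))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero-variance vector")
    return float(np.clip((xc @ zc) / denom, -1.0, 1.0))


def rank_inverse_candidates(aligned: AlignedDataset,
                            mode: PerturbationMode | str = PerturbationMode.KNOCKDOWN,
                            cell_line: str | None = None) -> pd.DataFrame:
    """Score every (target, disease) pair and rank by inverse correlation.

    Returns a table with columns (cell_line, target_gene, disease_id, mode,
    pearson_r, score, rank); score = -pearson_r, rank 1 = most negative r.
    Ties break lexicographically on (target_gene, disease_id).  Pairs with
    undefined correlation (zero-variance signature) are excluded and their
    count logged.
    """
    mode = PerturbationMode(mode)
    X, Z = aligned.X, aligned.Z
    Xc = X - X.mean(axis=1, keepdims=True)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    zn = np.linalg.norm(Zc, axis=1)
    ok_x, ok_z = xn > 0, zn > 0
    n_dropped = (~ok_x).sum() * Z.shape[0] + ok_x.sum() * (~ok_z).sum()
    if n_dropped:
        logger.warning("excluding %d pairs with undefined correlation", int(n_dropped))
    R = np.full((X.shape[0], Z.shape[0]), np.nan)
    if ok_x.any() and ok_z.any():
        R[np.ix_(ok_x, ok_z)] = (
            (Xc[ok_x] / xn[ok_x, None]) @ (Zc[ok_z] / zn[ok_z, None]).T
        )
    R = np.clip(R, -1.0, 1.0)
    rows = []
    for i, t in enumerate(aligned.target_ids):
        for j, dis in enumerate(aligned.disease_ids):
            if np.isfinite(R[i, j]):
                rows.append((cell_line or "", t, dis, mode.value, R[i, j], -R[i, j]))
    df = pd.DataFrame(rows, columns=["cell_line", "target_gene", "disease_id",
                                     "mode", "pearson_r", "score"])
    df = df.sort_values(["pearson_r", "target_gene", "disease_id"],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
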