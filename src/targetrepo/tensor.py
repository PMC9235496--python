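"""Masked CP completion of the perturbation signature tensor.

Perturbational data form a third-order tensor (perturbed gene x measured
gene x cell line); most (perturbed gene, cell line) slices were never
assayed.  Missing slices are imputed by a canonical polyadic (CP)
decomposition fitted to the observed entries only, via EM-style
alternating least squares: fill the missing entries with the current
reconstruction, run one unmasked ALS sweep, repeat.  The masked residual
is non-increasing across iterations and observed entries are returned
unchanged by :func:`impute`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PerturbationTensor", "TensorAssemblyError", "DecompositionError",
           "CpConfig", "assemble_tensor", "cp_reconstruct",
           "cp_decompose_masked", "impute", "select_rank"]

logger = logging.getLogger(__name__)


class TensorAssemblyError(ValueError):
    """Raised on duplicate (perturbed gene, cell line) signatures."""


class DecompositionError(RuntimeError):
    """Raised when a fitted slice contains no observed entry."""


@dataclass
class PerturbationTensor:
    """3-way array (perturbed x measured x cell line) with an observation mask."""

    T: np.ndarray
    mask: np.ndarray          # 1 = observed
    perturbed_genes: list[str]
    measured_genes: list[str]
    cell_lines: list[str]

    def __post_init__(self) -> None:
        expected = (len(self.perturbed_genes), len(self.measured_genes),
                    len(self.cell_lines))
        if self.T.shape != expected or self.mask.shape != expected:
            raise ValueError("tensor/mask shape inconsistent with axis labels")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if not np.all(np.isfinite(self.T[self.mask.astype(bool)])):
            raise ValueError("observed entries must be finite")

    def missing_rate_per_cell_line(self) -> pd.Series:
        obs = self.mask.mean(axis=(0, 1))
        return pd.Series(1.0 - obs, index=self.cell_lines, name="missing_rate")


@dataclass
class CpConfig:
    """ALS settings: factor rank, seed, iteration cap and stopping tolerance."""

    rank: int = 3
    seed: int = 0
    max_iters: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def assemble_tensor(signatures, measured_gene_list, cell_line_list) -> PerturbationTensor:
    """Lay signatures into the (perturbed, measured, cell line) tensor.

    Each signature fills the fiber T[i, :, k] for its perturbed gene i and
    cell line k; fibers without a signature are masked missing.
    """
    signatures = list(signatures)
    measured = list(measured_gene_list)
    cells = list(cell_line_list)
    perturbed = sorted({s.perturbed_gene for s in signatures})
    pix = {g: i for i, g in enumerate(perturbed)}
    cix = {c: k for k, c in enumerate(cells)}
    T = np.zeros((len(perturbed), len(measured), len(cells)))
    mask = np.zeros_like(T)
    seen = set()
    for s in signatures:
        key = (s.perturbed_gene, s.cell_line)
        if key in seen:
            raise TensorAssemblyError(f"duplicate signature for {key}")
        seen.add(key)
        if s.cell_line not in cix:
            continue
        vals = s.values.reindex(measured)
        if vals.isna().any():
            raise ValueError(
                f"signature {key}: missing measured genes "
                f"{vals.index[vals.isna()].tolist()[:5]}")
        T[pix[s.perturbed_gene], :, cix[s.cell_line]] = vals.to_numpy(dtype=float)
        mask[pix[s.perturbed_gene], :, cix[s.cell_line]] = 1.0
    tensor = PerturbationTensor(T=T, mask=mask, perturbed_genes=perturbed,
                                measured_genes=measured, cell_lines=cells)
    for cell, rate in tensor.missing_rate_per_cell_line().items():
        logger.info("cell line %s: missing rate %.3f", cell, rate)
    return tensor


def cp_reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Dense tensor from CP factors: T_ijk = sum_r A_ir B_jr C_kr."""
    return np.einsum("ir,jr,kr->ijk", A, B, C)


def _als_sweep(T_full, A, B, C):
    # classic unmasked ALS updates via mode unfoldings and Khatri-Rao products
    eps = 1e-12 * np.eye(A.shape[1])

    def khatri_rao(U, V):
        return (U[:, None, :] * V[None, :, :]).reshape(-1, U.shape[1])

    KR = khatri_rao(B, C)  # (J*K, R) matching unfold order below
    G = (B.T @ B) * (C.T @ C)
    A = np.linalg.solve(G + eps, KR.T @ T_full.reshape(T_full.shape[0], -1).T).T
    KR = khatri_rao(A, C)
    G = (A.T @ A) * (C.T @ C)
    unfold1 = np.moveaxis(T_full, 1, 0).reshape(T_full.shape[1], -1)
    B = np.linalg.solve(G + eps, KR.T @ unfold1.T).T
    KR = khatri_rao(A, B)
    G = (A.T @ A) * (B.T @ B)
    unfold2 = np.moveaxis(T_full, 2, 0).reshape(T_full.shape[2], -1)
    C = np.linalg.solve(G + eps, KR.T @ unfold2.T).T
    return A, B, C


def cp_decompose_masked(T: np.ndarray, mask: np.ndarray, rank: int,
                        config: CpConfig | None = None):
    """Fit CP factors to the observed entries of a partially observed tensor.

    EM / alternating least squares: the missing entries are imputed with the
    current reconstruction, one full unmasked ALS sweep updates the three
    factors, and the masked residual is tracked until its relative change
    falls below ``config.tol``.  Returns ``(A, B, C, residual_trace)``.
    """
    T = np.asarray(T, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if config is None:
        config = CpConfig(rank=rank)
    bmask = mask.astype(bool)
    n_obs = int(bmask.sum())
    if n_obs == 0:
        raise DecompositionError("tensor has no observed entries")
    for axis, names in ((0, "perturbed-gene"), (1, "measured-gene"), (2, "cell-line")):
        per_slice = mask.sum(axis=tuple(a for a in range(3) if a != axis))
        empty = np.flatnonzero(per_slice == 0)
        if empty.size:
            raise DecompositionError(
                f"{names} slice(s) {empty.tolist()[:5]} have no observed entries")
    rng = np.random.default_rng(config.seed)
    scale = np.std(T[bmask]) or 1.0
    A = rng.standard_normal((T.shape[0], rank)) * scale ** (1 / 3)
    B = rng.standard_normal((T.shape[1], rank)) * scale ** (1 / 3)
    C = rng.standard_normal((T.shape[2], rank)) * scale ** (1 / 3)
    obs_norm = np.linalg.norm(T[bmask]) or 1.0
    recon = cp_reconstruct(A, B, C)
    residual = np.linalg.norm((T - recon)[bmask]) / obs_norm
    trace = [residual]
    for _ in range(config.max_iters):
        T_full = np.where(bmask, T, recon)
        A, B, C = _als_sweep(T_full, A, B, C)
        recon = cp_reconstruct(A, B, C)
        new_residual = np.linalg.norm((T - recon)[bmask]) / obs_norm
        trace.append(new_residual)
        if new_residual < 1e-12 or \
                abs(residual - new_residual) <= config.tol * max(residual, 1e-12):
            residual = new_residual
            break
        residual = new_residual
    else:
        warnings.warn(
            f"masked ALS did not converge in {config.max_iters} iterations; "
            f"final relative residual {residual:.3e}", RuntimeWarning)
    return A, B, C, np.array(trace)


def impute(T: np.ndarray, mask: np.ndarray, factors) -> np.ndarray:
    """Replace missing entries by the CP reconstruction; observed entries pass through bit-exactly."""
    A, B, C = factors[:3]
    T = np.asarray(T, dtype=float)
    mask = np.asarray(mask, dtype=float)
    recon = cp_reconstruct(A, B, C)
    if recon.shape != T.shape or mask.shape != T.shape:
        raise ValueError("factor shapes inconsistent with tensor")
    return np.where(mask.astype(bool), T, recon)


def select_rank(T: np.ndarray, mask: np.ndarray, rank_grid,
                holdout_fraction: float = 0.1, seed: int = 0,
                config: CpConfig | None = None) -> int:
    """Choose the CP rank minimizing error on held-out observed entries."""
    rng = np.random.default_rng(seed)
    bmask = np.asarray(mask, dtype=float).astype(bool)
    obs_idx = np.argwhere(bmask)
    n_hold = max(1, int(holdout_fraction * len(obs_idx)))
    held = obs_idx[rng.choice(len(obs_idx), size=n_hold, replace=False)]
    train_mask = bmask.copy()
    train_mask[tuple(held.T)] = False
    best_rank, best_err = None, np.inf
    for rank in rank_grid:
        cfg = CpConfig(rank=rank, seed=seed,
                       max_iters=config.max_iters if config else 200,
                       tol=config.tol if config else 1e-6)
        try:
            A, B, C, _ = cp_decompose_masked(T, train_mask.astype(float), rank, cfg)
        except DecompositionError:
            continue
        recon = cp_reconstruct(A, B, C)
        err = float(np.sqrt(np.mean((T - recon)[tuple(held.T)] ** 2)))
        if err < best_err:
            best_rank, best_err = rank, err
    if best_rank is None:
        raise DecompositionError("no rank in the grid could be fitted")
    return best_rank
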