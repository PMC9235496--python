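"""Synthetic data generators mirroring the structure of the real inputs.

The generators emulate, at desk scale, the statistical features the method
relies on: block-structured disease similarity (diseases fall into
clusters with a controlled within-cluster cosine), sparse known
associations (a handful of curated positives per disease), missing
(perturbed gene x cell line) tensor fibers, and a GWAS-like SNP catalog
with strong P values on true pairs over a uniform background.

Labels are drawn from the model itself: the true weight vector of disease
m is ``signal_strength`` times its cluster direction, features are standard
normal, and y ~ Bernoulli(sigma(w*^T x)).  The drawn positives are then
thinned to ``positives_per_disease`` known associations by keeping those
with the highest generative probability — emulating curation bias toward
the strongest responders.  Thinned-out drawn positives are deleted from
the learning set (marked unobserved), mirroring a curated gold standard
in which most true biology is simply unrecorded; drawn negatives remain
observed negatives.

All generators are deterministic given ``spec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (DiseaseSignature, ExpressionProfile, PerturbationMode,
                 AlignedDataset, write_profiles_tsv,
                 write_disease_signatures_tsv)
from .model import LabelMatrix
from .tensor import PerturbationTensor, cp_reconstruct

__all__ = ["SyntheticSpec", "DiseaseSimulation", "simulate_disease_signatures",
           "simulate_targets_and_labels", "simulate_masked_tensor",
           "simulate_snp_catalog", "simulate_inverse_recovery",
           "write_synthetic_dataset"]


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    N: int = 200                       # targets (perturbed genes)
    M: int = 12                        # diseases
    d: int = 50                        # genes in the common space
    n_clusters: int = 3                # disease clusters
    within_cluster_similarity: float = 0.8   # expected within-cluster cosine
    signal_strength: float = 3.0       # ||w*|| per disease
    positives_per_disease: int = 5     # curated associations kept per disease
    noise_sd: float = 0.1              # tensor observation noise
    missing_rate: float = 0.3          # tensor fiber missingness
    cp_rank: int = 3                   # planted CP rank
    seed: int = 0
    n_cell_lines: int = 2              # for the file-level dataset
    replicates_per_profile: int = 2    # replicate profiles per signature
    background_snp_rate: float = 0.1   # fraction of null pairs with a record

    def __post_init__(self) -> None:
        if not (0 < self.n_clusters <= self.M):
            raise ValueError("need 0 < n_clusters <= M")
        if self.positives_per_disease > self.N:
            raise ValueError("positives_per_disease exceeds N")
        if not (0.0 < self.within_cluster_similarity <= 1.0):
            raise ValueError("within_cluster_similarity must lie in (0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")

    def gene_names(self) -> list[str]:
        return [f"G{k:04d}" for k in range(self.d)]

    def target_names(self) -> list[str]:
        return [f"TG{i:04d}" for i in range(self.N)]

    def disease_names(self) -> list[str]:
        return [f"D{m:02d}" for m in range(self.M)]


@dataclass
class DiseaseSimulation:
    """Simulated disease signatures with their generating cluster structure."""

    signatures: list[DiseaseSignature]
    cluster_labels: np.ndarray          # (M,) cluster index per disease
    centers: np.ndarray                 # (n_clusters, d) unit cluster directions


def simulate_disease_signatures(spec: SyntheticSpec) -> DiseaseSimulation:
    """Clustered disease signatures with controlled within-cluster cosine.

    Each cluster has a random unit direction c; disease signatures are
    z = c + sigma * u with isotropic u (E||u||^2 = 1) and
    sigma^2 = (1 - rho) / rho, which makes the expected within-cluster
    cosine approximately rho = ``within_cluster_similarity``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.standard_normal((spec.n_clusters, spec.d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    cluster_labels = np.arange(spec.M) % spec.n_clusters
    rho = spec.within_cluster_similarity
    sigma = np.sqrt((1.0 - rho) / rho)
    genes = spec.gene_names()
    sigs = []
    for m, name in enumerate(spec.disease_names()):
        noise = rng.standard_normal(spec.d) / np.sqrt(spec.d)
        z = centers[cluster_labels[m]] + sigma * noise
        sigs.append(DiseaseSignature(disease_id=name,
                                     values=pd.Series(z, index=genes),
                                     n_patients_averaged=1))
    return DiseaseSimulation(signatures=sigs, cluster_labels=cluster_labels,
                             centers=centers)


def simulate_targets_and_labels(
    spec: SyntheticSpec, disease_sim: DiseaseSimulation,
) -> tuple[np.ndarray, LabelMatrix, np.ndarray]:
    """Features, curated labels, and the true weight matrix W*.

    w*_m = signal_strength x (unit cluster direction of disease m); rows of
    X are standard normal; y ~ Bernoulli(sigma(w*^T x)), thinned per
    disease to ``positives_per_disease`` curated positives.  Thinning is a
    point-process deletion with curation bias: the kept positives are the
    drawn positives with the highest generative probability (the strongest
    responders, as a curated gold standard favors), and the thinned-out
    drawn positives are removed from the learning set entirely — they are
    marked unobserved in ``labels.observed``, not relabelled negative.
    If a disease draws fewer positives than required the whole draw is
    regenerated with an incremented seed (up to 10 tries).
    """
    W_true = (spec.signal_strength
              * disease_sim.centers[disease_sim.cluster_labels].T)  # (d, M)
    for attempt in range(10):
        rng = np.random.default_rng(spec.seed + attempt)
        X = rng.standard_normal((spec.N, spec.d))
        P = expit(X @ W_true)
        drawn = (rng.random((spec.N, spec.M)) < P).astype(float)
        if np.all(drawn.sum(axis=0) >= spec.positives_per_disease):
            break
    else:
        raise RuntimeError("could not draw enough positives in 10 attempts")
    Y = np.zeros_like(drawn)
    observed = np.ones_like(drawn)
    for m in range(spec.M):
        pos = np.flatnonzero(drawn[:, m] > 0)
        keep = pos[np.argsort(-P[pos, m], kind="stable")[:spec.positives_per_disease]]
        Y[keep, m] = 1.0
        observed[np.setdiff1d(pos, keep), m] = 0.0
    labels = LabelMatrix(Y=Y, target_ids=spec.target_names(),
                         disease_ids=spec.disease_names(), observed=observed)
    return X, labels, W_true


def simulate_masked_tensor(
    spec: SyntheticSpec, shape: tuple[int, int, int] | None = None,
) -> tuple[PerturbationTensor, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Planted low-rank tensor with Gaussian noise and Bernoulli missingness."""
    rng = np.random.default_rng(spec.seed)
    shape = shape or (spec.N, spec.d, spec.n_cell_lines)
    A = rng.standard_normal((shape[0], spec.cp_rank))
    B = rng.standard_normal((shape[1], spec.cp_rank))
    C = rng.standard_normal((shape[2], spec.cp_rank))
    T = cp_reconstruct(A, B, C) + spec.noise_sd * rng.standard_normal(shape)
    mask = (rng.random(shape) >= spec.missing_rate).astype(float)
    tensor = PerturbationTensor(
        T=T, mask=mask,
        perturbed_genes=[f"TG{i:04d}" for i in range(shape[0])],
        measured_genes=[f"G{k:04d}" for k in range(shape[1])],
        cell_lines=[f"CELL_{c}" for c in range(shape[2])],
    )
    return tensor, (A, B, C)


def simulate_snp_catalog(spec: SyntheticSpec, labels: LabelMatrix) -> pd.DataFrame:
    """GWAS-like catalog: strong P on true pairs, uniform background elsewhere.

    True (target, disease) pairs get 1-3 records with P = 10^-U(3, 8);
    each null pair independently gets one record with probability
    ``background_snp_rate`` and P ~ U(0.05, 1).
    """
    rng = np.random.default_rng(spec.seed + 104729)
    rows = []
    snp = 0
    for i, gene in enumerate(labels.target_ids):
        for j, disease in enumerate(labels.disease_ids):
            if labels.Y[i, j] == 1.0:
                for _ in range(rng.integers(1, 4)):
                    rows.append((f"rs{snp:06d}", gene, disease,
                                 10.0 ** -rng.uniform(3, 8)))
                    snp += 1
            elif rng.random() < spec.background_snp_rate:
                rows.append((f"rs{snp:06d}", gene, disease, rng.uniform(0.05, 1.0)))
                snp += 1
    return pd.DataFrame(rows, columns=["snp_id", "gene", "disease_id", "p_value"])


def simulate_inverse_recovery(n_targets: int = 20, d: int = 50,
                              snr: float = 5.0, seed: int = 0
                              ) -> tuple[AlignedDataset, dict[str, str]]:
    """Construction for inverse-correlation recovery: disease = -target + noise.

    Each disease signature is the negation of one target's signature plus
    isotropic noise with per-gene standard deviation 1/snr (target entries
    are unit variance).  Returns the aligned dataset and the true
    disease -> target map.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{k:04d}" for k in range(d)]
    targets = [f"TG{i:04d}" for i in range(n_targets)]
    diseases = [f"D{i:02d}" for i in range(n_targets)]
    X = rng.standard_normal((n_targets, d))
    Z = -X + (1.0 / snr) * rng.standard_normal((n_targets, d))
    aligned = AlignedDataset(gene_list=genes, X=X, target_ids=targets,
                             Z=Z, disease_ids=diseases)
    return aligned, dict(zip(diseases, targets))


def write_synthetic_dataset(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Emit the full file-level dataset in the dialects the readers consume.

    Writes: perturbational profiles (long TSV, ``replicates_per_profile``
    noisy replicates per (target, cell line) whose mean is the target's
    signature row), disease signatures (TSV), gold-standard associations
    (TSV, knockdown -> inhibitory), a SNP catalog (TSV), and a truth JSON
    (spec, W*, cluster labels).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disease_sim = simulate_disease_signatures(spec)
    X, labels, W_true = simulate_targets_and_labels(spec, disease_sim)
    rng = np.random.default_rng(spec.seed + 7919)
    genes = spec.gene_names()
    profiles = []
    for i, target in enumerate(labels.target_ids):
        for c in range(spec.n_cell_lines):
            cell = f"CELL_{c}"
            reps = spec.replicates_per_profile
            noise = rng.standard_normal((reps, spec.d)) * spec.noise_sd
            noise -= noise.mean(axis=0, keepdims=True)  # replicate mean == signature
            for r in range(reps):
                profiles.append(ExpressionProfile(
                    profile_id=f"sig_{target}_{cell}_r{r}",
                    perturbed_gene=target, mode=PerturbationMode.KNOCKDOWN,
                    cell_line=cell, time_h=24.0 * (r + 1), dose=1.0,
                    values=dict(zip(genes, X[i] + noise[r])),
                ))
    paths = {
        "profiles": outdir / "perturbation_profiles.tsv",
        "diseases": outdir / "disease_signatures.tsv",
        "associations": outdir / "associations.tsv",
        "snp": outdir / "snp_catalog.tsv",
        "truth": outdir / "truth.json",
    }
    write_profiles_tsv(paths["profiles"], profiles)
    write_disease_signatures_tsv(paths["diseases"], disease_sim.signatures)
    assoc = [(t, d, "inhibitory")
             for i, t in enumerate(labels.target_ids)
             for j, d in enumerate(labels.disease_ids) if labels.Y[i, j] == 1.0]
    pd.DataFrame(assoc, columns=["target_gene", "disease_id", "mode"]).to_csv(
        paths["associations"], sep="\t", index=False)
    simulate_snp_catalog(spec, labels).to_csv(
        paths["snp"], sep="\t", index=False, float_format="%.10g")
    truth = {
        "spec": asdict(spec),
        "W_true": W_true.tolist(),
        "cluster_labels": disease_sim.cluster_labels.tolist(),
        "target_ids": labels.target_ids,
        "disease_ids": labels.disease_ids,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh)
    return paths
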