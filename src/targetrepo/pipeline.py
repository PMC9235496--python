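"""End-to-end orchestration: files in, score tables and CV reports out.

A run is described by a small YAML/JSON config (see :data:`CONFIG_KEYS`),
executes aggregate -> align -> (optional) tensor completion -> disease
graph -> score (inverse | trans_disease | snp) -> cross-validated
evaluation, and writes deterministic TSV outputs plus a JSON run log
(parameters, seed, input checksums).  Rerunning the same config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .graph import build_disease_graph
from .inverse import rank_inverse_candidates
from .model import LabelMatrix, TrainConfig, TransDiseaseLogistic
from .evaluation import cross_validate, roc_auc
from .snp import aggregate_pvalues, snp_scores
from .tensor import CpConfig, assemble_tensor, cp_decompose_masked, impute

__all__ = ["ConfigError", "load_config", "run_pipeline", "repositioning_summary"]

logger = logging.getLogger(__name__)

CONFIG_KEYS = {
    "profiles": str,        # long-format perturbational profile TSV
    "diseases": str,        # disease signature TSV
    "associations": str,    # gold-standard TSV
    "snp_catalog": str,     # optional SNP catalog TSV
    "mode": str,            # knockdown | overexpression
    "method": str,          # inverse | trans_disease | snp
    "complete_tensor": bool,
    "cp_rank": int,
    "lambda_s": float,
    "lambda_r": float,
    "cv_folds": int,
    "seed": int,
    "outdir": str,
}
_REQUIRED = ["profiles", "diseases", "associations", "method", "outdir"]
_MODE_TO_ASSOC = {"knockdown": "inhibitory", "overexpression": "activatory"}


class ConfigError(ValueError):
    """Raised on a config that violates the schema."""


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in cfg]
    if missing:
        raise ConfigError(f"{path}: missing required keys {missing}")
    cfg.setdefault("mode", "knockdown")
    cfg.setdefault("method", "trans_disease")
    cfg.setdefault("complete_tensor", False)
    cfg.setdefault("cp_rank", 3)
    cfg.setdefault("lambda_s", 0.1)
    cfg.setdefault("lambda_r", 0.1)
    cfg.setdefault("cv_folds", 5)
    cfg.setdefault("seed", 0)
    if cfg["method"] not in ("inverse", "trans_disease", "snp"):
        raise ConfigError(f"unknown method {cfg['method']!r}")
    if cfg["mode"] not in _MODE_TO_ASSOC:
        raise ConfigError(f"unknown mode {cfg['mode']!r}")
    if cfg["method"] == "snp" and "snp_catalog" not in cfg:
        raise ConfigError("method 'snp' requires a snp_catalog path")
    base = Path(path).parent
    for key in ("profiles", "diseases", "associations", "snp_catalog"):
        if key in cfg:
            p = Path(cfg[key])
            cfg[key] = str(p if p.is_absolute() else base / p)
            if not Path(cfg[key]).exists():
                raise ConfigError(f"{key} file not found: {cfg[key]}")
    return cfg


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config_path) -> Path:
    """Execute the configured run; returns the artifact directory."""
    cfg = load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    assoc_mode = _MODE_TO_ASSOC[cfg["mode"]]

    profiles = tio.read_profiles_tsv(cfg["profiles"])
    signatures = tio.aggregate_perturbation_profiles(profiles, cfg["mode"])
    if not signatures:
        raise ConfigError(f"no profiles of mode {cfg['mode']!r} in input")
    disease_sigs = tio.read_disease_signatures_tsv(cfg["diseases"])
    associations = tio.read_associations_tsv(cfg["associations"])

    cell_lines = sorted({s.cell_line for s in signatures})
    if cfg["complete_tensor"]:
        measured = sorted(signatures[0].values.index)
        tensor = assemble_tensor(signatures, measured, cell_lines)
        factors = cp_decompose_masked(
            tensor.T, tensor.mask, cfg["cp_rank"],
            CpConfig(rank=cfg["cp_rank"], seed=cfg["seed"]))[:3]
        completed = impute(tensor.T, tensor.mask, factors)
        signatures = [
            tio.PerturbationSignature(
                perturbed_gene=g, mode=cfg["mode"], cell_line=c,
                values=pd.Series(completed[i, :, k], index=measured))
            for i, g in enumerate(tensor.perturbed_genes)
            for k, c in enumerate(tensor.cell_lines)
        ]
        tensor.missing_rate_per_cell_line().to_frame().to_csv(
            outdir / "missing_rates.tsv", sep="\t", float_format="%.10g")

    graph = build_disease_graph(disease_sigs)
    graph.to_frame("S").to_csv(outdir / "disease_similarity.tsv", sep="\t",
                               float_format="%.10g")
    graph.to_frame("Ls").to_csv(outdir / "disease_laplacian.tsv", sep="\t",
                                float_format="%.10g")

    score_tables, cv_rows = [], []
    for cell in cell_lines:
        cell_sigs = [s for s in signatures if s.cell_line == cell]
        if not cell_sigs:
            continue
        aligned = tio.align_common_genes(cell_sigs, disease_sigs)
        labels = LabelMatrix.from_associations(
            associations, aligned.target_ids, aligned.disease_ids, assoc_mode)
        if cfg["method"] == "inverse":
            table = rank_inverse_candidates(aligned, cfg["mode"], cell)
            tix = {t: i for i, t in enumerate(aligned.target_ids)}
            dix = {d: j for j, d in enumerate(aligned.disease_ids)}
            y = np.array([labels.Y[tix[t], dix[d]] for t, d in
                          zip(table["target_gene"], table["disease_id"])])
            auc = roc_auc(table["score"].to_numpy(), y).auc if 0 < y.sum() < len(y) else np.nan
            cv_rows.append((cell, cfg["method"], "all", auc))
        elif cfg["method"] == "trans_disease":
            tc = TrainConfig(lambda_s=cfg["lambda_s"], lambda_r=cfg["lambda_r"],
                             seed=cfg["seed"])
            report = cross_validate(aligned.X, labels, graph, tc,
                                    k=cfg["cv_folds"], seed=cfg["seed"])
            for f, auc in enumerate(report.fold_aucs):
                cv_rows.append((cell, cfg["method"], f"fold_{f}", auc))
            cv_rows.append((cell, cfg["method"], "mean", report.mean_auc))
            res = TransDiseaseLogistic(aligned.X, labels, graph,
                                       gene_list=aligned.gene_list).fit(tc)
            table = res.predict_frame(aligned.X, aligned.target_ids)
            table.insert(0, "cell_line", cell)
            res.save(outdir / f"weights_{cell}.tsv",
                     outdir / f"weights_{cell}.json")
        else:  # snp
            catalog = pd.read_csv(cfg["snp_catalog"], sep="\t")
            profiles_by_disease = snp_scores(aggregate_pvalues(catalog),
                                             aligned.target_ids)
            rows = []
            for dis in aligned.disease_ids:
                prof = profiles_by_disease.get(dis)
                for t in aligned.target_ids:
                    score = float(prof.scores[t]) if prof is not None else 0.0
                    rows.append((cell, t, dis, score))
            table = pd.DataFrame(rows, columns=["cell_line", "target_gene",
                                                "disease_id", "score"])
            y = np.array([labels.Y[aligned.target_ids.index(t),
                                   aligned.disease_ids.index(d)]
                          for t, d in zip(table["target_gene"], table["disease_id"])])
            auc = roc_auc(table["score"].to_numpy(), y).auc if 0 < y.sum() < len(y) else np.nan
            cv_rows.append((cell, cfg["method"], "all", auc))
        score_tables.append(table)

    _write_tsv(pd.concat(score_tables, ignore_index=True), outdir / "scores.tsv")
    _write_tsv(pd.DataFrame(cv_rows, columns=["cell_line", "method", "fold", "auc"]),
               outdir / "cv_report.tsv")
    log = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "input_checksums": {k: _checksum(cfg[k]) for k in
                            ("profiles", "diseases", "associations", "snp_catalog")
                            if k in cfg},
        "cell_lines": cell_lines,
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return outdir


def repositioning_summary(known: pd.DataFrame, predicted: pd.DataFrame,
                          class_map: dict[str, str], top_k: int | None = 20,
                          threshold: float | None = None) -> pd.DataFrame:
    """Class-to-class counts of predicted new indications for known targets.

    ``known``: (target_gene, disease_id) associations; ``predicted``:
    (target_gene, disease_id, score).  A prediction counts when its target
    has at least one known association, the pair itself is not known, and
    it survives the cut (top_k per disease by score, or score >= threshold).
    Each counted prediction adds one to cell (class of the target's first
    known disease in sorted order, class of the new disease); the diagonal
    is within-class repositioning.
    """
    for df, cols in ((known, ("target_gene", "disease_id")),
                     (predicted, ("target_gene", "disease_id", "score"))):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
    unmapped = (set(known["disease_id"]) | set(predicted["disease_id"])) - set(class_map)
    if unmapped:
        raise ValueError(f"diseases without a class: {sorted(unmapped)}")
    if threshold is not None:
        kept = predicted[predicted["score"] >= threshold]
    else:
        kept = (predicted.sort_values(["score", "target_gene"],
                                      ascending=[False, True], kind="mergesort")
                .groupby("disease_id", group_keys=False).head(top_k or 20))
    known_pairs = set(zip(known["target_gene"], known["disease_id"]))
    known_by_target: dict[str, list[str]] = {}
    for t, dis in sorted(known_pairs):
        known_by_target.setdefault(t, []).append(dis)
    classes = sorted(set(class_map.values()))
    counts = pd.DataFrame(0, index=classes, columns=classes)
    for t, dis in zip(kept["target_gene"], kept["disease_id"]):
        if t not in known_by_target or (t, dis) in known_pairs:
            continue
        from_class = class_map[known_by_target[t][0]]
        counts.loc[from_class, class_map[dis]] += 1
    return counts
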