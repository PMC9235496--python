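"""GWAS-catalog style SNP baseline for target prioritization.

Each (gene, disease) pair's association P values — over all SNPs in the
gene and all studies reporting it — are averaged; the predictive score is
-log10(mean P), and genes with no SNP record for a disease score 0.  The
score says nothing about direction of effect, so the same SNP profile is
used for both inhibitory and activatory evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SnpProfile", "SnpValidationError", "aggregate_pvalues", "snp_scores"]


class SnpValidationError(ValueError):
    """Raised on P values outside (0, 1]."""


@dataclass
class SnpProfile:
    """Per-disease gene scores: -log10 of the mean association P value."""

    disease_id: str
    scores: pd.Series   # index: gene, value: -log10(mean P), 0 when uncovered
    mean_p: pd.Series   # covered genes only, values in (0, 1]


def aggregate_pvalues(records: pd.DataFrame) -> pd.DataFrame:
    """Mean P value per (gene, disease_id) pair.

    ``records`` needs columns gene, disease_id, p_value; P values must lie
    in (0, 1] (a zero P is rejected, not mapped to an infinite score).
    """
    required = {"gene", "disease_id", "p_value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    p = records["p_value"].astype(float)
    bad = (p <= 0) | (p > 1) | ~np.isfinite(p)
    if bad.any():
        rows = records.index[bad].tolist()[:5]
        raise SnpValidationError(f"P values outside (0, 1] at row(s) {rows}")
    out = (records.assign(p_value=p)
           .groupby(["gene", "disease_id"], as_index=False)["p_value"].mean()
           .rename(columns={"p_value": "mean_p"}))
    return out


def snp_scores(aggregated: pd.DataFrame, gene_universe) -> dict[str, SnpProfile]:
    """Per-disease SNP profiles over ``gene_universe``; uncovered genes score 0."""
    genes = list(gene_universe)
    profiles: dict[str, SnpProfile] = {}
    for disease_id, grp in aggregated.groupby("disease_id", sort=True):
        mean_p = pd.Series(grp["mean_p"].to_numpy(), index=grp["gene"].to_numpy())
        scores = pd.Series(0.0, index=genes)
        covered = [g for g in mean_p.index if g in scores.index]
        scores[covered] = -np.log10(mean_p[covered].astype(float))
        profiles[str(disease_id)] = SnpProfile(
            disease_id=str(disease_id), scores=scores, mean_p=mean_p)
    return profiles
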