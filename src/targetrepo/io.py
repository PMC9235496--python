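"""Reading, writing and aggregation of expression signatures.

Perturbational profiles (one experiment each: a gene knocked down or
overexpressed in one cell line at one time/dose) are collapsed into one
signature per (perturbed gene, cell line) by averaging over replicates,
time points and doses in a single pooled mean.  Patient differential
expression profiles are averaged per disease into disease signatures.
Both sides are then restricted to their common gene space for scoring.

File formats: GCT 1.2 text matrices, and tab-delimited long tables
(see :data:`PROFILE_COLUMNS` and friends).  All text I/O is UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationMode",
    "ExpressionProfile",
    "PerturbationSignature",
    "DiseaseSignature",
    "AlignedDataset",
    "GctParseError",
    "AlignmentError",
    "read_gct",
    "write_gct",
    "aggregate_perturbation_profiles",
    "build_disease_signatures",
    "align_common_genes",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "read_disease_signatures_tsv",
    "write_disease_signatures_tsv",
    "read_associations_tsv",
]

#: column order of the long-format perturbational profile table
PROFILE_COLUMNS = [
    "profile_id", "perturbed_gene", "mode", "cell_line",
    "time_h", "dose", "gene", "value",
]
#: column order of the disease signature table
DISEASE_COLUMNS = ["disease_id", "gene", "value"]
#: column order of the gold-standard association table
ASSOCIATION_COLUMNS = ["target_gene", "disease_id", "mode"]


class PerturbationMode(str, Enum):
    """Kind of profile: genetic perturbation or patient tissue."""

    KNOCKDOWN = "knockdown"
    OVEREXPRESSION = "overexpression"
    PATIENT = "patient"


class GctParseError(ValueError):
    """Raised when a GCT file violates the 1.2 text layout."""


class AlignmentError(ValueError):
    """Raised when gene universes cannot be reconciled."""


@dataclass
class ExpressionProfile:
    """A single expression-change profile versus its plate/tissue control.

    ``values`` maps gene symbol to the expression change (unitless,
    perturbed minus control).  ``disease_id`` is set only for patient
    profiles.
    """

    profile_id: str
    perturbed_gene: str
    mode: PerturbationMode
    cell_line: str
    values: Mapping[str, float]
    time_h: float | None = None
    dose: float | None = None
    disease_id: str | None = None

    def __post_init__(self) -> None:
        self.mode = PerturbationMode(self.mode)
        if not self.values:
            raise ValueError(f"profile {self.profile_id!r}: empty values")


@dataclass
class PerturbationSignature:
    """Averaged expression-change vector for one perturbed gene in one cell line."""

    perturbed_gene: str
    mode: PerturbationMode
    cell_line: str
    values: pd.Series  # index: gene symbols

    def __post_init__(self) -> None:
        self.mode = PerturbationMode(self.mode)
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"signature ({self.perturbed_gene}, {self.cell_line}): non-finite entries"
            )


@dataclass
class DiseaseSignature:
    """Per-disease differential-expression vector, averaged over patients."""

    disease_id: str
    values: pd.Series  # index: gene symbols
    n_patients_averaged: int = 1

    def __post_init__(self) -> None:
        if self.n_patients_averaged < 1:
            raise ValueError("n_patients_averaged must be positive")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"disease signature {self.disease_id}: non-finite entries")


@dataclass
class AlignedDataset:
    """Perturbation and disease signatures restricted to a common gene list.

    ``X`` is N targets x d genes, ``Z`` is M diseases x d genes; columns of
    both are indexed by ``gene_list`` in identical order.
    """

    gene_list: list[str]
    X: np.ndarray
    target_ids: list[str]
    Z: np.ndarray
    disease_ids: list[str]

    def __post_init__(self) -> None:
        d = len(self.gene_list)
        if self.X.shape != (len(self.target_ids), d):
            raise ValueError("X shape inconsistent with target_ids / gene_list")
        if self.Z.shape != (len(self.disease_ids), d):
            raise ValueError("Z shape inconsistent with disease_ids / gene_list")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")

    @property
    def d(self) -> int:
        """Number of common genes."""
        return len(self.gene_list)


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def read_gct(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCT 1.2 text file.

    Returns ``(matrix, descriptions)`` where ``matrix`` is a DataFrame
    (rows: NAME ids, columns: sample ids) and ``descriptions`` is the
    per-row Description column.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise GctParseError(f"{path}: line 1: expected version line '#1.2'")
    try:
        nrow_s, ncol_s = lines[1].split("\t")[:2]
        nrow, ncol = int(nrow_s), int(ncol_s)
    except (IndexError, ValueError) as exc:
        raise GctParseError(f"{path}: line 2: malformed dimensions line") from exc
    header = lines[2].split("\t")
    if len(header) != ncol + 2 or header[0].upper() != "NAME":
        raise GctParseError(
            f"{path}: line 3: expected NAME, Description and {ncol} sample columns"
        )
    body = [ln for ln in lines[3:] if ln != ""]
    if len(body) != nrow:
        raise GctParseError(
            f"{path}: line {3 + len(body) + 1}: dims declare {nrow} rows, body has {len(body)}"
        )
    ids, descs, rows = [], [], []
    for k, ln in enumerate(body):
        fields = ln.split("\t")
        lineno = k + 4
        if len(fields) != ncol + 2:
            raise GctParseError(
                f"{path}: line {lineno}: expected {ncol + 2} fields, got {len(fields)}"
            )
        ids.append(fields[0])
        descs.append(fields[1])
        try:
            rows.append([float(v) for v in fields[2:]])
        except ValueError as exc:
            raise GctParseError(f"{path}: line {lineno}: non-numeric cell") from exc
    matrix = pd.DataFrame(np.array(rows, dtype=float).reshape(nrow, ncol),
                          index=ids, columns=header[2:])
    return matrix, pd.Series(descs, index=ids, name="Description")


def write_gct(path, matrix: pd.DataFrame, descriptions: Sequence[str] | None = None) -> None:
    """Write a DataFrame as a GCT 1.2 text file (round-trips with :func:`read_gct`)."""
    nrow, ncol = matrix.shape
    if descriptions is None:
        descriptions = ["na"] * nrow
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{nrow}\t{ncol}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for rid, desc, row in zip(matrix.index, descriptions, matrix.to_numpy()):
            fh.write(str(rid) + "\t" + str(desc) + "\t"
                     + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _check_universe(profiles: Sequence[ExpressionProfile]) -> list[str]:
    universe = sorted(profiles[0].values.keys())
    for p in profiles[1:]:
        if sorted(p.values.keys()) != universe:
            raise AlignmentError(
                f"profile {p.profile_id!r} gene universe differs from {profiles[0].profile_id!r}"
            )
    return universe


def aggregate_perturbation_profiles(
    profiles: Iterable[ExpressionProfile],
    mode: PerturbationMode | str,
) -> list[PerturbationSignature]:
    """Collapse profiles of one perturbation mode into per-(gene, cell line) signatures.

    Every profile matching ``mode`` contributes with equal weight: the
    signature is a single pooled arithmetic mean over replicates, time
    points and doses.  Profiles of other modes are ignored.
    """
    mode = PerturbationMode(mode)
    selected = [p for p in profiles if p.mode == mode]
    if not selected:
        return []
    universe = _check_universe(selected)
    groups: dict[tuple[str, str], list[ExpressionProfile]] = {}
    for p in selected:
        groups.setdefault((p.perturbed_gene, p.cell_line), []).append(p)
    out = []
    for (gene, cell), members in sorted(groups.items()):
        stack = np.array([[m.values[g] for g in universe] for m in members], dtype=float)
        out.append(PerturbationSignature(
            perturbed_gene=gene, mode=mode, cell_line=cell,
            values=pd.Series(stack.mean(axis=0), index=universe),
        ))
    return out


def build_disease_signatures(
    patient_profiles: Iterable[ExpressionProfile],
) -> list[DiseaseSignature]:
    """Average patient-specific profiles into one signature per disease."""
    selected = [p for p in patient_profiles if p.mode == PerturbationMode.PATIENT]
    if not selected:
        return []
    for p in selected:
        if p.disease_id is None:
            raise ValueError(f"patient profile {p.profile_id!r} lacks a disease_id")
    universe = _check_universe(selected)
    groups: dict[str, list[ExpressionProfile]] = {}
    for p in selected:
        groups.setdefault(p.disease_id, []).append(p)
    out = []
    for disease_id, members in sorted(groups.items()):
        stack = np.array([[m.values[g] for g in universe] for m in members], dtype=float)
        out.append(DiseaseSignature(
            disease_id=disease_id,
            values=pd.Series(stack.mean(axis=0), index=universe),
            n_patients_averaged=len(members),
        ))
    return out


def align_common_genes(
    perturbation_sigs: Sequence[PerturbationSignature],
    disease_sigs: Sequence[DiseaseSignature],
) -> AlignedDataset:
    """Restrict both signature collections to their common genes.

    The common gene list is the sorted exact-match intersection of the two
    gene universes; no alias or ortholog resolution is attempted.
    """
    if not perturbation_sigs or not disease_sigs:
        raise AlignmentError("both signature collections must be non-empty")
    pert_genes = set(perturbation_sigs[0].values.index)
    for s in perturbation_sigs[1:]:
        pert_genes &= set(s.values.index)
    dis_genes = set(disease_sigs[0].values.index)
    for s in disease_sigs[1:]:
        dis_genes &= set(s.values.index)
    common = sorted(pert_genes & dis_genes)
    if not common:
        raise AlignmentError("perturbation and disease gene universes are disjoint")
    target_ids = [s.perturbed_gene for s in perturbation_sigs]
    disease_ids = [s.disease_id for s in disease_sigs]
    X = np.array([s.values.reindex(common).to_numpy(dtype=float) for s in perturbation_sigs])
    Z = np.array([s.values.reindex(common).to_numpy(dtype=float) for s in disease_sigs])
    return AlignedDataset(gene_list=common, X=X, target_ids=target_ids,
                          Z=Z, disease_ids=disease_ids)


# ---------------------------------------------------------------------------
# Long-format TSV
# ---------------------------------------------------------------------------

def write_profiles_tsv(path, profiles: Iterable[ExpressionProfile]) -> None:
    rows = []
    for p in profiles:
        for gene in sorted(p.values):
            rows.append((p.profile_id, p.perturbed_gene, p.mode.value, p.cell_line,
                         p.time_h, p.dose, gene, p.values[gene],
                         p.disease_id if p.disease_id is not None else ""))
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS + ["disease_id"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profiles_tsv(path) -> list[ExpressionProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"profile_id": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (pid,), grp in df.groupby(["profile_id"], sort=True):
        first = grp.iloc[0]
        disease = first.get("disease_id")
        if isinstance(disease, float) and np.isnan(disease):
            disease = None
        out.append(ExpressionProfile(
            profile_id=pid,
            perturbed_gene=str(first["perturbed_gene"]),
            mode=PerturbationMode(first["mode"]),
            cell_line=str(first["cell_line"]),
            time_h=None if pd.isna(first["time_h"]) else float(first["time_h"]),
            dose=None if pd.isna(first["dose"]) else float(first["dose"]),
            disease_id=None if disease in (None, "") else str(disease),
            values=dict(zip(grp["gene"].astype(str), grp["value"].astype(float))),
        ))
    return out


def write_disease_signatures_tsv(path, sigs: Iterable[DiseaseSignature]) -> None:
    rows = []
    for s in sigs:
        for gene, value in s.values.items():
            rows.append((s.disease_id, gene, value, s.n_patients_averaged))
    df = pd.DataFrame(rows, columns=DISEASE_COLUMNS + ["n_patients_averaged"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_disease_signatures_tsv(path) -> list[DiseaseSignature]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DISEASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for disease_id, grp in df.groupby("disease_id", sort=True):
        n = int(grp["n_patients_averaged"].iloc[0]) if "n_patients_averaged" in grp else 1
        out.append(DiseaseSignature(
            disease_id=str(disease_id),
            values=pd.Series(grp["value"].astype(float).to_numpy(),
                             index=grp["gene"].astype(str).to_numpy()),
            n_patients_averaged=n,
        ))
    return out


def read_associations_tsv(path) -> pd.DataFrame:
    """Read the gold-standard association table (target_gene, disease_id, mode)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = set(df["mode"]) - {"inhibitory", "activatory"}
    if bad:
        raise ValueError(f"{path}: unknown association modes {sorted(bad)}")
    return df[ASSOCIATION_COLUMNS]
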