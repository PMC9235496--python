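import numpy as np
import pandas as pd
import pytest

from targetrepo.io import (AlignedDataset, DiseaseSignature, ExpressionProfile,
                           PerturbationMode, PerturbationSignature)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(pid, gene, mode, cell, values, disease=None, time_h=24.0, dose=1.0):
    return ExpressionProfile(profile_id=pid, perturbed_gene=gene, mode=mode,
                             cell_line=cell, values=values, disease_id=disease,
                             time_h=time_h, dose=dose)


@pytest.fixture
def knockdown_profiles():
    """Two replicates for (GENE1, CELL_A), one for GENE2, one in CELL_B."""
    return [
        make_profile("p1", "GENE1", "knockdown", "CELL_A", {"g1": 1.0, "g2": 3.0}),
        make_profile("p2", "GENE1", "knockdown", "CELL_A", {"g1": 3.0, "g2": 5.0}),
        make_profile("p3", "GENE2", "knockdown", "CELL_A", {"g1": -1.0, "g2": 0.5}),
        make_profile("p4", "GENE1", "knockdown", "CELL_B", {"g1": 7.0, "g2": 9.0}),
        make_profile("p5", "GENE9", "overexpression", "CELL_A", {"g1": 2.0, "g2": 2.0}),
    ]


@pytest.fixture
def small_aligned(rng):
    """A tiny aligned dataset with 4 targets, 3 diseases, 6 genes."""
    genes = [f"g{k}" for k in range(6)]
    X = rng.standard_normal((4, 6))
    Z = rng.standard_normal((3, 6))
    return AlignedDataset(gene_list=genes, X=X, target_ids=list("ABCD"),
                          Z=Z, disease_ids=["d1", "d2", "d3"])


@pytest.fixture
def disease_sigs():
    genes = ["g1", "g2", "g3"]
    vec = lambda v: pd.Series(v, index=genes)
    return [
        DiseaseSignature("d1", vec([1.0, 0.0, 0.0])),
        DiseaseSignature("d2", vec([1.0, 1.0, 0.0])),
        DiseaseSignature("d3", vec([0.0, 0.0, 2.0])),
    ]
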