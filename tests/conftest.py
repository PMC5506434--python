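import numpy as np
import pandas as pd
import pytest

from crmarkers.io_formats import ExpressionStudy, GeneSetCollection


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """3 genes x 4 samples, two strains x two groups, 2 samples each would be
    too few for per-strain tests — this fixture is for IO/contract checks."""
    values = pd.DataFrame(
        [[8.0, 8.5, 9.0, 9.5], [5.0, 5.1, 4.9, 5.2], [10.0, 10.2, 9.8, 10.1]],
        index=pd.Index(["GeneA", "GeneB", "GeneC"], name="gene"),
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "strain": ["C57BL/6J"] * 4,
            "tissue": ["heart"] * 4,
            "group": ["control", "control", "CR", "CR"],
            "replicate": [1, 2, 1, 2],
        }
    ).set_index("sample_id")
    return ExpressionStudy(values, meta)


def make_study(values: np.ndarray, strains, groups, tissue="WAT") -> ExpressionStudy:
    """Build a study from a (genes x samples) array and per-sample labels."""
    n_genes, n_samples = values.shape
    genes = [f"G{i}" for i in range(n_genes)]
    sids = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": sids,
            "strain": strains,
            "tissue": tissue,
            "group": groups,
            "replicate": list(range(1, n_samples + 1)),
        }
    ).set_index("sample_id")
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sids)
    return ExpressionStudy(vals, meta)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        {
            "GO:A": ("set A", ("g1", "g2", "g3", "g4")),
            "GO:B": ("set B", ("g3", "g4", "g5", "g6")),
            "GO:C": ("set C", ("g7", "g8")),
        }
    )
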