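import numpy as np
import pandas as pd
import pytest

from concordia.datamodel import (
    PROTEIN,
    TRANSCRIPT,
    CohortDesign,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)


@pytest.fixture
def design10():
    """5 case + 5 control samples."""
    return CohortDesign({f"case_{i}": "case" for i in range(1, 6)}
                        | {f"ctrl_{i}": "control" for i in range(1, 6)})


@pytest.fixture
def protein_matrix(design10):
    """6 proteins x 10 samples with planted missingness."""
    rng = np.random.default_rng(7)
    vals = np.exp(rng.normal(20, 1, size=(6, 10)))
    vals[0, :3] = np.nan            # partially missing in cases
    vals[1, 5:] = np.nan            # absent in all controls
    df = pd.DataFrame(vals, index=[f"P{i}" for i in range(6)],
                      columns=list(design10.assignments))
    return ExpressionMatrix(ome=PROTEIN, values=df)


@pytest.fixture
def transcript_matrix(design10):
    rng = np.random.default_rng(11)
    counts = rng.poisson(50, size=(8, 10)).astype(float)
    counts[0, 5:] = 0               # undetected in controls
    df = pd.DataFrame(counts, index=[f"G{i}" for i in range(8)],
                      columns=list(design10.assignments))
    return ExpressionMatrix(
        ome=TRANSCRIPT, values=df,
        feature_length_bp=pd.Series(2000.0, index=df.index))


@pytest.fixture
def gene_sets():
    return GeneSetCollection([
        GeneSet("setA", "functional_group", frozenset({"G0", "G1", "G2"})),
        GeneSet("setB", "cellular_component", frozenset({"G3", "G4"})),
    ])
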