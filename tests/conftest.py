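import hypothesis
import numpy as np
import pandas as pd
import pytest

from nsburden import GenotypeMatrix, Variant, VariantPanel

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def tiny_panel() -> VariantPanel:
    return VariantPanel(
        [
            Variant("rs1", "GENE1", "A", "G"),
            Variant("rs2", "GENE2", "C", "T"),
            Variant("rs3", "GENE3", "G", "T"),
        ]
    )


def make_matrix(panel, dosages, phenotypes, samples=None):
    """Build a GenotypeMatrix from a list of per-individual dosage rows
    (None encodes a missing call)."""
    samples = samples or [f"S{i:03d}" for i in range(len(dosages))]
    df = pd.DataFrame(
        [[np.nan if d is None else float(d) for d in row] for row in dosages],
        index=samples,
        columns=panel.rsids,
    )
    pheno = pd.Series(list(phenotypes), index=samples, name="phenotype")
    return GenotypeMatrix(df, pheno, panel)


@pytest.fixture
def matrix_factory():
    return make_matrix
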