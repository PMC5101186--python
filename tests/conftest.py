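import numpy as np
import pandas as pd
import pytest

from chromabench.io_formats import (
    AnnotationCatalog,
    ProteinQuantTable,
    SampleDescriptor,
)


def make_quant_table(intensities: dict[str, list[float]], ids: list[str],
                     roles: list[str] | None = None) -> ProteinQuantTable:
    """Small quant table from a {sample_label: column} dict."""
    labels = list(intensities)
    if roles is None:
        roles = ["bait" if lab.startswith("pull") else "control" for lab in labels]
    reps: dict[str, int] = {}
    samples = []
    for lab, role in zip(labels, roles):
        reps[role] = reps.get(role, 0) + 1
        samples.append(SampleDescriptor(label=lab, replicate=reps[role], role=role))
    index = pd.Index(ids, name="protein_id")
    inten = pd.DataFrame(intensities, index=index, dtype=float)
    pep = (inten > 0).astype(np.int64)
    return ProteinQuantTable(intensity=inten, peptide_count=pep, samples=samples)


@pytest.fixture
def two_protein_table():
    return make_quant_table(
        {"pull_r1": [10.0, 4.0], "pull_r2": [10.0, 4.0],
         "noAB_r1": [4.0, 4.0], "noAB_r2": [4.0, 4.0]},
        ids=["A", "B"],
    )


@pytest.fixture
def small_catalog():
    return AnnotationCatalog(
        classes={
            "bait": {"BAIT"},
            "histone": {"H3", "H4"},
            "known_interactor": {"KI1", "KI2"},
            "chromatin_dna_binder": {"CB1"},
            "ribosomal": {"RB1"},
            "ribonucleoprotein": {"RNP1"},
            "cytoplasmic_other": {"CY1"},
            "affinity_reagent": {"IGG"},
        }
    )
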