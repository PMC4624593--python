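import numpy as np
import pandas as pd
import pytest

import clinomics as cg


@pytest.fixture
def stage_table() -> cg.ClinicalTable:
    """Six samples with clinical stage, sex, and a molecular subtype."""
    data = pd.DataFrame(
        {
            "ClinicalStage": ["I", "II", "III", "IV", "II", np.nan],
            "Gender": ["female", "male", "male", "female", "male", "female"],
            "MolecularSubtype": ["CIN", "EBV", "CIN", "GS", "MSI", "EBV"],
        },
        index=[f"S{i}" for i in range(6)],
    )
    metadata = {
        "ClinicalStage": cg.ParameterMeta("ordinal", ["I", "II", "III", "IV"]),
        "Gender": cg.ParameterMeta("binary", ["female", "male"]),
        "MolecularSubtype": cg.ParameterMeta("categorical", ["CIN", "GS", "MSI", "EBV"]),
    }
    return cg.ClinicalTable(data=data, metadata=metadata, source="tcga")


@pytest.fixture
def small_cohort() -> cg.SyntheticCohort:
    """Three-platform cohort with four planted effects; no degradation."""
    config = cg.CohortConfig(
        n_samples=120,
        platforms=[
            cg.PlatformSpec("RNASEQ", 30),
            cg.PlatformSpec("CNV", 20),
            cg.PlatformSpec("MUT", 10),
        ],
        n_planted=4,
        effect_sizes=[1.5, -1.5, 1.5, 1.5],
        noise_sd=1.0,
        clinical_params=[
            cg.ClinicalParamSpec("ClinicalStage", "ordinal", ["I", "II", "III", "IV"]),
            cg.ClinicalParamSpec("MStatus", "binary", ["M0", "M1"]),
        ],
        seed=7,
    )
    return cg.generate_cohort(config)


@pytest.fixture
def small_integrated(small_cohort):
    """Integrated matrix + stage outcome for the small cohort."""
    targets = cg.TargetList.from_sources(
        {"COSMIC": [str(f) for m in small_cohort.platforms for f in m.features]}
    )
    X, _ = cg.preprocess_group(list(small_cohort.platforms), "gene", targets)
    y = cg.encode_outcome(small_cohort.clinical_sources[0], "ClinicalStage")
    return X, y
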