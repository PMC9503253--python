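import pandas as pd
import pytest
from hypothesis import settings

from cernanet import CohortConfig, generate_cohort, run_stages
from cernanet.network import CeRNATriple

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# Hub ceRNA subnetwork reported for a plasma hypertrophic-cardiomyopathy
# cohort: two lncRNAs sponging three miRNAs which target twelve mRNAs.
REFERENCE_SUBNETWORK = [
    ("LINC00310", "hsa-miR-146b-5p", "SRF"),
    ("LINC00310", "hsa-miR-103a-3p", "RIPPLY1"),
    ("LINC00310", "hsa-miR-103a-3p", "KCNJ8"),
    ("LINC00310", "hsa-miR-103a-3p", "RAB41"),
    ("LINC00310", "hsa-miR-103a-3p", "AC005606.1"),
    ("LINC00310", "hsa-miR-103a-3p", "CCBE1"),
    ("RP11-66N24.4", "hsa-miR-146b-5p", "SRF"),
    ("RP11-66N24.4", "hsa-miR-122-5p", "NUDT19"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "SLC19A1"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "MTHFD2L"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "AC005606.1"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "KCNJ8"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "TUB"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "ADGRL3"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "CCBE1"),
    ("RP11-66N24.4", "hsa-miR-103a-3p", "DUSP16"),
]


@pytest.fixture(scope="session")
def reference_triples():
    return [CeRNATriple(l, m, g) for l, m, g in REFERENCE_SUBNETWORK]


@pytest.fixture(scope="session")
def recovery_cohort():
    """Strong-effect, low-noise cohort used for end-to-end recovery."""
    cfg = CohortConfig(
        n_motifs=5, effect_log2fc=3.0, intensity_sigma=0.2, n_pairs=10, seed=1
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_results(recovery_cohort):
    co = recovery_cohort
    return run_stages(
        co.lncrna, co.mrna, co.mirna, co.samples, [co.lnc_mir_db], [co.mir_mrna_db]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized cohort for cheap structural tests."""
    return generate_cohort(CohortConfig(seed=3))


@pytest.fixture
def toy_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["case_P01", "ctrl_P01", "case_P02", "ctrl_P02",
                          "case_P03", "ctrl_P03"],
            "group": ["case", "control"] * 3,
            "pair_id": ["P01", "P01", "P02", "P02", "P03", "P03"],
        }
    )
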