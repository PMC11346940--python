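import pandas as pd
import pytest

from adcscout.cascade import CascadeConfig, run_cascade
from adcscout.combos import DEFAULT_PAYLOADS
from adcscout.payloads import run_payload_pipeline
from adcscout.synthetic import generate_gi50_inputs, generate_target_inputs


@pytest.fixture(scope="session")
def target_bundle():
    """Default-scale synthetic target-arm bundle (500 genes, seed 7)."""
    return generate_target_inputs(500, seed=7)


@pytest.fixture(scope="session")
def cascade_result(target_bundle):
    b = target_bundle
    return run_cascade(
        b.annotations,
        b.normal_ihc,
        b.pathology,
        b.tumor,
        b.normal_mrna,
        b.hema,
        CascadeConfig(hsc_mpp_samples=b.hsc_mpp_samples),
    )


@pytest.fixture(scope="session")
def gi50_bundle():
    """Default-scale synthetic GI50 bundle with the planted 33/631/65 groups."""
    return generate_gi50_inputs(seed=7, payload_names=DEFAULT_PAYLOADS)


@pytest.fixture(scope="session")
def payload_result(gi50_bundle):
    return run_payload_pipeline(gi50_bundle.measurements)


@pytest.fixture
def annotations_frame():
    return pd.DataFrame(
        {
            "gene": ["A", "B", "C", "D"],
            "is_membrane": [True, True, False, True],
            "has_protein_evidence": [True, False, True, True],
            "is_surfaceome": [True, True, True, False],
            "literature": [True, False, False, False],
            "antibody": [True, False, False, False],
            "protein_family": [False, False, False, False],
            "preclinical": [False, False, False, False],
            "clinical": [False, False, False, False],
        }
    )
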