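import numpy as np
import pytest

from pansurv.core import (
    CancerTypeCode,
    FeatureBag,
    PatientRecord,
    SurvivalLabel,
    encode_clinical,
)
from pansurv.network import ModelConfig, init_params
from pansurv.synthetic import SimConfig, simulate_cohort


def make_bag(n=5, d=16, seed=0, slide_id="s0"):
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    coords = np.stack(
        [224 * (np.arange(n) % side), 224 * (np.arange(n) // side)], axis=1
    )
    return FeatureBag(
        slide_id=slide_id,
        features=rng.standard_normal((n, d)).astype(np.float32),
        coords=coords.astype(np.int32),
    )


def make_record(n=5, d=16, seed=0, cancer_index=0, K=2, time=12.0, event=1,
                n_bags=1, patient_id="p0"):
    bags = [make_bag(n, d, seed + i, slide_id=f"{patient_id}-s{i}") for i in range(n_bags)]
    return PatientRecord(
        patient_id=patient_id,
        bags=bags,
        clinical=encode_clinical(age=60, sex="female", stage="II"),
        cancer=CancerTypeCode(index=cancer_index, label=f"C{cancer_index}", K=K),
        survival=SurvivalLabel(time=time, event=event),
    )


@pytest.fixture
def tiny_config():
    return ModelConfig(
        D=8, K=2, d_slide=8, d=8, n_tokens=2, n_heads=2,
        attn_hidden=8, expert_hidden=8,
    )


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient, 2-cancer synthetic cohort shared by read-only tests."""
    cfg = SimConfig(K=2, n_per_type=30, D=8, bag_size_range=(4, 10), seed=7)
    return simulate_cohort(cfg)
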