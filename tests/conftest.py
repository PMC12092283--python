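import numpy as np
import pandas as pd
import pytest

from graftdd import scoring, synthdata as sd


@pytest.fixture(scope="session")
def default_truth():
    return sd.make_truth(500, seed=11)


@pytest.fixture(scope="session")
def reference(default_truth):
    return sd.generate_reference_cohort(250, 500, seed=11, truth=default_truth)


@pytest.fixture(scope="session")
def panel(default_truth):
    return sd.generate_cell_profiles(default_truth, seed=12)


@pytest.fixture(scope="session")
def trial(default_truth):
    return sd.generate_trial(sd.TrialDesign(), default_truth, seed=13)


@pytest.fixture(scope="session")
def score_table(trial, default_truth):
    return scoring.assemble_score_table(trial, sd.planted_library(default_truth))


@pytest.fixture(scope="session")
def noise_free_trial():
    """Trial with planted effects but all noise sources off."""
    cfg = sd.GeneratorConfig(visit_effect_sd=0.0)
    truth = sd.make_truth(300, cfg, seed=21, patient_sd=0.0, resid_sd=0.0)
    return truth, sd.generate_trial(sd.TrialDesign(), truth, cfg, seed=22)


def toy_meta(n_per_arm=2):
    rows = []
    for i in range(2 * n_per_arm):
        p = f"P{i + 1:02d}"
        arm = "placebo" if i < n_per_arm else "felzartamab"
        for j, v in enumerate(("baseline", "week24", "week52")):
            rows.append(
                {
                    "sample_id": f"{p}_{v}",
                    "patient_id": p,
                    "arm": arm,
                    "visit": v,
                    "pct_cortex": 40.0 + (7 * i + 11 * j) % 61,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
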