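import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dsimmune import synth


@pytest.fixture(scope="session")
def default_bundle():
    """Full cohort at the default study conditions (seed fixed)."""
    return synth.generate_cohort(synth.default_config(seed=7))


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config(seed=7)


def small_config(seed: int = 0, n_t21: int = 40, n_d21: int = 20,
                 **overrides) -> synth.SyntheticConfig:
    """Compact cohort for fast tests: a few features of each kind."""
    antigens = {
        "TRUE1": synth.AntigenParams(6.2, 0.5, {"T21": 0.5, "D21": 0.05}, 3.0),
        "NULLA": synth.AntigenParams(6.2, 0.5, {"T21": 0.2, "D21": 0.2}, 3.0),
        "NULLB": synth.AntigenParams(6.2, 0.5, {"T21": 0.2, "D21": 0.2}, 3.0),
    }
    analytes = {
        "HOT": synth.AnalyteParams(4.0, t21_log2fc=1.0, plate_sd=0.1,
                                   lower_limit=0.0, upper_limit=np.inf),
        "COLD": synth.AnalyteParams(4.0, plate_sd=0.1,
                                    lower_limit=0.0, upper_limit=np.inf),
    }
    isgs = {
        "ISGHI": synth.IsgParams(6.0, t21_log2fc=1.0, batch_sd=0.1),
        "ISGLO": synth.IsgParams(6.0, t21_log2fc=0.0, batch_sd=0.1),
        "MX1": synth.IsgParams(6.0, t21_log2fc=1.0, batch_sd=0.1, chr21=True),
    }
    clusters = synth.ClusterParams(
        baseline={"C1": 0.6, "C2": 0.3, "C3": 0.1},
        t21_log_odds={"C3": np.log(2.0)},
        sigma=0.3,
    )
    trial = synth.TrialParams(
        n_participants=6,
        weeks=(0, 2, 8, 16),
        treatment_log2fc={"score": -1.0},
        baseline_log2_mean={"score": 4.0},
        baseline_log2_sd={"score": 0.3},
        noise_sd=0.05,
        trigger_events=(("P03", 8, 4.0),),
    )
    kwargs = dict(
        seed=seed, n_t21=n_t21, n_d21=n_d21,
        prevalence={"AITD": {"T21": 0.5, "D21": 0.05}},
        antigen_params=antigens, analyte_params=analytes,
        isg_params=isgs, cluster_params=clusters, trial_params=trial,
    )
    kwargs.update(overrides)
    return synth.SyntheticConfig(**kwargs)


@pytest.fixture()
def small_cfg():
    return small_config(seed=3)
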