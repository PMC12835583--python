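import numpy as np
import pytest

from rvcirc.initialize import ClinicalSummary, build_initial_parameters
from rvcirc.io import load_reference_cohort
from rvcirc.synth import phenotype_preset, generate_patient


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 25-subject clinical-hemodynamics table."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def mean_summary(reference_cohort):
    """Cohort-mean clinical summary (used for representative baselines)."""
    rc = reference_cohort
    return ClinicalSummary(
        HR=float(np.mean([c.HR for c in rc])),
        CO=float(np.mean([c.CO for c in rc])),
        PAWP=float(np.mean([c.PAWP for c in rc])),
        mPAP=float(np.mean([c.mPAP for c in rc])),
        phenotype="Ipc-PH",
    )


@pytest.fixture(scope="session")
def baseline_params(mean_summary):
    return build_initial_parameters(mean_summary)


@pytest.fixture(scope="session")
def virtual_patient():
    """One reproducible synthetic subject with noiseless and noisy data."""
    return generate_patient(phenotype_preset("Pre-capillary"), seed=1234)


def random_valid_parameters(seed, n):
    """n random valid parameter vectors spanning the phenotype presets."""
    rng = np.random.default_rng(seed)
    labels = ("Pre-capillary", "Ipc-PH", "Cpc-PH", "No PH")
    from rvcirc.synth import _sample_truth
    out = []
    for i in range(n):
        preset = phenotype_preset(labels[i % 4])
        out.append(_sample_truth(preset, rng))
    return out
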