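import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_report():
    """Full pipeline on a 20,000-patient cohort with planted text/code signal.

    The scaled-down replication run: default generator conditions (0.89%
    prevalence, planted signal), embedding dimension 50, the full 1000-
    replicate paired bootstrap.  Shared across tests because it is the
    expensive end-to-end artefact.
    """
    from notecast.pipeline import RunConfig, Seeds, run_all

    cfg = RunConfig(n_patients=20_000, dim=50, n_boot=1000, seeds=Seeds.from_base(7))
    return run_all(cfg)


@pytest.fixture(scope="session")
def null_report():
    """Pipeline on a cohort with every case/control difference switched off.

    signal_strength = icpc_effect = 1 removes the planted note and code
    signal; the demographic differences that the generator plants by design
    (age mixture, gender share, consultation volume) are equalised as well,
    so any residual discrimination would indicate information leaking
    through the pipeline machinery.  Prevalence is raised so the test split
    holds enough cases for the null AUROC band to be tight relative to its
    sampling error.
    """
    from notecast.pipeline import RunConfig, Seeds, run_all
    from notecast.synth import _default_age_mixture

    mix = _default_age_mixture()["control"]
    cfg = RunConfig(
        n_patients=10_000,
        dim=50,
        n_boot=500,
        synth={
            "prevalence": 0.15,
            "signal_strength": 1.0,
            "icpc_effect": 1.0,
            "age_mixture": {"control": mix, "case": mix},
            "female_fraction": {"control": 0.55, "case": 0.55},
            "case_consults_mean": 59.0,
        },
        seeds=Seeds.from_base(21),
    )
    return run_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
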