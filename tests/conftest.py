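import numpy as np
import pytest

import seasongamm as sg


@pytest.fixture(scope="session")
def survey_fixture():
    """Deterministic survey-shaped records matching the printed margins."""
    return sg.build_survey_fixture(seed=0)


@pytest.fixture(scope="session")
def small_fit():
    """One shared small GAMM fit on synthetic data with known truth.

    Kept deliberately modest (n=1200, 3 chains x 12k sweeps) so the suite
    stays fast; tests that need tighter posteriors use their own fits.
    """
    truth = sg.TruthConfig(n=1200, seed=7)
    records, truth_record = sg.generate_survey(truth)
    spec = sg.build_spec(records)
    settings = sg.McmcSettings(n_chains=3, burn_in=2000, iterations=10000, thin=10, seed=42)
    draws = sg.sample_posterior(spec, settings)
    return {"truth": truth, "truth_record": truth_record, "records": records,
            "spec": spec, "draws": draws}


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
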