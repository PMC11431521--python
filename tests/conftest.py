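import numpy as np
import pandas as pd
import pytest

from gagdx import GagomeProfile, PANEL_NAMES, bayes, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (85 cases / 28 controls), fixed seed."""
    return simulate_cohort(seed=7)


@pytest.fixture
def reduced_mcmc():
    """Short MCMC profile used in simulation studies (still passes the
    R-hat/ESS gates for the near-iid Gibbs draws)."""
    return bayes.McmcConfig(chains=4, iterations=750, warmup=250, seed=11)


@pytest.fixture
def complete_profile():
    """A complete 17-disaccharide profile with simple hand-checkable values."""
    conc = {name: 0.0 for name in PANEL_NAMES}
    conc.update({"0S CS": 2.0, "4S CS": 1.0, "TriS CS": 1.0})
    return GagomeProfile("sample-1", conc)


def random_profile_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Cohort of random non-negative concentrations for property tests."""
    vals = rng.gamma(1.5, 0.3, size=(n, len(PANEL_NAMES)))
    return pd.DataFrame(vals, columns=list(PANEL_NAMES),
                        index=[f"S{i}" for i in range(n)])
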