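import numpy as np
import pytest

from hale_ensemble import PanelConfig, StratumSeries, generate_panel

SMALL_AGES = (0, 1, 5, 10, 15, 20, 25, 30)


@pytest.fixture(scope="session")
def small_panel():
    """3 countries x 2 sexes x 18 ages x 30 years, default noise."""
    return generate_panel(PanelConfig(n_countries=3, seed=42))


@pytest.fixture(scope="session")
def noiseless_linear_panel():
    return generate_panel(
        PanelConfig(n_countries=2, noise_sd=0.0, trend_regime="linear", seed=7)
    )


@pytest.fixture(scope="session")
def noisy_series(small_panel):
    return StratumSeries.from_panel(small_panel, "C001", "female")


def make_common_drift_series(
    rng: np.random.Generator,
    ages=SMALL_AGES,
    years=(1990, 2019),
    drift: float = 0.25,
    noise_sd: float = 0.0,
) -> StratumSeries:
    """Series drawn from the age-time family itself: y = alpha_a + d(t - tbar)."""
    ages = np.asarray(ages, dtype=float)
    yrs = np.arange(years[0], years[1] + 1)
    alpha = 65.0 - 0.8 * ages
    values = alpha[:, None] + drift * (yrs - yrs.mean())[None, :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return StratumSeries(location="X", sex="female", ages=ages, years=yrs,
                         values=values)
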