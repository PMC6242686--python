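import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_params():
    """The packaged per-genotype split-line parameter table (44 rows)."""
    from peavigour import reference_growth_params

    return reference_growth_params()


@pytest.fixture(scope="session")
def regen_series():
    """Noise-free regeneration of a genotype series from its parameter row."""
    from peavigour import GrowthSeries, broken_stick_value

    def make(row, day_start=11, day_end=39):
        days = np.arange(day_start, day_end + 1, dtype=float)
        values = broken_stick_value(days, row.x_day, row.y_kpix, row.slope1, row.slope2)
        return GrowthSeries(row.genotype, None, days, values)

    return make
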