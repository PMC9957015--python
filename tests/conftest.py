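import numpy as np
import pytest

import residuechain as rc


@pytest.fixture
def rng():
    return np.random.default_rng(20230213)


@pytest.fixture
def carbendazim_wheat():
    return rc.builtin_model("carbendazim", "wheat")


@pytest.fixture
def factorial_points():
    """4x4 condition grid x 10 sampling days, as (t, T, RH) rows."""
    return np.array(
        [
            (t, T, RH)
            for T in (20.0, 30.0, 40.0, 50.0)
            for RH in (50.0, 60.0, 70.0, 80.0)
            for t in np.linspace(0.0, 90.0, 10)
        ]
    )


def make_timecourse(days, conc, censored=None, **meta):
    days = np.asarray(days, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if censored is None:
        censored = np.zeros(days.size, dtype=bool)
    defaults = dict(pesticide="carbendazim", matrix="wheat", temperature_C=20.0, rh_pct=60.0)
    defaults.update(meta)
    return rc.ResidueTimeCourse(days=days, concentrations=conc, censored=censored, **defaults)


@pytest.fixture
def timecourse_factory():
    return make_timecourse
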