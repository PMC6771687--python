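import numpy as np
import pandas as pd
import pytest

from locmorph.loc_table import LocalizationTable


def make_table(frame, x, y, photons=1000.0, fwhm=300.0, channel="ch"):
    n = len(frame)
    df = pd.DataFrame(
        {
            "frame": frame,
            "x": x,
            "y": y,
            "photons": np.broadcast_to(photons, n).astype(float),
            "fwhm": np.broadcast_to(fwhm, n).astype(float),
        }
    )
    return LocalizationTable(df, channel=channel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_table(rng):
    n = 1000
    return make_table(
        frame=rng.integers(0, 100, n),
        x=rng.uniform(0, 5000, n),
        y=rng.uniform(0, 5000, n),
        photons=rng.lognormal(8, 0.5, n),
        fwhm=rng.normal(330, 40, n).clip(100),
        channel="rnd",
    )
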