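import numpy as np
import pandas as pd
import pytest

import cropcarb as cc


@pytest.fixture(scope="session")
def small_frame():
    return cc.generate_frame(100, domain=(400.0, 400.0), total_area=1e6,
                             n_replicates=10, n_regions=3, seed=11)


@pytest.fixture(scope="session")
def small_weather(small_frame):
    return cc.generate_weather(small_frame, years=(1979, 2015), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_frame):
    return cc.generate_truth_histories(small_frame, seed=11)


@pytest.fixture(scope="session")
def small_donors(small_frame, small_truth):
    return cc.generate_donors(small_frame, small_truth, 150, seed=11)


@pytest.fixture(scope="session")
def default_params():
    return cc.ModelParams()


@pytest.fixture(scope="session")
def small_batch(small_frame, small_weather, small_truth, default_params):
    return cc.simulate_batch(small_frame, small_weather, small_truth, default_params)
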