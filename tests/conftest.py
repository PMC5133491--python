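import numpy as np
import pandas as pd
import pytest

import omicforest as of


@pytest.fixture
def small_table():
    """3 samples x 2 features, values chosen for easy hand-checks."""
    df = pd.DataFrame(
        {"f1": [1.0, 2.0, 3.0], "f2": [5.0, 7.0, 6.0]},
        index=["s1", "s2", "s3"],
    )
    return of.FeatureTable("toy", df)


@pytest.fixture
def dose_study():
    """Small 5-class dose study: one informative platform, one noise platform."""
    design = of.StudyDesign(
        groups=[
            of.synthetic_data.Group("control", 12, 0.0),
            of.synthetic_data.Group("low", 12, 30.0),
            of.synthetic_data.Group("int1", 12, 100.0),
            of.synthetic_data.Group("int2", 12, 300.0),
            of.synthetic_data.Group("high", 12, 1000.0),
        ]
    )
    specs = [
        of.DatasetSpec("signal", 30, 8, 2.0),
        of.DatasetSpec("noise", 25, 0, 0.0),
    ]
    phenos = [
        of.PhenotypeSpec(
            "driven",
            drivers=[("signal", f"signal_f{i:03d}") for i in range(1, 4)],
            beta=1.0,
            sigma=0.5,
        ),
        of.PhenotypeSpec("flat", drivers=[], sigma=1.0),
    ]
    collection, truth = of.simulate_study(design, specs, phenos, seed=7)
    return collection, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
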