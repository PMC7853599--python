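import numpy as np
import pandas as pd
import pytest

import stemtherm as st


def simulate_gxe(I=300, J=3, R=2, s2=(1.0, 0.5, 0.25), seed=0, mu=10.0):
    """Balanced crossed G x Y dataset with known variance components."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2[0]), I)
    y = rng.normal(0, 1.0, J)
    gy = rng.normal(0, np.sqrt(s2[1]), (I, J))
    rows = []
    for i in range(I):
        for j in range(J):
            for _ in range(R):
                rows.append(
                    (
                        f"g{i:04d}",
                        2015 + j,
                        mu + g[i] + y[j] + gy[i, j] + rng.normal(0, np.sqrt(s2[2])),
                    )
                )
    return pd.DataFrame(rows, columns=["genotype", "year", "value"]), g


@pytest.fixture(scope="session")
def paper_scale():
    """Full-cohort study conditions: 330 genotypes x 2 reps x 3 years."""
    return st.run_pipeline(st.RunConfig(), seed=1)


def noiseless_config(n_genotypes: int = 60) -> st.RunConfig:
    """Zero measurement noise, no genotype-by-year deviations, benign
    temperatures (no cold days that would clamp growth at zero), and a
    schedule long enough for every plot to reach its plateau."""
    return st.RunConfig(
        scenario=st.ScenarioConfig(
            genotype=st.GenotypeConfig(n_genotypes=n_genotypes, gy_var_ratio=0.0),
            temperature=st.TemperatureConfig(noise_sd=0.6),
            noise_sd=0.0,
            measure_span_days=95,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def noiseless_result():
    return st.run_pipeline(noiseless_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
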