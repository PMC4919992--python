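import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sipshift import GradientConfig, GradientFraction, GradientRun, make_community
from sipshift.evaluate import paired_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast 12-fraction gradient config."""
    return GradientConfig(seed=7)


@pytest.fixture
def community(rng):
    """50 taxa, the first 5 fully labelled at >=1% abundance."""
    return make_community(50, 5, rng=rng)


@pytest.fixture(scope="session")
def paired_runs():
    """One simulated 13C/12C paired experiment (3 replicates per arm)."""
    rng = np.random.default_rng(999)
    taxa = make_community(50, 5, rng=rng)
    cfg = GradientConfig(seed=31)
    runs13, runs12 = paired_experiment(taxa, cfg, replicates=3)
    truth = {t.taxon_id for t in taxa if t.labelled}
    return runs13, runs12, truth


def toy_run(matrix, densities, run_id="toy", treatment="12C", copies=None,
            values_kind="relative", **kw):
    """Build a small GradientRun from a taxon x fraction array."""
    matrix = pd.DataFrame(
        np.asarray(matrix, dtype=float),
        index=[f"t{i}" for i in range(np.shape(matrix)[0])],
        columns=range(1, np.shape(matrix)[1] + 1),
    )
    fractions = [
        GradientFraction(index=i + 1, density=d) for i, d in enumerate(densities)
    ]
    return GradientRun(
        run_id=run_id,
        soil=kw.get("soil", "D"),
        treatment=treatment,
        replicate=kw.get("replicate", 1),
        timepoint_days=kw.get("timepoint_days", 32),
        fractions=fractions,
        abundance=matrix,
        copies=copies,
        values_kind=values_kind,
    )
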