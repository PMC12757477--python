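import numpy as np
import pandas as pd
import pytest

from phosphodiff import simulate as sim
from phosphodiff.model import AbundanceTable, SampleDesign, Thresholds


def small_config(seed: int, **overrides) -> sim.SimulationConfig:
    """Scaled-down study: same fractions, effects, noise and replicate
    structure as the default conditions, smaller feature counts so that
    multi-seed experiments stay fast."""
    kw = dict(
        n_proteins=300,
        n_transcripts=900,
        n_phosphopeptides=40,
        n_gof_genes=25,
        n_lof_genes=25,
        n_tfs=10,
        seed=seed,
    )
    kw.update(overrides)
    return sim.SimulationConfig(**kw)


def null_config(seed: int, **overrides) -> sim.SimulationConfig:
    """No planted effects at all: every downstream call is a false positive."""
    kw = dict(
        n_proteins=120,
        n_transcripts=300,
        n_phosphopeptides=25,
        frac_dep=0.0,
        frac_deg=0.0,
        frac_dphospho=0.0,
        frac_concordant=0.0,
        n_gof_genes=0,
        n_lof_genes=0,
        n_tfs=6,
        seed=seed,
    )
    kw.update(overrides)
    return sim.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def bundle() -> sim.SimulatedBundle:
    return sim.simulate(small_config(seed=1))


@pytest.fixture(scope="session")
def th() -> Thresholds:
    return Thresholds()


@pytest.fixture()
def toy_design() -> SampleDesign:
    rows = [(f"{c}_{r}", c, r) for c in ("WT", "MUT") for r in (1, 2, 3)]
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_table(values: np.ndarray, features=None, samples=None,
               kind: str = "protein") -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=features, columns=samples), kind)
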