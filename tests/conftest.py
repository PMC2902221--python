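import numpy as np
import pandas as pd
import pytest

from loopcgh.synthetic import ProbeRatioTable


def make_table(
    ratios,
    array_id: str = "arr",
    cy3: str = "a1",
    cy5: str = "a2",
    chrom: str = "chr1",
    spacing: int = 300,
    probe_length: int = 60,
    seed: int = 0,
    x=None,
    y=None,
) -> ProbeRatioTable:
    """Probe table with prescribed log2 ratios and log-normal intensities."""
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    rng = np.random.default_rng(seed)
    ch2 = 1_000.0 * rng.lognormal(0.0, 1.0, n)
    ch1 = ch2 * np.power(2.0, ratios)
    nx = max(1, int(np.ceil(np.sqrt(n))))
    frame = pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + probe_length,
            "x": np.arange(n) % nx if x is None else x,
            "y": np.arange(n) // nx if y is None else y,
            "ch1": ch1,
            "ch2": ch2,
            "ratio": ratios,
        }
    )
    return ProbeRatioTable(frame, array_id, cy3, cy5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A 4-animal noiseless loop with one planted CNV per animal."""
    from loopcgh.pipeline import SimulationSpec, simulate_inputs

    spec = SimulationSpec(
        n_animals=4,
        n_chromosomes=1,
        chromosome_length=300_000,
        n_cnvs_per_animal=1,
        noise_sd=0.0,
        cnv_size_range=(5_000, 10_000),
    )
    return simulate_inputs(spec, seed=11)
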