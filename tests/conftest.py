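import logging

import pytest

from mirsomatic.simulate import SimulationConfig, simulate_cohort

logging.getLogger("mirsomatic").setLevel(logging.ERROR)


SMALL_CHROMS = ("chr1", "chr2", "chr3")


def small_config(**overrides) -> SimulationConfig:
    """A compact cohort sharing the generative model of the full-scale one."""
    base = dict(
        seed=7,
        n_genes=80,
        chromosomes=SMALL_CHROMS,
        n_samples={"LUAD": 15, "LUSC": 12},
        background_rate=2e-4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """Perfect-sensitivity cohort with no noise: pipeline must recover truth."""
    cfg = small_config(
        planted={"seed": 4, "motif_lost": 4, "motif_gained": 4, "cleavage": 4},
        hotspots=[(3, 8.0)],
    )
    outdir = tmp_path_factory.mktemp("clean_cohort")
    return simulate_cohort(cfg, str(outdir))


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    """Cohort with germline contaminants and filter-violating records."""
    cfg = small_config(
        seed=13,
        background_rate=4e-4,
        germline_per_sample=0.8,
        violate_fractions={
            "min_alt_reads": 0.08,
            "freq_ratio": 0.08,
            "ssc": 0.08,
            "bq": 0.08,
            "non_pass": 0.08,
        },
    )
    outdir = tmp_path_factory.mktemp("noisy_cohort")
    return simulate_cohort(cfg, str(outdir))
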