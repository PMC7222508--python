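import pytest

from clonaltraj.io import SampleSheet
from clonaltraj.simgen import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sheet() -> SampleSheet:
    return SampleSheet.default()


@pytest.fixture(scope="session")
def noise_free_cohort():
    """A small noise-free cohort with planted structure everywhere."""
    cfg = SimConfig(
        seed=101,
        noise_sd=0.0,
        n_loci=400,
        frac_selected_up=0.025,
        frac_selected_down=0.025,
        n_genes=120,
        n_planted_degs=20,
        n_eqtl_links=8,
        n_mirnas=30,
        n_target_pairs=25,
        n_concordant_pairs=10,
        n_immune_genes=40,
        n_immune_candidates=5,
    )
    return simulate_cohort(cfg)
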