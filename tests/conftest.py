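import pandas as pd
import pytest

from primkit.dynamics import PrimCutoff, derive_prim_cutoff
from primkit.pipeline import study_state_tables
from primkit.promoters import build_prim_table, consensus_state
from primkit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """Default-scale study (1,000 genes, 3 cell types) with all noise off."""
    return simulate_study(SimulationConfig(seed=11).noise_free())


@pytest.fixture(scope="session")
def noisy_study():
    """Default noise model: peak drop/insert 0.05, NB dispersion 0.3."""
    return simulate_study(SimulationConfig(seed=23))


def analyze_study(study):
    """Run the promoter/PRIM stages in memory; returns a dict of tables."""
    promoters, states, k4, k27, groups = study_state_tables(study)
    cts = list(study.config.chip_replicates)
    consensus = {}
    for ct in cts:
        cols = [s for s in states.columns if groups[s] == ct]
        consensus[ct] = consensus_state([states[c] for c in cols], 2)
    consensus = pd.DataFrame(consensus)
    prim_samples = build_prim_table(states, k4, k27)
    prim_ct = build_prim_table(states, k4, k27, sample_groups=groups)
    cutoffs = {
        ct: derive_prim_cutoff(prim_ct[ct], consensus[ct]) for ct in cts
    }
    return {
        "promoters": promoters,
        "states": states,
        "k4": k4,
        "k27": k27,
        "groups": groups,
        "consensus": consensus,
        "prim_samples": prim_samples,
        "prim_celltypes": prim_ct,
        "cutoffs": cutoffs,
    }


@pytest.fixture(scope="session")
def noise_free_tables(noise_free_study):
    return analyze_study(noise_free_study)


@pytest.fixture(scope="session")
def noisy_tables(noisy_study):
    return analyze_study(noisy_study)
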