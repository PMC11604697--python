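import pytest

from capv2g.simulate import SimConfig, generate_bundle


def calibration_config(seed: int, delta: float) -> SimConfig:
    """Single-cell-type config for expression-comparison calibration:
    no planted chains, 130 promoter-connected genes out of 280."""
    return SimConfig(
        seed=seed,
        chrom_lengths={"chr1": 2_400_000},
        n_genes=280,
        cell_types=("EndoC_BH1",),
        chain_celltype_probs=(1.0,),
        n_planted_chains=0,
        n_connected_genes=130,
        n_sentinels=8,
        n_consensus_peaks=300,
        n_contacts=200,
        frac_bait_to_bait=0.0,
        frac_subthreshold_contacts=0.1,
        expression_log2_shift=delta,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full four-cell-type bundle shared across tests."""
    return generate_bundle(SimConfig(seed=11))
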