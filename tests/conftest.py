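import numpy as np
import pytest

from clonetrace.core_io import SampleMeta
from clonetrace.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def two_clone_study():
    """300+300 mutations in two clones over two pure diploid samples."""
    cfg = SimulationConfig(
        samples=[SampleMeta("a"), SampleMeta("b")],
        parent=[None, 0],
        ccf=np.array([[1.0, 1.0], [0.4, 0.05]]),
        branch_n_snvs=[300, 300],
        branch_sig_weights=np.full((2, 3), 1 / 3),
        generate_sequences=False,
    )
    return simulate_study(cfg, seed=5)


@pytest.fixture(scope="session")
def small_study_with_sequences():
    """Small study including FASTA, CNV segments and planted deletions."""
    from clonetrace.core_io import CopyNumberSegment
    from clonetrace.synthetic_data import PlantedDeletion

    cfg = SimulationConfig(
        samples=[SampleMeta("t1"), SampleMeta("t2")],
        parent=[None, 0],
        ccf=np.array([[1.0, 1.0], [0.6, 0.1]]),
        branch_n_snvs=[150, 150],
        branch_sig_weights=np.array([[0.5, 0.5, 0.0], [0.1, 0.3, 0.6]]),
        chrom_lengths={"1": 40_000, "9": 10_000, "17": 12_000},
        cn_segments=[CopyNumberSegment("t2", "17", 1, 6_000, 1, 0)],
        branch_n_on_lost_segment={1: 10},
        lost_segment=("17", 1, 6_000),
        deletions=[
            PlantedDeletion(chrom="9", bp_low=2_000, bp_high=4_000,
                            spacer_len=23, offset=10, strand="+"),
        ],
    )
    return simulate_study(cfg, seed=11)
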