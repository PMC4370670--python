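import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from apafeedback.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    simulate_tail_reads,
    synthetic_zfr_like,
)


@pytest.fixture(scope="session")
def zfr():
    """Synthetic minus-strand fixture reproducing the ZFR/mir-579
    geometry (1409-nt UTR, miRNA in intron 11, three cleavage sites)."""
    return synthetic_zfr_like()


@pytest.fixture(scope="session")
def small_cohort():
    """20 genes, 10 intronic miRNAs (one arm each, half host-targeting),
    planted decoys and shifts."""
    cfg = SimulationConfig(
        rng_seed=17,
        n_genes=20,
        n_intronic_mirnas=10,
        fraction_ht=0.5,
        n_priming_decoys=10,
        n_shorter=4,
        n_longer=4,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The small cohort written to disk, with tail reads."""
    d = tmp_path_factory.mktemp("cohort")
    from apafeedback.synthetic_data import write_cohort

    write_cohort(small_cohort, d)
    simulate_tail_reads(
        small_cohort, out_tsv=d / "tail_reads.tsv", out_sam=d / "tail_reads.sam"
    )
    return d
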