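import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from prfscan import ScanConfig, TranscriptModel, max_basepair_fold, permutation_zscore
from prfscan.simulate import SimulationConfig, generate_transcriptome


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the folding kernels once so per-test timings are honest."""
    max_basepair_fold("GGGAAAACCC")
    permutation_zscore("GGGAAAACCCGGGAAAACCC", n_perm=5, seed=0)


def random_cds(rng: np.random.Generator, max_len: int = 3000) -> str:
    n = 3 * int(rng.integers(3, max_len // 3 + 1))
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def planted_phe_transcriptome():
    """Small all-planted transcriptome shared by structure/frameshift tests."""
    cfg = SimulationConfig(
        n_transcripts=40, p_plant_phe_signal=1.0, p_plant_lys_signal=0.0, seed=11
    )
    return cfg, *generate_transcriptome(cfg)


@pytest.fixture()
def robo1_like_model():
    """Constructed transcript reproducing a PTC 52 nt upstream of the next
    exon-exon junction (synthetic stand-in; no real annotation involved)."""
    # CDS: slip site at 5, -1-frame PTC at 11, stop last base at coord 13
    return TranscriptModel(
        transcript_id="robo1_like_synthetic",
        cds="AUGCAAAAUUUUAAGUAA",
        cds_offset=0,
        junctions=(66,),
    )


@pytest.fixture()
def default_scan_config():
    return ScanConfig(seed=123)
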