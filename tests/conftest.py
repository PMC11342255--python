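import numpy as np
import pytest

from tcrmil.repertoire_io import TCRClone
from tcrmil.synthetic_data import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small labelled cohort shared across tests (10 bags of 20 clones)."""
    cfg = SimConfig(n_per_class=5, clones_per_sample=25, seed=7)
    return generate_cohort(cfg, k=20)


@pytest.fixture
def toy_table(tmp_path):
    """Three-row MiXCR-style clone table on disk."""
    path = tmp_path / "sample.tsv"
    path.write_text(
        "aaSeqCDR3\tallVHitsWithScore\tcloneCount\tcloneFraction\n"
        "CASSGTEQFF\tTRBV6-1*00(1200)\t50\t0.5\n"
        "CASSLAPGATNEKLFF\tTRBV7-9*00(900)\t30\t0.3\n"
        "CASRRGSSYEQYF\tTRBV2*00(800)\t20\t0.2\n"
    )
    return path


def make_clone(seq="CASSGTEQFF", v="TRBV6-1*00(1200)", count=10, fraction=None):
    return TCRClone(cdr3_aa=seq, v_gene=v, clone_count=count, clone_fraction=fraction)
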