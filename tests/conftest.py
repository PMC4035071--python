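import numpy as np
import pytest

from xsanno.fixtures import FixtureConfig, generate_pair
from xsanno.model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-gene fixture with every hazard class planted once or twice."""
    cfg = FixtureConfig(
        n_genes=20,
        n_paralog_sp1=1,
        n_paralog_sp2=2,
        n_paralog_both=1,
        n_lift_fail=2,
        n_truncation=1,
        n_translocated=1,
        n_exon_gap=1,
        seed=42,
    )
    return generate_pair(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """A hazard-free diverged pair."""
    return generate_pair(FixtureConfig(n_genes=12, seed=5))


@pytest.fixture(scope="session")
def identity_bundle():
    """Two identical genomes joined by identity chains."""
    return generate_pair(
        FixtureConfig(n_genes=10, divergence=0.0, indel_rate=0.0, seed=3)
    )


@pytest.fixture
def toy_annotation():
    """Two genes, three transcripts, five exons on a toy chromosome."""
    return AnnotationSet(
        [
            GeneModel(
                "gA",
                [
                    TranscriptModel(
                        "tA1",
                        [GenomicInterval("chr1", 10, 60), GenomicInterval("chr1", 100, 160)],
                    ),
                    TranscriptModel("tA2", [GenomicInterval("chr1", 10, 60)]),
                ],
            ),
            GeneModel(
                "gB",
                [
                    TranscriptModel(
                        "tB1",
                        [
                            GenomicInterval("chr1", 300, 360, "-"),
                            GenomicInterval("chr1", 400, 450, "-"),
                        ],
                    )
                ],
            ),
        ]
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
    return SequenceStore({"chr1": seq})
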