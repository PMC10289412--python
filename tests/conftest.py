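import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from retroce.mre_scan import MatureMiRNA, seed_patterns
from retroce.synthetic_data import (
    SyntheticConfig,
    simulate_genome_and_annotations,
    simulate_sam_corpus,
)

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture(scope="session")
def let7a_patterns():
    return seed_patterns(MatureMiRNA("hsa-let-7a-5p", LET7A))


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus: genome, annotations, miRNAs, manifest."""
    outdir = tmp_path_factory.mktemp("corpus")
    manifest = simulate_genome_and_annotations(SyntheticConfig(seed=42), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def sam_corpus(tmp_path_factory):
    """Small corpus with per-sample SAM files and labelled straddlers/antisense."""
    outdir = tmp_path_factory.mktemp("sam_corpus")
    config = SyntheticConfig(
        seed=17, n_re_loci=12, n_normal=2, n_tumor=2, reads_per_sample=400_000
    )
    manifest = simulate_genome_and_annotations(config, outdir)
    paths, expected, totals, groups = simulate_sam_corpus(manifest, outdir / "sam")
    return manifest, paths, expected, totals, groups
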