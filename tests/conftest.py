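import numpy as np
import pytest

from atacre import encoder, simulate
from atacre.genomic_io import GenomicInterval, PairedFragment, Peak


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A small seeded 4-class synthetic study shared across test modules."""
    outdir = tmp_path_factory.mktemp("tiny_study")
    return simulate.simulate_study(
        str(outdir), n_train=40, n_val=16, n_test=16, seed=7,
        fragments_per_peak=120.0,
    )


@pytest.fixture(scope="session")
def tiny_encoded(tiny_study):
    """Encodings + stats for the tiny study (fragments-BED route)."""
    ref = tiny_study.reference()
    source = encoder.ListFragmentSource(tiny_study.fragments)
    cfg = encoder.EncoderConfig()
    encodings, stats = encoder.encode_dataset(
        tiny_study.peaks, source, ref, cfg
    )
    return encodings, stats, cfg, source


def make_fragments(spans, chrom="chr1"):
    return [PairedFragment(GenomicInterval(chrom, s, e)) for s, e in spans]


def make_peak(start, end, chrom="chr1", name="p", qval=None):
    return Peak(GenomicInterval(chrom, start, end), name, qval)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
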