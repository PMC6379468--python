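import numpy as np
import pysam
import pytest

from nirvspipe.core import NirvsLocus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def locus():
    return NirvsLocus(
        locus_id="SynFlavi1",
        contig="contig1",
        start=100,
        end=612,
        viral_family="Flavivirus",
        viral_orf="capsid",
        context="piRNA_cluster",
    )


def make_read(name, contig, start, seq, cigar, mapq, header):
    """Build one aligned segment against a single-contig header."""
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = seq
    seg.reference_id = header.get_tid(contig)
    seg.reference_start = start
    seg.cigarstring = cigar
    seg.mapping_quality = mapq
    seg.flag = 0
    return seg


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "contig1", "LN": 100000}]}
    )
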