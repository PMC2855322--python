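import numpy as np
import pandas as pd
import pytest

from nucorg.chip import CALL_COLUMNS, BindingTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_track(statuses, log2=None, chrom="chr1", locus_size=300, factor="A"):
    """Build a BindingTrack from a status list on a contiguous grid."""
    n = len(statuses)
    log2 = log2 if log2 is not None else [1.0 if s == "positive" else 0.0 for s in statuses]
    starts = np.arange(n) * locus_size
    calls = pd.DataFrame(
        {
            "locus_id": [f"{chrom}:{s}-{s + locus_size}" for s in starts],
            "chrom": chrom,
            "start": starts,
            "end": starts + locus_size,
            "resolution": locus_size,
            "log2_ratio": log2,
            "p_up": [0.001 if s == "positive" else 0.5 for s in statuses],
            "p_down": [0.001 if s == "negative" else 0.5 for s in statuses],
            "status": statuses,
        },
        columns=CALL_COLUMNS,
    )
    return BindingTrack(calls=calls, factor=factor)


@pytest.fixture
def track_factory():
    return make_track


GFF_TEXT = """##gff-version 3
chr1\ttest\tgene\t2001\t3000\t.\t-\t.\tID=geneL
chr1\ttest\tgene\t3301\t4300\t.\t+\t.\tID=geneR
chr1\ttest\tgene\t8001\t9500\t.\t+\t.\tID=geneS
chr1\ttest\tgene\t20001\t23000\t.\t+\t.\tID=geneFar
chr2\ttest\tgene\t1001\t2000\t.\t-\t.\tID=geneM
chr2\ttest\tgene\t6001\t7000\t.\t+\t.\tID=geneN
"""


@pytest.fixture
def gff_file(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF_TEXT)
    return p
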