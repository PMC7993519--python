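import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from repdab.io import Clonotype, RepertoireSample, SampleMetadata


@pytest.fixture
def tiny_sample() -> RepertoireSample:
    s = RepertoireSample(sample_id="T1")
    rows = [
        ("TGTGCCAGCAGT", "CASS", 5, "TRBV01-01", "TRBJ01-01"),
        ("TGTGCCAGCAGC", "CASS", 2, "TRBV01-01", "TRBJ01-01"),
        ("TGTGCCTGGAGT", "CAWS", 1, "TRBV02-01", "TRBJ01-02"),
        ("TGTGCCTTTAGT", "CAFS", 3, "TRBV03-01", "TRBJ02-01"),
    ]
    for nt, aa, count, v, j in rows:
        s.add(Clonotype(nt_seq=nt, aa_seq=aa, count=count, v_gene=v, j_gene=j))
    return s


@pytest.fixture
def immunoseq_file(tmp_path):
    """3-row valid immunoseq fixture."""
    path = tmp_path / "sample.tsv"
    path.write_text(
        "nucleotide\taminoAcid\tcount (templates/reads)\tvGeneName\tdGeneName\tjGeneName\n"
        "TGTGCCAGCAGT\tCASS\t5\tTCRBV01-01*01\tTCRBD01-01\tTCRBJ01-01\n"
        "TGTGCCTGGAGT\tCAWS\t2\tTCRBV02-01\tunresolved\tTCRBJ01-02\n"
        "TGTGCCTTTAGT\tCAFS\t3\tTCRBV03-01\tTCRBD02-01\tTCRBJ02-01\n"
    )
    return path


@pytest.fixture
def metadata_4v4() -> SampleMetadata:
    sids = [f"S{i:02d}" for i in range(1, 9)]
    return SampleMetadata(
        table=pd.DataFrame(
            {
                "sample_id": sids,
                "subject_id": [f"subj{i}" for i in range(8)],
                "group": ["control"] * 4 + ["condition"] * 4,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
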