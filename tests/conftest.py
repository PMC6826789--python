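import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loop2gene.loops import GenomicInterval, LoopRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_loop(chrom="chr1", s1=100_000, e1=105_000, s2=300_000, e2=305_000,
              pets=4, q=0.001, cell_line="", loop_id=None):
    return LoopRecord(GenomicInterval(chrom, s1, e1),
                      GenomicInterval(chrom, s2, e2),
                      pet_count=pets, q_value=q, cell_line=cell_line,
                      loop_id=loop_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def loop_file(tmp_path):
    """Write a BEDPE file from rows of raw fields; returns the path."""

    def _write(rows, name="loops.bedpe"):
        path = tmp_path / name
        with path.open("w") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return _write
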