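from __future__ import annotations

import pytest
from hypothesis import settings

from biopilot.bench import generate_fixture_case
from biopilot.config import parse_config

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


MINIMAL_CONFIG = """\
data:
  - ./data/reads.fastq.gz: single-end reads
goal: assemble the genome
"""

RNASEQ_CONFIG = """\
data:
  - ./data/SRR1374921.fastq.gz: single-end reads in LoGlu group
  - ./data/SRR1374922.fastq.gz: single-end reads in LoGlu group, replicate 2
  - ./data/SRR1374923.fastq.gz: single-end reads in HiGlu group
  - ./data/SRR1374924.fastq.gz: single-end reads in HiGlu group, replicate 2
  - ./data/mm39.fa: mouse reference genome
  - ./data/mm39.ncbiRefSeq.gtf: genome annotation
goal: identify differentially expressed genes
"""


@pytest.fixture
def minimal_config():
    return parse_config(MINIMAL_CONFIG)


@pytest.fixture
def rnaseq_config():
    return parse_config(RNASEQ_CONFIG)


@pytest.fixture
def rnaseq_case(tmp_path):
    return generate_fixture_case("rnaseq_deg", 7, tmp_path / "rnaseq")


@pytest.fixture
def generic_case(tmp_path):
    return generate_fixture_case("generic_fail_repair", 3, tmp_path / "generic")
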