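"""Shared fixtures: every input file is generated at test time by the
package's own fixture generators, with ground truth recorded in the
accompanying manifest."""

import pytest

from longreadqc import fixtures


@pytest.fixture(scope="session")
def read_set(tmp_path_factory):
    out = tmp_path_factory.mktemp("read_set")
    return fixtures.generate_read_set(out, n=100, seed=7)


@pytest.fixture(scope="session")
def read_set_gz(tmp_path_factory):
    out = tmp_path_factory.mktemp("read_set_gz")
    return fixtures.generate_read_set(out, n=30, seed=7, gzipped=True)


@pytest.fixture(scope="session")
def aligned(tmp_path_factory):
    out = tmp_path_factory.mktemp("aligned")
    return fixtures.generate_alignments(out, n_primary=20, seed=11)


@pytest.fixture(scope="session")
def aligned_rrms(tmp_path_factory):
    out = tmp_path_factory.mktemp("aligned_rrms")
    return fixtures.generate_alignments(out, n_primary=16, seed=13,
                                        rrms_plan=True)


@pytest.fixture(scope="session")
def modified(tmp_path_factory):
    out = tmp_path_factory.mktemp("modified")
    return fixtures.generate_modified_bam(out, n_reads=12, seed=5)


@pytest.fixture(scope="session")
def transcripts_uniform(tmp_path_factory):
    out = tmp_path_factory.mktemp("tx_uniform")
    return fixtures.generate_transcript_bam(out, "uniform", depth=20, seed=1)


@pytest.fixture(scope="session")
def transcripts_spiked(tmp_path_factory):
    out = tmp_path_factory.mktemp("tx_spiked")
    return fixtures.generate_transcript_bam(out, "spiked", depth=20, seed=1)


@pytest.fixture(scope="session")
def transcripts_biased(tmp_path_factory):
    out = tmp_path_factory.mktemp("tx_biased")
    return fixtures.generate_transcript_bam(out, "three_prime_biased",
                                            depth=20, seed=1)


@pytest.fixture(scope="session")
def signal(tmp_path_factory):
    out = tmp_path_factory.mktemp("signal")
    return fixtures.generate_signal_files(out, n_reads=3, seed=2)
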