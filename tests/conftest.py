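"""Shared fixtures: the seed-7 synthetic benchmark (run once per session)
and the packaged printed-peptide table."""

from __future__ import annotations

import pytest

from npmine.fixtures import mature_peptides_by_precursor
from npmine.pipeline import PipelineConfig, run_pipeline
from npmine.synthdata import benchmark_queries, generate_dataset

BENCHMARK_SEED = 7
BENCHMARK_PRECURSORS = 5
BENCHMARK_DECOYS = 20


@pytest.fixture(scope="session")
def benchmark():
    """(transcripts, truth, report) for the standard synthetic benchmark:
    5 embedded precursors among 20 decoys, seed 7."""
    transcripts, truth = generate_dataset(
        BENCHMARK_PRECURSORS, BENCHMARK_DECOYS, BENCHMARK_SEED
    )
    report = run_pipeline(transcripts, benchmark_queries(), PipelineConfig())
    return transcripts, truth, report


@pytest.fixture(scope="session")
def table2():
    """Printed mature-peptide rows grouped by precursor."""
    return mature_peptides_by_precursor()
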