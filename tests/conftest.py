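import numpy as np
import pytest

from ribotail import (
    CraceSimConfig,
    RiboSimConfig,
    TranscriptModel,
    make_crace_reference,
    simulate_crace_reads,
    simulate_ribo_experiment,
)
from ribotail.io import transcript_index


def make_transcript(
    tid: str,
    codons: list[str],
    utr5: int = 20,
    utr3: int = 20,
    sp: bool = False,
    tm: bool = False,
) -> TranscriptModel:
    """Build a transcript from explicit CDS codons with fixed-G UTRs."""
    cds = "".join(codons)
    seq = "G" * utr5 + cds + "G" * utr3
    return TranscriptModel(
        transcript_id=tid,
        sequence=seq,
        cds_start=utr5,
        cds_end=utr5 + len(cds),
        has_signal_peptide=sp,
        has_transmembrane=tm,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A small two-condition ribosome-profiling experiment with truth."""
    config = RiboSimConfig(
        n_genes=150,
        cds_length_range=(60, 150),
        library_depth=150_000,
        n_planted_down=10,
        fraction_sp_genes=0.3,
    )
    transcripts, truth, rpf, mrna = simulate_ribo_experiment(config, 101)
    return {
        "config": config,
        "transcripts": transcripts,
        "tidx": transcript_index(transcripts),
        "truth": truth,
        "rpf": rpf,
        "mrna": mrna,
    }


@pytest.fixture(scope="session")
def crace_world():
    """Error-free cRACE read set with reference and truth table."""
    config = CraceSimConfig(n_reads=600)
    reference = make_crace_reference(config, 7)
    reads, truth = simulate_crace_reads(reference, config, 8)
    return {"config": config, "reference": reference, "reads": reads, "truth": truth}
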