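"""Shared fixtures: one session-scoped synthetic dataset drives most tests."""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import settings

from lnckit.models import GenomicInterval, SequenceSet, TranscriptModel
from lnckit.simulate import (
    SimParams,
    plant_mimic_sites,
    simulate_counts,
    simulate_genome,
    simulate_mirnas,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def single_exon(tid: str, chrom: str = "chr1", start: int = 0, length: int = 500,
                strand: str = "+", **kw) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid, gene_id=kw.pop("gene_id", ""),
        exons=(GenomicInterval(chrom, start, start + length, strand),), **kw
    )


@pytest.fixture(scope="session")
def sim_params() -> SimParams:
    return SimParams(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_params) -> SimpleNamespace:
    """The full synthetic dataset: annotation, sequences, miRNAs, counts,
    planted truth."""
    transcripts, seqs, truth = simulate_genome(sim_params)
    mirnas = simulate_mirnas(sim_params)
    lnc_ids = sorted(truth.lncrna_classes)
    lnc_seqs = SequenceSet({i: seqs[i] for i in lnc_ids})
    lnc_seqs, truth = plant_mimic_sites(lnc_seqs, mirnas, sim_params, truth)
    merged = SequenceSet()
    for sid, s in seqs.items():
        merged.add(sid, lnc_seqs[sid] if sid in lnc_seqs else s)
    counts, truth = simulate_counts(transcripts, sim_params, truth)
    genes = [t for t in transcripts if t.biotype == "coding"]
    lncs = [t for t in transcripts if t.biotype == "lncRNA"]
    return SimpleNamespace(
        params=sim_params, transcripts=transcripts, genes=genes, lncs=lncs,
        seqs=merged, mirnas=mirnas, counts=counts, truth=truth,
    )
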