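"""Core domain types shared by every pipeline stage.

Coordinate convention
---------------------
All intervals are 0-based, half-open ``[start, end)`` on a named chromosome
with an explicit strand.  GTF/GFF3 readers and writers convert to and from
the 1-based inclusive convention of those formats at the I/O boundary, so
interval arithmetic inside the package never has to think about off-by-one
corrections: the length of an interval is always ``end - start``.

Sequences are stored in the DNA alphabet; RNA input (``U``) is normalised to
``T`` on entry and the record is flagged so it can be written back as RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
TISSUES = ("root", "shoot")
CONDITIONS = ("CK", "LS", "SS", "R")

DNA_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """An object violates one of the package's structural invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (nt).
    end : int
        0-based exclusive end (nt); must exceed ``start``.
    strand : str
        ``"+"`` or ``"-"``.  Unstranded features are rejected because the
        positional classification of a lncRNA depends on strand.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} must be > start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping nucleotides, ignoring strand (0 if disjoint
        or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in nt between the two intervals (0 if they overlap).

        Raises
        ------
        ValidationError
            If the intervals are on different chromosomes, where a genomic
            distance is undefined.
        """
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        if self.overlap(other) > 0:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``exons`` must be non-overlapping, sorted by start, and share one
    chromosome and strand.  ``length`` is always the spliced (exonic) length;
    genomic extent is available through :meth:`span`.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    class_code: str | None = None
    biotype: str = "candidate"  # coding | candidate | lncRNA

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chromosomes {sorted(chroms)}"
            )
        if len(strands) != 1:
            raise ValidationError(f"{self.transcript_id}: exons on mixed strands")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValidationError(f"{self.transcript_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in ("coding", "candidate", "lncRNA"):
            raise ValidationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced (exonic) transcript length in nt."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        """Genomic extent from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Intervals between consecutive exons (empty for single-exon)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


class SequenceSet:
    """A mapping of unique ids to non-empty nucleotide sequences.

    Sequences are stored DNA-normalised (``U`` -> ``T``); ids whose source
    was RNA are remembered in :attr:`rna_ids` so writers can restore ``U``.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None,
                 rna_ids: set[str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        self.rna_ids: set[str] = set(rna_ids or ())
        if sequences:
            for sid, seq in sequences.items():
                self.add(sid, seq)

    def add(self, sid: str, seq: str) -> None:
        if sid in self._seqs:
            raise ValidationError(f"duplicate sequence id {sid!r}")
        if not seq:
            raise ValidationError(f"empty sequence for id {sid!r}")
        seq = seq.upper()
        if "U" in seq:
            self.rna_ids.add(sid)
            seq = seq.replace("U", "T")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(f"{sid}: illegal characters {sorted(bad)}")
        self._seqs[sid] = seq

    def __getitem__(self, sid: str) -> str:
        return self._seqs[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def ids(self) -> list[str]:
        return list(self._seqs)


class CountMatrix:
    """Integer fragment counts, transcripts x samples, with a sample sheet.

    The sample sheet is a DataFrame indexed by sample id with columns
    ``tissue`` (root/shoot), ``condition`` (CK/LS/SS/R) and ``replicate``.
    Every sample column of the count table must appear exactly once in the
    sheet; counts must be non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> None:
        if counts.isna().any().any():
            raise ValidationError("count matrix contains missing values")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flo = counts.astype(float).to_numpy()
            if not np.all(flo == np.floor(flo)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.index.duplicated().any():
            raise ValidationError("duplicate transcript ids in counts")
        sheet = sample_sheet.copy()
        if "sample_id" in sheet.columns:
            sheet = sheet.set_index("sample_id")
        missing = set(counts.columns) - set(sheet.index)
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {sorted(missing)}")
        if sheet.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        for col in ("tissue", "condition", "replicate"):
            if col not in sheet.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        bad_t = set(sheet["tissue"]) - set(TISSUES)
        if bad_t:
            raise ValidationError(f"unknown tissue values {sorted(bad_t)}")
        bad_c = set(sheet["condition"]) - set(CONDITIONS)
        if bad_c:
            raise ValidationError(f"unknown condition values {sorted(bad_c)}")
        self.counts = counts
        self.sample_sheet = sheet.loc[list(counts.columns)]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, tissue: str | None = None,
                      condition: str | None = None) -> list[str]:
        """Sample ids matching the given tissue and/or condition."""
        sheet = self.sample_sheet
        mask = pd.Series(True, index=sheet.index)
        if tissue is not None:
            mask &= sheet["tissue"] == tissue
        if condition is not None:
            mask &= sheet["condition"] == condition
        return list(sheet.index[mask])


@dataclass
class ExpressionMatrix:
    """FPKM values on the same axes as the source :class:`CountMatrix`."""

    fpkm: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be >= 0")

    def max_per_transcript(self) -> pd.Series:
        return self.fpkm.max(axis=1)
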