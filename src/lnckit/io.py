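"""Readers and writers for the flat-file formats the pipeline touches.

GTF here means the gffcompare/StringTie dialect: tab-delimited, 1-based
inclusive coordinates, attribute column of ``key "value";`` pairs, with a
per-transcript ``class_code`` attribute describing the relation of an
assembled transcript to the reference annotation.  The attribute key that
carries the class code is configurable because assemblers disagree on it.

All tabular writers emit deterministically ordered TSV so that repeated runs
of any pipeline stage are byte-identical.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CountMatrix,
    GenomicInterval,
    SequenceSet,
    TranscriptModel,
    ValidationError,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Malformed GTF/GFF line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, class_code_key: str = "class_code") -> list[TranscriptModel]:
    """Read a (gffcompare-dialect) GTF into :class:`TranscriptModel` records.

    Only ``exon`` features are used; they are grouped by ``transcript_id``.
    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  A ``class_code`` attribute (key configurable) is
    captured from any feature of the transcript.  Transcripts are returned
    sorted by transcript id.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_ids: dict[str, str] = {}
    class_codes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-delimited fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if end1 < start1:
                raise ValidationError(f"line {lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise ValidationError(f"line {lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(lineno, "missing transcript_id attribute")
            if class_code_key in attrs:
                class_codes[tid] = attrs[class_code_key]
            if "gene_id" in attrs:
                gene_ids.setdefault(tid, attrs["gene_id"])
            if feature != "exon":
                continue
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            # GTF 1-based inclusive -> 0-based half-open
            exons[tid].append(GenomicInterval(chrom, start1 - 1, end1, strand))
    out = []
    for tid in sorted(order):
        ivs = tuple(sorted(exons[tid], key=lambda e: e.start))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_ids.get(tid, ""),
                exons=ivs,
                class_code=class_codes.get(tid),
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              class_code_key: str = "class_code") -> None:
    """Write transcripts as GTF (transcript + exon lines, sorted by id)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            span = t.span()
            attrs = f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}";'
            if t.class_code is not None:
                attrs += f' {class_code_key} "{t.class_code}";'
            fh.write(
                f"{t.chrom}\tlnckit\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tlnckit\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read a reference annotation GFF3 (gene/mRNA/exon features).

    Exons are grouped under their ``Parent`` mRNA; mRNAs inherit the gene id
    of their parent gene.  Returned transcripts carry ``biotype="coding"``.
    """
    mrna_gene: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _phase, attrs_s = fields
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if kv and "=" in kv
            )
            if feature == "mRNA":
                mrna_gene[attrs["ID"]] = attrs.get("Parent", "")
            elif feature == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise GtfParseError(lineno, "exon without Parent")
                if strand not in ("+", "-"):
                    raise ValidationError(f"line {lineno}: unknown strand {strand!r}")
                start1, end1 = int(start_s), int(end_s)
                if end1 < start1:
                    raise ValidationError(f"line {lineno}: end < start")
                exons.setdefault(parent, []).append(
                    GenomicInterval(chrom, start1 - 1, end1, strand)
                )
    out = []
    for tid in sorted(exons):
        ivs = tuple(sorted(exons[tid], key=lambda e: e.start))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=mrna_gene.get(tid, ""),
                exons=ivs,
                biotype="coding",
            )
        )
    return out


def write_gff3(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write coding transcripts as a minimal gene/mRNA/exon GFF3."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id or t.transcript_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene):
            ts = sorted(by_gene[gid], key=lambda t: t.transcript_id)
            start = min(t.span().start for t in ts)
            end = max(t.span().end for t in ts)
            chrom, strand = ts[0].chrom, ts[0].strand
            fh.write(
                f"{chrom}\tlnckit\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )
            for t in ts:
                span = t.span()
                fh.write(
                    f"{chrom}\tlnckit\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                    f"{strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )
                for i, e in enumerate(t.exons, start=1):
                    fh.write(
                        f"{chrom}\tlnckit\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )


def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`.

    The id is the first whitespace-delimited header token.  ``U`` is
    normalised to ``T`` and the record flagged as RNA.  Duplicate ids and
    empty sequences are errors.
    """
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        out.add(rec.id, str(rec.seq))
    return out


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    """Write a SequenceSet as FASTA (ids sorted); RNA-flagged records are
    written back with ``U``."""
    records = []
    for sid in sorted(seqs.ids()):
        seq = seqs[sid]
        if sid in seqs.rna_ids:
            seq = seq.replace("T", "U")
        records.append(SeqRecord(Seq(seq), id=sid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_counts(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column transcript id, header of sample ids)
    plus a sample sheet TSV (sample_id, tissue, condition, replicate)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample_id" not in sheet.columns:
        raise ValidationError("sample sheet must have a sample_id column")
    return CountMatrix(counts, sheet)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 sheet_path: str | Path) -> None:
    counts = cm.counts.sort_index()
    counts.index.name = "transcript_id"
    counts.to_csv(counts_path, sep="\t")
    sheet = cm.sample_sheet.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sheet_path, sep="\t")


def write_table(records: pd.DataFrame | Sequence, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write tabular records as TSV with a deterministic row order.

    Rows are sorted by the first column, ties broken by the second (when
    present).  Accepts a DataFrame or a sequence of dataclass-like objects
    (anything with ``__dict__`` or ``_asdict``).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if columns is not None:
            df = df[list(columns)]
    else:
        rows = []
        for r in records:
            if hasattr(r, "_asdict"):
                rows.append(r._asdict())
            elif hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows, columns=columns)
        if df.empty and columns is not None:
            df = pd.DataFrame(columns=list(columns))
    if df.shape[1] == 0:
        raise ValidationError("cannot write a table with no columns")
    sort_cols = list(df.columns[: min(2, df.shape[1])])
    if len(df):
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of term_id -> gene_id into a term map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("term map needs at least two columns (term_id, gene_id)")
    term_col, gene_col = df.columns[0], df.columns[1]
    out: dict[str, set[str]] = {}
    for term, gene in zip(df[term_col], df[gene_col]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
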