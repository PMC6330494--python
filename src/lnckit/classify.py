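"""Positional classification of lncRNAs against a reference gene annotation.

Each lncRNA gets exactly one class, decided in a fixed precedence order
(first match wins):

1. **sense** — >= 1 nt of exonic overlap with a gene's exon on the same
   strand (the strongest structural evidence);
2. **antisense** — any overlap with a gene's genomic span on the opposite
   strand;
3. **intronic** — the lncRNA's span lies wholly inside a single intron of a
   same-strand gene;
4. **lincRNA** — none of the above (intergenic).

The supporting gene is the overlapping/containing gene with maximal overlap,
ties broken by the lexicographically smaller gene id, which makes the result
independent of gene input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .identify import LncRNARecord, longest_orf
from .models import SequenceSet, TranscriptModel, ValidationError

CLASSES = ("lincRNA", "antisense", "intronic", "sense")

# Fig-style histogram bin edges (nt) for transcript lengths
LENGTH_BINS = (200, 600, 1000, 1400, 1800, 2200, 2600, 3000)


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    positional_class: str
    supporting_gene_id: str  # empty for lincRNA
    overlap_nt: int

    def __post_init__(self) -> None:
        if self.positional_class not in CLASSES:
            raise ValidationError(f"unknown class {self.positional_class!r}")
        if (self.positional_class == "lincRNA") != (self.supporting_gene_id == ""):
            raise ValidationError("lincRNA iff supporting gene empty")


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Sequence[TranscriptModel]) -> None:
        self.genes = {g.transcript_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            span = g.span()
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                span.start, span.end, g.transcript_id
            )

    def spanning_candidates(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.overlap(start, end)]


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += ea.overlap(eb)
    return total


def classify_lncrna(
    lnc: TranscriptModel, index: GeneIndex | Sequence[TranscriptModel]
) -> ClassificationResult:
    """Classify one lncRNA against the indexed reference genes."""
    if not isinstance(index, GeneIndex):
        index = GeneIndex(index)
    span = lnc.span()
    candidates = index.spanning_candidates(span.chrom, span.start, span.end)
    for g in candidates:
        if g.chrom != lnc.chrom:
            raise AssertionError("interval index returned a cross-chromosome gene")

    def pick(scored: list[tuple[int, str]]) -> tuple[int, str]:
        # maximal overlap, ties by smaller gene id
        return min(scored, key=lambda kv: (-kv[0], kv[1]))

    sense_hits = [
        (_exonic_overlap(lnc, g), g.transcript_id)
        for g in candidates
        if g.strand == lnc.strand and _exonic_overlap(lnc, g) >= 1
    ]
    if sense_hits:
        ov, gid = pick(sense_hits)
        return ClassificationResult(lnc.transcript_id, "sense", gid, ov)

    anti_hits = [
        (span.overlap(g.span()), g.transcript_id)
        for g in candidates
        if g.strand != lnc.strand and span.overlap(g.span()) > 0
    ]
    if anti_hits:
        ov, gid = pick(anti_hits)
        return ClassificationResult(lnc.transcript_id, "antisense", gid, ov)

    intronic_hits = []
    for g in candidates:
        if g.strand != lnc.strand:
            continue
        for intron in g.introns():
            if intron.start <= span.start and span.end <= intron.end:
                intronic_hits.append((len(span), g.transcript_id))
                break
    if intronic_hits:
        ov, gid = pick(intronic_hits)
        return ClassificationResult(lnc.transcript_id, "intronic", gid, ov)

    return ClassificationResult(lnc.transcript_id, "lincRNA", "", 0)


def _histogram(values: Sequence[int], edges: Sequence[int]) -> dict[str, int]:
    """Closed-open bins between consecutive edges plus a final > last-edge bin."""
    out: dict[str, int] = {}
    for lo, hi in zip(edges, edges[1:]):
        out[f"{lo}-{hi}"] = sum(1 for v in values if lo <= v < hi)
    out[f">{edges[-1]}"] = sum(1 for v in values if v >= edges[-1])
    return out


def classify_all(
    lncs: Sequence[LncRNARecord],
    genes: Sequence[TranscriptModel],
    seqs: SequenceSet | None = None,
) -> tuple[list[ClassificationResult], dict]:
    """Classify every lncRNA and summarise composition and structure.

    The summary carries per-class counts, a transcript-length histogram, an
    exon-count histogram, the spliced fraction (share of multi-exon
    transcripts) and, when sequences are supplied, an ORF-length histogram.
    Also sets ``positional_class`` on each input record.
    """
    index = GeneIndex(genes)
    results = []
    for rec in sorted(lncs, key=lambda r: r.transcript_id):
        res = classify_lncrna(rec.transcript, index)
        rec.positional_class = res.positional_class
        results.append(res)

    composition = {c: 0 for c in CLASSES}
    for r in results:
        composition[r.positional_class] += 1
    lengths = [rec.transcript.length for rec in lncs]
    exon_counts = [rec.transcript.n_exons for rec in lncs]
    summary: dict = {
        "composition": composition,
        "n_lncrnas": len(results),
        "length_hist": _histogram(lengths, LENGTH_BINS) if lengths else
            {f"{lo}-{hi}": 0 for lo, hi in zip(LENGTH_BINS, LENGTH_BINS[1:])}
            | {f">{LENGTH_BINS[-1]}": 0},
        "exon_count_hist": {
            str(k): exon_counts.count(k) for k in sorted(set(exon_counts))
        },
        "spliced_fraction": (
            sum(1 for n in exon_counts if n >= 2) / len(exon_counts)
            if exon_counts else 0.0
        ),
    }
    if seqs is not None:
        orf_lens = [
            longest_orf(seqs[rec.transcript_id])
            for rec in lncs
            if rec.transcript_id in seqs
        ]
        summary["orf_length_hist"] = (
            _histogram(orf_lens, (0, 100, 200, 300, 400, 500, 600))
            if orf_lens else {}
        )
    return results, summary


def crosscheck_class_codes(
    results: Sequence[ClassificationResult],
    transcripts: Sequence[TranscriptModel],
) -> list[tuple[str, str, str]]:
    """Compare computed classes against supplied class codes.

    Class codes are trusted when present; this report only surfaces
    disagreements as (transcript_id, class_code, computed_class) triples.
    Expected correspondence: u->lincRNA, x->antisense, i->intronic,
    o/e->sense.
    """
    code_to_class = {"u": "lincRNA", "x": "antisense", "i": "intronic",
                     "o": "sense", "e": "sense"}
    codes = {t.transcript_id: t.class_code for t in transcripts}
    out = []
    for r in results:
        code = codes.get(r.transcript_id)
        if code is None:
            continue
        expected = code_to_class.get(code)
        if expected is not None and expected != r.positional_class:
            out.append((r.transcript_id, code, r.positional_class))
    return out
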