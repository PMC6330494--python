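"""The lncRNA identification cascade.

Candidate transcripts are filtered in four steps: (1) keep only class codes
describing novel/intronic/antisense/overlapping transcripts ({i, x, u, o, e});
(2) drop short transcripts (spliced length <= 200 nt) and single-exon
transcripts; (3) require evidence of expression (max FPKM across samples
>= 0.1); (4) require every configured coding-potential predictor to call the
transcript non-coding (the intersection rule).  Each step is a pure
predicate, so the retained set is independent of step order; only the
attrition log depends on it.

Two coding-potential scorers are built in: a longest-ORF rule (a transcript
with an ORF of >= 300 nt, the conventional 100-codon cutoff, is treated as
coding) and a hexamer log-odds score in the style of frame-free composition
classifiers, trained from example coding and non-coding sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .models import ExpressionMatrix, SequenceSet, TranscriptModel, ValidationError

STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_CLASS_CODES = frozenset("ixuoe")


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the candidate filter cascade.

    ``min_length=201`` encodes "length <= 200 nt removed";
    ``min_exons=2`` removes single-exon transcripts; ``min_fpkm`` is an
    inclusive lower bound on the max-over-samples FPKM.
    """

    allowed_class_codes: frozenset[str] = DEFAULT_CLASS_CODES
    min_length: int = 201
    min_exons: int = 2
    min_fpkm: float = 0.1

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if self.min_fpkm < 0:
            raise ValidationError("min_fpkm must be >= 0")


@dataclass(frozen=True)
class CodingVerdict:
    transcript_id: str
    predictor_name: str
    score: float
    is_coding: bool


@dataclass
class LncRNARecord:
    """A transcript that survived the full cascade, with its verdicts."""

    transcript: TranscriptModel
    verdicts: tuple[CodingVerdict, ...]
    positional_class: str | None = None

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def filter_candidates(
    transcripts: Sequence[TranscriptModel],
    fpkm: ExpressionMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Apply the class-code / length / exon-count / FPKM gates.

    Returns the retained transcripts (input order preserved) and an
    attrition log: transcripts removed at each step, steps applied in the
    order class_code, length, exon_count, fpkm.

    Raises
    ------
    ValidationError
        If a transcript has no class code or is missing from ``fpkm``.
    """
    max_fpkm = fpkm.max_per_transcript()
    for t in transcripts:
        if t.class_code is None:
            raise ValidationError(f"{t.transcript_id}: missing class_code")
        if t.transcript_id not in max_fpkm.index:
            raise ValidationError(f"{t.transcript_id}: no FPKM values")
    attrition = {"class_code": 0, "length": 0, "exon_count": 0, "fpkm": 0}
    kept = []
    for t in transcripts:
        if t.class_code not in thresholds.allowed_class_codes:
            attrition["class_code"] += 1
        elif t.length < thresholds.min_length:
            attrition["length"] += 1
        elif t.n_exons < thresholds.min_exons:
            attrition["exon_count"] += 1
        elif max_fpkm[t.transcript_id] < thresholds.min_fpkm:
            attrition["fpkm"] += 1
        else:
            kept.append(t)
    return kept, attrition


def longest_orf_span(seq: str) -> tuple[int, int]:
    """(start, end) of the longest open reading frame in the three forward
    frames; (0, 0) when there is none.

    An ORF runs from an ATG through its stop codon (inclusive); an
    ATG-initiated frame that reaches the sequence end without a stop is
    counted up to the last complete codon.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"illegal characters in sequence: {sorted(bad)}")
    best = (0, 0)
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                if pos + 3 - start > best[1] - best[0]:
                    best = (start, pos + 3)
                start = None
        if start is not None:
            end = start + ((n - start) // 3) * 3
            if end - start > best[1] - best[0]:
                best = (start, end)
    return best


def longest_orf(seq: str) -> int:
    """Length in nt of the longest forward-frame ORF (see
    :func:`longest_orf_span`)."""
    s, e = longest_orf_span(seq)
    return e - s


def coding_potential_orf(
    transcript_id: str, seq: str, min_orf_nt: int = 300
) -> CodingVerdict:
    """ORF-length coding call: coding iff the longest ORF is >= ``min_orf_nt``."""
    if not seq:
        raise ValidationError("empty sequence")
    score = longest_orf(seq)
    return CodingVerdict(transcript_id, "orf", float(score), score >= min_orf_nt)


ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}


def _hexamer_counts(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(4096)
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        for i in range(len(s) - 5):
            idx = _HEX_INDEX.get(s[i : i + 6])
            if idx is not None:  # windows containing N are skipped
                counts[idx] += 1
    return counts


def train_hexamer_model(
    coding_seqs: Iterable[str],
    noncoding_seqs: Iterable[str],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Train a 4096-entry hexamer log-odds table log(P_coding/P_noncoding).

    Both hexamer frequency tables are pseudocount-smoothed so every hexamer
    has positive probability under both models.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    c = _hexamer_counts(coding_seqs) + pseudocount
    nc = _hexamer_counts(noncoding_seqs) + pseudocount
    return np.log(c / c.sum()) - np.log(nc / nc.sum())


def hexamer_score(seq: str, model: np.ndarray) -> float:
    """Mean hexamer log-odds over all sliding windows of the sequence."""
    if len(seq) < 6:
        raise ValidationError("sequence shorter than 6 nt")
    model = np.asarray(model, dtype=float)
    if model.shape != (4096,):
        raise ValidationError("hexamer model must cover all 4096 hexamers")
    s = seq.upper().replace("U", "T")
    vals = []
    for i in range(len(s) - 5):
        idx = _HEX_INDEX.get(s[i : i + 6])
        if idx is not None:
            vals.append(model[idx])
    if not vals:
        raise ValidationError("no scoreable hexamer windows (all contain N)")
    return float(np.mean(vals))


def coding_potential_hexamer(
    transcript_id: str, seq: str, model: np.ndarray, threshold: float = 0.0
) -> CodingVerdict:
    """Hexamer-composition coding call: coding iff mean log-odds > threshold."""
    score = hexamer_score(seq, model)
    return CodingVerdict(transcript_id, "hexamer", score, score > threshold)


# A predictor maps (transcript_id, sequence) -> CodingVerdict.
Predictor = Callable[[str, str], CodingVerdict]


def run_predictors(
    candidates: Sequence[TranscriptModel],
    seqs: SequenceSet,
    predictors: Mapping[str, Predictor],
) -> list[CodingVerdict]:
    """Score every candidate with every predictor."""
    verdicts = []
    for t in candidates:
        if t.transcript_id not in seqs:
            raise ValidationError(f"{t.transcript_id}: no sequence")
        for name, pred in predictors.items():
            v = pred(t.transcript_id, seqs[t.transcript_id])
            if v.predictor_name != name:
                v = CodingVerdict(v.transcript_id, name, v.score, v.is_coding)
            verdicts.append(v)
    return verdicts


def intersect_noncoding(
    candidates: Sequence[TranscriptModel],
    verdicts: Sequence[CodingVerdict],
    required_predictors: Sequence[str],
) -> list[LncRNARecord]:
    """Keep a candidate iff *all* required predictors call it non-coding.

    This is the intersection rule: each predictor produces a set of putative
    non-coding transcripts and only the intersection of those sets is
    reported as lncRNA.  Output is sorted by transcript id.
    """
    if not required_predictors:
        raise ValidationError("at least one predictor must be required")
    by_tx: dict[str, dict[str, CodingVerdict]] = {}
    for v in verdicts:
        slot = by_tx.setdefault(v.transcript_id, {})
        if v.predictor_name in slot:
            raise ValidationError(
                f"duplicate verdict for ({v.transcript_id}, {v.predictor_name})"
            )
        slot[v.predictor_name] = v
    out = []
    for t in sorted(candidates, key=lambda t: t.transcript_id):
        slot = by_tx.get(t.transcript_id, {})
        vs = []
        for name in required_predictors:
            if name not in slot:
                raise ValidationError(
                    f"missing verdict for ({t.transcript_id}, {name})"
                )
            vs.append(slot[name])
        if all(not v.is_coding for v in vs):
            out.append(LncRNARecord(transcript=t, verdicts=tuple(vs)))
    return out
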