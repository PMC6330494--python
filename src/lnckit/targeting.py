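"""Cis/trans target prediction and miRNA target-mimic scanning.

*Cis* targets are protein-coding genes whose genomic span lies less than a
window (default 100 kb) from the lncRNA's span, on either side and on either
strand.

*Trans* targets are mRNAs that can base-pair extensively with an antisense
lncRNA.  Pairing is scored with a simple position-wise pseudo-energy
(GC -3, AT -2, G:T wobble -1, otherwise 0) over a gapless window, normalised
by window length (ndG); candidate pairs are reported when the best window is
at least ``min_len`` nt and its ndG falls at or below a cutoff.

*Target mimics* are lncRNA loci that pair a mature miRNA nearly perfectly:
fewer than three mismatches in a gapless antiparallel alignment, with G:U
wobble pairs tolerated (counted separately, half a mismatch in the ranking
score).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np

from .identify import LncRNARecord
from .models import SequenceSet, TranscriptModel, ValidationError, revcomp

PAIR_CAP = 200  # nt; longest pairing window considered

# pseudo-energy per aligned position: keys are (lnc base, revcomp(mRNA) base)
_GC, _AT, _WOBBLE = -3.0, -2.0, -1.0


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    gap_nt: int
    relative_position: str  # upstream | downstream | overlapping


@dataclass(frozen=True)
class TransPair:
    lncrna_id: str
    mrna_id: str
    dG: float
    ndG: float
    paired_len: int


@dataclass(frozen=True)
class MimicHit:
    lncrna_id: str
    mirna_id: str
    offset: int
    mismatches: int
    gu_pairs: int

    @property
    def score(self) -> float:
        return self.mismatches + 0.5 * self.gu_pairs


def cis_targets(
    lncs: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    window_nt: int = 100_000,
) -> list[CisPair]:
    """Genes within ``window_nt`` (strict <) of each lncRNA's genomic span.

    Strand-agnostic; the gap is measured between spans (0 when they
    overlap).  ``relative_position`` locates the gene on the + genomic axis
    with respect to the lncRNA.  Output sorted by (lncrna_id, gap, gene_id).
    """
    if window_nt < 0:
        raise ValidationError("window must be >= 0")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for lnc in lncs:
        lspan = lnc.span()
        for g in by_chrom.get(lnc.chrom, []):
            gspan = g.span()
            gap = lspan.gap_to(gspan)
            if gap >= window_nt:
                continue
            if lspan.overlap(gspan) > 0:
                rel = "overlapping"
            elif gspan.start >= lspan.end:
                rel = "downstream"
            else:
                rel = "upstream"
            out.append(CisPair(lnc.transcript_id, g.transcript_id, gap, rel))
    out.sort(key=lambda p: (p.lncrna_id, p.gap_nt, p.gene_id))
    return out


_SCORE_TABLE = np.zeros((5, 5))
_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}
# lnc base vs revcomp(mRNA) base: equality means a Watson-Crick pair
for _b, _e in (("G", _GC), ("C", _GC), ("A", _AT), ("T", _AT)):
    _SCORE_TABLE[_BASE_INDEX[_b], _BASE_INDEX[_b]] = _e
# wobble G:U == lnc G vs mRNA T (revcomp A), or lnc T vs mRNA G (revcomp C)
_SCORE_TABLE[_BASE_INDEX["G"], _BASE_INDEX["A"]] = _WOBBLE
_SCORE_TABLE[_BASE_INDEX["T"], _BASE_INDEX["C"]] = _WOBBLE

_SCORE_TABLE_I16 = _SCORE_TABLE.astype(np.int16)  # scores are small integers


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as e:
        raise ValidationError(f"illegal base {e.args[0]!r}") from None


def pairing_energy(lnc_window: str, mrna_window: str) -> tuple[float, float, int]:
    """Position-wise pairing pseudo-energy of two equal-length windows.

    The mRNA window is given in its native 5'->3' orientation; pairing is
    antiparallel, so it is compared against the lncRNA window through its
    reverse complement.  Returns (dG, ndG, window length) with
    ``ndG = dG / length``.
    """
    if len(lnc_window) != len(mrna_window):
        raise ValidationError("pairing windows must have equal length")
    if not lnc_window:
        raise ValidationError("empty pairing window")
    a = _encode(lnc_window.upper())
    b = _encode(revcomp(mrna_window.upper()))
    dg = float(_SCORE_TABLE[a, b].sum())
    return dg, dg / len(lnc_window), len(lnc_window)


def _best_window(lnc: str, mrna: str, length: int) -> tuple[float, float, int]:
    """Most negative ndG over all (lnc offset, mRNA offset) window pairs.

    The per-position score matrix ``M[i, j]`` (lnc position i against
    reverse-complemented mRNA position j) is prefix-summed along its
    diagonals, so every length-``length`` gapless window sum is available in
    O(n*m) total instead of enumerating window pairs.
    """
    a = _encode(lnc.upper())
    rc = _encode(revcomp(mrna.upper()))
    n, m = a.size, rc.size
    L = length
    M = _SCORE_TABLE_I16[a[:, None], rc[None, :]]
    # skew the matrix so each diagonal j - i becomes a column, then a single
    # cumulative sum along rows yields every gapless window sum
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :] - rows + (n - 1)
    acc = np.int16 if 3 * n < 32_000 else np.int64  # cumsum head-room
    B = np.zeros((n, n + m - 1), dtype=acc)
    B[np.broadcast_to(rows, M.shape), cols] = M
    C = np.zeros((n + 1, n + m - 1), dtype=acc)
    np.cumsum(B, axis=0, out=C[1:])
    S = C[L:, :] - C[:-L, :]
    i_idx = np.arange(n - L + 1)[:, None]
    c_idx = np.arange(m - L + 1)[None, :] - i_idx + (n - 1)
    best = float(S[i_idx, c_idx].min())
    return best, best / L, L


def trans_targets(
    antisense_lncs: Sequence[LncRNARecord],
    lnc_seqs: SequenceSet,
    mrnas: SequenceSet,
    ndG_max: float = -0.1,
    min_len: int = 20,
) -> list[TransPair]:
    """Antisense-lncRNA / mRNA pairs with strong best-window pairing.

    Only records classified ``antisense`` are eligible; others are skipped
    with a warning.  For each eligible pair the gapless pairing window of
    length ``min(|lnc|, |mRNA|, 200)`` is slid over both sequences and the
    most negative ndG kept; the pair is reported iff ``ndG <= ndG_max`` and
    the window is at least ``min_len`` nt.
    """
    out = []
    for rec in antisense_lncs:
        if rec.positional_class != "antisense":
            warnings.warn(
                f"{rec.transcript_id}: not an antisense lncRNA, skipped from "
                "trans-target scan"
            )
            continue
        if rec.transcript_id not in lnc_seqs:
            raise ValidationError(f"{rec.transcript_id}: no sequence")
        lseq = lnc_seqs[rec.transcript_id]
        if not lseq:
            raise ValidationError(f"{rec.transcript_id}: empty sequence")
        for mid in sorted(mrnas.ids()):
            mseq = mrnas[mid]
            length = min(len(lseq), len(mseq), PAIR_CAP)
            if length < min_len:
                continue
            dg, ndg, plen = _best_window(lseq, mseq, length)
            if ndg <= ndG_max:
                out.append(TransPair(rec.transcript_id, mid, dg, ndg, plen))
    out.sort(key=lambda p: (p.lncrna_id, p.ndG, p.mrna_id))
    return out


def _pair_counts(site: str, rc_mirna: str, allow_gu: bool) -> tuple[int, int]:
    """(mismatches, gu_pairs) of a gapless site/miRNA alignment.

    ``site`` is the lncRNA subsequence 5'->3'; ``rc_mirna`` the reverse
    complement of the miRNA, so equality is a Watson-Crick pair.  A G:U
    wobble shows up as site G against rc A, or site T against rc C.
    """
    mm = gu = 0
    for s, r in zip(site, rc_mirna):
        if s == r and s != "N":
            continue
        if (s == "G" and r == "A") or (s == "T" and r == "C"):
            if allow_gu:
                gu += 1
            else:
                mm += 1
        else:
            mm += 1
    return mm, gu


def scan_mimics(
    lncrna_id: str,
    lnc_seq: str,
    mirna_id: str,
    mirna_seq: str,
    max_mismatches: int = 3,
    allow_gu: bool = True,
) -> list[MimicHit]:
    """All target-mimic sites of a miRNA on a lncRNA.

    Every offset where the lncRNA subsequence pairs the reverse-oriented
    miRNA with ``mismatches < max_mismatches`` (strict) is reported, best
    score first (score = mismatches + 0.5 * G:U pairs; ties by offset).
    With ``allow_gu`` false, wobble positions count as mismatches.
    """
    lnc = lnc_seq.upper().replace("U", "T")
    mir = mirna_seq.upper().replace("U", "T")
    if len(mir) > len(lnc):
        raise ValidationError("miRNA longer than lncRNA")
    if max_mismatches >= len(mir):
        raise ValidationError("mismatch allowance must be below miRNA length")
    rc = revcomp(mir)
    hits = []
    for off in range(len(lnc) - len(mir) + 1):
        mm, gu = _pair_counts(lnc[off : off + len(mir)], rc, allow_gu)
        if mm < max_mismatches:
            hits.append(MimicHit(lncrna_id, mirna_id, off, mm, gu))
    hits.sort(key=lambda h: (h.score, h.offset))
    return hits


def scan_all_mimics(
    lnc_seqs: SequenceSet,
    mirnas: SequenceSet,
    max_mismatches: int = 3,
    allow_gu: bool = True,
) -> list[MimicHit]:
    """Mimic scan of every lncRNA against every miRNA (sorted output)."""
    hits: list[MimicHit] = []
    for lid in sorted(lnc_seqs.ids()):
        for mid in sorted(mirnas.ids()):
            if len(mirnas[mid]) > len(lnc_seqs[lid]):
                continue
            hits.extend(
                scan_mimics(lid, lnc_seqs[lid], mid, mirnas[mid],
                            max_mismatches, allow_gu)
            )
    hits.sort(key=lambda h: (h.lncrna_id, h.mirna_id, h.offset))
    return hits
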