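"""Cis windows, pairing energy, trans scanning and mimic detection."""

import numpy as np
import pytest

from lnckit.identify import LncRNARecord
from lnckit.models import GenomicInterval, SequenceSet, TranscriptModel, \
    ValidationError, revcomp
from lnckit.targeting import (
    cis_targets,
    pairing_energy,
    scan_all_mimics,
    scan_mimics,
    trans_targets,
)


def span_tx(tid, start, end, strand="+", biotype="candidate"):
    return TranscriptModel(
        tid, tid, (GenomicInterval("chr1", start, end, strand),),
        biotype=biotype,
    )


class TestCisTargets:
    def test_gap_and_relative_position(self):
        lnc = span_tx("l1", 10_000, 11_000)
        gene = span_tx("g1", 50_000, 60_000, biotype="coding")
        (pair,) = cis_targets([lnc], [gene])
        assert pair.gap_nt == 39_000
        assert pair.relative_position == "downstream"

    def test_window_boundary_is_strict(self):
        lnc = span_tx("l1", 0, 1000)
        at_window = span_tx("g1", 101_000, 102_000, biotype="coding")
        inside = span_tx("g2", 100_999, 102_000, biotype="coding")
        pairs = cis_targets([lnc], [at_window, inside])
        assert [p.gene_id for p in pairs] == ["g2"]
        assert pairs[0].gap_nt == 99_999

    def test_overlap_counts_as_gap_zero(self):
        lnc = span_tx("l1", 10_000, 12_000)
        gene = span_tx("g1", 11_000, 13_000, biotype="coding")
        (pair,) = cis_targets([lnc], [gene])
        assert pair.gap_nt == 0 and pair.relative_position == "overlapping"

    def test_matches_quadratic_brute_force_on_random_features(self):
        rng = np.random.default_rng(17)
        chroms = ["chr1", "chr2"]
        lncs, genes = [], []
        for i in range(150):
            c = chroms[int(rng.integers(0, 2))]
            s = int(rng.integers(0, 2_000_000))
            t = TranscriptModel(f"l{i:03d}", "", (GenomicInterval(c, s, s + 500, "+"),))
            lncs.append(t)
        for i in range(150):
            c = chroms[int(rng.integers(0, 2))]
            s = int(rng.integers(0, 2_000_000))
            genes.append(TranscriptModel(
                f"g{i:03d}", f"g{i:03d}",
                (GenomicInterval(c, s, s + 2000, "+"),), biotype="coding"))
        got = {(p.lncrna_id, p.gene_id) for p in cis_targets(lncs, genes)}
        expected = set()
        for l in lncs:
            for g in genes:
                if l.chrom != g.chrom:
                    continue
                if l.span().gap_to(g.span()) < 100_000:
                    expected.add((l.transcript_id, g.transcript_id))
        assert got == expected

    def test_negative_window_rejected(self):
        with pytest.raises(ValidationError):
            cis_targets([], [], window_nt=-1)


class TestPairingEnergy:
    def test_all_gc_window(self):
        lnc = "G" * 20
        mrna = "C" * 20  # revcomp -> G, pairs G:C at every position
        dg, ndg, n = pairing_energy(lnc, mrna)
        assert (dg, ndg, n) == (-60.0, -3.0, 20)

    def test_at_pairs_and_no_complementarity(self):
        _, ndg, _ = pairing_energy("A" * 15, "T" * 15)  # A:T at every position
        assert ndg == -2.0
        dg, ndg, _ = pairing_energy("A" * 15, "A" * 15)  # A:A never pairs
        assert (dg, ndg) == (0.0, 0.0)

    def test_matches_positionwise_reference_on_random_pairs(self):
        rng = np.random.default_rng(23)
        table = {("G", "C"): -3, ("C", "G"): -3, ("A", "T"): -2, ("T", "A"): -2,
                 ("G", "T"): -1, ("T", "G"): -1}
        for _ in range(25):
            a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            dg, ndg, n = pairing_energy(a, b)
            # independent evaluation: pair a[k] against b[L-1-k] directly
            expected = sum(table.get((x, y), 0)
                           for x, y in zip(a, b[::-1]))
            assert dg == expected and n == 50

    def test_symmetric_under_window_swap(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            assert pairing_energy(a, b)[0] == pairing_energy(b, a)[0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pairing_energy("ACGT", "ACG")


def rec_for(tid, cls):
    t = span_tx(tid, 0, 100)
    r = LncRNARecord(transcript=t, verdicts=())
    r.positional_class = cls
    return r


class TestTransTargets:
    def test_perfect_complement_reported_with_strong_ndg(self):
        rng = np.random.default_rng(31)
        m = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        lnc_seqs = SequenceSet({"l1": revcomp(m)})
        mrnas = SequenceSet({"m1": m})
        pairs = trans_targets([rec_for("l1", "antisense")], lnc_seqs, mrnas)
        assert len(pairs) == 1
        assert pairs[0].ndG <= -2.0

    def test_non_antisense_input_skipped_with_warning(self):
        lnc_seqs = SequenceSet({"l1": "ACGT" * 30})
        mrnas = SequenceSet({"m1": "ACGT" * 30})
        with pytest.warns(UserWarning, match="not an antisense"):
            pairs = trans_targets([rec_for("l1", "lincRNA")], lnc_seqs, mrnas)
        assert pairs == []

    def test_best_window_matches_exhaustive_offset_scan(self):
        rng = np.random.default_rng(37)
        lnc = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        m = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        lnc_seqs = SequenceSet({"l1": lnc})
        mrnas = SequenceSet({"m1": m})
        pairs = trans_targets([rec_for("l1", "antisense")], lnc_seqs, mrnas,
                              ndG_max=0.0)
        L = 60
        best = min(
            pairing_energy(lnc, m[j : j + L])[0]
            for j in range(len(m) - L + 1)
        )
        assert pairs and pairs[0].dG == best


def oracle_mimic_counts(site, mirna, allow_gu=True):
    """Independent per-position evaluation: site[k] pairs mirna[L-1-k]."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "T"), ("T", "G")}
    mm = gu = 0
    for k in range(len(mirna)):
        pair = (site[k], mirna[len(mirna) - 1 - k])
        if pair in wc:
            continue
        if pair in wob and allow_gu:
            gu += 1
        else:
            mm += 1
    return mm, gu


class TestScanMimics:
    def test_perfect_site_detected(self):
        mir = "TGACGAGGATTGACGAGGATT"
        lnc = "A" * 50 + revcomp(mir) + "A" * 50
        hits = scan_mimics("l", lnc, "m", mir)
        assert hits[0].offset == 50
        assert hits[0].mismatches == 0 and hits[0].gu_pairs == 0

    def test_planted_sites_recovered_and_threshold_enforced(self, sim_dataset):
        lnc_seqs = SequenceSet(
            {t.transcript_id: sim_dataset.seqs[t.transcript_id]
             for t in sim_dataset.lncs})
        for ms in sim_dataset.truth.mimic_sites:
            hits = scan_mimics(ms.lncrna_id, lnc_seqs[ms.lncrna_id],
                               ms.mirna_id, sim_dataset.mirnas[ms.mirna_id])
            at = [h for h in hits if h.offset == ms.offset]
            if ms.mismatches < 3:
                assert len(at) == 1
                assert (at[0].mismatches, at[0].gu_pairs) == \
                    (ms.mismatches, ms.gu_pairs)
            else:
                assert at == []  # negative control: 3 mismatches rejected

    def test_gu_counted_separately_not_as_mismatch(self):
        mir = "AAACCCGGGTTTAAACCCGGG"
        site = list(revcomp(mir))
        # two wobble edits: G where a Watson-Crick A would sit, T where C would
        idx_a = site.index("A"); site[idx_a] = "G"
        idx_c = site.index("C"); site[idx_c] = "T"
        lnc = "C" * 30 + "".join(site) + "C" * 30
        hits = scan_mimics("l", lnc, "m", mir)
        best = hits[0]
        assert best.offset == 30
        assert best.mismatches == 0 and best.gu_pairs == 2
        # without wobble tolerance the same site carries 2 mismatches
        strict = scan_mimics("l", lnc, "m", mir, allow_gu=False)
        at = [h for h in strict if h.offset == 30]
        assert at and at[0].mismatches == 2

    def test_matches_brute_force_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            lnc = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
            mir = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 21)])
            hits = {h.offset: (h.mismatches, h.gu_pairs)
                    for h in scan_mimics("l", lnc, "m", mir, max_mismatches=12)}
            expected = {}
            for off in range(1000 - 21 + 1):
                mm, gu = oracle_mimic_counts(lnc[off : off + 21], mir)
                if mm < 12:
                    expected[off] = (mm, gu)
            assert hits == expected

    def test_reverse_complement_scan_mirrors_offsets(self):
        mir = "TGACGAGGATTGACGAGGATT"
        lnc = "A" * 40 + revcomp(mir) + "A" * 60
        fwd = scan_mimics("l", lnc, "m", mir)
        # on the reverse complement of the lncRNA the site becomes the
        # miRNA itself, pairing the reverse-complemented miRNA
        rev = scan_mimics("l", revcomp(lnc), "m", revcomp(mir))
        n = len(lnc) - len(mir)
        assert {h.offset for h in fwd} == {n - h.offset for h in rev}

    def test_mirna_longer_than_lncrna_rejected(self):
        with pytest.raises(ValidationError):
            scan_mimics("l", "ACGT", "m", "ACGTACGTA")

    def test_scan_all_covers_every_pair(self, sim_dataset):
        lnc_seqs = SequenceSet(
            {t.transcript_id: sim_dataset.seqs[t.transcript_id]
             for t in sim_dataset.lncs})
        hits = scan_all_mimics(lnc_seqs, sim_dataset.mirnas)
        planted = {(m.lncrna_id, m.mirna_id, m.offset)
                   for m in sim_dataset.truth.mimic_sites if m.mismatches < 3}
        assert planted <= {(h.lncrna_id, h.mirna_id, h.offset) for h in hits}
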