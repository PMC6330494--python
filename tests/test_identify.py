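"""Filter cascade, coding-potential scorers and the intersection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lnckit.identify import (
    CodingVerdict,
    FilterThresholds,
    coding_potential_orf,
    filter_candidates,
    hexamer_score,
    intersect_noncoding,
    longest_orf,
    train_hexamer_model,
)
from lnckit.models import (
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)
from conftest import single_exon


def two_exon(tid: str, length: int, code: str = "u") -> TranscriptModel:
    half = length // 2
    return TranscriptModel(
        tid, "",
        (GenomicInterval("chr1", 0, half, "+"),
         GenomicInterval("chr1", half + 100, length + 100, "+")),
        class_code=code,
    )


def expr_for(values: dict[str, float]) -> ExpressionMatrix:
    df = pd.DataFrame({"s1": values, "s2": {k: 0.0 for k in values}})
    sheet = pd.DataFrame(
        {"sample_id": ["s1", "s2"], "tissue": ["root", "root"],
         "condition": ["CK", "SS"], "replicate": [1, 1]}
    ).set_index("sample_id")
    return ExpressionMatrix(df, sheet)


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "transcript, fpkm, kept, step",
        [
            (two_exon("t", 300, code="="), 5.0, False, "class_code"),
            (two_exon("t", 300, code="j"), 5.0, False, "class_code"),
            (two_exon("t", 200), 5.0, False, "length"),
            (two_exon("t", 201), 5.0, True, None),
            (single_exon("t", length=300, class_code="u"), 5.0, False, "exon_count"),
            (two_exon("t", 300), 0.0999, False, "fpkm"),
            (two_exon("t", 300), 0.1, True, None),  # boundary inclusive
        ],
        ids=["ref-match-code", "novel-isoform-code", "len200", "len201",
             "single-exon", "fpkm-below", "fpkm-boundary"],
    )
    def test_threshold_boundaries(self, transcript, fpkm, kept, step):
        for code in "ixuoe":
            if transcript.class_code == code:
                break
        retained, attrition = filter_candidates(
            [transcript], expr_for({"t": fpkm})
        )
        assert (len(retained) == 1) is kept
        if step is not None:
            assert attrition[step] == 1

    def test_every_allowed_class_code_passes_step_one(self):
        for code in "ixuoe":
            t = two_exon("t", 400, code=code)
            retained, _ = filter_candidates([t], expr_for({"t": 1.0}))
            assert retained, code

    def test_attrition_counts_sum_to_removed(self):
        ts = [two_exon(f"t{i}", 150 + 30 * i, code=c)
              for i, c in enumerate("=iuxj")]
        fpkm = expr_for({t.transcript_id: 0.5 for t in ts})
        retained, attrition = filter_candidates(ts, fpkm)
        assert sum(attrition.values()) == len(ts) - len(retained)

    def test_membership_is_order_independent(self):
        """Each gate is a pure predicate, so the retained set must not
        depend on which gate fires first; check against an explicit
        conjunction of the predicates."""
        ts = [two_exon(f"t{i}", 180 + 7 * i, code=c)
              for i, c in enumerate("iuxo=ju")] + [
            single_exon("t_single", length=400, class_code="u")]
        vals = {t.transcript_id: (0.05 + 0.02 * i) for i, t in enumerate(ts)}
        fpkm = expr_for(vals)
        retained, _ = filter_candidates(ts, fpkm)
        th = FilterThresholds()
        expected = {
            t.transcript_id for t in ts
            if t.class_code in th.allowed_class_codes
            and t.length >= th.min_length
            and t.n_exons >= th.min_exons
            and max(vals[t.transcript_id], 0.0) >= th.min_fpkm
        }
        assert {t.transcript_id for t in retained} == expected

    def test_missing_fpkm_is_an_error(self):
        with pytest.raises(ValidationError, match="t1"):
            filter_candidates([two_exon("t1", 300)], expr_for({"other": 1.0}))


def brute_force_orf(seq: str) -> int:
    """Exhaustive enumeration of every ATG..stop span in 3 forward frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
            j += 3
        else:
            best = max(best, ((len(seq) - i) // 3) * 3)
    return best


class TestOrfScorer:
    def test_long_orf_is_coding(self):
        seq = "CC" + "ATG" + "GCT" * 120 + "TAA" + "GG"
        v = coding_potential_orf("t", seq)
        assert v.is_coding and v.score >= 350

    def test_all_stop_tiling_scores_zero(self):
        v = coding_potential_orf("t", "TAATAATAA" * 30)
        assert v.score == 0 and not v.is_coding

    def test_matches_exhaustive_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 250)])
            assert longest_orf(seq) == brute_force_orf(seq)

    def test_illegal_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            coding_potential_orf("t", "ACGTXZ")


class TestHexamerScorer:
    def test_identical_tables_score_zero(self):
        model = np.zeros(4096)  # log(P/P) for equal distributions
        assert hexamer_score("ACGTACGTACGT", model) == 0.0

    def test_single_hexamer_sequence_takes_table_value(self):
        model = np.zeros(4096)
        model[0] = 1.0  # AAAAAA
        assert hexamer_score("AAAAAAA", model) == 1.0  # both windows are AAAAAA

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            hexamer_score("ACGT", np.zeros(4096))

    def test_separates_simulated_coding_from_noncoding(self, sim_dataset):
        """Trained on the generator's planted coding vs non-coding
        sequences, the score must separate the two sets with AUC > 0.9."""
        coding = [sim_dataset.seqs[g.transcript_id] for g in sim_dataset.genes]
        noncoding = [sim_dataset.seqs[t.transcript_id] for t in sim_dataset.lncs]
        model = train_hexamer_model(coding, noncoding)
        s_cod = [hexamer_score(s, model) for s in coding]
        s_non = [hexamer_score(s, model) for s in noncoding]
        # AUC via the rank-sum statistic
        wins = sum((c > n) + 0.5 * (c == n) for c in s_cod for n in s_non)
        auc = wins / (len(s_cod) * len(s_non))
        assert auc > 0.9


class TestIntersectNoncoding:
    def vd(self, tid, name, coding):
        return CodingVerdict(tid, name, 0.0, coding)

    def test_unanimous_noncoding_retained(self):
        t = two_exon("t1", 300)
        recs = intersect_noncoding(
            [t], [self.vd("t1", "a", False), self.vd("t1", "b", False)], ["a", "b"]
        )
        assert [r.transcript_id for r in recs] == ["t1"]

    def test_single_coding_vote_excludes(self):
        t = two_exon("t1", 300)
        recs = intersect_noncoding(
            [t], [self.vd("t1", "a", False), self.vd("t1", "b", True)], ["a", "b"]
        )
        assert recs == []

    def test_zero_predictors_is_degenerate(self):
        with pytest.raises(ValidationError):
            intersect_noncoding([two_exon("t1", 300)], [], [])

    def test_missing_verdict_names_pair(self):
        with pytest.raises(ValidationError, match=r"t1.*b"):
            intersect_noncoding(
                [two_exon("t1", 300)], [self.vd("t1", "a", False)], ["a", "b"]
            )

    def test_duplicate_verdict_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            intersect_noncoding(
                [two_exon("t1", 300)],
                [self.vd("t1", "a", False), self.vd("t1", "a", False)], ["a"]
            )

    @given(votes=st.lists(st.tuples(st.booleans(), st.booleans()),
                          min_size=1, max_size=8))
    def test_retained_iff_all_noncoding(self, votes):
        ts = [two_exon(f"t{i}", 300) for i in range(len(votes))]
        verdicts = []
        for t, (a, b) in zip(ts, votes):
            verdicts += [self.vd(t.transcript_id, "a", a),
                         self.vd(t.transcript_id, "b", b)]
        recs = intersect_noncoding(ts, verdicts, ["a", "b"])
        expected = sorted(
            t.transcript_id for t, (a, b) in zip(ts, votes) if not a and not b
        )
        assert [r.transcript_id for r in recs] == expected


class TestCascadeOnSyntheticData:
    def test_planted_truth_recovered_end_to_end(self, sim_dataset):
        """All planted lncRNAs survive the cascade; all coding genes are
        removed (class-code gate) and would also fail the ORF gate."""
        from lnckit.pipeline import identify_lncrnas

        records, attrition, _ = identify_lncrnas(
            sim_dataset.transcripts, sim_dataset.seqs, sim_dataset.counts
        )
        got = {r.transcript_id for r in records}
        assert got == set(sim_dataset.truth.lncrna_classes)
        assert attrition["class_code"] == len(sim_dataset.genes)

    def test_coding_genes_fail_orf_gate_directly(self, sim_dataset):
        for g in sim_dataset.genes:
            v = coding_potential_orf(g.transcript_id,
                                     sim_dataset.seqs[g.transcript_id])
            assert v.is_coding
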