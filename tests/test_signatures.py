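"""Signature assembly, serialization, refinement, evaluation, selection."""

import itertools

import pytest
from hypothesis import given, strategies as st

from barcodesig.patterns import DiscriminatingSite, Pattern
from barcodesig.records import BarcodeError, BarcodeRecord
from barcodesig.signatures import (
    EvaluationReport,
    Signature,
    assemble_signature,
    categorize,
    diagnose_gap_breaks,
    evaluate_signature,
    incorporate_site,
    parse_signature,
    refine_signature,
    select_candidate,
    serialize_signature,
)


def sig_from(starts_literals, species="Croton gratissimus", exemplar="EU214230.1",
             tolerance=0):
    pats = [Pattern(start=s, literal=l) for s, l in starts_literals]
    return assemble_signature(species, pats, exemplar_id=exemplar, tolerance=tolerance)


class TestAssemble:
    def test_exact_gap_arithmetic_and_regex(self):
        sig = sig_from([(39, "GTCTTGGAATAGG"), (129, "TTCTCATGT")])
        assert sig.gaps == (77,)  # 129 - (39 + 13)
        assert sig.regex == "GTCTTGGAATAGG.{77}TTCTCATGT"

    def test_single_pattern_signature(self):
        sig = sig_from([(10, "ACGTACG")])
        assert sig.gaps == ()
        assert sig.regex == "ACGTACG"

    def test_span_of_full_croton_geometry(self):
        # first pattern starts at 39, last ends at 742 -> 704 bp span
        sig = sig_from([(39, "GTCTTGGAATAGG"), (129, "TTCTCATGT"), (735, "ACGTACGT")])
        start, end, length = sig.span
        assert (start, end) == (39, 742)
        assert length == 704

    def test_overlapping_patterns_rejected(self):
        with pytest.raises(BarcodeError, match="overlap"):
            sig_from([(10, "ACGTACGT"), (12, "GTAC")])

    def test_unsorted_patterns_sorted_with_warning(self):
        with pytest.warns(UserWarning, match="sort"):
            sig = sig_from([(50, "ACGT"), (10, "GGGG")])
        assert sig.patterns[0].start == 10

    def test_gap_tolerance_regex_dialect(self):
        sig = sig_from([(1, "ACGT"), (10, "GGGG")], tolerance=1)
        assert sig.regex == "ACGT.{4,6}GGGG"


class TestSerialization:
    def test_two_line_format(self):
        sig = sig_from([(39, "GTCTTGGAATAGG"), (129, "TTCTCATGT")])
        text = serialize_signature(sig)
        lines = text.splitlines()
        assert lines[0] == (
            "#species=Croton gratissimus\t#exemplar=EU214230.1\t#span=39-129"
            .replace("39-129", "39-137")
        )
        assert lines[1] == "GTCTTGGAATAGG.{77}TTCTCATGT"

    def test_round_trip_identity(self):
        sig = sig_from([(39, "GTCTTGGAATAGG"), (129, "TTCTCATGT"), (735, "ACGT")])
        back = parse_signature(serialize_signature(sig))
        assert back.species == sig.species
        assert back.exemplar_id == sig.exemplar_id
        assert back.regex == sig.regex
        assert back.span == sig.span
        assert back.gaps == sig.gaps

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.text(alphabet="ACGT", min_size=1, max_size=12)),
            min_size=1, max_size=6,
        ),
        st.integers(1, 200),
    )
    def test_round_trip_on_random_signatures(self, chunks, first_start):
        pats = []
        pos = first_start
        for gap, literal in chunks:
            pats.append(Pattern(start=pos, literal=literal))
            pos += len(literal) + gap + 1  # +1 keeps patterns non-adjacent
        sig = assemble_signature("Aa bb", pats, exemplar_id="X1")
        back = parse_signature(serialize_signature(sig))
        assert back.regex == sig.regex
        assert back.span == sig.span

    def test_malformed_text_rejected(self):
        with pytest.raises(BarcodeError):
            parse_signature("not a signature\nACGT\n")
        with pytest.raises(BarcodeError):
            parse_signature("#species=X y\t#exemplar=a\t#span=1-9\nAC?GT\n")


class TestEvaluation:
    def test_formula_arithmetic(self):
        r = EvaluationReport(tp=3, fp=0, fn=1)
        assert r.recall == 0.75
        assert r.precision == 1.0
        assert r.f_measure == pytest.approx(6 / 7)
        assert r.category == "A"

    def test_zero_tp_degenerate_convention(self):
        r = EvaluationReport(tp=0, fp=0, fn=4)
        assert r.recall == 0.0 and r.precision == 0.0 and r.f_measure == 0.0
        assert r.category == "D"

    def test_perfect_classifier_identity(self):
        sig = sig_from([(1, "AAACCC")])
        targets = ["AAACCCGGTT", "TTAAACCCAA"]
        others = ["GGGGTTTT", "CACACACA"]
        r = evaluate_signature(sig, targets, others)
        assert (r.recall, r.precision, r.f_measure) == (1.0, 1.0, 1.0)

    def test_counts_sequences_not_occurrences(self):
        sig = sig_from([(1, "ACAC")])
        r = evaluate_signature(sig, ["ACACACACAC"], [])
        assert r.tp == 1


class TestCategorize:
    @pytest.mark.parametrize(
        "f,cat",
        [(0.75, "A"), (1.0, "A"), (0.0, "D"), (0.4999, "C"), (0.5, "B"),
         (0.25, "C"), (0.2499, "D"), (0.7499, "B")],
    )
    def test_half_open_boundaries(self, f, cat):
        assert categorize(f) == cat

    def test_exhaustive_grid_is_monotone(self):
        order = {"D": 0, "C": 1, "B": 2, "A": 3}
        cats = [order[categorize(i / 1000)] for i in range(1001)]
        assert cats == sorted(cats)

    def test_out_of_range_rejected(self):
        with pytest.raises(BarcodeError):
            categorize(1.2)


class TestSelectCandidate:
    def s(self, regex_len=4, n_pat=1, start=1):
        pats = [Pattern(start=start + 10 * i, literal="A" * regex_len)
                for i in range(n_pat)]
        return assemble_signature("X y", pats)

    def test_highest_f_wins(self):
        a = (self.s(), EvaluationReport(9, 1, 0))   # F ~ 0.947
        b = (self.s(), EvaluationReport(8, 0, 2))   # F = 0.888
        assert select_candidate([a, b]) is a[0]

    def test_recall_breaks_f_ties(self):
        a = (self.s(), EvaluationReport(tp=2, fp=1, fn=0))  # P=2/3 R=1 F=0.8
        b = (self.s(), EvaluationReport(tp=2, fp=0, fn=1))  # P=1 R=2/3 F=0.8
        assert select_candidate([a, b]) is a[0]

    def test_fewer_patterns_break_remaining_ties(self):
        a = (self.s(n_pat=1), EvaluationReport(1, 0, 0))
        b = (self.s(n_pat=2), EvaluationReport(1, 0, 0))
        assert select_candidate([b, a]) is a[0]

    def test_single_candidate_returned(self):
        only = (self.s(), EvaluationReport(0, 0, 1))
        assert select_candidate([only]) is only[0]

    def test_empty_list_rejected(self):
        with pytest.raises(BarcodeError):
            select_candidate([])


def _exemplar(seq):
    return BarcodeRecord(id="EX1", genus="Poa", species="Poa annua",
                         locus="matK", seq=seq)


class TestRefinement:
    def poa_fixture(self):
        """Two species identical except one G/C substitution at pos 40."""
        base = "".join("ACGT"[i % 4] for i in range(80))
        target = base[:39] + "G" + base[40:]
        decoy = base[:39] + "C" + base[40:]
        ex = _exemplar(target)
        # initial signature from a conserved window: matches both species
        init = assemble_signature(
            "Poa annua", [Pattern(start=5, literal=target[4:14])],
            exemplar_id="EX1",
        )
        site = DiscriminatingSite(
            column=40, level="species",
            alleles=(("Poa annua", "G"), ("Poa compressa", "C")),
        )
        return ex, target, decoy, init, site

    def test_single_bp_site_eliminates_false_positive(self):
        ex, target, decoy, init, site = self.poa_fixture()
        assert evaluate_signature(init, [target], [decoy]).fp == 1
        refined, traj = refine_signature(
            init, [target], [decoy], [site], ex, ex.seq, flank=6
        )
        report = evaluate_signature(refined, [target], [decoy])
        assert report.fp == 0 and report.tp == 1
        assert len(traj) == 2

    def test_fixpoint_when_no_false_positives(self):
        ex, target, decoy, init, site = self.poa_fixture()
        good = incorporate_site(init, site, ex, ex.seq, flank=6)
        refined, traj = refine_signature(
            good, [target], [decoy], [site], ex, ex.seq
        )
        assert refined is good and traj == [good]

    def test_monotone_fp_decrease_tp_preserved(self):
        # 2 decoy species, 3 spare planted sites; verify against the
        # exhaustive subset-search oracle
        base = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(120))
        tgt = list(base)
        d1 = list(base)
        d2 = list(base)
        for pos, allele in [(30, "A"), (60, "C"), (90, "A")]:
            tgt[pos - 1] = allele
        d1[30 - 1] = "A"  # decoy 1 shares site 30 with the target
        d2[60 - 1] = "C"  # decoy 2 shares site 60
        target, decoy1, decoy2 = "".join(tgt), "".join(d1), "".join(d2)
        ex = _exemplar(target)
        sites = [
            DiscriminatingSite(column=c, level="species",
                               alleles=(("t", a), ("o", "T")))
            for c, a in [(30, "A"), (60, "C"), (90, "A")]
        ]
        init = assemble_signature(
            "Poa annua", [Pattern(start=1, literal=target[0:10])], exemplar_id="EX1"
        )
        refined, traj = refine_signature(
            init, [target], [decoy1, decoy2], sites, ex, ex.seq, flank=6
        )
        reports = [evaluate_signature(s, [target], [decoy1, decoy2]) for s in traj]
        for before, after in zip(reports, reports[1:]):
            assert after.fp <= before.fp
            assert after.tp >= before.tp
        assert reports[-1].fp == 0

        # oracle: smallest site subset achieving FP = 0 has size 1 (site 90)
        best_size = None
        for k in range(0, 4):
            for combo in itertools.combinations(sites, k):
                sig = init
                for s in combo:
                    sig = incorporate_site(sig, s, ex, ex.seq, flank=6)
                r = evaluate_signature(sig, [target], [decoy1, decoy2])
                if r.fp == 0 and r.tp == 1:
                    best_size = k
                    break
            if best_size is not None:
                break
        assert best_size == 1  # site 90 alone separates target from both decoys
        assert len(traj) - 1 == best_size  # greedy found the minimum

    def test_unhelpful_pool_flagged(self):
        ex, target, decoy, init, _ = self.poa_fixture()
        useless = DiscriminatingSite(
            column=10, level="species", alleles=(("a", "A"), ("b", "C"))
        )
        with pytest.warns(UserWarning, match="false positives"):
            refined, _ = refine_signature(
                init, [target], [decoy], [useless], ex, ex.seq
            )
        assert evaluate_signature(refined, [target], [decoy]).fp == 1


class TestGapBreakDiagnosis:
    def test_indel_between_patterns_reported(self):
        sig = sig_from([(1, "AAAA"), (15, "CCCC")])  # gap of 10
        broken = "AAAA" + "G" * 9 + "CCCC"  # one base deleted from the gap
        (problem,) = diagnose_gap_breaks(sig, broken)
        assert problem["expected"] == 10 and problem["observed"] == 9

    def test_matching_sequence_reports_nothing(self):
        sig = sig_from([(1, "AAAA"), (15, "CCCC")])
        ok = "AAAA" + "G" * 10 + "CCCC"
        assert diagnose_gap_breaks(sig, ok) == []
        assert sig.search(ok) is not None

    def test_missing_pattern_reported(self):
        sig = sig_from([(1, "AAAA"), (15, "CCCC")])
        assert diagnose_gap_breaks(sig, "AAAA" + "G" * 20)[0]["observed"] is None


class TestExemplarInvariant:
    def test_signature_always_matches_its_exemplar(self, clean_alignment):
        from barcodesig.pipeline import discover_sites, generate_species_signature
        genus_sites, species_sites = discover_sites(clean_alignment)
        for sp in sorted({r.species for r in clean_alignment.records}):
            res = generate_species_signature(
                sp, clean_alignment, genus_sites, species_sites[sp.split()[0]]
            )
            exemplar = next(
                r for r in clean_alignment.records if r.id == res.signature.exemplar_id
            )
            m = res.signature.search(exemplar.ungapped)
            assert m is not None
            assert m.start() + 1 == res.signature.span[0]
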